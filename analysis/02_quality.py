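"""Windowed SCI/PSP channel-quality screen: mark poorly coupled channels
and fully noisy participants for exclusion."""

from config import analysis_config
from fnirsevents.pipeline_cli import stage_qc

result = stage_qc(analysis_config())
for pid, channels in sorted(result["included_channels"].items()):
    print(f"{pid}: {len(channels)} channels included")
if result["excluded_participants"]:
    print("participants excluded entirely:",
          result["excluded_participants"])
else:
    print("no participant excluded entirely")
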