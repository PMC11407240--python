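"""Generate the seeded synthetic study: raw dual-wavelength recordings,
per-participant condition timelines, questionnaire scores and the
ground-truth event manifest."""

from config import analysis_config, OUT_DIR
from fnirsevents.pipeline_cli import stage_simulate

result = stage_simulate(analysis_config())
print(f"wrote {result['n_participants']} participants to {OUT_DIR}")
print("participants:", ", ".join(result["participants"]))
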