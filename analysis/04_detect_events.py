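"""Automatic functional-event detection: grid search over every
(onset, duration) boxcar convolved with the canonical HRF, greedy
collection with joint refitting and pruning, one event list per
channel."""

from config import analysis_config, OUT_DIR
from fnirsevents.pipeline_cli import stage_detect

result = stage_detect(analysis_config())
print(f"detected {result['n_events']} functional events"
      f" -> {OUT_DIR / 'events.tsv'}")
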