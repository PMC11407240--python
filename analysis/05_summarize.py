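"""Condition assignment and participant-level parameters: per channel and
condition cell, the event count, mean duration, mean and maximum GLM
t-value, raw and normalised by the cell duration."""

from config import analysis_config, OUT_DIR
from fnirsevents.pipeline_cli import stage_summarize

result = stage_summarize(analysis_config())
print(f"{result['n_rows']} participant x channel x cell rows"
      f" -> {OUT_DIR / 'param_table.tsv'}")
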