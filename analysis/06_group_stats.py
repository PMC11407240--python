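"""Group statistics: channel-wise Fragranced vs Unfragranced paired
t-tests with KS normality screening and Benjamini-Hochberg correction,
plus brain-questionnaire Pearson correlations."""

import pandas as pd

from config import analysis_config, OUT_DIR
from fnirsevents.pipeline_cli import stage_stats

result = stage_stats(analysis_config())
print(f"{result['paired_tests']} paired tests,"
      f" {result['correlations']} correlations -> {OUT_DIR}")
tests = pd.read_csv(OUT_DIR / "paired_tests.tsv", sep="\t")
sig = tests[tests.significant_unc.fillna(False)]
print(f"{len(sig)} uncorrected-significant contrasts"
      f" ({int(tests.significant_fdr.fillna(False).sum())} survive FDR)")
if len(sig):
    cols = ["channel", "parameter", "task", "n_pairs", "t", "p"]
    print(sig[cols].to_string(index=False))
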