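"""Haemodynamic preprocessing: optical density, wavelet motion
correction, 0.01-0.3 Hz band-pass, Beer-Lambert concentrations, CBSI
activation signals down-sampled to 1 Hz."""

from config import analysis_config
from fnirsevents.pipeline_cli import stage_preprocess

result = stage_preprocess(analysis_config())
print("activation signals written for:", ", ".join(result["preprocessed"]))
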