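"""Shared configuration for the numbered analysis drivers.

A compact synthetic study (4 participants, 8 channels, the default noise
and event conditions) keeps every step runnable in a couple of minutes
while exercising the full chain. All outputs go to results/analysis/.
"""

from pathlib import Path

from fnirsevents.pipeline_cli import load_config

OUT_DIR = Path(__file__).resolve().parent.parent / "results" / "analysis"


def analysis_config():
    return load_config(None, {
        "paths": {"output_dir": str(OUT_DIR)},
        "seed": 7,
        "synth": {"n_participants": 4, "n_channels": 8},
        "log_level": "WARNING",
    })
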