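"""Shared configuration for the numbered analysis scripts.

All scripts operate on one run directory (results/study) produced by
01_generate_world.py, at the default study conditions: a 300-drug x 150-HLT
world, a strong-signal ground-truth link model, and two follow-up snapshots
with asymmetric accrual, extra-link noise, and frequency missingness.
"""

from pathlib import Path

from adeconcord.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 1


def study_config(stages) -> RunConfig:
    return RunConfig(outdir=RESULTS, seed=SEED, stages=tuple(stages))
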