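"""Generate the synthetic study world.

Writes the controlled vocabularies (synonyms, ATC, MedDRA PT→HLT→SOC), the
per-drug property vectors, and three raw PT-level snapshots (training-era
base plus two later follow-ups) under results/study/. Drug names in the raw
snapshots are random synonyms and terms are PTs, so the harmonization stage
has real work to do.
"""

import json

from common import RESULTS, study_config

from adeconcord.pipeline import run_pipeline

run_pipeline(study_config(["generate"]))

truth = json.loads((RESULTS / "truth.json").read_text())
n_raw = {p.stem: sum(1 for _ in open(p)) - 1 for p in (RESULTS / "raw").glob("*.tsv")}
print("generated synthetic world under", RESULTS)
print("ground-truth coefficients:", dict(zip(truth["covariates"], truth["beta"][1:])))
print("raw snapshot rows:", n_raw)
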