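"""Harmonize the raw snapshots onto canonical drug ids and MedDRA HLT level.

Raw drug names are standardized through the synonym table and PT terms are
expanded to their HLT(s); the harmonized HLT-level tables drive every later
stage.
"""

from common import RESULTS, study_config

from adeconcord.io import read_snapshot
from adeconcord.pipeline import run_pipeline

run_pipeline(study_config(["harmonize"]))

for p in sorted((RESULTS / "harmonized").glob("*.tsv")):
    s = read_snapshot(p)
    print(f"{s.source}: {len(s.pairs)} (drug, HLT) pairs over "
          f"{len(s.drugs)} drugs and {len(s.terms)} HLTs")
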