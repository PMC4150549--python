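"""Validate the fitted model against both follow-ups as reference standards.

For each follow-up, positives are its new links over the base within the
common vocabularies and negatives are all other non-base pairs; every such
pair is scored with the trained model and AUROC (with stratified-bootstrap
CI), the ROC polyline, and per-SOC stratified AUROCs with relative changes
are written. Finishes by aggregating everything into report.json.
"""

import json

from common import RESULTS, study_config

from adeconcord.pipeline import run_pipeline

report = run_pipeline(study_config(["validate", "report"]))

for label, v in report["validation"].items():
    lo, hi = v["ci"]
    print(f"AUROC vs reference {label}: {v['auroc']:.3f} "
          f"(95% CI {lo:.3f}-{hi:.3f}; {v['n_pos']} positives, "
          f"{v['n_neg']} negatives)")
print(f"relative change in overall AUROC between references: "
      f"{report['auroc_relative_change_pct']}%")
flagged = [l.split("\t")[0] for l in
           (RESULTS / "validation" / "stratified_auroc.tsv").read_text().splitlines()[1:]
           if l.endswith("\t1")]
print(f"SOC strata flagged for insufficient positives/negatives: "
      f"{flagged or 'none'}")
print("aggregated study report written to", RESULTS / "report.json")
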