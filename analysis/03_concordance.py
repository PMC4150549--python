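"""Compare the two follow-up snapshots: correlation, accrual, breakdowns.

Restricts both follow-ups (and the base) to their common drug/HLT
vocabularies, then reports Spearman correlations of per-drug ADE counts and
per-HLT drug counts with bootstrap CIs, new-association accrual rates, and
ATC/SOC/frequency breakdowns of the B-only surplus.
"""

import json

from common import RESULTS, study_config

from adeconcord.pipeline import run_pipeline

run_pipeline(study_config(["concord"]))

conc = json.loads((RESULTS / "concordance" / "concordance.json").read_text())
rho_a, lo_a, hi_a = conc["rho_ade"]
rho_d, lo_d, hi_d = conc["rho_drug"]
print(f"common vocabulary: {conc['common_drugs']} drugs "
      f"({conc['drug_overlap_pct']}%), {conc['common_terms']} HLTs "
      f"({conc['term_overlap_pct']}%)")
print(f"Spearman rho, ADE counts per drug: {rho_a:.3f} (95% CI {lo_a:.3f}-{hi_a:.3f})")
print(f"Spearman rho, drug counts per HLT: {rho_d:.3f} (95% CI {lo_d:.3f}-{hi_d:.3f})")
print(f"new associations: A {conc['n_new_a']} ({conc['rate_a']:.0f}/yr), "
      f"B {conc['n_new_b']} ({conc['rate_b']:.0f}/yr); "
      f"B-only {conc['n_b_only']}, frequency missing for "
      f"{conc['freq_missing_share']:.1f}% of them")
top = (RESULTS / "concordance" / "breakdown_atc.tsv").read_text().splitlines()[1]
print("largest ATC share of the B-only surplus:", top.replace("\t", "  "))
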