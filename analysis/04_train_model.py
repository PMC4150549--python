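"""Fit the bipartite logistic link-prediction model on the base snapshot.

Builds the drugs x HLTs network, computes the twelve network/taxonomic/
intrinsic covariates for every pair, and fits the Bernoulli logistic model
by penalized maximum likelihood. Coefficients, standard errors and the
frozen standardization constants go to results/study/model/model.json.
"""

import json

from common import RESULTS, study_config

from adeconcord.pipeline import run_pipeline

run_pipeline(study_config(["train"]))

model = json.loads((RESULTS / "model" / "model.json").read_text())
print(f"fit converged in {model['n_iter']} Newton steps; "
      f"log-likelihood {model['loglik']:.1f}")
print("coefficient (z-score) by covariate:")
for name, b, se in zip(model["columns"], model["beta_hat"], model["se"]):
    print(f"  {name:28s} {b:+7.3f}  (z = {b / se:+6.1f})")
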