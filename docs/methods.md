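# Methods

## Harmonization

Snapshot tables arrive as raw (drug name, term) pairs at the MedDRA
Preferred Term (PT) level with optional frequency annotations. Drug names
are case-normalized (lowercase, trimmed, internal whitespace collapsed)
before synonym lookup; canonical identifiers always map to themselves, so
standardization is idempotent. Unmapped names raise under the `strict`
policy and are kept (case-normalized, counted) under `passthrough`;
`strict` is the default in library code and tests, `passthrough` in the
pipeline, because real vocabularies are always incomplete.

PT→HLT mapping is one-to-many: each (drug, PT) expands to one pair per
mapped HLT and the result is deduplicated. When PTs with different
frequency classes collapse onto one (drug, HLT), the class earliest in the
fixed order **exact-number > frequent > infrequent > rare > postmarketing >
potential > missing** wins. This order is this package's choice — it
prefers the more informative annotation and makes the expansion
deterministic; no external convention exists for the conflict.

Vocabulary intersection reports integer-rounded percentages relative to the
first snapshot's vocabulary. Breakdown-table percentages are rounded
half-up to one decimal, matching the usual presentation of such tables.

## Concordance statistics

Per-drug ADE counts and per-HLT drug counts are compared between the two
later snapshots with Spearman rank correlation (mid-ranks for ties; point
estimate via `scipy.stats.spearmanr`). The 95% CI is a paired percentile
bootstrap (default 2,000 replicates, seeded); a Fisher-z normal
approximation is available as an alternative. Bootstrap replicates with
zero rank variance are dropped rather than imputed.

Accrual rates divide new-association counts by the real-valued difference
of the snapshots' manifest years; the denominator is explicit input, never
inferred. Each B-only association is attributed exactly once in every
breakdown: to the top-level group of the drug's *primary* (first-listed)
ATC code, and to the HLT's *primary* SOC. Single attribution keeps the ATC
and SOC tables summing to the same total. The frequency breakdown reports
the missing share over all B-only pairs and a conditional table over the
non-missing remainder.

## Link-prediction model

The twelve covariates are defined in `ppn.py` with explicit totality
conventions: isolated drugs or terms get zeros (via `max(1, ·)`
denominators and zero-empty-set rules), so no pair is ever NaN. Covariates
are z-standardized over the training pair set; the constants are frozen in
the fit result and reused at scoring time, so validation pairs never
influence the scaling. Covariates for held-out pairs are always computed
from the *training* network — the scoring population is exactly "pairs not
reported in the training data".

Training labels cover all drug×term pairs of the vocabulary universe
(positives = network links, negatives = everything else); negative
subsampling exists as an option but is off by default. The fit is Newton's
method with step-halving on the penalized log-likelihood, ridge 1e-6 on
non-intercept terms to stabilize near-separation, convergence at max
absolute gradient < 1e-6, and standard errors from the inverse observed
information (pseudo-inverse when the design is rank-deficient, e.g.
constant columns). At ridge 0, complete separation is detected (perfect
classification with saturated predictions) and raises rather than
returning a diverging estimate.

## Validation

A reference standard's positives are the validation snapshot's new links
over the training snapshot within the common vocabularies; negatives are
all other non-training pairs of that universe. AUROC uses the mid-rank
Mann–Whitney formula (ties half-credited); the ROC polyline has one point
per distinct threshold, and its trapezoidal area equals the rank-formula
AUROC to machine precision. CIs are stratified percentile bootstraps
(positives and negatives resampled independently, 1,000 replicates,
seeded); no analytic (DeLong) variance is provided. SOC strata with fewer
than 2 positives or 2 negatives in either reference are flagged, never
silently dropped. Relative change between references uses the first
(earlier-style) reference's AUROC as denominator, rounded half-up to the
configured precision. Case-study metrics threshold at the queried pair's
own score: specificity counts negatives strictly below it, PPV counts
positives at-or-above among all pairs at-or-above.

## Synthetic worlds

The generator emulates the study's data environment: drugs with synonyms
(Poisson-distributed aliases), 1–2 ATC codes drawn from a shared pool so
pharmacological classes hold several drugs, HLTs with one primary SOC, PTs
partitioned among HLTs with 15% mapping to two HLTs (exercising the
expansion logic), and standard-normal drug property vectors.

Base-snapshot generation is two-stage to break the circularity that
covariates depend on the network being generated: a uniform scaffold
network (density 0.10) is drawn first, the twelve covariates are computed
on it, and the base snapshot is sampled per-pair from
`sigmoid(β·x_scaffold)`. Follow-ups are supersets of the base: non-base
pairs enter with probability `accrual_intensity · sigmoid(β·x)` (same
ground-truth scores, hence predictable by a well-fitted model), plus
uniform extra links whose odds can be multiplied inside chosen ATC/SOC
categories to create one-sided category skew. Frequency classes are drawn
from a categorical distribution with postmarketing heaviest (46/16/16/11/8/3
percent across the six classes), masked at each snapshot's missingness rate.

Two preset coefficient vectors define the study conditions. The `null`
preset is intercept-only (density ≈ sigmoid(β₀); default −2.8 ≈ 5.7%,
comparable to real drug–HLT networks): downstream AUROC must be ≈ 0.5. The
`strong` preset spreads the linear predictor over ≈ 5 logits, reproducing
the ≈ 0.85 held-out AUROC regime reported for real ADE link-prediction
models; its intercept −6.5 yields base densities of 10–14%. The default
follow-up schedule has A (year 2010) accruing at intensity 0.35 with extra
rate 0.002 and 30% frequency missingness, and B (year 2012) at 0.85 / 0.008
/ 63% — a faster-growing, noisier, worse-annotated dataset, the qualitative
asymmetry observed between public and commercial ADE sources. The
accrual-only variant (`clean_snapshot_specs`) zeroes the extra rates and is
the condition for signal- and null-recoverability checks.

All randomness flows from one integer seed through labeled CRC32-derived
sub-streams, so adding a snapshot spec never shifts earlier draws and every
output is a pure function of (config, seed).

What the generator does **not** emulate: real chemical structure, real
ATC/MedDRA code semantics, text-mining extraction noise beyond uniform
extras, or any dependence between the two follow-ups beyond their shared
ground truth. Passing tests therefore demonstrate correctness of the
pipeline's operations and recoverability of a known generating model — not
performance claims about any real dataset pair.

## Problem sizes and numerical choices

Recoverability and robustness checks run 20 seeds at 300 drugs × 150 HLTs
(45,000 pairs, 13 coefficients), the scale at which coefficient standard
errors are small enough for 3·SE coverage checks to bite while a full
20-seed sweep stays comfortable on one CPU. Oracle-equivalence checks
(AUROC rank formula vs exhaustive pairwise comparison, Spearman vs the d²
formula, logistic MLE vs grid search) use instances small enough for the
brute-force oracle to be exact. Pipeline determinism is checked by running
the file-based pipeline twice at one seed and comparing SHA-256 digests of
every output file.

Degenerate inputs are first-class: fewer than 3 paired counts or zero rank
variance, all-one-class labels, empty reference positives, and strata too
small to bootstrap all raise typed errors (or are flagged) rather than
returning NaN.

## Known limitations

* The twelve covariates are this package's canonical set, chosen to honor
  the three-family structure (network / taxonomic / intrinsic); published
  models of this kind do not standardize an exact covariate list, and the
  set is pluggable behind the named-column interface.
* The percentile bootstrap CIs are first-order; no BCa correction.
* The generator's shared-truth + independent-extras dependence model
  between follow-ups is an assumption; real dataset pairs share upstream
  sources in ways it does not capture.
* Training on the full negative universe is quadratic in vocabulary sizes;
  for much larger worlds enable negative subsampling.
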