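"""Temporal-holdout validation of link-prediction scores.

A *reference standard* for a validation snapshot consists of positives (its
new links over the training snapshot, within the common vocabularies) and
negatives (every other non-training pair over the same vocabularies). AUROC
uses the mid-rank Mann–Whitney formula with half-credit ties; confidence
intervals come from a stratified percentile bootstrap. Stratified AUROC by
SOC and the relative change between two reference standards reproduce the
table-level comparisons this pipeline exists for.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import CoverageError, DegenerateInputError
from .vocab import AssociationSnapshot, MeddraMap

Pair = tuple[str, str]
ScoreTable = dict[Pair, float]


@dataclass(frozen=True)
class ReferenceStandard:
    positives: frozenset[Pair]
    negatives: frozenset[Pair]
    label: str

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise DegenerateInputError("positives and negatives overlap")


def build_reference(training: AssociationSnapshot, validation: AssociationSnapshot,
                    common_drugs: set[str], common_terms: set[str],
                    label: str | None = None) -> ReferenceStandard:
    """Positives = validation-only links within the common universe;
    negatives = all remaining non-training pairs of that universe."""
    universe = {(d, t) for d in common_drugs for t in common_terms}
    training_pairs = set(training.pairs) & universe
    positives = (set(validation.pairs) - set(training.pairs)) & universe
    if not positives:
        raise DegenerateInputError(
            f"validation snapshot {validation.source!r} adds no new links in "
            "the common universe")
    negatives = universe - training_pairs - positives
    return ReferenceStandard(frozenset(positives), frozenset(negatives),
                             label or validation.source)


def _score_arrays(scores: ScoreTable,
                  ref: ReferenceStandard) -> tuple[np.ndarray, np.ndarray]:
    try:
        pos = np.asarray([scores[p] for p in sorted(ref.positives)])
        neg = np.asarray([scores[p] for p in sorted(ref.negatives)])
    except KeyError as e:
        raise CoverageError(f"score table missing pair {e.args[0]!r}") from None
    return pos, neg


def _auroc_from_arrays(pos: np.ndarray, neg: np.ndarray) -> float:
    # mid-rank Mann-Whitney: ties between classes get half credit
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc(scores: ScoreTable, ref: ReferenceStandard) -> float:
    """Probability a random positive outscores a random negative."""
    pos, neg = _score_arrays(scores, ref)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError("need at least one positive and one negative")
    return _auroc_from_arrays(pos, neg)


def auroc_ci(scores: ScoreTable, ref: ReferenceStandard, *, n_boot: int = 1000,
             seed: int = 0, conf: float = 0.95) -> tuple[float, float]:
    """Stratified percentile bootstrap CI (positives and negatives resampled
    independently)."""
    pos, neg = _score_arrays(scores, ref)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateInputError("need >= 2 positives and >= 2 negatives for a CI")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pb = pos[rng.integers(0, len(pos), len(pos))]
        nb = neg[rng.integers(0, len(neg), len(neg))]
        reps[b] = _auroc_from_arrays(pb, nb)
    alpha = 1.0 - conf
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RocResult:
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), thresholds descending
    thresholds: tuple[float, ...]
    auroc: float
    n_pos: int
    n_neg: int


def roc_curve(scores: ScoreTable, ref: ReferenceStandard) -> RocResult:
    """ROC polyline with one point per distinct score threshold.

    The trapezoidal area of the returned points equals the rank-formula AUROC
    exactly (ties produce diagonal segments whose trapezoids give half
    credit).
    """
    pos, neg = _score_arrays(scores, ref)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError("need at least one positive and one negative")
    all_scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-all_scores, kind="stable")
    s_sorted = all_scores[order]
    y_sorted = labels[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [len(s_sorted) - 1]])
    tp = np.cumsum(y_sorted)[cut]
    fp = np.cumsum(1 - y_sorted)[cut]
    tpr = tp / len(pos)
    fpr = fp / len(neg)
    points = [(0.0, 0.0)] + list(zip(fpr.tolist(), tpr.tolist()))
    thresholds = s_sorted[cut].tolist()
    area = float(np.trapezoid([p[1] for p in points], [p[0] for p in points]))
    return RocResult(tuple(points), tuple(thresholds), area, len(pos), len(neg))


@dataclass(frozen=True)
class StratumRow:
    soc: str
    auroc_a: float | None
    ci_a: tuple[float, float] | None
    auroc_b: float | None
    ci_b: tuple[float, float] | None
    relative_change_pct: float | None
    flagged: bool  # too few positives/negatives in a stratum


def relative_change(a: float, b: float, decimals: int = 0) -> float:
    """100·(a − b)/a, rounded half-up; the first reference standard's AUROC
    is the denominator."""
    if a <= 0:
        raise DegenerateInputError("reference AUROC must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * (a - b) / a).quantize(q, rounding=ROUND_HALF_UP))


def _restrict_to_soc(ref: ReferenceStandard, soc: str,
                     meddra: MeddraMap) -> ReferenceStandard | None:
    pos = frozenset(p for p in ref.positives if meddra.primary_soc(p[1]) == soc)
    neg = frozenset(p for p in ref.negatives if meddra.primary_soc(p[1]) == soc)
    if len(pos) < 2 or len(neg) < 2:
        return None
    return ReferenceStandard(pos, neg, f"{ref.label}:{soc}")


def stratified_auroc(scores_a: ScoreTable, ref_a: ReferenceStandard,
                     scores_b: ScoreTable, ref_b: ReferenceStandard,
                     meddra: MeddraMap, *, n_boot: int = 1000, seed: int = 0,
                     change_decimals: int = 0) -> tuple[StratumRow, ...]:
    """Per-SOC AUROC under both reference standards plus relative change.

    SOCs with fewer than 2 positives or 2 negatives in either reference are
    returned flagged (AUROCs None), never silently dropped.
    """
    socs = sorted({meddra.primary_soc(t)
                   for p in (ref_a.positives | ref_a.negatives |
                             ref_b.positives | ref_b.negatives)
                   for t in [p[1]]})
    rows = []
    for k, soc in enumerate(socs):
        ra = _restrict_to_soc(ref_a, soc, meddra)
        rb = _restrict_to_soc(ref_b, soc, meddra)
        if ra is None or rb is None:
            rows.append(StratumRow(soc, None, None, None, None, None, True))
            continue
        a = auroc(scores_a, ra)
        b = auroc(scores_b, rb)
        change = relative_change(a, b, change_decimals) if a > 0 else None
        rows.append(StratumRow(
            soc, a, auroc_ci(scores_a, ra, n_boot=n_boot, seed=seed + 2 * k),
            b, auroc_ci(scores_b, rb, n_boot=n_boot, seed=seed + 2 * k + 1),
            change, False))
    return tuple(rows)


def case_study_metrics(scores: ScoreTable, ref: ReferenceStandard,
                       pair: Pair) -> tuple[float, float]:
    """Specificity and PPV at the threshold set by one pair's own score.

    specificity = fraction of negatives scored strictly below the pair;
    PPV = positives at-or-above the threshold over all pairs at-or-above.
    """
    if pair not in ref.positives and pair not in ref.negatives:
        raise CoverageError(f"pair {pair!r} is not in the reference standard")
    if pair not in scores:
        raise CoverageError(f"pair {pair!r} has no score")
    t = scores[pair]
    pos, neg = _score_arrays(scores, ref)
    specificity = float(np.mean(neg < t))
    n_above = int(np.sum(pos >= t) + np.sum(neg >= t))
    ppv = float(np.sum(pos >= t) / n_above) if n_above else 0.0
    return specificity, ppv
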