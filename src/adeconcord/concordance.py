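"""Concordance analysis between two harmonized ADE snapshots.

Per-entity counts, Spearman rank correlations with bootstrap CIs, new
associations relative to a baseline snapshot and their annual accrual rates,
and breakdowns of one dataset's surplus (B-only) associations by ATC
top-level drug category, MedDRA SOC, and frequency class.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import DegenerateInputError
from .vocab import (FREQUENCY_CLASSES, AssociationSnapshot, AtcMap, MeddraMap)

Pair = tuple[str, str]


def count_per_drug(s: AssociationSnapshot, drugs: set[str]) -> dict[str, int]:
    """Distinct HLTs per drug, with explicit zeros for unlinked drugs."""
    counts = dict.fromkeys(drugs, 0)
    for d, _ in s.pairs:
        if d in counts:
            counts[d] += 1
    return counts


def count_per_term(s: AssociationSnapshot, terms: set[str]) -> dict[str, int]:
    """Distinct drugs per HLT, with explicit zeros for unlinked terms."""
    counts = dict.fromkeys(terms, 0)
    for _, t in s.pairs:
        if t in counts:
            counts[t] += 1
    return counts


def spearman_ci(x: dict[str, int], y: dict[str, int], *, n_boot: int = 2000,
                seed: int = 0, conf: float = 0.95,
                method: str = "bootstrap") -> tuple[float, float, float]:
    """Spearman rho between two count vectors sharing a key set, with CI.

    The point estimate is the Pearson correlation of mid-ranked values. The
    default CI is a paired percentile bootstrap (seeded); ``method="fisher"``
    gives the Fisher-z normal approximation instead.
    """
    if set(x) != set(y):
        raise DegenerateInputError("count vectors must share one key set")
    keys = sorted(x)
    if len(keys) < 3:
        raise DegenerateInputError("need at least 3 paired observations")
    xv = np.asarray([x[k] for k in keys], dtype=float)
    yv = np.asarray([y[k] for k in keys], dtype=float)
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise DegenerateInputError("zero variance in a count vector")
    rho = float(stats.spearmanr(xv, yv).statistic)
    alpha = 1.0 - conf
    if method == "fisher":
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(len(keys) - 3)
        q = stats.norm.ppf(1 - alpha / 2)
        return rho, float(np.tanh(z - q * se)), float(np.tanh(z + q * se))
    rng = np.random.default_rng(seed)
    n = len(keys)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = xv[idx], yv[idx]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            reps[b] = np.nan
            continue
        reps[b] = stats.spearmanr(xb, yb).statistic
    reps = reps[~np.isnan(reps)]
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return rho, float(min(lo, rho)), float(max(hi, rho))


def new_associations(baseline: AssociationSnapshot,
                     later: AssociationSnapshot) -> set[Pair]:
    """Pairs reported in ``later`` but not in ``baseline``."""
    return set(later.pairs) - set(baseline.pairs)


def annual_rate(new_set: set[Pair], elapsed_years: float) -> float:
    """New associations per year over the elapsed period."""
    if elapsed_years <= 0:
        raise DegenerateInputError("elapsed_years must be positive")
    return len(new_set) / elapsed_years


def difference_set(new_a: set[Pair], new_b: set[Pair]) -> set[Pair]:
    """Associations newly reported only by dataset B."""
    return set(new_b) - set(new_a)


def percent_round(count: int, total: int, decimals: int = 1) -> float:
    """100·count/total rounded half-up to ``decimals`` places (table style)."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * count / total).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BreakdownTable:
    dimension: str  # "ATC" | "SOC" | "frequency"
    rows: tuple[tuple[str, int, float], ...]  # (label, count, percent)
    total: int

    def counts(self) -> dict[str, int]:
        return {label: n for label, n, _ in self.rows}

    def percents(self) -> dict[str, float]:
        return {label: pct for label, _, pct in self.rows}


def _make_table(dimension: str, counts: dict[str, int]) -> BreakdownTable:
    total = sum(counts.values())
    rows = tuple(sorted(((label, n, percent_round(n, total))
                         for label, n in counts.items()),
                        key=lambda r: (-r[1], r[0])))
    return BreakdownTable(dimension, rows, total)


def breakdown_by_atc(assoc: set[Pair], atc: AtcMap) -> BreakdownTable:
    """Attribute each association once, to the top-level group of its drug's
    primary ATC code."""
    counts: dict[str, int] = {}
    for d, _ in assoc:
        label = AtcMap.top_level(atc.primary_code(d))
        counts[label] = counts.get(label, 0) + 1
    return _make_table("ATC", counts)


def breakdown_by_soc(assoc: set[Pair], meddra: MeddraMap) -> BreakdownTable:
    """Attribute each association once, to its HLT's primary SOC."""
    counts: dict[str, int] = {}
    for _, h in assoc:
        label = meddra.primary_soc(h)
        counts[label] = counts.get(label, 0) + 1
    return _make_table("SOC", counts)


def breakdown_by_frequency(assoc: set[Pair],
                           snapshot: AssociationSnapshot
                           ) -> tuple[float, BreakdownTable]:
    """Missing share over all associations, and the conditional class table
    over the non-missing remainder (its percents sum to 100 within rounding)."""
    classes = {p: snapshot.frequency_of(p) for p in assoc}
    n_missing = sum(1 for c in classes.values() if c == "missing")
    missing_share = percent_round(n_missing, len(classes)) if classes else 0.0
    counts = {c: 0 for c in FREQUENCY_CLASSES if c != "missing"}
    for c in classes.values():
        if c != "missing":
            counts[c] += 1
    counts = {c: n for c, n in counts.items() if n > 0}
    return missing_share, _make_table("frequency", counts)


@dataclass(frozen=True)
class ConcordanceReport:
    rho_ade: tuple[float, float, float]
    rho_drug: tuple[float, float, float]
    n_new_a: int
    n_new_b: int
    rate_a: float
    rate_b: float
    b_only: frozenset[Pair]
    breakdowns: tuple[BreakdownTable, ...]
    freq_missing_share: float


def concordance_report(base: AssociationSnapshot, a: AssociationSnapshot,
                       b: AssociationSnapshot, common_drugs: set[str],
                       common_terms: set[str], atc: AtcMap, meddra: MeddraMap,
                       *, n_boot: int = 2000, seed: int = 0) -> ConcordanceReport:
    """Full comparative analysis of snapshots a and b against a baseline.

    ``rho_ade`` correlates per-drug ADE counts between a and b (one point per
    common drug); ``rho_drug`` correlates per-term drug counts. Accrual rates
    divide the new-association counts by each snapshot's elapsed years since
    the baseline. Breakdowns characterize the B-only surplus.
    """
    ade_a = count_per_drug(a, common_drugs)
    ade_b = count_per_drug(b, common_drugs)
    drug_a = count_per_term(a, common_terms)
    drug_b = count_per_term(b, common_terms)
    rho_ade = spearman_ci(ade_a, ade_b, n_boot=n_boot, seed=seed)
    rho_drug = spearman_ci(drug_a, drug_b, n_boot=n_boot, seed=seed + 1)
    new_a = new_associations(base, a)
    new_b = new_associations(base, b)
    b_only = difference_set(new_a, new_b)
    missing_share, freq_table = breakdown_by_frequency(b_only, b)
    return ConcordanceReport(
        rho_ade=rho_ade, rho_drug=rho_drug,
        n_new_a=len(new_a), n_new_b=len(new_b),
        rate_a=annual_rate(new_a, a.year - base.year),
        rate_b=annual_rate(new_b, b.year - base.year),
        b_only=frozenset(b_only),
        breakdowns=(breakdown_by_atc(b_only, atc),
                    breakdown_by_soc(b_only, meddra),
                    freq_table),
        freq_missing_share=missing_share,
    )
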