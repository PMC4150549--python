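"""Harmonization of association snapshots onto common vocabularies.

The two real-world datasets this pipeline was designed around (a commercial
drug-information extract and a public package-insert database) name drugs and
adverse events inconsistently; the operations here bring both onto canonical
ingredient identifiers and the MedDRA HLT level, then restrict to the shared
vocabulary so downstream comparisons are apples-to-apples.
"""

from __future__ import annotations

from typing import NamedTuple

from .errors import TermLevelError, UnmappedDrugError, UnmappedTermError
from .vocab import (AssociationSnapshot, DrugSynonymMap, MeddraMap,
                    merge_frequency, normalize_name)


class StandardizeResult(NamedTuple):
    snapshot: AssociationSnapshot
    n_unmapped: int
    n_merged: int


def standardize_drug_names(snapshot: AssociationSnapshot, synonyms: DrugSynonymMap,
                           policy: str = "strict") -> StandardizeResult:
    """Replace raw drug names by canonical ingredient identifiers.

    Under ``strict`` policy an unmapped raw name raises
    :class:`~adeconcord.errors.UnmappedDrugError`; under ``passthrough`` it is
    case-normalized, kept, and counted in ``n_unmapped``. Pairs that collapse
    onto one (drug, term) after standardization are merged, keeping the more
    informative frequency class; ``n_merged`` counts collapsed duplicates.
    """
    if policy not in ("strict", "passthrough"):
        raise ValueError(f"unknown policy {policy!r}")
    new_pairs: dict[tuple[str, str], str] = {}
    unmapped: set[str] = set()
    n_merged = 0
    for drug, term in sorted(snapshot.pairs):
        canonical = synonyms.lookup(drug)
        if canonical is None:
            if policy == "strict":
                raise UnmappedDrugError(f"drug name {drug!r} not in synonym map")
            unmapped.add(drug)
            canonical = normalize_name(drug)
        pair = (canonical, term)
        cls = snapshot.frequency_of((drug, term))
        if pair in new_pairs:
            n_merged += 1
            new_pairs[pair] = merge_frequency(new_pairs[pair], cls)
        else:
            new_pairs[pair] = cls
    freq = {p: c for p, c in new_pairs.items() if c != "missing"}
    out = snapshot.replace(pairs=frozenset(new_pairs), freq=freq)
    return StandardizeResult(out, len(unmapped), n_merged)


def map_pt_to_hlt(snapshot: AssociationSnapshot, meddra: MeddraMap,
                  policy: str = "strict") -> AssociationSnapshot:
    """Expand a PT-level snapshot to HLT level (one pair per mapped HLT).

    Several PTs typically map to the same HLT, so the result is deduplicated;
    when colliding PTs carry different frequency classes the more informative
    class (see :data:`~adeconcord.vocab.FREQUENCY_CLASSES`) is kept.
    """
    if snapshot.level != "PT":
        raise TermLevelError(f"snapshot {snapshot.source!r} is at {snapshot.level} level, "
                             "expected PT")
    if policy not in ("strict", "passthrough"):
        raise ValueError(f"unknown policy {policy!r}")
    expanded: dict[tuple[str, str], str] = {}
    for drug, pt in sorted(snapshot.pairs):
        hlts = meddra.hlts_of(pt)
        if hlts is None:
            if policy == "strict":
                raise UnmappedTermError(f"PT {pt!r} not in MedDRA map")
            continue
        cls = snapshot.frequency_of((drug, pt))
        for hlt in hlts:
            pair = (drug, hlt)
            if pair in expanded:
                expanded[pair] = merge_frequency(expanded[pair], cls)
            else:
                expanded[pair] = cls
    freq = {p: c for p, c in expanded.items() if c != "missing"}
    return snapshot.replace(pairs=frozenset(expanded), level="HLT", freq=freq)


class VocabularyOverlap(NamedTuple):
    common_drugs: set[str]
    common_terms: set[str]
    drug_overlap_pct: int
    term_overlap_pct: int


def intersect_vocabularies(a: AssociationSnapshot, b: AssociationSnapshot) -> VocabularyOverlap:
    """Common drug and term vocabularies of two HLT-level snapshots.

    Percentages are relative to ``a``'s vocabulary, rounded to the nearest
    integer for reporting.
    """
    _require_hlt(a)
    _require_hlt(b)
    common_drugs = a.drugs & b.drugs
    common_terms = a.terms & b.terms
    return VocabularyOverlap(
        common_drugs, common_terms,
        overlap_pct(len(common_drugs), len(a.drugs)),
        overlap_pct(len(common_terms), len(a.terms)),
    )


def overlap_pct(n_common: int, n_total: int) -> int:
    """100·n_common/n_total rounded half-up to the nearest integer."""
    if n_total == 0:
        return 0
    return int(100 * n_common / n_total + 0.5)


def restrict_to_common(s: AssociationSnapshot, common_drugs: set[str],
                       common_terms: set[str]) -> AssociationSnapshot:
    """Keep only pairs whose drug and term both lie in the common sets."""
    pairs = frozenset((d, t) for d, t in s.pairs
                      if d in common_drugs and t in common_terms)
    freq = {p: c for p, c in s.freq.items() if p in pairs}
    return s.replace(pairs=pairs, freq=freq)


def _require_hlt(s: AssociationSnapshot) -> None:
    if s.level != "HLT":
        raise TermLevelError(f"snapshot {s.source!r} is at {s.level} level, expected HLT")
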