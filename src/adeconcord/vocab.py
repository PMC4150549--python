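"""Controlled vocabularies: drug synonyms, ATC assignments, MedDRA hierarchy,
and the association-snapshot record they act on.

Drug identifiers are case-normalized name strings; ADE terms live at either
the MedDRA Preferred Term (PT) or High-Level Term (HLT) level, and every
snapshot carries its level explicitly so that mixing levels is a detectable
error rather than silent garbage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigError

#: The 14 anatomical main groups of the WHO ATC classification, keyed by the
#: first letter of an ATC code.
ATC_TOP_LEVELS: dict[str, str] = {
    "A": "Alimentary tract and metabolism",
    "B": "Blood and blood forming organs",
    "C": "Cardiovascular system",
    "D": "Dermatologicals",
    "G": "Genito-urinary system and sex hormones",
    "H": "Systemic hormonal preparations (excl sex hormones)",
    "J": "Antiinfectives for systemic use",
    "L": "Antineoplastic and immunomodulating agents",
    "M": "Musculo-skeletal system",
    "N": "Nervous system",
    "P": "Antiparasitic products insecticides and repellents",
    "R": "Respiratory system",
    "S": "Sensory organs",
    "V": "Various",
}

#: Frequency annotation classes, ordered from most to least informative. When
#: several PTs with different classes collapse onto one (drug, HLT) pair the
#: class earliest in this order wins.
FREQUENCY_CLASSES: tuple[str, ...] = (
    "exact-number",
    "frequent",
    "infrequent",
    "rare",
    "postmarketing",
    "potential",
    "missing",
)

_FREQ_RANK = {c: i for i, c in enumerate(FREQUENCY_CLASSES)}

# ATC codes at any truncation level: A, A10, A10B, A10BA, A10BA02
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


def normalize_name(raw: str) -> str:
    """Case-normalize a drug name: lowercase, trim, collapse whitespace."""
    return re.sub(r"\s+", " ", raw.strip().lower())


def merge_frequency(a: str, b: str) -> str:
    """Resolve two frequency classes to the more informative one."""
    return a if _FREQ_RANK[a] <= _FREQ_RANK[b] else b


@dataclass(frozen=True)
class DrugSynonymMap:
    """Raw-name → canonical-ingredient lookup (NPC-style standardization).

    Keys are case-normalized; every canonical identifier maps to itself so a
    second standardization pass is a fixed point.
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        entries = {normalize_name(k): v for k, v in self.entries.items()}
        # canonical ids must be self-mapping for idempotence
        for canonical in set(entries.values()):
            entries.setdefault(normalize_name(canonical), canonical)
        object.__setattr__(self, "entries", entries)

    def lookup(self, raw: str) -> str | None:
        return self.entries.get(normalize_name(raw))

    def canonical_ids(self) -> set[str]:
        return set(self.entries.values())


@dataclass(frozen=True)
class MeddraMap:
    """PT→HLT (one-to-many) and HLT→SOC (primary-first) mappings."""

    pt_to_hlt: Mapping[str, frozenset[str]]
    hlt_to_soc: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        pt = {k: frozenset(v) for k, v in self.pt_to_hlt.items()}
        soc = {k: tuple(v) for k, v in self.hlt_to_soc.items()}
        for p, hlts in pt.items():
            if not hlts:
                raise ConfigError(f"PT {p!r} maps to no HLT")
            for h in hlts:
                if h not in soc:
                    raise ConfigError(f"HLT {h!r} has no SOC assignment")
        for h, socs in soc.items():
            if not socs:
                raise ConfigError(f"HLT {h!r} maps to no SOC")
        object.__setattr__(self, "pt_to_hlt", pt)
        object.__setattr__(self, "hlt_to_soc", soc)

    def hlts_of(self, pt: str) -> frozenset[str] | None:
        return self.pt_to_hlt.get(pt)

    def primary_soc(self, hlt: str) -> str:
        return self.hlt_to_soc[hlt][0]


@dataclass(frozen=True)
class AtcMap:
    """Canonical drug id → ordered ATC codes; first code is primary."""

    assignments: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        assignments = {k: tuple(v) for k, v in self.assignments.items()}
        for drug, codes in assignments.items():
            if not codes:
                raise ConfigError(f"drug {drug!r} has no ATC codes")
            for code in codes:
                if not _ATC_RE.match(code) or code[0] not in ATC_TOP_LEVELS:
                    raise ConfigError(f"invalid ATC code {code!r} for {drug!r}")
        object.__setattr__(self, "assignments", assignments)

    def primary_code(self, drug: str) -> str:
        return self.assignments[drug][0]

    @staticmethod
    def top_level(code: str) -> str:
        """Name of the anatomical main group an ATC code belongs to."""
        return ATC_TOP_LEVELS[code[0]]


@dataclass(frozen=True)
class VocabularyBundle:
    """The three vocabularies the pipeline harmonizes against."""

    synonyms: DrugSynonymMap
    meddra: MeddraMap
    atc: AtcMap


@dataclass(frozen=True)
class AssociationSnapshot:
    """A dated, source-labelled set of (drug, ADE-term) pairs.

    ``level`` is ``"PT"`` or ``"HLT"`` and applies to every pair. ``freq``
    optionally annotates pairs with a frequency class from
    :data:`FREQUENCY_CLASSES`; its key set must be a subset of ``pairs``.
    """

    source: str
    year: float
    pairs: frozenset[tuple[str, str]]
    level: str = "HLT"
    freq: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        if self.level not in ("PT", "HLT"):
            raise ConfigError(f"unknown term level {self.level!r}")
        freq = dict(self.freq)
        bad = set(freq) - self.pairs
        if bad:
            raise ConfigError(f"frequency annotations for unknown pairs: {sorted(bad)[:3]}")
        for cls in freq.values():
            if cls not in _FREQ_RANK:
                raise ConfigError(f"unknown frequency class {cls!r}")
        object.__setattr__(self, "freq", freq)

    @property
    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    @property
    def terms(self) -> set[str]:
        return {t for _, t in self.pairs}

    def frequency_of(self, pair: tuple[str, str]) -> str:
        """Frequency class of a pair; unannotated pairs count as missing."""
        return self.freq.get(pair, "missing")

    def replace(self, **kw) -> "AssociationSnapshot":
        data = dict(source=self.source, year=self.year, pairs=self.pairs,
                    level=self.level, freq=self.freq)
        data.update(kw)
        return AssociationSnapshot(**data)


def snapshot_from_pairs(pairs: Iterable[tuple[str, str]], *, source: str = "test",
                        year: float = 2000.0, level: str = "HLT",
                        freq: Mapping[tuple[str, str], str] | None = None) -> AssociationSnapshot:
    """Convenience constructor used heavily in tests and examples."""
    return AssociationSnapshot(source=source, year=year, pairs=frozenset(pairs),
                               level=level, freq=freq or {})
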