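"""Plain-text readers and writers for the pipeline's tabular formats.

All association tables are TSV with header ``drug, term, term_level,
frequency`` (empty frequency = missing); each snapshot's ``source`` and
``year`` live in a JSON manifest next to the table. Vocabulary files are
two-or-three-column TSVs. Everything round-trips deterministically (sorted
rows, sorted JSON keys) so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .vocab import (AssociationSnapshot, AtcMap, DrugSynonymMap, MeddraMap,
                    VocabularyBundle)


def write_snapshot(snapshot: AssociationSnapshot, table_path: Path,
                   manifest_path: Path | None = None) -> None:
    table_path = Path(table_path)
    rows = [
        {"drug": d, "term": t, "term_level": snapshot.level,
         "frequency": "" if snapshot.frequency_of((d, t)) == "missing"
         else snapshot.frequency_of((d, t))}
        for d, t in sorted(snapshot.pairs)
    ]
    df = pd.DataFrame(rows, columns=["drug", "term", "term_level", "frequency"])
    df.to_csv(table_path, sep="\t", index=False)
    if manifest_path is None:
        manifest_path = table_path.with_suffix(".manifest.json")
    manifest = {"source": snapshot.source, "year": snapshot.year,
                "table": table_path.name}
    Path(manifest_path).write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")


def read_snapshot(table_path: Path, manifest_path: Path | None = None) -> AssociationSnapshot:
    table_path = Path(table_path)
    if manifest_path is None:
        manifest_path = table_path.with_suffix(".manifest.json")
    manifest = json.loads(Path(manifest_path).read_text())
    df = pd.read_csv(table_path, sep="\t", dtype=str, keep_default_na=False)
    levels = set(df["term_level"]) if len(df) else set()
    if len(levels) > 1:
        raise ValueError(f"{table_path}: mixed term levels {sorted(levels)}")
    level = levels.pop() if levels else "HLT"
    pairs = frozenset(zip(df["drug"], df["term"]))
    freq = {(r.drug, r.term): r.frequency for r in df.itertuples() if r.frequency}
    return AssociationSnapshot(source=manifest["source"], year=manifest["year"],
                               pairs=pairs, level=level, freq=freq)


def write_synonyms(synonyms: DrugSynonymMap, path: Path) -> None:
    df = pd.DataFrame(sorted(synonyms.entries.items()), columns=["raw_name", "canonical_id"])
    df.to_csv(path, sep="\t", index=False)


def read_synonyms(path: Path) -> DrugSynonymMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return DrugSynonymMap(dict(zip(df["raw_name"], df["canonical_id"])))


def write_meddra(meddra: MeddraMap, pt_path: Path, soc_path: Path) -> None:
    pt_rows = [(pt, hlt) for pt, hlts in sorted(meddra.pt_to_hlt.items())
               for hlt in sorted(hlts)]
    pd.DataFrame(pt_rows, columns=["pt", "hlt"]).to_csv(pt_path, sep="\t", index=False)
    soc_rows = [(hlt, soc, int(i == 0))
                for hlt, socs in sorted(meddra.hlt_to_soc.items())
                for i, soc in enumerate(socs)]
    pd.DataFrame(soc_rows, columns=["hlt", "soc", "is_primary"]).to_csv(
        soc_path, sep="\t", index=False)


def read_meddra(pt_path: Path, soc_path: Path) -> MeddraMap:
    pt_df = pd.read_csv(pt_path, sep="\t", dtype=str, keep_default_na=False)
    pt_to_hlt: dict[str, set[str]] = {}
    for r in pt_df.itertuples():
        pt_to_hlt.setdefault(r.pt, set()).add(r.hlt)
    soc_df = pd.read_csv(soc_path, sep="\t", dtype=str, keep_default_na=False)
    hlt_to_soc: dict[str, list[str]] = {}
    # primary SOC first, then file order
    for r in soc_df.itertuples():
        hlt_to_soc.setdefault(r.hlt, [])
        if r.is_primary == "1":
            hlt_to_soc[r.hlt].insert(0, r.soc)
        else:
            hlt_to_soc[r.hlt].append(r.soc)
    return MeddraMap({k: frozenset(v) for k, v in pt_to_hlt.items()},
                     {k: tuple(v) for k, v in hlt_to_soc.items()})


def write_atc(atc: AtcMap, path: Path) -> None:
    rows = [(drug, code, int(i == 0))
            for drug, codes in sorted(atc.assignments.items())
            for i, code in enumerate(codes)]
    pd.DataFrame(rows, columns=["drug", "atc_code", "is_primary"]).to_csv(
        path, sep="\t", index=False)


def read_atc(path: Path) -> AtcMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    assignments: dict[str, list[str]] = {}
    for r in df.itertuples():
        assignments.setdefault(r.drug, [])
        if r.is_primary == "1":
            assignments[r.drug].insert(0, r.atc_code)
        else:
            assignments[r.drug].append(r.atc_code)
    return AtcMap({k: tuple(v) for k, v in assignments.items()})


def write_properties(props: dict[str, "list[float]"], path: Path) -> None:
    import numpy as np
    drugs = sorted(props)
    dim = len(next(iter(props.values()))) if props else 0
    cols = [f"p{i+1}" for i in range(dim)]
    df = pd.DataFrame(np.asarray([props[d] for d in drugs]), columns=cols)
    df.insert(0, "drug", drugs)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_properties(path: Path) -> dict[str, "list[float]"]:
    df = pd.read_csv(path, sep="\t")
    return {r[0]: list(map(float, r[1:])) for r in df.itertuples(index=False)}


def write_vocabularies(bundle: VocabularyBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_synonyms(bundle.synonyms, outdir / "synonyms.tsv")
    write_meddra(bundle.meddra, outdir / "pt_to_hlt.tsv", outdir / "hlt_to_soc.tsv")
    write_atc(bundle.atc, outdir / "atc.tsv")


def read_vocabularies(outdir: Path) -> VocabularyBundle:
    outdir = Path(outdir)
    return VocabularyBundle(
        synonyms=read_synonyms(outdir / "synonyms.tsv"),
        meddra=read_meddra(outdir / "pt_to_hlt.tsv", outdir / "hlt_to_soc.tsv"),
        atc=read_atc(outdir / "atc.tsv"),
    )
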