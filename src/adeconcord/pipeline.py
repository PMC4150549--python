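"""Study orchestration: generate → harmonize → concord → train → validate → report.

Each stage reads its inputs from the run directory and writes its outputs
plus a provenance record there, so any stage can be re-run in isolation.
Under a fixed config and seed the whole run is byte-identical on repeat:
every table is written with sorted rows and every JSON with sorted keys, and
no wall-clock timestamps enter the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__, concordance, harmonize, io, ppn, synthetic, validation
from .errors import DependencyError
from .vocab import AssociationSnapshot

ALL_STAGES = ("generate", "harmonize", "concord", "train", "validate", "report")


@dataclass(frozen=True)
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    world: dict[str, Any] = field(default_factory=dict)
    truth: str = "strong"               # "strong" | "null" preset
    snapshot_specs: tuple[synthetic.SnapshotSpec, ...] | None = None
    policy: str = "passthrough"          # unmapped-name handling outside tests
    ridge: float = 1e-6
    n_boot_rho: int = 2000
    n_boot_auroc: int = 1000
    change_decimals: int = 0

    @staticmethod
    def from_dict(data: dict[str, Any], outdir: Path | None = None,
                  seed: int | None = None) -> "RunConfig":
        data = dict(data)
        specs = data.pop("snapshot_specs", None)
        if specs is not None:
            specs = tuple(synthetic.SnapshotSpec(
                **{**s, "enriched_categories": frozenset(s.get("enriched_categories", ()))})
                for s in specs)
        if outdir is not None:
            data["outdir"] = outdir
        if seed is not None:
            data["seed"] = seed
        data["outdir"] = Path(data["outdir"])
        data["stages"] = tuple(data.get("stages", ALL_STAGES))
        return RunConfig(snapshot_specs=specs, **data)

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["stages"] = list(self.stages)
        if self.snapshot_specs is not None:
            d["snapshot_specs"] = [
                {**dataclasses.asdict(s),
                 "enriched_categories": sorted(s.enriched_categories)}
                for s in self.snapshot_specs]
        return d


def _truth_for(cfg: RunConfig) -> synthetic.LinkModelConfig:
    specs = cfg.snapshot_specs or synthetic.default_snapshot_specs()
    preset = synthetic.strong_truth if cfg.truth == "strong" else synthetic.null_truth
    return dataclasses.replace(preset(), snapshot_specs=specs)


def _config_hash(cfg: RunConfig) -> str:
    # outdir is location, not configuration: identical runs in different
    # directories must hash identically
    payload = {k: v for k, v in cfg.to_jsonable().items() if k != "outdir"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(path: Path, obj: Any) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _provenance(cfg: RunConfig, stage: str, inputs: list[Path]) -> None:
    record = {
        "stage": stage,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "inputs": {p.name: _checksum(p) for p in sorted(inputs)},
    }
    _write_json(cfg.outdir / "provenance" / f"{stage}.json", record)


def _need(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing artifact {path} (run the {produced_by!r} "
                              "stage first)")
    return path


def _snapshot_path(cfg: RunConfig, folder: str, name: str) -> Path:
    return cfg.outdir / folder / f"{name}.tsv"


def _write_stage_snapshot(cfg: RunConfig, folder: str, name: str,
                          snap: AssociationSnapshot) -> Path:
    path = _snapshot_path(cfg, folder, name)
    path.parent.mkdir(parents=True, exist_ok=True)
    io.write_snapshot(snap, path)
    return path


def stage_generate(cfg: RunConfig) -> None:
    truth = _truth_for(cfg)
    world_cfg = synthetic.WorldConfig(seed=cfg.seed, **cfg.world)
    world, base, followups = synthetic.generate_study(world_cfg, truth)
    io.write_vocabularies(world.vocabularies, cfg.outdir / "vocab")
    io.write_properties({d: list(v) for d, v in world.properties.items()},
                        cfg.outdir / "vocab" / "properties.tsv")
    written = []
    for snap in [base, *followups]:
        raw = synthetic.degrade_to_raw(world, snap, snap.source)
        written.append(_write_stage_snapshot(cfg, "raw", snap.source, raw))
    _write_json(cfg.outdir / "truth.json",
                {"beta": list(truth.beta), "base_year": truth.base_year,
                 "covariates": list(ppn.COVARIATE_NAMES),
                 "sources": [s.source for s in truth.snapshot_specs]})
    _provenance(cfg, "generate", written)


def _sources(cfg: RunConfig) -> list[str]:
    truth_meta = json.loads(_need(cfg.outdir / "truth.json", "generate").read_text())
    return ["base", *truth_meta["sources"]]


def stage_harmonize(cfg: RunConfig) -> None:
    bundle = io.read_vocabularies(_need(cfg.outdir / "vocab", "generate"))
    inputs = []
    for name in _sources(cfg):
        raw_path = _need(_snapshot_path(cfg, "raw", name), "generate")
        snap = io.read_snapshot(raw_path)
        std = harmonize.standardize_drug_names(snap, bundle.synonyms, cfg.policy)
        hlt = harmonize.map_pt_to_hlt(std.snapshot, bundle.meddra, cfg.policy) \
            if std.snapshot.level == "PT" else std.snapshot
        _write_stage_snapshot(cfg, "harmonized", name, hlt)
        inputs.append(raw_path)
    _provenance(cfg, "harmonize", inputs)


def _load_harmonized(cfg: RunConfig) -> dict[str, AssociationSnapshot]:
    return {name: io.read_snapshot(_need(_snapshot_path(cfg, "harmonized", name),
                                         "harmonize"))
            for name in _sources(cfg)}


def stage_concord(cfg: RunConfig) -> None:
    snaps = _load_harmonized(cfg)
    bundle = io.read_vocabularies(cfg.outdir / "vocab")
    base, (a_name, b_name) = snaps["base"], _sources(cfg)[1:3]
    a, b = snaps[a_name], snaps[b_name]
    overlap = harmonize.intersect_vocabularies(a, b)
    base_c = harmonize.restrict_to_common(base, overlap.common_drugs, overlap.common_terms)
    a_c = harmonize.restrict_to_common(a, overlap.common_drugs, overlap.common_terms)
    b_c = harmonize.restrict_to_common(b, overlap.common_drugs, overlap.common_terms)
    report = concordance.concordance_report(
        base_c, a_c, b_c, overlap.common_drugs, overlap.common_terms,
        bundle.atc, bundle.meddra, n_boot=cfg.n_boot_rho, seed=cfg.seed)
    outdir = cfg.outdir / "concordance"
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(outdir / "concordance.json", {
        "common_drugs": len(overlap.common_drugs),
        "common_terms": len(overlap.common_terms),
        "drug_overlap_pct": overlap.drug_overlap_pct,
        "term_overlap_pct": overlap.term_overlap_pct,
        "rho_ade": list(report.rho_ade), "rho_drug": list(report.rho_drug),
        "n_new_a": report.n_new_a, "n_new_b": report.n_new_b,
        "rate_a": report.rate_a, "rate_b": report.rate_b,
        "n_b_only": len(report.b_only),
        "freq_missing_share": report.freq_missing_share,
    })
    for table, fname in zip(report.breakdowns,
                            ("breakdown_atc.tsv", "breakdown_soc.tsv",
                             "breakdown_freq.tsv")):
        _write_breakdown(outdir / fname, table)
    for counts, fname in (
            ((concordance.count_per_drug(a_c, overlap.common_drugs),
              concordance.count_per_drug(b_c, overlap.common_drugs)), "scatter_ade.tsv"),
            ((concordance.count_per_term(a_c, overlap.common_terms),
              concordance.count_per_term(b_c, overlap.common_terms)), "scatter_drug.tsv")):
        ca, cb = counts
        lines = ["entity\tcount_a\tcount_b"]
        lines += [f"{k}\t{ca[k]}\t{cb[k]}" for k in sorted(ca)]
        (outdir / fname).write_text("\n".join(lines) + "\n")
    _provenance(cfg, "concord", [_snapshot_path(cfg, "harmonized", n)
                                 for n in _sources(cfg)])


def _write_breakdown(path: Path, table: concordance.BreakdownTable) -> None:
    lines = ["category\tcount\tpercent"]
    lines += [f"{label}\t{n}\t{pct:.1f}" for label, n, pct in table.rows]
    path.write_text("\n".join(lines) + "\n")


def _training_universe(cfg: RunConfig):
    bundle = io.read_vocabularies(cfg.outdir / "vocab")
    props = io.read_properties(cfg.outdir / "vocab" / "properties.tsv")
    drugs = tuple(sorted(props))
    terms = tuple(sorted(bundle.meddra.hlt_to_soc))
    return bundle, props, drugs, terms


def stage_train(cfg: RunConfig) -> None:
    snaps = _load_harmonized(cfg)
    bundle, props, drugs, terms = _training_universe(cfg)
    net = ppn.build_network(snaps["base"], drugs, terms)
    pairs = ppn.all_pairs(net)
    X = ppn.compute_covariates(net, bundle.atc, bundle.meddra, props, pairs)
    y = ppn.training_labels(net, pairs)
    fit = ppn.fit_logistic(X, y, ridge=cfg.ridge)
    _write_json(cfg.outdir / "model" / "model.json", {
        "beta_hat": fit.beta_hat.tolist(), "se": fit.se.tolist(),
        "columns": list(fit.columns), "loglik": fit.loglik,
        "converged": fit.converged, "n_iter": fit.n_iter,
        "standardizer": {"mean": fit.standardizer.mean.tolist(),
                         "sd": fit.standardizer.sd.tolist()},
    })
    _provenance(cfg, "train", [_snapshot_path(cfg, "harmonized", "base")])


def _load_model(cfg: RunConfig) -> ppn.FitResult:
    meta = json.loads(_need(cfg.outdir / "model" / "model.json", "train").read_text())
    std = ppn.Standardizer(np.asarray(meta["standardizer"]["mean"]),
                           np.asarray(meta["standardizer"]["sd"]))
    return ppn.FitResult(beta_hat=np.asarray(meta["beta_hat"]),
                         se=np.asarray(meta["se"]), loglik=meta["loglik"],
                         converged=meta["converged"], n_iter=meta["n_iter"],
                         columns=tuple(meta["columns"]), standardizer=std)


def stage_validate(cfg: RunConfig) -> None:
    snaps = _load_harmonized(cfg)
    bundle, props, drugs, terms = _training_universe(cfg)
    fit = _load_model(cfg)
    base = snaps["base"]
    a_name, b_name = _sources(cfg)[1:3]
    overlap = harmonize.intersect_vocabularies(snaps[a_name], snaps[b_name])
    net = ppn.build_network(base, drugs, terms)

    refs, score_tables = {}, {}
    for name in (a_name, b_name):
        ref = validation.build_reference(base, snaps[name], overlap.common_drugs,
                                         overlap.common_terms, label=name)
        pairs = sorted(ref.positives | ref.negatives)
        X = ppn.compute_covariates(net, bundle.atc, bundle.meddra, props, pairs,
                                   standardizer=fit.standardizer)
        scores = ppn.score_pairs(fit, X)
        refs[name], score_tables[name] = ref, scores
        auc = validation.auroc(scores, ref)
        ci = validation.auroc_ci(scores, ref, n_boot=cfg.n_boot_auroc, seed=cfg.seed)
        roc = validation.roc_curve(scores, ref)
        outdir = cfg.outdir / "validation"
        outdir.mkdir(parents=True, exist_ok=True)
        _write_json(outdir / f"validation_{name}.json", {
            "label": name, "auroc": auc, "ci": list(ci),
            "n_pos": len(ref.positives), "n_neg": len(ref.negatives)})
        lines = ["fpr\ttpr\tthreshold"]
        lines += [f"{f:.6f}\t{t:.6f}\t{th:.6g}" for (f, t), th in
                  zip(roc.points[1:], roc.thresholds)]
        (outdir / f"roc_{name}.tsv").write_text("\n".join(lines) + "\n")

    rows = validation.stratified_auroc(
        score_tables[a_name], refs[a_name], score_tables[b_name], refs[b_name],
        bundle.meddra, n_boot=cfg.n_boot_auroc, seed=cfg.seed,
        change_decimals=cfg.change_decimals)
    lines = ["soc\tauroc_a\tci_a_lo\tci_a_hi\tauroc_b\tci_b_lo\tci_b_hi\t"
             "relative_change_pct\tflagged"]
    for r in rows:
        if r.flagged:
            lines.append(f"{r.soc}\t\t\t\t\t\t\t\t1")
        else:
            change = "" if r.relative_change_pct is None else r.relative_change_pct
            lines.append(f"{r.soc}\t{r.auroc_a:.4f}\t{r.ci_a[0]:.4f}\t{r.ci_a[1]:.4f}"
                         f"\t{r.auroc_b:.4f}\t{r.ci_b[0]:.4f}\t{r.ci_b[1]:.4f}"
                         f"\t{change}\t0")
    (cfg.outdir / "validation" / "stratified_auroc.tsv").write_text(
        "\n".join(lines) + "\n")
    _provenance(cfg, "validate", [cfg.outdir / "model" / "model.json"])


def stage_report(cfg: RunConfig) -> None:
    report: dict[str, Any] = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                              "version": __version__}
    conc = cfg.outdir / "concordance" / "concordance.json"
    if conc.exists():
        report["concordance"] = json.loads(conc.read_text())
    vdir = cfg.outdir / "validation"
    if vdir.exists():
        report["validation"] = {
            p.stem.removeprefix("validation_"): json.loads(p.read_text())
            for p in sorted(vdir.glob("validation_*.json"))}
        aurocs = [v["auroc"] for v in report["validation"].values()]
        if len(aurocs) == 2:
            report["auroc_relative_change_pct"] = validation.relative_change(
                aurocs[0], aurocs[1], decimals=1)
    _write_json(cfg.outdir / "report.json", report)


STAGE_FUNCS = {
    "generate": stage_generate,
    "harmonize": stage_harmonize,
    "concord": stage_concord,
    "train": stage_train,
    "validate": stage_validate,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in canonical order; return report.json."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    for stage in ALL_STAGES:
        if stage in cfg.stages:
            STAGE_FUNCS[stage](cfg)
    report_path = cfg.outdir / "report.json"
    return json.loads(report_path.read_text()) if report_path.exists() else {}
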