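"""End-to-end pipeline driver: raw wells to pathway-interactome networks.

Stage order: normalize -> z-score -> QC -> group tests -> delta-z -> hit
calling -> clustering -> target expansion (ranked lists) -> pre-ranked
GSEA -> enrichment-map networks -> size-control analysis.  Every stage
writes its artifact into the output directory and the run closes with a
manifest recording the configuration, a config hash, and a SHA-256
checksum per artifact.  Runs are deterministic given config + seed: two
identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cluster as cluster_mod
from . import enrichment_map as emap
from . import gsea as gsea_mod
from . import hit_calling as hits_mod
from . import io as io_mod
from . import qc as qc_mod
from . import size_control as size_mod
from . import target_expansion as expand_mod
from .core_types import ScreenDataset, validate_dataset
from .normalization import delta_z, normalize_to_controls, zscore

logger = logging.getLogger("drugpath")


@dataclass
class PipelineConfig:
    screen_path: str | None = None
    target_map_path: str | None = None
    gmt_path: str | None = None
    outdir: str = "drugpath_out"
    control_kind: str = "vehicle"
    z_scope: str = "cell_line"
    consolidate: bool = True
    consolidate_groups: tuple[str, ...] = ("ESC", "IPSC")
    consolidated_name: str = "ESC/IPSC"
    equal_var: bool = False
    alpha: float = 0.01
    noise_cutoff: float = 2.0
    aggregation_rule: str = "signed_max"
    metric_mode: str = "difference"
    concentration_ceiling_uM: float = 5.0
    gsea_weight: float = 1.0
    n_perm: int = 1000
    fdr_alpha: float = 0.25
    gsea_min_size: int = 3
    gsea_max_size: int = 500
    overlap_cutoff: float = 0.05
    sphere_convention: str = "area"
    cluster_significant_only: bool = True
    seed: int = 0

    def __post_init__(self):
        for name, lo, hi in (
            ("alpha", 0.0, 1.0),
            ("fdr_alpha", 0.0, 1.0),
            ("overlap_cutoff", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.noise_cutoff < 0:
            raise ValueError("noise_cutoff must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.seed is None:
            raise ValueError("seed is required")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["consolidate_groups"] = list(self.consolidate_groups)
        return d

    def digest(self) -> str:
        """Hash of the analysis parameters (input/output locations excluded)."""
        d = self.to_dict()
        for k in ("outdir", "screen_path", "target_map_path", "gmt_path"):
            d.pop(k, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    cfg: PipelineConfig,
    ds: ScreenDataset | None = None,
    tmap=None,
    collection=None,
) -> dict:
    """Execute all stages; returns the manifest dict.

    Inputs may be passed in memory or loaded from the configured paths.
    Any stage failure aborts with the stage name in the exception message.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stage_outputs: dict[str, list[str]] = {}

    def emit(stage: str, *paths: Path):
        rels = [str(p.relative_to(out)) for p in paths]
        stage_outputs.setdefault(stage, []).extend(rels)
        artifacts.extend(rels)

    def run_stage(name: str, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # -- load inputs --------------------------------------------------------
    if ds is None:
        if cfg.screen_path is None:
            raise ValueError("no screen: provide a dataset or screen_path")
        ds = io_mod.read_screen_table(cfg.screen_path)
    if tmap is None and cfg.target_map_path:
        tmap = io_mod.read_target_map(cfg.target_map_path)
    if collection is None and cfg.gmt_path:
        collection, _w = io_mod.read_gmt(cfg.gmt_path)

    violations = validate_dataset(ds)
    if violations:
        io_mod.write_json({"violations": violations}, out / "validation.json")
        emit("validate", out / "validation.json")
        logger.warning("dataset has %d invariant violations", len(violations))

    # -- 1-3: normalization, z, delta-z ------------------------------------
    def s_norm():
        norm = normalize_to_controls(ds, cfg.control_kind)
        io_mod.write_screen_table(norm, out / "screen_normalized.tsv")
        emit("normalize", out / "screen_normalized.tsv")
        return norm

    norm = run_stage("normalize", s_norm)

    def s_z():
        z = zscore(norm, scope=cfg.z_scope)
        io_mod.write_z_matrices(z, out / "zscores", prefix="z")
        emit("zscore", *sorted((out / "zscores").glob("*")))
        return z

    z = run_stage("zscore", s_z)

    def s_dz():
        dz = delta_z(z, cfg.control_kind)
        io_mod.write_z_matrices(dz, out / "delta_z", prefix="dz")
        emit("delta_z", *sorted((out / "delta_z").glob("*")))
        return dz

    dz = run_stage("delta_z", s_dz)

    # -- 4: QC --------------------------------------------------------------
    def s_qc():
        report = qc_mod.qc_report(z, qc_mod.plate_assignment(ds))
        (out / "qc_report.json").write_text(report.to_json(), encoding="utf-8")
        (out / "qc_summary.txt").write_text(report.summary_text() + "\n", encoding="utf-8")
        emit("qc", out / "qc_report.json", out / "qc_summary.txt")
        return report

    run_stage("qc", s_qc)

    # -- 5-6: hit calling ---------------------------------------------------
    samples = z.samples
    if cfg.consolidate:
        samples = hits_mod.consolidate_groups(
            samples, cfg.consolidate_groups, cfg.consolidated_name
        )

    group_order = None
    if cfg.consolidate:
        group_order = [cfg.consolidated_name] + [
            g for g in dict.fromkeys(samples["group"]) if g != cfg.consolidated_name
        ]

    def s_hits():
        tests = hits_mod.group_tests(
            z, samples=samples, equal_var=cfg.equal_var, group_order=group_order
        )
        table = hits_mod.call_hits(
            tests,
            dz=dz,
            alpha=cfg.alpha,
            noise_cutoff=cfg.noise_cutoff,
            samples=samples,
        )
        table.to_csv(out / "hits.tsv", sep="\t", index=False)
        io_mod.write_json(hits_mod.hit_summary(table), out / "hit_summary.json")
        emit("hits", out / "hits.tsv", out / "hit_summary.json")
        return table

    hit_table = run_stage("hits", s_hits)

    # -- 7: clustering ------------------------------------------------------
    def s_cluster():
        cdir = out / "cluster"
        cdir.mkdir(exist_ok=True)
        written = []
        for process in z.processes:
            conds = None
            if cfg.cluster_significant_only:
                sub = hit_table[(hit_table["process"] == process) & hit_table["hit"]]
                conds = sorted(sub["condition"].unique())
                if len(conds) < 2:  # not enough hit profiles; use all conditions
                    conds = None
            corr = cluster_mod.sample_correlations(z, process, conds)
            corr.to_csv(cdir / f"{process}_sample_correlations.tsv", sep="\t")
            written.append(cdir / f"{process}_sample_correlations.tsv")
            link, labels, _ = cluster_mod.hierarchical_cluster(z, process, conds)
            (cdir / f"{process}_dendrogram.nwk").write_text(
                cluster_mod.linkage_to_newick(link, labels) + "\n", encoding="utf-8"
            )
            written.append(cdir / f"{process}_dendrogram.nwk")
            scores, evr = cluster_mod.pca_scores(z, process, conds)
            scores.to_csv(cdir / f"{process}_pca.tsv", sep="\t", index_label="sample")
            io_mod.write_json(
                {"explained_variance_ratio": list(evr)},
                cdir / f"{process}_pca_variance.json",
            )
            written.append(cdir / f"{process}_pca.tsv")
            written.append(cdir / f"{process}_pca_variance.json")
        emit("cluster", *written)

    run_stage("cluster", s_cluster)

    # -- 8-10: expansion, GSEA, networks ------------------------------------
    if tmap is not None and collection is not None:
        rdir = out / "rank"
        gdir = out / "gsea"
        ndir = out / "network"
        for d in (rdir, gdir, ndir):
            d.mkdir(exist_ok=True)
        groups = group_order or list(dict.fromkeys(samples["group"]))
        network_summaries = {}
        for process in z.processes:
            sub = hit_table[(hit_table["process"] == process) & hit_table["hit"]]
            if sub.empty:
                continue

            def s_rank(sub=sub, process=process):
                gene_map, warnings = expand_mod.expand_hits(
                    sub, tmap, cfg.concentration_ceiling_uM, cfg.metric_mode
                )
                if not gene_map:
                    return None
                rl = expand_mod.aggregate_to_ranked_list(
                    gene_map,
                    cfg.aggregation_rule,
                    comparison=f"{sub.iloc[0]['group_a']} vs {sub.iloc[0]['group_b']}",
                    process=process,
                )
                io_mod.write_rnk(rl, rdir / f"{process}.rnk")
                emit("rank", rdir / f"{process}.rnk")
                if warnings:
                    io_mod.write_json(warnings, rdir / f"{process}_warnings.json")
                    emit("rank", rdir / f"{process}_warnings.json")
                return rl

            rl = run_stage(f"rank[{process}]", s_rank)
            if rl is None or len(rl) < 2:
                continue

            def s_gsea(rl=rl, process=process):
                res = gsea_mod.run_gsea(
                    rl,
                    collection,
                    alpha_fdr=cfg.fdr_alpha,
                    n_perm=cfg.n_perm,
                    seed=cfg.seed,
                    weight_exponent=cfg.gsea_weight,
                    min_size=cfg.gsea_min_size,
                    max_size=cfg.gsea_max_size,
                )
                res.table.to_csv(gdir / f"{process}_results.tsv", sep="\t", index=False)
                emit("gsea", gdir / f"{process}_results.tsv")
                return res

            res = run_stage(f"gsea[{process}]", s_gsea)
            if res.passing.empty:
                continue

            def s_network(res=res, process=process):
                graph = emap.build_network(
                    res.passing,
                    cutoff=cfg.overlap_cutoff,
                    positive_group=groups[0],
                    negative_group=groups[1] if len(groups) > 1 else "other",
                )
                emap.write_graphml(graph, ndir / f"{process}.graphml")
                emap.write_sif(graph, ndir / f"{process}.sif")
                summary = emap.classify_interactomes(graph)
                network_summaries[process] = {
                    "universal_fraction": summary.universal_fraction,
                    "n_nodes": summary.n_nodes,
                    "n_edges": summary.n_edges,
                    "components": summary.components,
                }
                emit("network", ndir / f"{process}.graphml", ndir / f"{process}.sif")

            run_stage(f"network[{process}]", s_network)
        if network_summaries:
            io_mod.write_json(network_summaries, out / "network_summary.json")
            emit("network", out / "network_summary.json")

    # -- size-control analysis ---------------------------------------------
    def s_size():
        means = (
            norm.wells.groupby(["condition", "group"], sort=True)[["size_g1", "size_g2m"]]
            .mean()
            .reset_index()
        )
        records, skipped = size_mod.size_records(means, cfg.sphere_convention)
        records.to_csv(out / "size_records.tsv", sep="\t", index=False)
        result: dict = {"skipped": skipped, "per_group": {}}
        for group, sub in records.groupby("group"):
            if len(sub) < 3:
                continue
            fit = size_mod.fit_size_model(sub["volume_g1"], sub["delta_v"])
            corr = size_mod.birth_division_correlation(sub["size_g1"], sub["size_g2m"])
            result["per_group"][group] = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "slope_ci": list(fit.slope_ci),
                "classification": fit.classification,
                "qualifier": fit.qualifier,
                "added_variance": fit.added_variance,
                "r_value": fit.r_value,
                "n": fit.n,
                "birth_division": corr,
            }
        if records["group"].nunique() >= 2:
            groups_added = {
                g: sub["delta_v"].to_numpy()
                for g, sub in records.groupby("group")
                if len(sub) >= 3
            }
            if len(groups_added) >= 2:
                result["added_size_variance"] = size_mod.added_size_variance(
                    groups_added
                ).to_dict("records")
        io_mod.write_json(result, out / "size_model.json")
        emit("size_model", out / "size_records.tsv", out / "size_model.json")

    run_stage("size_model", s_size)

    # -- manifest ------------------------------------------------------------
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "stages": stage_outputs,
        "checksums": {a: _sha256(out / a) for a in sorted(set(artifacts))},
    }
    io_mod.write_json(manifest, out / "manifest.json")
    return manifest
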