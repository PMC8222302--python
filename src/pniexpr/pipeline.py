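"""End-to-end orchestration: simulate/read -> normalize -> DEG -> clustering
-> panel score/ROC -> enrichment -> cohort stats, with a run manifest.

Contrasts are two-group only, mirroring the study design: EXT vs NON,
EXT vs FOCAL, FOCAL vs NON, and EXT vs the combined FOCAL_NON control
group.  A confounder check stratifies a cohort on a covariate (nerve
fraction by default, boundary rule: "low" = value <= cutoff) and reruns
the differential expression within the stratified cohort.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .cluster import evaluate_segregation, hierarchical_cluster, scale_genes
from .containers import ExpressionMatrix
from .diffexpr import (compare_deg_sets, log_transform, moderated_t_table,
                       select_degs)
from .enrich import hypergeometric_ora
from .cohort import cohort_summary
from .normalize import normalize_pipeline
from .panel import (build_panel, classify, confusion_metrics, roc_curve,
                    score_samples)
from .simulate import GeneratorConfig, generate_cohort

CONTRASTS = (("NON", "EXT"), ("FOCAL", "EXT"), ("NON", "FOCAL"), ("FOCAL_NON", "EXT"))


@dataclass
class PipelineConfig:
    """Everything one run needs; flat keys so a YAML file maps 1:1."""

    counts_path: str | None = None
    annotation_path: str | None = None
    simulate: bool = True
    seed: int = 0
    background_method: str = "mean"
    pseudocount: float = 0.0
    fc_cuts: tuple[float, ...] = (2.0, 3.0)
    adj_p_cut: float = 0.01
    cluster_top_n: int = 70
    cluster_linkage: str = "average"
    cluster_k: int = 2
    panel_size: int = 10
    panel_centile: float = 0.95
    panel_cutoff: float = 2.5
    panel_direction: str = "upper"
    gmt_path: str | None = None
    outdir: str = "pniexpr_out"
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fc_cuts" in raw:
            raw["fc_cuts"] = tuple(raw["fc_cuts"])
        return cls(**raw)

    def validate(self) -> "PipelineConfig":
        if any(fc <= 1 for fc in self.fc_cuts):
            raise ValueError("fold-change cuts must exceed 1")
        if not 0 < self.adj_p_cut < 1:
            raise ValueError("adj_p_cut must lie in (0, 1)")
        if not self.simulate and (self.counts_path is None
                                  or self.annotation_path is None):
            raise ValueError("need counts_path and annotation_path unless simulating")
        return self


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage, writing artifacts and a manifest under outdir.

    A stage failure aborts downstream stages but the manifest (with the
    error recorded) and completed outputs are preserved.
    """
    config = config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "warnings": [],
        "error": None,
    }

    def stage(name):
        manifest["stages"][name] = {"started": time.time(), "outputs": []}
        return manifest["stages"][name]

    def finish(rec, *paths):
        rec["outputs"] = [str(p) for p in paths]
        rec["checksums"] = {Path(p).name: _checksum(Path(p)) for p in paths}
        rec["seconds"] = round(time.time() - rec.pop("started"), 3)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _run_stages(config, outdir, manifest, stage, finish)
        manifest["warnings"] = sorted({str(w.message) for w in caught})
    except Exception as exc:  # manifest survives partial failure
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        pio.write_json(manifest, outdir / "manifest.json")
        raise
    pio.write_json(manifest, outdir / "manifest.json")
    return manifest


def _run_stages(config, outdir, manifest, stage, finish):
    # ---- input ------------------------------------------------------------
    rec = stage("input")
    if config.simulate:
        gen = GeneratorConfig(**{**config.generator, "seed": config.seed})
        matrix, annotation, _truth = generate_cohort(gen)
    else:
        matrix = pio.read_counts_table(config.counts_path)
        annotation = pio.read_annotation(config.annotation_path)
    counts_path = outdir / "counts.tsv"
    ann_path = outdir / "annotation.csv"
    pio.write_counts_table(matrix, counts_path)
    pio.write_annotation(annotation, ann_path)
    finish(rec, counts_path, ann_path)

    # ---- normalization ----------------------------------------------------
    rec = stage("normalize")
    norm, factors = normalize_pipeline(matrix, config.background_method,
                                       config.pseudocount)
    norm_path = outdir / "normalized.tsv"
    fac_path = outdir / "normalization_factors.tsv"
    pio.write_counts_table(norm, norm_path)
    pio.write_table(factors.to_frame(), fac_path, index_label="sample_id")
    finish(rec, norm_path, fac_path)

    # ---- differential expression -----------------------------------------
    rec = stage("diffexpr")
    log_norm = log_transform(norm)
    endo_log = ExpressionMatrix(values=log_norm.endogenous,
                                probe_classes=log_norm.probe_classes.loc[
                                    log_norm.endogenous.index])
    labels = annotation["cohort"].copy()
    combined = labels.replace({"NON": "FOCAL_NON", "FOCAL": "FOCAL_NON"})
    deg_tables: dict[str, pd.DataFrame] = {}
    deg_paths = []
    for g1, g2 in CONTRASTS:
        lab = combined if "FOCAL_NON" in (g1, g2) else labels
        table = moderated_t_table(endo_log, lab, g1, g2)
        name = f"{g2}_vs_{g1}"
        deg_tables[name] = table
        path = outdir / f"deg_{name}.tsv"
        pio.write_table(table, path, index_label="gene_id")
        deg_paths.append(path)
    finish(rec, *deg_paths)

    # ---- DEG set comparisons (Venn) --------------------------------------
    rec = stage("deg_sets")
    venn = {}
    sets = {}
    for name, table in deg_tables.items():
        for fc in config.fc_cuts:
            up, down = select_degs(table, fc_cut=fc, p_cut=config.adj_p_cut)
            sets[(name, fc, "up")] = up
            sets[(name, fc, "down")] = down
            venn[f"{name}_fc{fc:g}"] = {"n_up": len(up), "n_down": len(down)}
    fc_max = max(config.fc_cuts)
    for direction in ("up", "down"):
        comp = compare_deg_sets(sets[("EXT_vs_FOCAL", fc_max, direction)],
                                sets[("EXT_vs_NON", fc_max, direction)])
        venn[f"EXT_vs_FOCAL__EXT_vs_NON_{direction}"] = {
            "n_shared": comp["n_shared"],
            "n_unique_to_EXT_vs_FOCAL": comp["n_unique_to_a"],
            "n_unique_to_EXT_vs_NON": comp["n_unique_to_b"],
        }
    venn_path = outdir / "deg_set_comparisons.json"
    pio.write_json(venn, venn_path)
    finish(rec, venn_path)

    # ---- clustering -------------------------------------------------------
    rec = stage("clustering")
    main = deg_tables["EXT_vs_FOCAL_NON"]
    up, down = select_degs(main, fc_cut=fc_max, p_cut=config.adj_p_cut)
    chosen = [g for g in main.index if g in (up | down)][: config.cluster_top_n]
    if len(chosen) < 2:  # degenerate: fall back to the most significant genes
        chosen = list(main.index[: config.cluster_top_n])
    sub = ExpressionMatrix(values=endo_log.values.loc[chosen],
                           probe_classes=endo_log.probe_classes.loc[chosen])
    scaled, _flagged = scale_genes(sub)
    dend = hierarchical_cluster(scaled, axis="samples",
                                linkage=config.cluster_linkage)
    # segregation question: does EXT separate from the combined controls?
    assignment, crosstab, outliers = evaluate_segregation(
        dend, combined, k=config.cluster_k)
    clus_path = outdir / "cluster_assignments.tsv"
    merge_path = outdir / "cluster_merges.tsv"
    pio.write_table(assignment.to_frame(), clus_path, index_label="sample_id")
    pio.write_table(pd.DataFrame(dend.linkage_matrix,
                                 columns=["node_a", "node_b", "height", "size"]),
                    merge_path, index_label="merge")
    manifest["stages"]["clustering"]["outliers"] = outliers
    manifest["stages"]["clustering"]["crosstab"] = {
        str(k): {str(c): int(v) for c, v in row.items()}
        for k, row in crosstab.to_dict("index").items()}
    finish(rec, clus_path, merge_path)

    # ---- panel score ------------------------------------------------------
    rec = stage("panel")
    norm_endo = ExpressionMatrix(values=norm.endogenous,
                                 probe_classes=norm.probe_classes.loc[
                                     norm.endogenous.index])
    panel = build_panel(main, norm_endo, annotation, config.panel_size,
                        config.panel_centile, config.panel_direction)
    scores = score_samples(panel, norm_endo)
    predicted = classify(scores, config.panel_cutoff)
    truth = annotation["cohort"] == "EXT"
    metrics = confusion_metrics(predicted, truth)
    roc = roc_curve(scores.totals, truth)
    metrics["auc"] = roc.auc
    panel_path = outdir / "panel.tsv"
    score_path = outdir / "scores.tsv"
    roc_path = outdir / "roc.tsv"
    metrics_path = outdir / "panel_metrics.json"
    pio.write_table(panel.to_frame(), panel_path, index_label="gene_id")
    pio.write_table(scores.to_frame(), score_path, index_label="sample_id")
    pio.write_table(roc.to_frame(), roc_path)
    pio.write_json(metrics, metrics_path)
    finish(rec, panel_path, score_path, roc_path, metrics_path)

    # ---- enrichment -------------------------------------------------------
    if config.gmt_path:
        rec = stage("enrichment")
        collection = pio.read_gmt(config.gmt_path)
        universe = list(norm_endo.probe_ids)
        query = sorted(up | down) or list(main.index[: config.cluster_top_n])
        enr = hypergeometric_ora(query, collection, universe)
        enr_path = outdir / "enrichment.tsv"
        pio.write_table(enr, enr_path, index_label="set_id")
        finish(rec, enr_path)

    # ---- cohort stats -----------------------------------------------------
    rec = stage("cohort_stats")
    summary = cohort_summary(annotation)
    stats_path = outdir / "cohort_stats.tsv"
    pio.write_table(summary, stats_path, index_label="parameter")
    finish(rec, stats_path)


def stratify_confounder(matrix_log: ExpressionMatrix, annotation: pd.DataFrame,
                        covariate: str = "nerve_fraction", cutoff: float = 0.10,
                        cohort: str = "EXT", adj_p_cut: float = 0.05) -> dict:
    """Within-cohort DEG analysis between covariate-low and -high strata.

    "Low" means covariate <= cutoff (values exactly at the cutoff fall in
    the low stratum).  Returns the DEG table and the count of genes below
    the adjusted-p threshold; a stratum with fewer than two samples is an
    error suggesting a different cutoff.
    """
    ann = annotation[annotation["cohort"] == cohort]
    if covariate not in ann.columns or ann[covariate].isna().any():
        raise ValueError(f"covariate {covariate!r} missing for some {cohort} samples")
    strata = pd.Series(pd.NA, index=ann.index, dtype="object")
    strata[ann[covariate] <= cutoff] = "low"
    strata[ann[covariate] > cutoff] = "high"
    n_low = int((strata == "low").sum())
    n_high = int((strata == "high").sum())
    if n_low < 2 or n_high < 2:
        raise ValueError(
            f"stratum too small (low={n_low}, high={n_high}); choose a cutoff "
            f"closer to the covariate's median")
    sub = matrix_log.subset_samples(ann.index)
    table = moderated_t_table(sub, strata, "low", "high")
    n_sig = int((table["p_adj"] < adj_p_cut).sum())
    return {"table": table, "n_significant": n_sig, "n_low": n_low,
            "n_high": n_high, "cutoff": cutoff, "adj_p_cut": adj_p_cut}
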