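"""Simulation-study summaries: run the full analysis on one synthetic cohort
and report the quantities a validation study cares about (panel
sensitivity/specificity/AUC at the score cutoff, DEG counts at the
fold-change filters, null-contrast counts)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .diffexpr import log_transform, moderated_t_table, select_degs
from .normalize import normalize_pipeline
from .panel import build_panel, classify, confusion_metrics, roc_curve, score_samples
from .simulate import GeneratorConfig, generate_cohort


def _endogenous(matrix: ExpressionMatrix) -> ExpressionMatrix:
    endo = matrix.endogenous
    return ExpressionMatrix(values=endo,
                            probe_classes=matrix.probe_classes.loc[endo.index])


def run_cohort_analysis(config: GeneratorConfig, panel_size: int = 10,
                        centile: float = 0.95, cutoff: float = 2.5,
                        fc_cuts: tuple[float, ...] = (2.0, 3.0),
                        adj_p_cut: float = 0.01) -> dict:
    """Simulate -> normalize -> DEG -> panel -> score on one cohort.

    Returns per-cohort metrics: ``sensitivity``, ``specificity``, ``auc``
    (10-gene score vs EXT membership), ``n_deg_fc{c}`` per fold-change cut,
    ``n_focal_vs_non_significant`` (adjusted p < 0.05), and ``n_samples``.
    """
    matrix, annotation, _truth = generate_cohort(config)
    norm, _factors = normalize_pipeline(matrix)
    endo_log = _endogenous(log_transform(norm))
    labels = annotation["cohort"].replace({"NON": "FOCAL_NON", "FOCAL": "FOCAL_NON"})
    table = moderated_t_table(endo_log, labels, "FOCAL_NON", "EXT")

    out: dict = {"n_samples": matrix.shape[1]}
    for fc in fc_cuts:
        up, down = select_degs(table, fc_cut=fc, p_cut=adj_p_cut)
        out[f"n_deg_fc{fc:g}"] = len(up) + len(down)

    fvn = moderated_t_table(endo_log, annotation["cohort"], "NON", "FOCAL")
    out["n_focal_vs_non_significant"] = int((fvn["p_adj"] < 0.05).sum())

    endo_norm = _endogenous(norm)
    panel = build_panel(table, endo_norm, annotation, panel_size, centile)
    scores = score_samples(panel, endo_norm)
    truth_ext = annotation["cohort"] == "EXT"
    metrics = confusion_metrics(classify(scores, cutoff), truth_ext)
    out.update({k: metrics[k] for k in ("sensitivity", "specificity",
                                        "tp", "fn", "tn", "fp")})
    out["auc"] = roc_curve(scores.totals, truth_ext).auc
    return out


def sweep_seeds(seeds, **kwargs) -> pd.DataFrame:
    """Run :func:`run_cohort_analysis` across seeds; one row per seed."""
    rows = {s: run_cohort_analysis(GeneratorConfig(seed=int(s)), **kwargs)
            for s in seeds}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("seed")
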