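"""Percentile-threshold gene-panel risk score and its evaluation.

The panel takes the top genes of a differential-expression table (ranked
by adjusted p-value, 10 by default).  For each panel gene a threshold is
learned as the 95th centile (linear interpolation between order
statistics, the "type 7" definition) of the control-cohort (Non + Focal)
normalized expression.  A sample scores 1 per gene strictly above its
threshold, giving a total score of 0..panel_size; samples are called
high-risk above a score cutoff (2.5 by default).  Discrimination is
summarized by sensitivity/specificity at the cutoff and by the ROC curve,
whose trapezoid area equals the tie-corrected Mann-Whitney probability.

Because thresholding is rank-based, the score is invariant under any
strictly increasing per-gene transform applied consistently to training
and test values; whether thresholds are learned on linear or log scale is
therefore immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


@dataclass
class ScorePanel:
    """Panel genes with per-gene centile thresholds learned from controls."""

    genes: list[str]
    thresholds: pd.Series  # per-gene threshold on the training scale
    training_samples: list[str]
    centile: float = 0.95
    directions: pd.Series = field(default=None)  # +1 upper-tail, -1 lower-tail

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")
        if self.directions is None:
            self.directions = pd.Series(1, index=self.genes)

    @property
    def size(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "direction": self.directions.map({1: "up", -1: "down"})})


@dataclass
class ScoreResult:
    """Per-sample indicator matrix and total scores."""

    indicators: pd.DataFrame  # genes x samples, 0/1
    totals: pd.Series  # per sample, 0..panel_size

    def to_frame(self) -> pd.DataFrame:
        out = self.indicators.T.copy()
        out["total_score"] = self.totals
        return out


def centile_threshold(values, level: float = 0.95) -> float:
    """Linear-interpolation (type 7) centile of a 1-d sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("centile of an empty sample is undefined")
    return float(np.quantile(arr, level, method="linear"))


def build_panel(deg_table: pd.DataFrame, matrix_norm: ExpressionMatrix,
                annotation: pd.DataFrame, panel_size: int = 10,
                centile: float = 0.95, direction: str = "upper") -> ScorePanel:
    """Build the score panel from a sorted DEG table and normalized data.

    Panel genes are the first ``panel_size`` rows of ``deg_table`` (which is
    sorted by adjusted p).  Thresholds are the per-gene ``centile`` of the
    NON + FOCAL training samples' values in ``matrix_norm``.  With
    ``direction='auto'``, genes with negative log2fc instead use the lower
    (1 - centile) tail, scoring values strictly below the threshold.
    """
    if len(deg_table) < panel_size:
        raise ValueError(
            f"DEG table has {len(deg_table)} genes; panel needs {panel_size}")
    if direction not in ("upper", "auto"):
        raise ValueError("direction must be 'upper' or 'auto'")
    genes = list(deg_table.index[:panel_size])
    training = list(annotation.index[annotation["cohort"].isin(["NON", "FOCAL"])])
    training = [s for s in training if s in matrix_norm.sample_ids]
    if len(training) < 2:
        raise ValueError("panel requires >= 2 NON/FOCAL training samples")
    missing = [g for g in genes if g not in matrix_norm.probe_ids]
    if missing:
        raise ValueError(f"panel gene(s) absent from matrix: {missing}")

    if direction == "auto" and "log2fc" in deg_table.columns:
        dirs = pd.Series(np.where(deg_table.loc[genes, "log2fc"] < 0, -1, 1),
                         index=genes)
    else:
        dirs = pd.Series(1, index=genes)

    train_vals = matrix_norm.values.loc[genes, training].astype(float)
    thresholds = {}
    for g in genes:
        level = centile if dirs[g] == 1 else 1.0 - centile
        thresholds[g] = centile_threshold(train_vals.loc[g], level)
    return ScorePanel(genes=genes, thresholds=pd.Series(thresholds).loc[genes],
                      training_samples=training, centile=centile, directions=dirs)


def score_samples(panel: ScorePanel, matrix_norm: ExpressionMatrix) -> ScoreResult:
    """Score every sample: 1 per gene strictly beyond its threshold.

    Upper-tail genes score on value > threshold; lower-tail genes (auto
    mode) on value < threshold.  Values exactly at a threshold score 0.
    """
    missing = [g for g in panel.genes if g not in matrix_norm.probe_ids]
    if missing:
        raise ValueError(f"panel gene(s) absent from matrix: {missing}")
    vals = matrix_norm.values.loc[panel.genes].astype(float)
    above = vals.gt(panel.thresholds, axis=0)
    below = vals.lt(panel.thresholds, axis=0)
    indicators = above.copy()
    down_genes = [g for g in panel.genes if panel.directions[g] == -1]
    if down_genes:
        indicators.loc[down_genes] = below.loc[down_genes]
    indicators = indicators.astype(int)
    totals = indicators.sum(axis=0).rename("total_score")
    return ScoreResult(indicators=indicators, totals=totals)


def classify(result: ScoreResult, cutoff: float = 2.5) -> pd.Series:
    """High-risk (EXT-like) call: total score strictly above the cutoff."""
    return (result.totals > cutoff).rename("predicted_ext")


def confusion_metrics(predicted: pd.Series, truth: pd.Series) -> dict:
    """Sensitivity/specificity/PPV/NPV with EXT (True) as the positive class.

    ``truth`` is boolean (True = EXT).  Undefined metrics (empty class)
    are returned as None with a warning.
    """
    predicted, truth = predicted.align(truth, join="inner")
    pred = predicted.astype(bool)
    pos = truth.astype(bool)
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined: empty denominator", stacklevel=3)
            return None
        return num / den

    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "ppv": ratio(tp, tp + fp, "PPV"),
        "npv": ratio(tn, tn + fn, "NPV"),
    }


@dataclass
class RocResult:
    """ROC operating points and trapezoid AUC."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.cutoffs,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


def roc_curve(scores: pd.Series, truth: pd.Series) -> RocResult:
    """ROC over cutoffs at midpoints between distinct scores (plus sentinels).

    A sample is called positive when its score strictly exceeds the cutoff.
    The trapezoid area over (1 - specificity, sensitivity) equals the
    Mann-Whitney probability P(score_pos > score_neg) + P(tie)/2.
    """
    scores = pd.Series(scores).astype(float)
    truth = pd.Series(truth).reindex(scores.index).astype(bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    uniq = np.unique(scores.values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    # descending cutoffs walk the curve from (0, 0) to (1, 1)
    cutoffs = np.concatenate([[uniq[-1] + 1.0], mids[::-1], [uniq[0] - 1.0]])

    s = scores.values
    t = truth.values
    sens = np.array([np.mean(s[t] > c) for c in cutoffs])
    spec = np.array([np.mean(s[~t] <= c) for c in cutoffs])
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return RocResult(cutoffs=cutoffs, sensitivity=sens, specificity=spec, auc=auc)


def mann_whitney_auc(scores: pd.Series, truth: pd.Series) -> float:
    """AUC by exhaustive pair comparison with half-weight ties."""
    scores = pd.Series(scores).astype(float)
    truth = pd.Series(truth).reindex(scores.index).astype(bool)
    pos = scores[truth].values
    neg = scores[~truth].values
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires both classes present")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (pos.size * neg.size))


def null_score_calibration(panel: ScorePanel, null_matrix: ExpressionMatrix) -> dict:
    """Summarize scores of held-out null samples against the binomial reference.

    Under independence, per-gene exceedance should approach 1 - centile and
    the mean score panel_size * (1 - centile) as the training set grows.
    """
    result = score_samples(panel, null_matrix)
    n = null_matrix.shape[1]
    exceedance = result.indicators.mean(axis=1).rename("exceedance_rate")
    expected_rate = 1.0 - panel.centile
    score_counts = result.totals.value_counts().sort_index()
    return {
        "n_samples": n,
        "per_gene_exceedance": exceedance,
        "mean_exceedance": float(exceedance.mean()) if n else float("nan"),
        "expected_exceedance": expected_rate,
        "mean_score": float(result.totals.mean()) if n else float("nan"),
        "expected_mean_score": panel.size * expected_rate,
        "score_distribution": score_counts,
    }
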