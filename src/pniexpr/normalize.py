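"""nSolver-style preprocessing chain for nCounter count matrices.

Order follows the nSolver default: (1) background correction from the
spiked-in negative-control probes, (2) positive-control normalization,
(3) codeset-content ("housekeeping") normalization.  Both normalizations
use the same construction: per-sample geometric mean of the reference
probes, scaled so the cohort-average geometric mean is restored —

    factor(s) = mean_s'( geomean(ref probes, s') ) / geomean(ref probes, s)

Positive-control factors apply to all non-control probes; housekeeping
factors apply to endogenous probes only.  Factors outside [0.3, 3.0] are
flagged (QC convention) but never dropped here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

BACKGROUND_METHODS = ("mean", "mean_plus_2sd", "max")
FACTOR_QC_BOUNDS = (0.3, 3.0)


@dataclass
class NormalizationFactors:
    """Per-sample background estimates and normalization factors."""

    background: pd.Series | None = None
    positive_factor: pd.Series | None = None
    housekeeping_factor: pd.Series | None = None

    def flags(self) -> pd.DataFrame:
        """True where a factor falls outside the QC window [0.3, 3.0]."""
        lo, hi = FACTOR_QC_BOUNDS
        cols = {}
        for name in ("positive_factor", "housekeeping_factor"):
            f = getattr(self, name)
            if f is not None:
                cols[name] = (f < lo) | (f > hi)
        return pd.DataFrame(cols)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for name in ("background", "positive_factor", "housekeeping_factor"):
            f = getattr(self, name)
            if f is not None:
                cols[name] = f
        frame = pd.DataFrame(cols)
        flags = self.flags()
        for c in flags.columns:
            frame[c + "_flagged"] = flags[c]
        return frame


def background_correct(matrix: ExpressionMatrix, method: str = "mean"
                       ) -> tuple[ExpressionMatrix, pd.Series]:
    """Subtract a per-sample background estimated from negative controls.

    ``method`` is one of ``mean`` (nSolver default), ``mean_plus_2sd`` or
    ``max`` of the sample's negative probes.  The background is subtracted
    from all non-control probes with results floored at zero; control rows
    are retained unchanged for audit.
    """
    if method not in BACKGROUND_METHODS:
        raise ValueError(f"unknown background method {method!r}; "
                         f"expected one of {BACKGROUND_METHODS}")
    neg = matrix.negative
    if neg.shape[0] == 0:
        raise ValueError("background correction requires at least one Negative probe")
    if method == "mean":
        bg = neg.mean(axis=0)
    elif method == "mean_plus_2sd":
        bg = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    else:
        bg = neg.max(axis=0)
    bg = bg.astype(float)

    values = matrix.values.astype(float).copy()
    target = matrix.probe_classes.isin(["Endogenous", "Housekeeping"]).values
    corrected = values.loc[target].sub(bg, axis=1).clip(lower=0.0)
    values.loc[target] = corrected
    return matrix.with_values(values), bg.rename("background")


def _geometric_means(block: pd.DataFrame, pseudocount: float) -> pd.Series:
    if block.shape[0] == 0:
        raise ValueError("no reference probes for geometric mean")
    vals = block.astype(float) + pseudocount
    if (vals <= 0).any().any():
        bad = vals.columns[(vals <= 0).any(axis=0)]
        raise ValueError(
            "geometric mean undefined: zero reference count in sample(s) "
            f"{list(bad[:5])}; enable the pseudocount option"
        )
    return np.exp(np.log(vals).mean(axis=0))


def _factor_normalize(matrix: ExpressionMatrix, ref_class: str, target_mask,
                      pseudocount: float, scale_controls: bool
                      ) -> tuple[ExpressionMatrix, pd.Series]:
    ref = matrix.values.loc[matrix.probes_of_class(ref_class)]
    geo = _geometric_means(ref, pseudocount)
    factors = geo.mean() / geo
    values = matrix.values.astype(float).copy()
    mask = target_mask.values if hasattr(target_mask, "values") else target_mask
    values.loc[mask] = values.loc[mask].mul(factors, axis=1)
    if scale_controls:
        values.loc[~mask] = values.loc[~mask].mul(factors, axis=1)
    return matrix.with_values(values), factors.rename(f"{ref_class.lower()}_factor")


def positive_control_normalize(matrix: ExpressionMatrix, pseudocount: float = 0.0,
                               scale_controls: bool = False
                               ) -> tuple[ExpressionMatrix, pd.Series]:
    """Scale each sample so positive-control geometric means agree.

    The factor multiplies all non-control probes (endogenous and
    housekeeping).  With ``scale_controls=True`` the control rows are scaled
    too, which makes the equalized positive geometric means directly
    inspectable.
    """
    if matrix.positive.shape[0] == 0:
        raise ValueError("positive-control normalization requires Positive probes")
    target = matrix.probe_classes.isin(["Endogenous", "Housekeeping"])
    return _factor_normalize(matrix, "Positive", target, pseudocount, scale_controls)


def housekeeping_normalize(matrix: ExpressionMatrix, pseudocount: float = 0.0,
                           scale_housekeeping: bool = False
                           ) -> tuple[ExpressionMatrix, pd.Series]:
    """Codeset-content normalization: housekeeping-derived per-sample factor.

    Same geometric-mean construction as the positive-control step, computed
    over the housekeeping probes and applied to endogenous probes only
    (the nSolver "sample-specific correction factor to the target probes").
    A single-sample matrix is its own reference, so its factor is 1.
    """
    if matrix.housekeeping.shape[0] < 2:
        raise ValueError("housekeeping normalization requires >= 2 Housekeeping probes")
    target = matrix.probe_classes == "Endogenous"
    return _factor_normalize(matrix, "Housekeeping", target, pseudocount,
                             scale_housekeeping)


def normalize_pipeline(matrix: ExpressionMatrix, background_method: str = "mean",
                       pseudocount: float = 0.0
                       ) -> tuple[ExpressionMatrix, NormalizationFactors]:
    """Full chain: background -> positive-control -> housekeeping."""
    corrected, bg = background_correct(matrix, method=background_method)
    pos_norm, pos_f = positive_control_normalize(corrected, pseudocount=pseudocount)
    hk_norm, hk_f = housekeeping_normalize(pos_norm, pseudocount=pseudocount)
    factors = NormalizationFactors(background=bg, positive_factor=pos_f,
                                   housekeeping_factor=hk_f)
    return hk_norm, factors
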