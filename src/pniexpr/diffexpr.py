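"""Two-group differential expression with empirical-Bayes variance moderation.

Per gene, an ordinary two-sample comparison on log2 expression yields the
log fold change, pooled residual variance s2 (df = n1 + n2 - 2) and the
unscaled standard deviation sqrt(1/n1 + 1/n2).  The gene-wise variances are
then shrunk toward a common prior by fitting a scaled inverse-chi-square
prior s2_g ~ s0^2 * d0 / chi^2(d0) by method of moments on log variances
(Smyth 2004):

    z_g = log s2_g,
    e_g = z_g - digamma(df/2) + log(df/2),
    trigamma(d0/2) = var(e) - trigamma(df/2)        (solved for d0),
    log s0^2 = mean(e) + digamma(d0/2) - log(d0/2),
    s~2_g = (d0*s0^2 + df*s2_g) / (d0 + df),
    t_g = log2fc_g / (sqrt(s~2_g) * stdev_unscaled),

with two-sided p-values from a t reference on d0 + df degrees of freedom
(normal when d0 is unbounded).  Multiplicity is controlled with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix


def log_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset); values must be nonnegative."""
    vals = matrix.values.astype(float)
    if (vals.values < 0).any():
        raise ValueError("log transform requires nonnegative values")
    if offset <= 0 and (vals.values == 0).any():
        raise ValueError("offset must be positive when zeros are present")
    return matrix.with_values(np.log2(vals + offset))


@dataclass
class TwoGroupFit:
    """Per-gene summaries of an ordinary two-group comparison (log2 scale)."""

    log2fc: pd.Series  # mean(group2) - mean(group1)
    mean_g1: pd.Series
    mean_g2: pd.Series
    s2: pd.Series  # pooled residual variance
    df_residual: int
    stdev_unscaled: float  # sqrt(1/n1 + 1/n2)
    zero_variance_genes: list[str]


def fit_two_group(matrix_log: ExpressionMatrix, labels: pd.Series,
                  group1, group2) -> TwoGroupFit:
    """Ordinary per-gene two-group fit on a log2-scale matrix.

    ``labels`` maps sample id to group label; ``group1``/``group2`` select
    the contrast (log2fc is group2 minus group1).  Each group needs at
    least two samples.
    """
    labels = pd.Series(labels)
    ids1 = labels.index[labels == group1]
    ids2 = labels.index[labels == group2]
    n1, n2 = len(ids1), len(ids2)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >= 2 samples; got {group1}={n1}, {group2}={n2}"
        )
    x1 = matrix_log.values.loc[:, ids1].astype(float)
    x2 = matrix_log.values.loc[:, ids2].astype(float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss1 = ((x1.sub(m1, axis=0)) ** 2).sum(axis=1)
    ss2 = ((x2.sub(m2, axis=0)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    zero = list(s2.index[s2 == 0])
    return TwoGroupFit(
        log2fc=(m2 - m1).rename("log2fc"),
        mean_g1=m1.rename("mean_g1"),
        mean_g2=m2.rename("mean_g2"),
        s2=s2.rename("s2"),
        df_residual=df,
        stdev_unscaled=float(np.sqrt(1.0 / n1 + 1.0 / n2)),
        zero_variance_genes=zero,
    )


@dataclass
class ModerationFit:
    """Hyperparameters and posterior variances of the eBayes shrinkage."""

    d0: float  # prior degrees of freedom; inf when variances are exchangeable
    s0_sq: float  # prior variance
    s_tilde_sq: pd.Series  # posterior (moderated) variances


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0_sq) on log variances.

    Returns ``d0 = inf`` when the observed spread of log variances does not
    exceed what sampling alone explains (all true variances equal).
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("variance prior requires >= 2 genes")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(np.mean(e))
    # n-1 in the variance of e, following the moment estimator's finite-sample
    # correction for estimating the mean of e.
    n = s2.size
    evar = float(np.sum((e - ebar) ** 2) / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def ebayes_moderate(fit: TwoGroupFit, d0_override: float | None = None
                    ) -> tuple[ModerationFit, pd.DataFrame]:
    """Moderate gene-wise variances and compute moderated t statistics.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary pooled t exactly; inf fully pools the variance).  Returns the
    moderation fit and a table sorted by adjusted p (ties: raw p, gene id)
    with columns log2fc, mean_g1, mean_g2, s2, t_mod, df_total, p_raw, p_adj.
    """
    s2 = fit.s2.astype(float).copy()
    df = float(fit.df_residual)
    flagged = fit.zero_variance_genes
    if len(flagged) == len(s2):
        raise ValueError("all genes have zero variance; nothing to moderate")
    if flagged:
        # keep zero-variance genes in the moment fit at the smallest positive
        # variance rather than dropping them, which would bias d0 upward
        smallest = s2[s2 > 0].min()
        s2.loc[flagged] = smallest
        warnings.warn(
            f"{len(flagged)} zero-variance gene(s) set to the smallest positive "
            "variance for moderation", stacklevel=2)

    if len(s2) == 1:
        warnings.warn("single gene: moderation skipped, ordinary t returned",
                      stacklevel=2)
        d0, s0_sq = 0.0, float(s2.iloc[0])
    elif d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_variance_prior(s2.values, df)
    else:
        d0, s0_sq = fit_variance_prior(s2.values, df)

    if np.isinf(d0):
        s_tilde = pd.Series(s0_sq, index=s2.index)
        df_total = np.inf
    else:
        s_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0

    t_mod = fit.log2fc / (np.sqrt(s_tilde) * fit.stdev_unscaled)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = pd.Series(p_raw, index=t_mod.index)
    p_adj = adjust_bh(p_raw)

    table = pd.DataFrame(
        {
            "log2fc": fit.log2fc,
            "mean_g1": fit.mean_g1,
            "mean_g2": fit.mean_g2,
            "s2": fit.s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    table.index.name = "gene_id"
    table = table.sort_values(["p_adj", "p_raw", "gene_id"], kind="mergesort")
    mod = ModerationFit(d0=d0, s0_sq=s0_sq, s_tilde_sq=s_tilde.rename("s_tilde_sq"))
    return mod, table


def moderated_t_table(matrix_log: ExpressionMatrix, labels: pd.Series,
                      group1, group2) -> pd.DataFrame:
    """Convenience: fit_two_group then ebayes_moderate; returns the table."""
    fit = fit_two_group(matrix_log, labels, group1, group2)
    _, table = ebayes_moderate(fit)
    return table


def adjust_bh(p_raw) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    if isinstance(p_raw, pd.Series):
        return pd.Series(out, index=p_raw.index, name="p_adj")
    return out


def select_degs(table: pd.DataFrame, fc_cut: float = 2.0, p_cut: float = 0.01
                ) -> tuple[set[str], set[str]]:
    """Split significant genes into up/down sets by linear fold change.

    ``fc_cut`` is on the linear scale with strict inequalities: up-regulated
    genes satisfy 2^log2fc > fc_cut, down-regulated 2^log2fc < 1/fc_cut,
    both requiring adjusted p < ``p_cut``.
    """
    if fc_cut <= 1:
        raise ValueError("fc_cut must exceed 1 (linear fold-change scale)")
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must lie in (0, 1)")
    sig = table["p_adj"] < p_cut
    fc = 2.0 ** table["log2fc"]
    up = set(table.index[sig & (fc > fc_cut)])
    down = set(table.index[sig & (fc < 1.0 / fc_cut)])
    return up, down


def compare_deg_sets(set_a, set_b) -> dict:
    """Venn-style comparison of two DEG sets."""
    a, b = set(set_a), set(set_b)
    shared = a & b
    return {
        "shared": shared,
        "unique_to_a": a - b,
        "unique_to_b": b - a,
        "n_shared": len(shared),
        "n_unique_to_a": len(a - b),
        "n_unique_to_b": len(b - a),
    }
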