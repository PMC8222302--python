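"""Cohort-table statistics: Pearson chi-square and two-sample t tests.

These are the demographic/clinical comparisons of a three-cohort study
table: categorical covariates against cohort membership by the Pearson
chi-square test (no continuity correction by default), continuous
covariates by the Student two-sample t-test (pooled variance; Welch
optional).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def chi_square_test(table, yates: bool = False) -> dict:
    """Pearson chi-square test of independence on a contingency table.

    All-zero rows and columns are dropped first; the table must remain at
    least 2 x 2.  Returns statistic, df, p and a low-expected-count flag
    (any expected cell < 5).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if (obs < 0).any() or not np.all(obs == np.round(obs)):
        raise ValueError("contingency table requires nonnegative integer counts")
    obs = obs[obs.sum(axis=1) > 0, :]
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("degenerate contingency table after dropping zero margins")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return {
        "statistic": statistic,
        "df": df,
        "p": p,
        "low_expected": bool((expected < 5).any()),
    }


def two_sample_t(values_a, values_b, equal_variance: bool = True) -> dict:
    """Two-sample t-test: pooled-variance Student by default, Welch optional."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_variance:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    else:
        se2a, se2b = va / a.size, vb / b.size
        se = np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (se2a ** 2 / (a.size - 1) + se2b ** 2 / (b.size - 1))
    if se == 0:
        t = 0.0
    else:
        t = float((ma - mb) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return {"t": t, "df": float(df), "p": p}


def cohort_summary(annotation: pd.DataFrame, combine_non_focal: bool = True
                   ) -> pd.DataFrame:
    """Study-table comparisons of annotation covariates across cohorts.

    Categorical columns are tested by chi-square, numeric by the Student
    t-test (two groups only, so three-cohort layouts are combined to
    Non/Focal vs EXT unless ``combine_non_focal`` is False, in which case
    the chi-square runs on the 3-column layout and t-tests still compare
    EXT against the rest).
    """
    ann = annotation.copy()
    group = np.where(ann["cohort"] == "EXT", "EXT", "FOCAL_NON")
    rows = []
    skip = {"cohort"}
    for col in ann.columns:
        if col in skip:
            continue
        series = ann[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 5:
            res = two_sample_t(series[group == "FOCAL_NON"], series[group == "EXT"])
            rows.append({"parameter": col, "test": "t",
                         "statistic": res["t"], "df": res["df"], "p": res["p"]})
        else:
            cols = group if combine_non_focal else ann["cohort"]
            tab = pd.crosstab(series.astype(str), cols)
            try:
                res = chi_square_test(tab.values)
            except ValueError:
                continue
            rows.append({"parameter": col, "test": "chi2",
                         "statistic": res["statistic"], "df": res["df"],
                         "p": res["p"]})
    return pd.DataFrame(rows).set_index("parameter")
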