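"""Moderated-t machinery against independent oracles (brute force and limma)."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pniexpr.containers import ExpressionMatrix
from pniexpr.diffexpr import (
    adjust_bh,
    compare_deg_sets,
    ebayes_moderate,
    fit_two_group,
    log_transform,
    moderated_t_table,
    select_degs,
)
from pniexpr.simulate import GeneratorConfig, generate_cohort
from pniexpr.normalize import normalize_pipeline

from conftest import endogenous_only, make_matrix


def two_group_labels(n1, n2):
    ids = [f"s{j + 1}" for j in range(n1 + n2)]
    return pd.Series(["A"] * n1 + ["B"] * n2, index=ids)


class TestLogTransform:
    def test_values(self):
        m = make_matrix([[0.0, 7.0], [3.0, 15.0]])
        out = log_transform(m, offset=1.0)
        assert out.values.loc["g1", "s1"] == 0.0
        assert out.values.loc["g1", "s2"] == 3.0  # log2(8)
        assert out.values.loc["g2", "s2"] == 4.0

    def test_monotone_within_sample(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.integers(0, 1000, (50, 1)).astype(float))
        out = log_transform(m)
        orig = m.values["s1"].values
        trans = out.values["s1"].values
        assert (np.argsort(orig, kind="stable")
                == np.argsort(trans, kind="stable")).all()


class TestFitTwoGroup:
    def test_group_mean_difference(self):
        m = make_matrix([[5.0, 5.0, 8.0, 8.0]])
        fit = fit_two_group(m, two_group_labels(2, 2), "A", "B")
        assert fit.log2fc.iloc[0] == pytest.approx(3.0)
        assert fit.s2.iloc[0] == 0.0
        assert fit.zero_variance_genes == ["g1"]

    def test_identical_groups_zero_fc(self):
        rng = np.random.default_rng(2)
        block = rng.normal(5, 1, (20, 3))
        m = make_matrix(np.hstack([block, block]))
        fit = fit_two_group(m, two_group_labels(3, 3), "A", "B")
        assert np.allclose(fit.log2fc, 0.0)

    def test_pooled_variance_matches_textbook_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.normal(6, 1.3, (10, 8))
        m = make_matrix(data)
        fit = fit_two_group(m, two_group_labels(4, 4), "A", "B")
        for i in range(10):  # brute-force pooled variance, gene by gene
            a, b = data[i, :4], data[i, 4:]
            sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 6
            assert fit.s2.iloc[i] == pytest.approx(sp2, rel=1e-12)
        assert fit.df_residual == 6
        assert fit.stdev_unscaled == pytest.approx(np.sqrt(0.5))

    def test_small_group_rejected(self):
        m = make_matrix(np.ones((3, 3)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_two_group(m, two_group_labels(1, 2), "A", "B")


def _moment_oracle(s2, df):
    """Independent method-of-moments fit on log variances (closed form)."""
    from scipy.special import digamma, polygamma
    from scipy.optimize import brentq

    e = np.log(s2) - digamma(df / 2) + np.log(df / 2)
    n = len(s2)
    evar = np.sum((e - e.mean()) ** 2) / (n - 1) - polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, np.exp(e.mean())
    half_d0 = brentq(lambda x: polygamma(1, x) - evar, 1e-8, 1e8)
    d0 = 2 * half_d0
    s0 = np.exp(e.mean() + digamma(half_d0) - np.log(half_d0))
    return d0, s0


@pytest.fixture(scope="module")
def sim_fit():
    rng = np.random.default_rng(7)
    G, n1, n2 = 200, 4, 5
    sig2 = 6.0 * 0.25 / rng.chisquare(6.0, G)
    data = rng.normal(0, 1, (G, n1 + n2)) * np.sqrt(sig2)[:, None] + 5
    data[:30, n1:] += 1.0
    m = make_matrix(data)
    return fit_two_group(m, two_group_labels(n1, n2), "A", "B")


class TestEbayes:
    def test_hyperparameters_match_independent_oracle(self, sim_fit):
        mod, table = ebayes_moderate(sim_fit)
        d0_ref, s0_ref = _moment_oracle(sim_fit.s2.values, sim_fit.df_residual)
        assert mod.d0 == pytest.approx(d0_ref, rel=1e-6)
        assert mod.s0_sq == pytest.approx(s0_ref, rel=1e-6)
        # moderated t recomputed independently
        df = sim_fit.df_residual
        s_tilde = (d0_ref * s0_ref + df * sim_fit.s2) / (d0_ref + df)
        t_ref = sim_fit.log2fc / (np.sqrt(s_tilde) * sim_fit.stdev_unscaled)
        got = table["t_mod"].reindex(t_ref.index)
        assert np.allclose(got, t_ref, rtol=1e-6)

    def test_posterior_variance_between_prior_and_observed(self, sim_fit):
        mod, _ = ebayes_moderate(sim_fit)
        lo = np.minimum(sim_fit.s2, mod.s0_sq)
        hi = np.maximum(sim_fit.s2, mod.s0_sq)
        assert ((mod.s_tilde_sq >= lo - 1e-12) & (mod.s_tilde_sq <= hi + 1e-12)).all()

    def test_d0_zero_recovers_ordinary_pooled_t(self, sim_fit):
        _, table = ebayes_moderate(sim_fit, d0_override=0.0)
        t_ord = sim_fit.log2fc / (np.sqrt(sim_fit.s2) * sim_fit.stdev_unscaled)
        assert np.allclose(table["t_mod"].reindex(t_ord.index), t_ord, rtol=1e-12)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), sim_fit.df_residual)
        assert np.allclose(table["p_raw"].reindex(t_ord.index), p_ord, rtol=1e-12)

    def test_equal_variances_are_a_fixed_point(self):
        rng = np.random.default_rng(11)
        data = rng.normal(5, 1, (50, 8))
        m = make_matrix(data)
        fit = fit_two_group(m, two_group_labels(4, 4), "A", "B")
        fit.s2[:] = 0.7
        mod, _ = ebayes_moderate(fit)
        assert np.isinf(mod.d0)  # no excess spread -> unbounded prior df
        assert np.allclose(mod.s_tilde_sq, mod.s0_sq)

    def test_agreement_with_limma(self, tmp_path):
        """Dual route: the same fixture through Bioconductor limma."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma cross-check cannot run")
        rng = np.random.default_rng(7)
        G, n1, n2 = 120, 4, 5
        sig2 = 6.0 * 0.25 / rng.chisquare(6.0, G)
        data = rng.normal(0, 1, (G, n1 + n2)) * np.sqrt(sig2)[:, None] + 5
        data[:20, n1:] += 1.0
        csv = tmp_path / "fix.csv"
        pd.DataFrame(data, index=[f"g{i}" for i in range(G)]).to_csv(csv)
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'd <- as.matrix(read.csv("{csv}", row.names=1))\n'
            f'design <- model.matrix(~ c(rep(0,{n1}), rep(1,{n2})))\n'
            'fit <- eBayes(lmFit(d, design))\n'
            'res <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior)\n'
            f'write.csv(res, "{tmp_path / "out.csv"}")\n')
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)

        m = make_matrix(data, probe_ids=[f"g{i}" for i in range(G)])
        mod, table = ebayes_moderate(fit_two_group(m, two_group_labels(n1, n2), "A", "B"))
        assert mod.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        got = table["t_mod"].reindex(ref.index)
        assert np.allclose(got, ref["t"], rtol=1e-8)

    def test_table_sorted_and_signs_consistent(self, main_deg_table):
        t = main_deg_table
        assert (t["p_adj"].values >= t["p_raw"].values - 1e-15).all()
        assert t["p_adj"].is_monotonic_increasing
        nz = t["log2fc"] != 0
        assert (np.sign(t.loc[nz, "t_mod"]) == np.sign(t.loc[nz, "log2fc"])).all()


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=1000))
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        got = adjust_bh(p)
        m = len(p)
        # brute force: for each i, min over j with p_(j) >= p_i of p_(j)*m/j
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        ranked = p[order]
        q = ranked * m / np.arange(1, m + 1)
        for i in range(m - 2, -1, -1):
            q[i] = min(q[i], q[i + 1])
        expected[order] = np.minimum(q, 1.0)
        assert np.allclose(got, expected)
        assert (got >= p - 1e-15).all() and (got <= 1.0).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(500) ** 2
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjust_bh(p), ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_bh([0.5, 1.2])


class TestSelection:
    def test_fold_change_boundary_arithmetic(self):
        table = pd.DataFrame(
            {"log2fc": [1.59, 1.0, -2.0], "p_adj": [0.001, 0.02, 0.001]},
            index=["hi", "mid", "down"])
        up, down = select_degs(table, fc_cut=3.0, p_cut=0.01)
        assert up == {"hi"}  # 2^1.59 = 3.01 > 3
        assert down == {"down"}

    def test_p_threshold_excludes_regardless_of_fc(self):
        table = pd.DataFrame({"log2fc": [5.0], "p_adj": [0.02]}, index=["g"])
        up, down = select_degs(table, fc_cut=2.0, p_cut=0.01)
        assert not up and not down

    def test_set_comparison_enumeration(self):
        comp = compare_deg_sets({"g1", "g2", "g3"}, {"g2", "g3", "g4"})
        assert comp["shared"] == {"g2", "g3"}
        assert comp["unique_to_a"] == {"g1"}
        assert comp["unique_to_b"] == {"g4"}
        same = compare_deg_sets({"a"}, {"a"})
        assert same["n_unique_to_a"] == same["n_unique_to_b"] == 0
        disjoint = compare_deg_sets({"a"}, {"b"})
        assert disjoint["n_shared"] == 0


class TestNullBehaviour:
    def test_moderation_shrinks_t_spread_under_null(self):
        rng = np.random.default_rng(13)
        data = rng.normal(5, 1, (2000, 9))
        m = make_matrix(data)
        fit = fit_two_group(m, two_group_labels(4, 5), "A", "B")
        mod, table = ebayes_moderate(fit)
        t_ord = fit.log2fc / (np.sqrt(fit.s2) * fit.stdev_unscaled)
        assert table["t_mod"].var() <= t_ord.var()

    def test_focal_vs_non_has_no_significant_genes(self, normalized_cohort):
        norm, _, annotation, _ = normalized_cohort
        endo = endogenous_only(log_transform(norm))
        table = moderated_t_table(endo, annotation["cohort"], "NON", "FOCAL")
        assert int((table["p_adj"] < 0.05).sum()) == 0
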