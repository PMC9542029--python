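"""NB Wald testing: prefilter, dispersions, Wald calibration and power,
LFC shrinkage and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from hybriddom import (
    ContrastSpec,
    CountMatrix,
    bh_adjust,
    call_de,
    estimate_dispersions,
    prefilter,
    run_contrast,
    shrink_lfc,
    wald_test,
)


def nb_counts(rng, mu, alpha, n_genes, n_samples):
    r = 1.0 / alpha
    lam = rng.gamma(r, mu / r, size=(n_genes, n_samples))
    return rng.poisson(lam)


def two_group_setup(counts_a, counts_b):
    """CountMatrix + samples/factors for two groups given count blocks."""
    na, nb = counts_a.shape[1], counts_b.shape[1]
    counts = np.hstack([counts_a, counts_b])
    ids = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    cm = CountMatrix(
        [f"g{i}" for i in range(counts.shape[0])], ids, counts
    )
    samples = pd.DataFrame(
        {"sample_id": ids, "group": ["A"] * na + ["B"] * nb, "tissue": "t"}
    )
    factors = pd.Series(1.0, index=ids)
    return cm, samples, factors


class TestPrefilter:
    def test_rules(self):
        counts = np.array(
            [
                [0] * 10,  # all zero -> out
                [10, 10, 10, 0, 0, 0, 0, 0, 0, 0],  # 3 of 10 >= 10 -> out
                [10] * 10,  # everywhere >= 10 -> in
                [9] * 10,  # never reaches 10 -> out
                [10] * 5 + [0] * 5,  # exactly half -> in
            ]
        )
        cm = CountMatrix(
            [f"g{i}" for i in range(5)], [f"s{j}" for j in range(10)], counts
        )
        mask = prefilter(cm, list(cm.sample_ids))
        assert list(mask) == [False, False, True, False, True]

    def test_min_fraction_validated(self):
        cm = CountMatrix(["g"], ["s1", "s2"], [[1, 1]])
        with pytest.raises(ValueError, match="min_fraction"):
            prefilter(cm, ["s1", "s2"], min_fraction=0.0)


class TestBHAdjust:
    def brute_force(self, p):
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        adj = [None] * m
        for rank_pos, i in enumerate(order):
            candidates = [
                m * p[order[k]] / (k + 1) for k in range(rank_pos, m)
            ]
            adj[i] = min(1.0, min(candidates))
        return adj

    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01], [0.01]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.05, 0.01], [0.05, 0.02]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_step_up_definition(self, p):
        assert np.allclose(bh_adjust(p), self.brute_force(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.random(500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestShrinkLFC:
    def make(self, lfc, se):
        n = len(lfc)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "lfc_mle": lfc,
                "lfc_shrunk": lfc,
                "se": se,
                "tested": True,
            }
        )

    def test_closed_form(self):
        res = shrink_lfc(self.make([2.0], [1.0]), prior_scale=1.0)
        assert res["lfc_shrunk"].iloc[0] == pytest.approx(1.0)

    def test_zero_se_limit_keeps_mle(self):
        res = shrink_lfc(self.make([1.7], [0.0]), prior_scale=1.0)
        assert res["lfc_shrunk"].iloc[0] == pytest.approx(1.7)

    def test_zero_lfc_stays_zero(self):
        res = shrink_lfc(self.make([0.0], [0.5]), prior_scale="auto")
        assert res["lfc_shrunk"].iloc[0] == 0.0

    def test_magnitude_never_increases_sign_preserved(self):
        rng = np.random.default_rng(13)
        lfc = rng.normal(0, 2, 200)
        se = rng.uniform(0.05, 2, 200)
        res = shrink_lfc(self.make(lfc, se), prior_scale="auto")
        out = res["lfc_shrunk"].to_numpy()
        assert (np.abs(out) <= np.abs(lfc) + 1e-9).all()
        assert (np.sign(out) == np.sign(lfc)).all()


class TestDispersions:
    def run(self, counts_a, counts_b, **kw):
        cm, samples, factors = two_group_setup(counts_a, counts_b)
        return estimate_dispersions(
            cm, factors, samples.set_index("sample_id")["group"], **kw
        )

    def test_poisson_counts_collapse_to_negligible_dispersion(self):
        """For Poisson data (true alpha = 0) the bias-corrected per-gene
        likelihood piles estimates on the floor or at values whose extra
        variance is negligible at these counts."""
        rng = np.random.default_rng(21)
        a = rng.poisson(300.0, size=(300, 5))
        b = rng.poisson(300.0, size=(300, 5))
        d = self.run(a, b)
        assert d["at_floor"].mean() >= 0.4  # boundary pile-up of a ~unbiased estimator
        assert np.median(d["alpha_gene"]) < 1e-3
        # trend shrinkage keeps the final values an order below real-data dispersions
        assert np.median(d["alpha_final"]) < 0.01

    def test_constant_counts_at_floor(self):
        a = np.full((3, 5), 50)
        d = self.run(a, a.copy())
        assert d["at_floor"].all()

    def test_alpha_recovery_at_fifty_replicates(self):
        rng = np.random.default_rng(22)
        a = nb_counts(rng, 500.0, 0.5, 200, 25)
        b = nb_counts(rng, 500.0, 0.5, 200, 25)
        d = self.run(a, b)
        med = float(np.median(d["alpha_final"]))
        assert 0.4 <= med <= 0.6

    def test_final_between_gene_and_trend_in_log_space(self):
        rng = np.random.default_rng(23)
        mu = rng.lognormal(5, 1, 400)
        alpha = 2.0 / mu + 0.1
        a = nb_counts(rng, mu[:, None], alpha[:, None], 400, 5)
        b = nb_counts(rng, mu[:, None], alpha[:, None], 400, 5)
        d = self.run(a, b)
        ok = ~d["at_floor"]
        lo = np.minimum(np.log(d["alpha_gene"]), np.log(d["alpha_trend"]))
        hi = np.maximum(np.log(d["alpha_gene"]), np.log(d["alpha_trend"]))
        lf = np.log(d["alpha_final"])
        assert ((lf[ok] >= lo[ok] - 1e-9) & (lf[ok] <= hi[ok] + 1e-9)).all()

    def test_trend_recovers_simulated_coefficients(self):
        rng = np.random.default_rng(24)
        mu = rng.lognormal(5.5, 1.2, 2000)
        alpha = 3.0 / mu + 0.05
        a = nb_counts(rng, mu[:, None], alpha[:, None], 2000, 8)
        b = nb_counts(rng, mu[:, None], alpha[:, None], 2000, 8)
        d = self.run(a, b)
        coef = d.attrs["trend_coefficients"]
        assert coef["a0"] == pytest.approx(3.0, rel=0.5)
        assert coef["a1"] == pytest.approx(0.05, rel=0.5)


class TestWald:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(31)
        a = rng.poisson(200.0, size=(20, 5))
        cm, samples, factors = two_group_setup(a, a.copy())
        res = run_contrast(cm, samples, factors, ContrastSpec("AB", "A", "B"))
        tested = res[res["tested"]]
        assert np.allclose(tested["lfc_mle"], 0.0, atol=1e-8)
        assert np.allclose(tested["pvalue"], 1.0)
        assert not res["de"].any()

    def test_matches_statsmodels_glm(self):
        """The Newton fit is the same NB GLM statsmodels solves."""
        import statsmodels.api as sm

        rng = np.random.default_rng(32)
        a = nb_counts(rng, 150.0, 0.1, 15, 5)
        b = nb_counts(rng, 300.0, 0.1, 15, 5)
        cm, samples, factors = two_group_setup(a, b)
        factors.iloc[:] = rng.uniform(0.8, 1.2, len(factors))
        grp = samples.set_index("sample_id")["group"]
        disp = estimate_dispersions(cm, factors, grp)
        res = wald_test(
            cm, factors, ContrastSpec("AB", "A", "B"), samples, disp,
            tested=pd.Series(True, index=list(cm.gene_ids)),
        )
        X = np.column_stack([np.ones(10), [1] * 5 + [0] * 5])
        offset = np.log(factors.to_numpy())
        for i in range(cm.n_genes):
            alpha_i = disp["alpha_final"].iloc[i]
            glm = sm.GLM(
                cm.counts[i],
                X,
                family=sm.families.NegativeBinomial(alpha=alpha_i),
                offset=offset,
            ).fit()
            assert res["lfc_mle"].iloc[i] == pytest.approx(
                glm.params[1] / np.log(2), abs=1e-5
            )
            assert res["se"].iloc[i] == pytest.approx(
                glm.bse[1] / np.log(2), rel=1e-3
            )

    def test_group_swap_negates_lfc(self):
        rng = np.random.default_rng(33)
        a = nb_counts(rng, 150.0, 0.1, 60, 5)
        b = nb_counts(rng, 280.0, 0.1, 60, 5)
        cm, samples, factors = two_group_setup(a, b)
        res_ab = run_contrast(cm, samples, factors, ContrastSpec("AB", "A", "B"))
        res_ba = run_contrast(cm, samples, factors, ContrastSpec("BA", "B", "A"))
        t = res_ab["tested"].to_numpy()
        assert np.allclose(
            res_ab.loc[t, "lfc_mle"], -res_ba.loc[t, "lfc_mle"], atol=1e-8
        )
        assert np.allclose(
            res_ab.loc[t, "lfc_shrunk"], -res_ba.loc[t, "lfc_shrunk"], atol=1e-8
        )
        assert np.allclose(res_ab.loc[t, "pvalue"], res_ba.loc[t, "pvalue"])

    def test_all_zero_group_pseudocount_fallback(self):
        a = np.zeros((1, 5), dtype=int)
        b = np.full((1, 5), 100)
        cm, samples, factors = two_group_setup(a, b)
        disp = pd.DataFrame({"gene_id": ["g0"], "alpha_final": [0.1]})
        res = wald_test(
            cm, factors, ContrastSpec("AB", "A", "B"), samples, disp,
            tested=pd.Series(True, index=["g0"]),
        )
        assert res["pseudo_fallback"].iloc[0]
        assert np.isfinite(res["lfc_mle"].iloc[0])
        assert res["lfc_mle"].iloc[0] < -5  # strongly down in A

    def test_lfc_recovery_and_power(self):
        """True LFC=2 at mu=500, 5v5: median MLE within 0.1 of truth and
        >=95% of genes significant after BH."""
        rng = np.random.default_rng(34)
        n = 400
        a = nb_counts(rng, 500.0, 0.05, n, 5)
        b = nb_counts(rng, 125.0, 0.05, n, 5)
        cm, samples, factors = two_group_setup(a, b)
        res = run_contrast(cm, samples, factors, ContrastSpec("AB", "A", "B"))
        tested = res[res["tested"]]
        assert abs(np.median(tested["lfc_mle"]) - 2.0) < 0.1
        assert (tested["padj"] < 0.05).mean() >= 0.95

    def test_null_type_one_error_and_uniformity(self, null_run):
        """Raw Wald p-values under the all-conserved simulation are
        approximately uniform with type-I error near the nominal 5%."""
        res = null_run["contrasts"]["hybrid_vs_parent1"]
        t = res[res["tested"] & (res["base_mean"] >= 100)]
        p = t["pvalue"].to_numpy()
        assert 0.03 <= (p < 0.05).mean() <= 0.07
        assert kstest(p, "uniform").statistic < 0.05

    def test_padj_at_least_pvalue(self, null_run):
        res = null_run["contrasts"]["parent2_vs_parent1"]
        t = res[res["tested"]]
        assert (t["padj"].to_numpy() >= t["pvalue"].to_numpy() - 1e-12).all()


class TestCallDE:
    @pytest.mark.parametrize(
        "padj, lfc, expected_de, expected_dir",
        [
            (0.04, 0.5, True, 1),
            (0.04, 0.2, False, 0),   # LFC threshold binds
            (0.06, 3.0, False, 0),   # significance binds
            (0.04, -0.5, True, -1),
            (np.nan, 1.0, False, 0),
        ],
    )
    def test_rule(self, padj, lfc, expected_de, expected_dir):
        df = pd.DataFrame(
            {"gene_id": ["g"], "padj": [padj], "lfc_shrunk": [lfc], "tested": [True]}
        )
        out = call_de(df)
        assert bool(out["de"].iloc[0]) is expected_de
        assert out["direction"].iloc[0] == expected_dir
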