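import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import kstest, rankdata

from epidyn import expression as ex


def nb_counts(rng, mu, phi, shape=None):
    return rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * np.asarray(mu)), size=shape)


class TestTmm:
    def test_identical_columns_unity(self):
        c = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        f = ex.tmm_factors(c)
        assert np.allclose(f.factor, [1.0, 1.0])

    def test_pure_depth_difference_unity(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 500, size=200)
        c = pd.DataFrame({"a": a, "b": 2 * a})
        f = ex.tmm_factors(c)
        assert np.allclose(f.factor, [1.0, 1.0], atol=1e-9)

    def test_hand_computed_oracle(self):
        """Independent step-by-step evaluation of the trimmed-mean formula."""
        c = pd.DataFrame(
            {"ref": [100, 200, 300, 400, 50], "obs": [110, 190, 310, 2000, 55]},
            index=list("abcde"),
        )
        f = ex.tmm_factors(c, reference="ref")
        n_r, n_o = c["ref"].sum(), c["obs"].sum()
        o, r = c["obs"].to_numpy(float), c["ref"].to_numpy(float)
        p_o, p_r = o / n_o, r / n_r
        m = np.log2(p_o / p_r)
        a = 0.5 * np.log2(p_o * p_r)
        w = (1 - p_o) / p_o + (1 - p_r) / p_r
        n = len(m)
        lo_m = np.floor(n * 0.3) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        keep = (
            (rankdata(m) >= lo_m)
            & (rankdata(m) <= hi_m)
            & (rankdata(a) >= lo_a)
            & (rankdata(a) <= hi_a)
        )
        raw = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        expected = np.array([1.0, raw]) / np.sqrt(raw)  # geometric mean 1
        got = np.array(f.factor)[[f.sample_ids.index("ref"), f.sample_ids.index("obs")]]
        assert np.allclose(got, expected, atol=1e-12)

    def test_invariant_to_scaling_one_sample(self):
        rng = np.random.default_rng(1)
        c = pd.DataFrame(rng.integers(1, 300, size=(100, 3)), columns=list("abc"))
        f1 = ex.tmm_factors(c)
        c2 = c.copy()
        c2["b"] = c2["b"] * 7
        f2 = ex.tmm_factors(c2)
        assert np.allclose(f1.factor, f2.factor, atol=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        c = pd.DataFrame(rng.integers(0, 300, size=(80, 4)), columns=list("abcd"))
        f = ex.tmm_factors(c)
        assert abs(np.exp(np.mean(np.log(f.factor))) - 1) < 1e-9

    def test_all_zero_sample_rejected(self):
        c = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            ex.tmm_factors(c)


class TestLogCpm:
    def test_identical_columns_identical_values(self):
        c = pd.DataFrame({"a": [0, 5, 100], "b": [0, 5, 100]})
        v = ex.log_cpm(c, ex.tmm_factors(c))
        assert np.allclose(v["a"], v["b"])
        assert np.isfinite(v.values).all()

    def test_depth_doubling_stability(self):
        rng = np.random.default_rng(3)
        base = rng.integers(10, 1000, size=(50, 2))
        c1 = pd.DataFrame(base, columns=["a", "b"])
        c2 = pd.DataFrame(2 * base, columns=["a", "b"])
        v1 = ex.log_cpm(c1, ex.tmm_factors(c1))
        v2 = ex.log_cpm(c2, ex.tmm_factors(c2))
        assert np.abs(v1.values - v2.values).max() < 1e-3

    def test_zero_count_finite(self):
        c = pd.DataFrame({"a": [0, 100], "b": [0, 100]})
        v = ex.log_cpm(c, ex.tmm_factors(c))
        assert np.isfinite(v.values).all()


class TestBhAdjust:
    def test_step_up_hand_case(self):
        assert np.allclose(
            ex.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert ex.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        q = ex.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=333)
        assert np.allclose(ex.bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ex.bh_adjust([0.5, 1.5])


class TestClassifyDeg:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (1.2, 0.01, "up"),
            (0.9, 0.001, "ns"),
            (1.0, 0.01, "ns"),  # strict > on |log2FC|
            (-1.2, 0.01, "down"),
            (2.0, 0.05, "ns"),  # strict < on FDR
        ],
    )
    def test_rule(self, lfc, fdr, expected):
        assert ex.classify_deg(lfc, fdr) == expected


class TestExactTest:
    def test_poisson_limit_matches_binomial_oracle(self):
        """Conditional on the total, the Poisson two-sample test is binomial."""
        from scipy.stats import binom

        for z_a, z_b, n_a, n_b in [(3, 10, 2, 2), (40, 60, 2, 2), (5, 5, 1, 3), (0, 7, 2, 2)]:
            t = z_a + z_b
            pr = n_a / (n_a + n_b)
            pmf = binom.pmf(np.arange(t + 1), t, pr)
            le = pmf <= pmf[z_a] * (1 + 1e-10)
            p_tail = pmf[le].sum()
            got = ex.nb_exact_test(z_a, z_b, n_a, n_b, phi=0.0, midp=False)
            assert got == pytest.approx(min(1.0, p_tail), abs=1e-6)
            eq = np.abs(pmf - pmf[z_a]) <= pmf[z_a] * 1e-10
            p_mid = pmf[le & ~eq].sum() + 0.5 * pmf[eq].sum()
            got_mid = ex.nb_exact_test(z_a, z_b, n_a, n_b, phi=0.0, midp=True)
            assert got_mid == pytest.approx(min(1.0, p_mid), abs=1e-6)

    def test_symmetric_under_group_swap(self):
        for phi in (0.0, 0.1):
            assert ex.nb_exact_test(12, 30, 2, 2, phi) == pytest.approx(
                ex.nb_exact_test(30, 12, 2, 2, phi), abs=1e-12
            )

    def test_zero_total(self):
        assert ex.nb_exact_test(0, 0, 2, 2, 0.05) == 1.0


class TestDifferentialTest:
    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(6)
        mu = rng.lognormal(np.log(150), 1.0, size=2000)
        y = np.column_stack([nb_counts(rng, mu, 0.05) for _ in range(4)])
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(2000)], columns=list("abcd"))
        res, _ = ex.differential_test(counts, ["a", "b"], ["c", "d"])
        p = np.array([r.p_value for r in res])
        assert kstest(p, "uniform").pvalue > 0.01

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(7)
        mu_bg = rng.lognormal(np.log(150), 1.0, size=400)
        mu_a = np.concatenate([mu_bg, np.full(50, 200.0), np.full(50, 800.0)])
        mu_b = np.concatenate([mu_bg, np.full(50, 800.0), np.full(50, 200.0)])
        y = np.column_stack(
            [nb_counts(rng, m, 0.05) for m in (mu_a, mu_a, mu_b, mu_b)]
        )
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(500)], columns=list("abcd"))
        res, _ = ex.differential_test(counts, ["a", "b"], ["c", "d"])
        up = [r for r in res[400:450]]
        assert np.mean([r.status == "up" for r in up]) >= 0.9
        assert abs(np.mean([r.log2fc for r in up]) - 2.0) < 0.2

    def test_all_zero_features_filtered(self):
        counts = pd.DataFrame(
            {"a": [0, 5, 9], "b": [0, 6, 8], "c": [0, 30, 2], "d": [0, 28, 4]},
            index=["z", "g1", "g2"],
        )
        res, filtered = ex.differential_test(counts, ["a", "b"], ["c", "d"])
        assert filtered == ["z"]
        assert {r.feature_id for r in res} == {"g1", "g2"}

    def test_one_vs_one_requires_dispersion(self):
        counts = pd.DataFrame({"a": [5, 8], "b": [9, 2]})
        with pytest.raises(ValueError, match="dispersion"):
            ex.differential_test(counts, ["a"], ["b"])
        res, _ = ex.differential_test(counts, ["a"], ["b"], dispersion=0.1)
        assert len(res) == 2


class TestDispersionEstimation:
    def test_recovers_known_dispersion(self):
        rng = np.random.default_rng(8)
        for phi in (0.02, 0.2):
            y = nb_counts(rng, 500.0, phi, shape=(3000, 4))
            common, _ = ex.estimate_dispersion(y[:, :2], y[:, 2:])
            assert common == pytest.approx(phi, rel=0.25)


class TestClustering:
    def _toy(self, rng, n_per=40, noise=0.1):
        tps = [1, 2, 4, 7]
        cols = [f"tp{t}_rep{r}" for t in tps for r in (1, 2)]
        up = np.linspace(2, 8, 4)
        down = np.linspace(8, 2, 4)
        rows = []
        for prof in (up, down):
            for _ in range(n_per):
                rows.append(np.repeat(prof, 2) + rng.normal(0, noise, 8))
        idx = [f"g{i}" for i in range(2 * n_per)]
        logcpm = pd.DataFrame(rows, index=idx, columns=cols)
        timepoints = pd.Series([t for t in tps for _ in (1, 2)], index=cols)
        return logcpm, timepoints, idx

    def test_k1_single_cluster(self, rng):
        logcpm, tps, idx = self._toy(rng)
        assigns, means, _ = ex.cluster_deg_profiles(logcpm, tps, idx, k=1)
        assert {a.cluster_id for a in assigns} == {1}

    def test_planted_partition_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        logcpm, tps, idx = self._toy(rng)
        assigns, _, _ = ex.cluster_deg_profiles(logcpm, tps, idx, k=2)
        truth = [0] * 40 + [1] * 40
        got = [a.cluster_id for a in assigns]
        assert adjusted_rand_score(truth, got) == 1.0
        # earliest-peaking archetype gets cluster 1: the down profile peaks at tp1
        assert got[40] == 1 and got[0] == 2

    def test_z_profiles_standardized(self, rng):
        logcpm, tps, idx = self._toy(rng)
        _, _, z = ex.cluster_deg_profiles(logcpm, tps, idx, k=2)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_deterministic(self, rng):
        logcpm, tps, idx = self._toy(rng)
        a1, _, _ = ex.cluster_deg_profiles(logcpm, tps, idx, k=2)
        a2, _, _ = ex.cluster_deg_profiles(logcpm, tps, idx, k=2)
        assert [a.cluster_id for a in a1] == [a.cluster_id for a in a2]


class TestPca:
    def test_collinear_samples_pc1_everything(self):
        g = np.arange(10, dtype=float)
        logcpm = pd.DataFrame(
            {"s1": g, "s2": 2 * g, "s3": 3 * g}
        )
        _, varfrac = ex.pca_samples(logcpm)
        assert varfrac[0] == pytest.approx(1.0)

    def test_variance_fractions_contract(self, rng):
        logcpm = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        _, varfrac = ex.pca_samples(logcpm)
        assert varfrac.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(varfrac) <= 1e-12).all()
        assert (varfrac >= -1e-12).all()

    def test_duplicated_sample_identical_scores(self, rng):
        logcpm = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        logcpm["d"] = logcpm["c"]
        scores, _ = ex.pca_samples(logcpm)
        assert np.allclose(scores.loc["c"], scores.loc["d"], atol=1e-9)


class TestEnrichment:
    def test_closed_form_hypergeometric(self):
        universe = {f"g{i}" for i in range(10)}
        hits = {f"g{i}" for i in range(5)}
        sets = {"S": set(hits)}
        df = ex.gene_set_enrichment(hits, universe, sets)
        assert df.loc[0, "p_value"] == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_overlap_p_one(self):
        df = ex.gene_set_enrichment({"a"}, {"a", "b", "c"}, {"S": {"b", "c"}})
        assert df.loc[0, "p_value"] == 1.0

    def test_hits_equal_universe_saturated(self):
        uni = {"a", "b", "c", "d"}
        df = ex.gene_set_enrichment(uni, uni, {"S": {"a", "b"}})
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_hit_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="x"):
            ex.gene_set_enrichment({"x"}, {"a"}, {})
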