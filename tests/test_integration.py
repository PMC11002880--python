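import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from epidyn import integration as integ
from epidyn.peaks import PeakDifferential


class TestPearson:
    def test_perfect_linear(self):
        assert integ.pearson_r([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0)

    def test_anti(self):
        assert integ.pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert integ.pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_nan(self):
        assert np.isnan(integ.pearson_r([1, 1, 1], [1, 2, 3]))


def mwu_enumeration_p(x, y):
    """Oracle: exact two-sided p by enumerating all group assignments."""
    pooled = sorted(x) + sorted(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    obs = u_stat(x, y)
    mu = nx * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_enumerated_small_case(self):
        u, p = integ.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_symmetry_under_swap(self):
        x, y = [1.5, 2.2, 9.0], [0.1, 4.4]
        _, p1 = integ.mann_whitney_u(x, y)
        _, p2 = integ.mann_whitney_u(y, x)
        assert p1 == pytest.approx(p2)

    def test_identical_samples_p_near_one(self):
        x = list(np.linspace(0, 1, 25))
        _, p = integ.mann_whitney_u(x, x)
        assert p > 0.9

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(20):
            nx, ny = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            vals = rng.permutation(np.arange(20, dtype=float))  # tie-free
            x, y = list(vals[:nx]), list(vals[nx : nx + ny])
            _, p = integ.mann_whitney_u(x, y)
            assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            integ.mann_whitney_u([], [1.0])


class TestGenePlsLevel:
    LEVELS = pd.DataFrame(
        {"tp1_rep1": [3.0, 5.0, 1.0], "tp2_rep1": [2.0, 6.0, 0.5]},
        index=["p1", "p2", "p3"],
    )

    def test_max_rule_over_covering_peaks(self):
        pairs = [("p1", "gA"), ("p2", "gA"), ("p3", "gB")]
        gm = integ.gene_pls_level(pairs, self.LEVELS)
        assert gm.loc["gA", "tp1_rep1"] == 5.0
        assert gm.loc["gA", "tp2_rep1"] == 6.0
        assert gm.loc["gB", "tp1_rep1"] == 1.0

    def test_no_peak_gene_absent(self):
        gm = integ.gene_pls_level([("p1", "gA")], self.LEVELS)
        assert "gZ" not in gm.index

    def test_inherits_max_abs_lfc_peak(self):
        diffs = [
            PeakDifferential("p1", 0.2, 0.5, 0.9, "ns"),
            PeakDifferential("p2", -1.5, 0.001, 0.01, "hypo"),
        ]
        gm = integ.gene_pls_level(
            [("p1", "gA"), ("p2", "gA")], self.LEVELS, peak_diffs=diffs
        )
        assert gm.loc["gA", "status"] == "hypo"
        assert gm.loc["gA", "log2fc"] == -1.5

    def test_shared_peak_flagged(self):
        pairs = [("p1", "gA"), ("p1", "gB"), ("p2", "gC")]
        gm = integ.gene_pls_level(pairs, self.LEVELS)
        assert bool(gm.loc["gA", "shared_peak"]) and bool(gm.loc["gB", "shared_peak"])
        assert not gm.loc["gC", "shared_peak"]


class TestStratification:
    def test_constant_expression_null(self):
        genes = [f"g{i}" for i in range(40)]
        levels = pd.Series(np.arange(40, dtype=float), index=genes)
        expr = pd.Series(1.0, index=genes)
        rep = integ.stratify_expression_by_level(levels, expr, n_bins=4)
        meds = [rep.summary.loc[f"Q{b}", "median"] for b in range(1, 5)]
        assert len(set(meds)) == 1
        assert rep.trend_rho == 0.0

    def test_planted_monotone_recovered(self):
        genes = [f"g{i}" for i in range(41)]
        levels = pd.Series(np.arange(41, dtype=float), index=genes)
        expr = 1.0 + 0.5 * levels
        rep = integ.stratify_expression_by_level(levels, expr, n_bins=4)
        meds = [rep.summary.loc[f"Q{b}", "median"] for b in range(1, 5)]
        assert all(np.diff(meds) > 0)
        assert rep.trend_rho == pytest.approx(1.0)
        # near-equal bin sizes (+-1)
        sizes = [rep.summary.loc[f"Q{b}", "n"] for b in range(1, 5)]
        assert max(sizes) - min(sizes) <= 1

    def test_no_peak_bin_lowest(self):
        genes = [f"g{i}" for i in range(30)]
        levels = pd.Series(np.arange(30, dtype=float), index=genes)
        levels.iloc[:10] = np.nan  # no-peak genes
        expr = pd.Series(np.where(levels.isna(), 0.1, 5.0 + levels), index=genes)
        rep = integ.stratify_expression_by_level(levels, expr, n_bins=4)
        no_peak = rep.summary.loc["no_peak", "median"]
        assert all(
            no_peak < rep.summary.loc[f"Q{b}", "median"] for b in range(1, 5)
        )
        assert rep.summary["n"].sum() == 30

    def test_fewer_genes_than_bins_rejected(self):
        levels = pd.Series([1.0, 2.0], index=["a", "b"])
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            integ.stratify_expression_by_level(levels, expr, n_bins=4)


def marking_frame(rows):
    """(log2fc, status, gene_id) triples -> per-gene marking frame."""
    return pd.DataFrame(
        {"log2fc": [r[0] for r in rows], "status": [r[1] for r in rows]},
        index=[r[2] for r in rows],
    )


class TestLeadLagConcordance:
    def test_saturated_future(self):
        gm = marking_frame([(1.0, "hyper", "g1"), (2.0, "hyper", "g2")])
        de = pd.DataFrame({"log2fc": [0.5, 1.5], "status": ["ns", "up"]}, index=["g1", "g2"])
        rep = integ.lead_lag_concordance(gm, {"future": de}, mode="sign")
        assert rep.fractions["future"] == 1.0
        assert np.isnan(rep.fractions["past"])

    def test_empty_universe(self):
        gm = marking_frame([(0.1, "ns", "g1")])
        de = pd.DataFrame({"log2fc": [1.0], "status": ["up"]}, index=["g1"])
        rep = integ.lead_lag_concordance(gm, {"current": de})
        assert rep.universe == 0
        assert np.isnan(rep.fractions["current"])

    def test_counts_partition_universe(self, rng):
        genes = [f"g{i}" for i in range(50)]
        gm = marking_frame(
            [
                (float(rng.normal()), rng.choice(["hyper", "hypo", "ns"]), g)
                for g in genes
            ]
        )
        de = pd.DataFrame(
            {
                "log2fc": rng.normal(size=40),
                "status": rng.choice(["up", "down", "ns"], size=40),
            },
            index=genes[:40],  # 10 genes untested on the expression side
        )
        for mode in ("sign", "deg_status"):
            rep = integ.lead_lag_concordance(gm, {"current": de}, mode=mode)
            c = rep.counts["current"]
            assert c["concordant"] + c["discordant"] + c["unchanged"] == rep.universe

    def test_deg_status_mode(self):
        gm = marking_frame([(1.0, "hyper", "g1"), (-1.0, "hypo", "g2")])
        de = pd.DataFrame(
            {"log2fc": [2.0, 0.5], "status": ["up", "ns"]}, index=["g1", "g2"]
        )
        rep = integ.lead_lag_concordance(gm, {"current": de}, mode="deg_status")
        c = rep.counts["current"]
        assert c == {"concordant": 1, "discordant": 0, "unchanged": 1}

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            integ.lead_lag_concordance(marking_frame([]), {}, mode="bogus")


class TestPairwiseMarks:
    def test_identical_changes_r_one(self):
        genes = [f"g{i}" for i in range(10)]
        a = pd.Series(np.linspace(-2, 2, 10), index=genes)
        rep = integ.pairwise_mark_change_correlation(a, a.copy(), genes[:5], genes[5:])
        assert rep.pearson == pytest.approx(1.0)

    def test_all_up_positive_upper_right(self):
        genes = [f"g{i}" for i in range(6)]
        a = pd.Series([0.5, 1.0, 2.0, 0.1, 0.2, 0.3], index=genes)
        b = pd.Series([0.4, 1.1, 1.9, 0.2, 0.1, 0.5], index=genes)
        rep = integ.pairwise_mark_change_correlation(a, b, genes, [])
        assert rep.quadrants["up"]["UR"] == 1.0
        assert sum(rep.quadrants["up"].values()) == pytest.approx(1.0)

    def test_independent_changes_near_zero(self, rng):
        genes = [f"g{i}" for i in range(2000)]
        a = pd.Series(rng.normal(size=2000), index=genes)
        b = pd.Series(rng.normal(size=2000), index=genes)
        rep = integ.pairwise_mark_change_correlation(a, b, genes[:1000], genes[1000:])
        assert abs(rep.pearson) < 0.1

    def test_too_few_genes_rejected(self):
        a = pd.Series([1.0], index=["g1"])
        with pytest.raises(ValueError):
            integ.pairwise_mark_change_correlation(a, a, ["g1"], [])


class TestDegMarkingOverlap:
    def test_disjoint_zero(self):
        gm = marking_frame([(1.0, "hyper", "g1")])
        out = integ.deg_marking_overlap({"up": {"gX"}, "down": set()}, gm)
        row = out[out["direction"] == "up"].iloc[0]
        assert row["degs_with_matching_change"] == 0
        assert row["marked_genes_that_are_degs"] == 0

    def test_marked_subset_of_up(self):
        gm = marking_frame([(1.0, "hyper", "g1"), (0.5, "hyper", "g2")])
        out = integ.deg_marking_overlap({"up": {"g1", "g2", "g3"}, "down": set()}, gm)
        row = out[out["direction"] == "up"].iloc[0]
        assert row["degs_with_significant_matching_change"] == 2
        assert row["marked_genes_that_are_degs"] == 2

    def test_matches_brute_force(self, rng):
        genes = [f"g{i}" for i in range(60)]
        gm = marking_frame(
            [
                (float(rng.normal()), rng.choice(["hyper", "hypo", "ns"]), g)
                for g in genes
            ]
        )
        up = set(rng.choice(genes, size=20, replace=False))
        down = set(rng.choice([g for g in genes if g not in up], size=15, replace=False))
        out = integ.deg_marking_overlap({"up": up, "down": down}, gm)
        for direction, wanted, degs in (("up", "hyper", up), ("down", "hypo", down)):
            row = out[out["direction"] == direction].iloc[0]
            sign = (lambda v: v > 0) if direction == "up" else (lambda v: v < 0)
            exp_any = sum(1 for g in degs if g in gm.index and sign(gm.loc[g, "log2fc"]))
            exp_sig = sum(
                1
                for g in degs
                if g in gm.index
                and sign(gm.loc[g, "log2fc"])
                and gm.loc[g, "status"] == wanted
            )
            assert row["degs_with_matching_change"] == exp_any
            assert row["degs_with_significant_matching_change"] == exp_sig
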