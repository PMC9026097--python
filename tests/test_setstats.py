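"""Directional concordance, area statistic, enrichment, resampling nulls."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modscape.io import SignatureSet
from modscape.setstats import (
    aggregate_disease_sources,
    annotation_enrichment,
    cumulative_overlap_area,
    direction_fisher,
    fc_vector_correlation,
    random_set_fc_null,
    top_k_overlap,
)
from tests.conftest import make_de_table


class TestDirectionFisher:
    def test_extreme_table_infinite_odds(self):
        rng = np.random.default_rng(0)
        fc = rng.normal(0, 1, size=200)
        fc[:20] = np.abs(fc[:20]) + 0.1  # members all up
        de = make_de_table(fc)
        sig = SignatureSet("S", list(de.index[:20]), "up")
        res = direction_fisher(de, sig)
        assert res.n_up == 20 and res.n_down == 0
        assert res.odds_ratio == float("inf")
        assert res.fisher_p < 0.01

    def test_matches_hypergeometric_tail(self):
        """Fisher p on (8,2,5000,5000) equals the exact tail enumeration."""
        a, b, c, d = 8, 2, 5000, 5000
        _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
        # brute-force two-sided exact p: sum over tables with prob <= observed
        n_row = a + b
        n_up = a + c
        total = a + b + c + d
        probs = [
            stats.hypergeom.pmf(k, total, n_up, n_row) for k in range(n_row + 1)
        ]
        p_obs = stats.hypergeom.pmf(a, total, n_up, n_row)
        p_manual = sum(pk for pk in probs if pk <= p_obs * (1 + 1e-9))
        assert p_scipy == pytest.approx(p_manual, rel=1e-6)

    def test_null_signature_p_uniform(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            fc = rng.normal(size=500)
            de = make_de_table(fc)
            members = list(rng.choice(de.index, size=40, replace=False))
            res = direction_fisher(de, SignatureSet("S", members, "up"))
            pvals.append(res.fisher_p)
        # Fisher p is discrete and conservative; check no excess of small p
        assert (np.array(pvals) < 0.05).mean() <= 0.07

    def test_zero_fc_members_counted_separately(self):
        fc = np.array([0.0, 1.0, -1.0, 0.5, -0.5, 2.0])
        de = make_de_table(fc)
        sig = SignatureSet("S", list(de.index[:3]), "none")
        res = direction_fisher(de, sig)
        assert res.n_zero == 1
        assert res.n_up + res.n_down == 2

    def test_empty_intersection_rejected(self):
        de = make_de_table([1.0, -1.0])
        with pytest.raises(ValueError):
            direction_fisher(de, SignatureSet("S", ["absent"], "up"))


class TestCumulativeOverlapArea:
    def test_members_on_top_max_positive_area(self):
        n, s = 200, 20
        fc = np.linspace(3, -3, n)
        de = make_de_table(fc)
        members = list(de.index[:s])
        res = cumulative_overlap_area(de, SignatureSet("S", members, "up"))
        # closed form for the extreme ordering
        running = [min(k, s) / s - k / n for k in range(1, n + 1)]
        assert res.area == pytest.approx(np.mean(running))
        assert res.area > 0

    def test_antisymmetry_under_rank_reversal(self):
        rng = np.random.default_rng(2)
        fc = rng.normal(size=300)
        de = make_de_table(fc)
        members = list(rng.choice(de.index, size=30, replace=False))
        sig = SignatureSet("S", members, "up")
        a_fwd = cumulative_overlap_area(de, sig).area
        de_rev = make_de_table(-fc)
        a_rev = cumulative_overlap_area(de_rev, sig).area
        assert a_fwd == pytest.approx(-a_rev, abs=1e-9)

    def test_interleaved_members_near_zero(self):
        n = 5000
        fc = np.linspace(2, -2, n)
        de = make_de_table(fc)
        members = list(de.index[::50])  # exactly uniform interleaving
        res = cumulative_overlap_area(de, SignatureSet("S", members, "up"))
        assert abs(res.area) < 0.02

    def test_signature_equals_universe_rejected(self):
        de = make_de_table([1.0, -1.0, 0.5])
        with pytest.raises(ValueError):
            cumulative_overlap_area(de, SignatureSet("S", list(de.index), "up"))

    def test_sign_agreement_with_direction_fisher(self):
        """Planted 70/30 up-split: both tests point the same way."""
        rng = np.random.default_rng(3)
        agreements = 0
        for rep in range(100):
            fc = rng.normal(0, 1, size=600)
            de = make_de_table(fc)
            up_pool = list(de.index[fc > 0])
            down_pool = list(de.index[fc < 0])
            members = list(rng.choice(up_pool, 35, replace=False)) + list(
                rng.choice(down_pool, 15, replace=False)
            )
            sig = SignatureSet("S", members, "up")
            d = direction_fisher(de, sig)
            a = cumulative_overlap_area(de, sig)
            if (d.frac_up > 0.5) == (a.area > 0):
                agreements += 1
        assert agreements >= 95


class TestAnnotationEnrichment:
    def test_hand_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(20)]
        term = {"T": universe[:5]}
        degs = universe[1:5] + [universe[10]]  # overlap 4 of 5
        out = annotation_enrichment(degs, universe, term)
        expected = sum(
            comb(5, k) * comb(15, 5 - k) for k in range(4, 6)
        ) / comb(20, 5)
        assert out.loc["T", "p"] == pytest.approx(expected)
        assert out.loc["T", "overlap"] == 4

    def test_term_equals_degs_minimal_p(self):
        universe = [f"g{i}" for i in range(30)]
        degs = universe[:6]
        out = annotation_enrichment(degs, universe, {"T": degs})
        assert out.loc["T", "p"] == pytest.approx(1 / comb(30, 6))

    def test_random_term_p_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        universe = [f"g{i}" for i in range(400)]
        for _ in range(200):
            degs = list(rng.choice(universe, 50, replace=False))
            term = list(rng.choice(universe, 40, replace=False))
            out = annotation_enrichment(degs, universe, {"T": term})
            if len(out):
                pvals.append(out.loc["T", "p"])
        assert (np.array(pvals) < 0.05).mean() <= 0.08  # discrete, conservative

    def test_disjoint_term_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="disjoint"):
            out = annotation_enrichment(["g1"], ["g1", "g2"], {"T": ["absent"]})
        assert len(out) == 0


class TestDiseaseSources:
    def test_tier_counts_partition(self):
        sources = {
            "A": {"g1", "g2", "g3"},
            "B": {"g1", "g2"},
            "C": {"g1"},
        }
        table = aggregate_disease_sources(sources)
        assert table.loc["g1", "tier"] == 3
        assert table.loc["g3", "tier"] == 1
        assert table["tier"].value_counts().sum() == 3


class TestRandomSetFcNull:
    def test_extreme_target_minimal_p(self):
        rng = np.random.default_rng(5)
        de = make_de_table(rng.normal(size=1000))
        target = list(de["log2fc"].abs().sort_values(ascending=False).index[:30])
        obs, null, p = random_set_fc_null(de, target, n_trials=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_single_trial_add_one(self):
        rng = np.random.default_rng(6)
        de = make_de_table(rng.normal(size=100))
        _, _, p = random_set_fc_null(de, list(de.index[:10]), n_trials=1, seed=0)
        assert p in (0.5, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        de = make_de_table(rng.normal(size=500))
        target = list(de.index[:25])
        _, null1, p1 = random_set_fc_null(de, target, 500, seed=3)
        _, null2, p2 = random_set_fc_null(de, target, 500, seed=3)
        assert np.array_equal(null1, null2) and p1 == p2

    def test_null_target_p_uniform(self):
        """Empirical p uniform over repetitions for random targets."""
        rng = np.random.default_rng(8)
        pvals = []
        for rep in range(200):
            de = make_de_table(rng.normal(size=800))
            target = list(rng.choice(de.index, 30, replace=False))
            _, _, p = random_set_fc_null(de, target, n_trials=1000, seed=rep)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCrossStudy:
    def test_identity_correlation(self):
        de = make_de_table(np.random.default_rng(9).normal(size=100))
        out = fc_vector_correlation(de, de)
        assert out["r"] == pytest.approx(1.0)
        assert out["frac_up_down"] == 0.0

    def test_anticorrelated_construction(self):
        de = make_de_table(np.linspace(-1, 1, 50))
        de2 = make_de_table(-np.linspace(-1, 1, 50))
        out = fc_vector_correlation(de, de2)
        assert out["r"] == pytest.approx(-1.0)
        assert out["frac_up_down"] > 0.4

    def test_topk_identical_rankings(self):
        fc = np.random.default_rng(10).normal(size=400)
        de = make_de_table(fc)
        out = top_k_overlap(de, de, k=50)
        assert out["overlap"] == 50
        assert out["p"] < 1e-30

    def test_topk_independent_expected_overlap(self):
        """E[overlap] = k^2/N for independent rankings."""
        rng = np.random.default_rng(11)
        overlaps = []
        for _ in range(100):
            deA = make_de_table(rng.normal(size=5000))
            deB = make_de_table(rng.normal(size=5000))
            overlaps.append(top_k_overlap(deA, deB, k=100)["overlap"])
        assert np.mean(overlaps) == pytest.approx(100 * 100 / 5000, abs=0.6)

    def test_topk_p_equals_hypergeometric_tail(self):
        rng = np.random.default_rng(12)
        deA = make_de_table(rng.normal(size=300))
        deB = make_de_table(rng.normal(size=300))
        out = top_k_overlap(deA, deB, k=40)
        p_hyper = stats.hypergeom.sf(out["overlap"] - 1, 300, 40, 40)
        assert out["p"] == pytest.approx(p_hyper, rel=1e-9)

    def test_k_too_large_rejected(self):
        de = make_de_table(np.arange(10.0))
        with pytest.raises(ValueError):
            top_k_overlap(de, de, k=6)
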