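import itertools
from math import comb

import numpy as np
import pytest

from colxnet.io import ExpressionMatrix, GeneSetCollection, Unit
from colxnet.setstats import (
    activity_screen,
    bh_adjust,
    enrichment_screen,
    fisher_overlap,
    set_activity,
)


def hypergeom_tail(N, K, n, a):
    """P(overlap >= a) by direct enumeration of the hypergeometric pmf."""
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(a, min(K, n) + 1)) / comb(N, n)


class TestFisher:
    def test_hand_example(self):
        universe = [f"u{i}" for i in range(20)]
        s = universe[:5]
        module = universe[:3] + [universe[10]]
        odds, p, a = fisher_overlap(s, module, universe)
        assert a == 3
        assert p == pytest.approx(155 / 4845)

    def test_disjoint_set_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        odds, p, a = fisher_overlap(["x", "y"], universe[:3], universe)
        assert (a, p) == (0, 1.0)

    def test_module_equals_universe(self):
        universe = [f"u{i}" for i in range(10)]
        odds, p, a = fisher_overlap(universe[:4], universe, universe)
        assert a == 4 and p == pytest.approx(1.0)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(30):
            N = int(rng.integers(8, 61))
            universe = [f"u{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            s = list(rng.choice(universe, K, replace=False))
            module = list(rng.choice(universe, n, replace=False))
            a = len(set(s) & set(module))
            _, p, _ = fisher_overlap(s, module, universe)
            assert p == pytest.approx(hypergeom_tail(N, K, n, a), rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(["a"], [], [])


class TestBH:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        # sorted adjs are (0.03, 0.045, 0.04) before the step-up minimum,
        # which caps the middle one at 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrichmentScreen:
    def _screen(self, p_target_sets, universe_size=1000, module_size=50):
        rng = np.random.default_rng(0)
        universe = [f"u{i}" for i in range(universe_size)]
        module = universe[:module_size]
        coll = GeneSetCollection("c", p_target_sets)
        return enrichment_screen(coll, module, universe)

    def test_significance_requires_both_gates(self):
        universe = [f"u{i}" for i in range(100)]
        module = universe[:20]
        coll = GeneSetCollection("c", {
            "enriched": universe[:15],             # all inside the module
            "depleted": universe[20:60],           # none inside
        })
        rows = {r.set_name: r for r in enrichment_screen(coll, module, universe)}
        assert rows["enriched"].significant
        assert rows["enriched"].odds_ratio > 1
        assert not rows["depleted"].significant

    def test_tft_discovery_mode_relaxes_alpha(self):
        universe = [f"u{i}" for i in range(400)]
        module = universe[:40]
        # moderate overlap engineered to land between 0.05 and 0.10 after BH
        sets = {f"s{j}": universe[j:j + 30] for j in range(0, 300, 30)}
        coll = GeneSetCollection("c", sets)
        std = enrichment_screen(coll, module, universe, mode="standard")
        tft = enrichment_screen(coll, module, universe, mode="tft_discovery")
        sig_std = {r.set_name for r in std if r.significant}
        sig_tft = {r.set_name for r in tft if r.significant}
        assert sig_std <= sig_tft

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            enrichment_screen(GeneSetCollection("c", {}), ["a"], ["a"])


def _log2_cohort(rng, n_genes=200, n_per_group=30, rho=0.0, set_size=20,
                 shift=0.0):
    """Two-group cohort; first ``set_size`` genes optionally correlated/shifted."""
    n = 2 * n_per_group
    X = rng.standard_normal((n_genes, n))
    if rho > 0:
        shared = rng.standard_normal(n)
        X[:set_size] = (np.sqrt(rho) * shared[None, :]
                        + np.sqrt(1 - rho) * X[:set_size])
    X[:set_size, :n_per_group] += shift
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n)]
    em = ExpressionMatrix(genes, samples, X, Unit.LOG2)
    groups = {"high": samples[:n_per_group], "low": samples[n_per_group:]}
    return em, groups, genes


class TestSetActivity:
    def test_set_equal_background_is_zero(self, rng):
        em, groups, genes = _log2_cohort(rng)
        row = set_activity(em, groups, genes, genes)
        assert row.enrichment == 0.0

    def test_singleton_set_has_unit_vif(self, rng):
        em, groups, genes = _log2_cohort(rng)
        row = set_activity(em, groups, [genes[0]], genes)
        assert row.vif == 1.0

    def test_antisymmetric_under_group_swap(self, rng):
        em, groups, genes = _log2_cohort(rng, shift=0.5)
        fwd = set_activity(em, groups, genes[:20], genes)
        swapped = {"high": groups["low"], "low": groups["high"]}
        rev = set_activity(em, swapped, genes[:20], genes)
        assert fwd.enrichment == pytest.approx(-rev.enrichment)
        assert fwd.p == pytest.approx(rev.p, rel=1e-9)

    def test_planted_shift_recovered(self, rng):
        em, groups, genes = _log2_cohort(rng, n_genes=2000, n_per_group=100,
                                         shift=1.0)
        row = set_activity(em, groups, genes[:20], genes)
        assert row.enrichment == pytest.approx(1.0, abs=0.1)
        assert row.p < 1e-6

    def test_vif_controls_type_one_error_where_naive_fails(self, rng):
        """Correlated null sets: VIF-corrected rejections ~5%, naive >15%."""
        from scipy import stats as sps
        n_rep, rejections, naive_rejections = 400, 0, 0
        for _ in range(n_rep):
            em, groups, genes = _log2_cohort(rng, n_genes=120, n_per_group=25,
                                             rho=0.3, set_size=20)
            row = set_activity(em, groups, genes[:20], genes)
            rejections += row.p < 0.05
            # same statistic without the VIF inflation
            se_naive = row.vif ** -0.5
            z = sps.norm.isf(row.p / 2) / se_naive if row.p > 0 else np.inf
            naive_rejections += 2 * sps.norm.sf(z) < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08
        assert naive_rejections / n_rep > 0.15

    def test_small_group_rejected(self, rng):
        em, groups, genes = _log2_cohort(rng)
        groups = {"high": groups["high"][:2], "low": groups["low"]}
        with pytest.raises(ValueError):
            set_activity(em, groups, genes[:5], genes)


class TestActivityScreen:
    def test_magnitude_gate(self, rng):
        em, groups, genes = _log2_cohort(rng, n_genes=300, n_per_group=40,
                                         shift=1.0, set_size=30)
        anchor = genes[:30]            # strong activity (the reference)
        weak = genes[30:60]            # no shift: small enrichment
        coll = GeneSetCollection("c", {"anchor_again": anchor, "weak": weak})
        rows = {r.set_name: r for r in activity_screen(coll, em, groups,
                                                       anchor, genes)}
        # the anchor module tested against itself always passes the gate
        assert abs(rows["anchor_again"].enrichment) >= 0.25 * abs(
            rows["anchor_again"].reference_activity)
        assert not rows["weak"].significant

    def test_below_quarter_reference_not_significant(self, rng):
        em, groups, genes = _log2_cohort(rng, n_genes=400, n_per_group=60,
                                         shift=1.0, set_size=30)
        # plant a tiny but precise shift in a second set: p small, magnitude small
        em.values[200:260, :60] += 0.05
        coll = GeneSetCollection("c", {"tiny": genes[200:260]})
        rows = activity_screen(coll, em, groups, genes[:30], genes)
        row = rows[0]
        if row.p_adj < 0.05:
            assert not row.significant  # magnitude gate blocks it
        assert abs(row.enrichment) < 0.25 * abs(row.reference_activity)
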