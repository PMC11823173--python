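import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from colxnet import (
    SimConfig,
    simulate_celltype_counts,
    simulate_mixtures,
)
from colxnet.celltype import (
    build_signature_matrix,
    correlate_fractions_with_game,
    define_celltype_markers,
    impute_fractions,
)
from colxnet.io import ExpressionMatrix, Unit
from colxnet.preprocess import median_of_ratios_normalize


@pytest.fixture(scope="module")
def marker_pipeline():
    cfg = SimConfig(seed=2)
    counts, labels, truth = simulate_celltype_counts(cfg)
    norm, _ = median_of_ratios_normalize(counts)
    table = define_celltype_markers(norm, labels)
    return cfg, norm, labels, truth, table


class TestMarkers:
    def test_planted_markers_recovered(self, marker_pipeline):
        _, _, _, truth, table = marker_pipeline
        for t, planted in truth.marker_sets.items():
            rec = len(set(table.markers[t]) & set(planted)) / len(planted)
            assert rec >= 0.9

    def test_anchor_is_bmsc_marker(self, marker_pipeline):
        _, _, _, truth, table = marker_pipeline
        assert table.is_marker("COL10A1", "BMSC")

    def test_partial_fold_gene_is_not_marker(self):
        # 16-fold vs two types but flat vs the third
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        means = np.full((40, 4), 50.0)
        means[0, 0] = 800.0   # candidate up in type 0
        means[0, 3] = 700.0   # ... but also high in type 3
        reps = np.repeat(means, 3, axis=1)
        counts = rng.poisson(reps).astype(float)
        labels = [t for t in "ABCD" for _ in range(3)]
        X = ExpressionMatrix(genes, [f"s{j}" for j in range(12)], counts,
                             Unit.COUNTS)
        norm, _ = median_of_ratios_normalize(X)
        table = define_celltype_markers(norm, labels)
        assert not table.is_marker("g0", "A")

    def test_flat_gene_is_no_ones_marker(self, marker_pipeline):
        _, _, _, truth, table = marker_pipeline
        planted = {g for gs in truth.marker_sets.values() for g in gs}
        flat = next(g for g in table.contrasts["gene"].unique()
                    if g not in planted)
        assert not any(table.is_marker(flat, t) for t in truth.marker_sets)

    def test_single_replicate_rejected(self, marker_pipeline):
        _, norm, labels, _, _ = marker_pipeline
        bad_labels = ["solo"] + list(labels[1:])
        with pytest.raises(ValueError, match="replicate"):
            define_celltype_markers(norm, bad_labels)


class TestSignature:
    def test_rows_are_uniquely_claimed_markers(self, marker_pipeline):
        _, norm, labels, _, table = marker_pipeline
        sig = build_signature_matrix(norm, labels, table.markers)
        all_markers = [g for t in table.markers for g in table.markers[t]]
        assert len(all_markers) == len(set(all_markers))
        assert set(sig.index) <= set(all_markers)
        assert list(sig.columns) == list(dict.fromkeys(labels))

    def test_max_genes_cap(self, marker_pipeline):
        _, norm, labels, _, table = marker_pipeline
        k = len(table.markers)
        sig = build_signature_matrix(norm, labels, table.markers, max_genes=4 * k)
        per_type = pd.Series([t for t in table.markers
                              for g in table.markers[t] if g in set(sig.index)])
        assert len(sig) <= 4 * k

    def test_markerless_type_rejected(self, marker_pipeline):
        _, norm, labels, _, table = marker_pipeline
        markers = dict(table.markers)
        markers[list(markers)[0]] = []
        with pytest.raises(ValueError):
            build_signature_matrix(norm, labels, markers)


@pytest.fixture(scope="module")
def signature(marker_pipeline):
    _, norm, labels, _, table = marker_pipeline
    return build_signature_matrix(norm, labels, table.markers)


class TestDeconvolution:
    def _profiles(self, signature):
        return ExpressionMatrix(list(signature.index), list(signature.columns),
                                signature.to_numpy(), Unit.RSEM)

    def test_pure_sample_recovered_exactly(self, signature):
        prof = self._profiles(signature)
        bulk = simulate_mixtures(prof, np.array([[1.0, 0, 0, 0]]), noise_sd=0)
        fr = impute_fractions(signature, bulk)
        np.testing.assert_allclose(
            fr.iloc[0][[f"{t}_rel" for t in signature.columns]].to_numpy(),
            [1, 0, 0, 0], atol=1e-9)

    def test_even_mixture_recovered(self, signature):
        prof = self._profiles(signature)
        bulk = simulate_mixtures(prof, np.array([[0.5, 0.5, 0, 0]]), noise_sd=0)
        fr = impute_fractions(signature, bulk)
        np.testing.assert_allclose(
            fr.iloc[0][[f"{t}_rel" for t in signature.columns]].to_numpy(),
            [0.5, 0.5, 0, 0], atol=1e-6)

    def test_noisy_mixture_error_small(self, signature, rng):
        prof = self._profiles(signature)
        truth_fr = rng.dirichlet(np.ones(4), 100)
        noise = 0.1 * float(signature.to_numpy().mean())
        bulk = simulate_mixtures(prof, truth_fr, noise_sd=noise, seed=8)
        fr = impute_fractions(signature, bulk)
        rel = fr[[f"{t}_rel" for t in signature.columns]].to_numpy()
        assert np.abs(rel - truth_fr).mean() < 0.05
        # per-type rank agreement with the truth
        for j in range(4):
            assert spearmanr(rel[:, j], truth_fr[:, j])[0] >= 0.9

    def test_relative_fractions_sum_to_one(self, signature, rng):
        prof = self._profiles(signature)
        bulk = simulate_mixtures(prof, rng.dirichlet(np.ones(4), 20),
                                 noise_sd=1.0, seed=3)
        fr = impute_fractions(signature, bulk)
        rel = fr[[f"{t}_rel" for t in signature.columns]].to_numpy()
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)

    def test_no_shared_genes_rejected(self, signature):
        bulk = ExpressionMatrix(["zzz"], ["s1"], np.array([[1.0]]), Unit.RSEM)
        with pytest.raises(ValueError):
            impute_fractions(signature, bulk)


class TestFractionGameCorrelation:
    def test_monotone_fraction_gives_rho_one(self):
        game = pd.Series(np.linspace(0, 1, 30), index=[f"s{j}" for j in range(30)])
        fr = pd.DataFrame({
            "A": np.linspace(0, 1, 30), "B": np.linspace(1, 0, 30),
            "A_rel": np.linspace(0, 1, 30), "B_rel": np.linspace(1, 0, 30),
        }, index=game.index)
        out = correlate_fractions_with_game(fr, game)
        assert out.loc[out["celltype"] == "A", "rho"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out["celltype"] == "B", "rho"].iloc[0] == pytest.approx(-1.0)

    def test_bonferroni_multiplier_is_type_count(self):
        rng = np.random.default_rng(0)
        idx = [f"s{j}" for j in range(50)]
        game = pd.Series(rng.random(50), index=idx)
        fr = pd.DataFrame({t: rng.random(50) for t in "ABCD"}, index=idx)
        out = correlate_fractions_with_game(fr, game)
        for _, row in out.iterrows():
            assert row["p_bonf"] == pytest.approx(min(1.0, 4 * row["p"]))

    def test_independent_fractions_uncorrelated(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            idx = [f"s{j}" for j in range(200)]
            game = pd.Series(rng.random(200), index=idx)
            fr = pd.DataFrame({"A": rng.random(200)}, index=idx)
            out = correlate_fractions_with_game(fr, game)
            hits += abs(out["rho"].iloc[0]) < 0.2
        assert hits >= 38

    def test_too_few_samples_rejected(self):
        game = pd.Series([0.1, 0.2], index=["a", "b"])
        fr = pd.DataFrame({"A": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            correlate_fractions_with_game(fr, game)
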