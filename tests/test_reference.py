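"""Profile estimation, platform-effect recovery, spot batch correction."""

import numpy as np
import pandas as pd
import pytest

import spotcell as sc


class TestEstimateTypeProfiles:
    def test_log_mean_direct_average(self):
        # two cells of one type with counts (2,0) and (4,2)
        counts = np.array([[2, 4], [0, 2]])
        prof = sc.estimate_type_profiles(counts, pd.Series(["A", "A"]))
        np.testing.assert_allclose(
            prof.log_mean[0],
            [(np.log(3) + np.log(5)) / 2, (np.log(1) + np.log(3)) / 2])

    def test_single_cell_type_equals_cell(self):
        counts = np.array([[3, 1], [1, 4]])
        prof = sc.estimate_type_profiles(counts, pd.Series(["A", "B"]))
        np.testing.assert_allclose(prof.log_mean[0], np.log1p(counts[:, 0]))
        np.testing.assert_allclose(prof.count_mean[0],
                                   counts[:, 0] / counts[:, 0].sum())

    def test_identical_cells_give_identical_rows(self):
        counts = np.tile([[2], [5]], (1, 6))
        labels = pd.Series(["A", "A", "B", "B", "C", "C"])
        prof = sc.estimate_type_profiles(counts, labels)
        assert np.allclose(prof.count_mean, prof.count_mean[0])
        assert np.allclose(prof.log_mean, prof.log_mean[0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(10, 30))
        labels = pd.Series(rng.choice(["A", "B"], size=30))
        perm = rng.permutation(30)
        p1 = sc.estimate_type_profiles(counts, labels)
        p2 = sc.estimate_type_profiles(counts[:, perm],
                                       labels.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(p1.count_mean, p2.count_mean)
        np.testing.assert_allclose(p1.log_mean, p2.log_mean)

    def test_count_mean_rows_are_rates(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(20, 40)) + 1
        labels = pd.Series(rng.choice(["A", "B"], size=40))
        prof = sc.estimate_type_profiles(counts, labels)
        np.testing.assert_allclose(prof.count_mean.sum(axis=1), 1.0)

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            sc.estimate_type_profiles(np.ones((2, 3)), pd.Series(["A", "B"]))


class TestEstimatePlatformEffects:
    def _simulate(self, seed, gamma_sd=0.0, designated=None):
        spec = sc.SimulationSpec(n_types=3, n_genes=200,
                                 cells_per_type=[450] * 3, grid_shape=(25, 20),
                                 cells_per_spot=(1, 2), gamma_sd=gamma_sd,
                                 seed=seed)
        ref = sc.simulate_reference(spec)
        spots, truth = sc.simulate_spots(ref, spec)
        if designated is not None:
            y = spots.counts.copy()
            y[:, designated] *= 2.0  # gamma = log 2 for one gene
            spots = sc.SpotDataset(counts=y, coords=spots.coords,
                                   cell_counts=spots.cell_counts)
        prof = sc.estimate_type_profiles(*ref)
        return spots, truth, prof

    def test_null_gamma_recovered_near_zero(self):
        spots, _, prof = self._simulate(seed=0)
        eff = sc.estimate_platform_effects(spots, prof)
        assert np.abs(eff.gamma).max() < 0.1

    def test_designated_gene_effect_recovered(self):
        spots, _, prof = self._simulate(seed=1, designated=7)
        eff = sc.estimate_platform_effects(spots, prof)
        assert abs(eff.gamma[7] - np.log(2)) < 0.15

    def test_exact_mixture_gives_zero_gamma(self):
        # pseudo-bulk exactly equal to a mixture of profile rows
        rng = np.random.default_rng(3)
        count_mean = rng.dirichlet(np.ones(30), size=2)
        prof = sc.ReferenceProfile(count_mean=count_mean,
                                   log_mean=np.zeros((2, 30)),
                                   type_names=["A", "B"],
                                   gene_names=[f"g{i}" for i in range(30)],
                                   cell_total_mean=100.0)
        mix = 4000 * count_mean[0] + 6000 * count_mean[1]
        coords = pd.DataFrame({"spot_id": ["s0", "s1"], "x": [0.0, 1.0],
                               "y": [0.0, 0.0], "slice": 0})
        spots = sc.SpotDataset(counts=np.stack([mix / 2, mix / 2]),
                               coords=coords, cell_counts=np.array([1, 1]))
        eff = sc.estimate_platform_effects(spots, prof)
        assert np.abs(eff.gamma).max() < 1e-6

    def test_all_zero_gene_flagged(self):
        spots, _, prof = self._simulate(seed=4)
        y = spots.counts.copy()
        y[:, 5] = 0.0
        cm = prof.count_mean.copy()
        cm[:, 5] = 0.0
        prof2 = sc.ReferenceProfile(count_mean=cm, log_mean=prof.log_mean,
                                    type_names=prof.type_names,
                                    gene_names=prof.gene_names,
                                    cell_total_mean=prof.cell_total_mean)
        spots2 = sc.SpotDataset(counts=y, coords=spots.coords,
                                cell_counts=spots.cell_counts)
        with pytest.warns(UserWarning, match="zero counts"):
            eff = sc.estimate_platform_effects(spots2, prof2)
        assert 5 in eff.flagged_genes
        assert eff.gamma[5] == 0.0


class TestCorrectSpotExpression:
    def test_identity_when_no_effects_and_matching_depth(self):
        y = np.array([2.0, 3.0, 5.0])
        eff = sc.PlatformEffects.null(3, 1)
        np.testing.assert_allclose(
            sc.correct_spot_expression(y, eff, target_depth=10.0), y)

    def test_single_gene_effect_halves_that_gene(self):
        y = np.array([4.0, 4.0, 4.0])
        gamma = np.array([0.0, np.log(2), 0.0])
        eff = sc.PlatformEffects(gamma=gamma, alpha=np.zeros(1))
        out = sc.correct_spot_expression(y, eff, target_depth=4 + 2 + 4.0)
        np.testing.assert_allclose(out, [4.0, 2.0, 4.0])

    def test_total_matches_target_depth(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5.0, size=50).astype(float)
        eff = sc.PlatformEffects(gamma=rng.normal(0, 0.3, 50),
                                 alpha=np.zeros(1))
        out = sc.correct_spot_expression(y, eff, target_depth=123.4)
        assert out.min() >= 0
        assert np.isclose(out.sum(), 123.4)

    def test_all_zero_spot_rejected(self):
        eff = sc.PlatformEffects.null(3, 1)
        with pytest.raises(ValueError, match="all-zero"):
            sc.correct_spot_expression(np.zeros(3), eff, target_depth=5.0)

    def test_correction_roundtrip_recovers_proportions(self):
        # with the true simulated gamma, corrected spots match pre-effect
        # gene proportions (noiseless in the effect application)
        spec = sc.SimulationSpec(n_types=2, n_genes=50,
                                 cells_per_type=[200, 200], grid_shape=(4, 4),
                                 cells_per_spot=(1, 2), gamma_sd=0.5,
                                 depth_sd=0.3, seed=5)
        ref = sc.simulate_reference(spec)
        spots, truth = sc.simulate_spots(ref, spec)
        eff = sc.PlatformEffects(gamma=truth.gamma,
                                 alpha=np.zeros(spots.n_spots))
        for i in range(spots.n_spots):
            pre = truth.cell_counts[truth.cell_spot == i].sum(axis=0).astype(float)
            out = sc.correct_spot_expression(spots.counts[i], eff,
                                             target_depth=pre.sum())
            cos = out @ pre / (np.linalg.norm(out) * np.linalg.norm(pre))
            assert cos >= 0.99


def test_gamma_recovery_correlation_property():
    """gamma ~ N(0, 0.5^2) at G=200, I=500: Pearson(gamma_hat, gamma) >= 0.9."""
    from spotcell.benchmarks import gamma_recovery_study

    out = gamma_recovery_study(seed=3, n_seeds=3)
    assert out["min_pearson"] >= 0.9
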