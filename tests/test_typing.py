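"""Neighbor graph, Potts energy, Poisson likelihood, ICM, singlet/doublet."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import spotcell as sc


def _spots(xy, cells, slices=None):
    n = len(xy)
    coords = pd.DataFrame({
        "spot_id": [f"s{i}" for i in range(n)],
        "x": [p[0] for p in xy], "y": [p[1] for p in xy],
        "slice": slices if slices is not None else 0})
    counts = np.ones((n, 4))
    return sc.SpotDataset(counts=counts, coords=coords,
                          cell_counts=np.asarray(cells))


class TestNeighborGraph:
    def test_within_spot_triangle(self, one_spot_dataset):
        g = sc.build_neighbor_graph(one_spot_dataset, radius=1.0)
        assert g.n_cells == 3 and g.n_edges == 3

    def test_distant_spots_not_linked(self):
        g = sc.build_neighbor_graph(_spots([(0, 0), (5, 0)], [1, 1]),
                                    radius=1.0)
        assert g.n_edges == 0

    def test_grid_four_neighborhood(self):
        # 2x2 unit grid, radius 1.01: 4 edges, no diagonals
        g = sc.build_neighbor_graph(
            _spots([(0, 0), (1, 0), (0, 1), (1, 1)], [1, 1, 1, 1]),
            radius=1.01)
        assert g.n_edges == 4
        assert not any({u, v} == {0, 3} or {u, v} == {1, 2}
                       for u, v in g.edges)

    def test_cross_slice_link(self):
        spots = _spots([(0, 0), (0, 0.1)], [1, 1], slices=[0, 1])
        g0 = sc.build_neighbor_graph(spots, radius=0.01, z_link=False)
        g1 = sc.build_neighbor_graph(spots, radius=0.01, z_link=True)
        assert g0.n_edges == 0 and g1.n_edges == 1

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _spots([(0, 0), (0, 0)], [1, 1])


class TestPottsEnergy:
    def _graph(self):
        return sc.build_neighbor_graph(
            _spots([(0, 0)], [3]), radius=1.0)

    def test_uniform_labels_zero_energy(self):
        g = self._graph()
        assert sc.potts_energy(np.zeros(3, int), g, nu=10.0) == 0.0

    def test_single_discordant_edge(self):
        g = sc.build_neighbor_graph(_spots([(0, 0), (0.5, 0)], [1, 1]),
                                    radius=1.0)
        assert sc.potts_energy(np.array([0, 1]), g, nu=10.0) == 10.0

    def test_triangle_three_distinct_labels(self):
        g = self._graph()
        assert sc.potts_energy(np.array([0, 1, 2]), g, nu=1.0) == 3.0

    def test_missing_labels_rejected(self):
        g = self._graph()
        with pytest.raises(ValueError):
            sc.potts_energy(np.array([0, 1]), g, nu=1.0)


class TestSpotLogLikelihood:
    def _single_gene_profile(self, mu=0.5):
        return sc.ReferenceProfile(count_mean=np.array([[mu]]),
                                   log_mean=np.zeros((1, 1)),
                                   type_names=["A"], gene_names=["g"])

    def test_matches_poisson_pmf(self):
        # N=10, mu=0.5 -> rate 5; log Poisson(5; 5) ~ -1.7403
        prof = self._single_gene_profile()
        eff = sc.PlatformEffects.null(1, 1)
        ll = sc.spot_log_likelihood(np.array([5.0]), 10.0, np.array([0]),
                                    prof, eff)
        expected = -5 + 5 * np.log(5) - gammaln(6)
        assert np.isclose(ll, expected, atol=1e-10)
        assert np.isclose(ll, -1.7403, atol=5e-5)

    def test_all_zero_counts(self):
        rng = np.random.default_rng(0)
        mu = rng.dirichlet(np.ones(6))[None, :]
        prof = sc.ReferenceProfile(count_mean=mu, log_mean=np.zeros((1, 6)),
                                   type_names=["A"],
                                   gene_names=list("abcdef"))
        eff = sc.PlatformEffects.null(6, 1)
        N = 20.0
        ll = sc.spot_log_likelihood(np.zeros(6), N, np.array([0]), prof, eff)
        assert np.isclose(ll, -N * mu.sum())

    def test_quadrature_continuity_at_zero_noise(self):
        rng = np.random.default_rng(1)
        mu = rng.dirichlet(np.ones(8))[None, :]
        prof = sc.ReferenceProfile(count_mean=mu, log_mean=np.zeros((1, 8)),
                                   type_names=["A"],
                                   gene_names=[f"g{i}" for i in range(8)])
        y = rng.poisson(3.0, size=8).astype(float)
        ll0 = sc.spot_log_likelihood(y, y.sum(), np.array([0]), prof,
                                     sc.PlatformEffects.null(8, 1))
        eff = sc.PlatformEffects(gamma=np.zeros(8), alpha=np.zeros(1),
                                 sigma_eps=1e-8)
        ll1 = sc.spot_log_likelihood(y, y.sum(), np.array([0]), prof, eff)
        assert abs(ll0 - ll1) < 1e-6

    def test_zero_rate_with_positive_count_floored(self):
        prof = sc.ReferenceProfile(count_mean=np.array([[0.0, 1.0]]),
                                   log_mean=np.zeros((1, 2)),
                                   type_names=["A"], gene_names=["a", "b"])
        eff = sc.PlatformEffects.null(2, 1)
        with pytest.warns(UserWarning, match="floored"):
            ll = sc.spot_log_likelihood(np.array([2.0, 3.0]), 5.0,
                                        np.array([0]), prof, eff)
        assert np.isfinite(ll)


class TestICM:
    def test_nu_zero_single_cells_equals_independent_ml(self, tiny_profile):
        rng = np.random.default_rng(2)
        n = 9
        coords = pd.DataFrame({"spot_id": [f"s{i}" for i in range(n)],
                               "x": np.arange(n, dtype=float), "y": 0.0,
                               "slice": 0})
        true_k = rng.integers(0, 3, size=n)
        y = np.stack([rng.poisson(200 * tiny_profile.count_mean[k])
                      for k in true_k]).astype(float)
        spots = sc.SpotDataset(counts=y, coords=coords,
                               cell_counts=np.ones(n, int))
        eff = sc.PlatformEffects.null(8, n)
        graph = sc.build_neighbor_graph(spots, radius=1.01)
        field = sc.icm_map_labels(spots, graph, tiny_profile, eff, nu=0.0,
                                  n_restarts=1, seed=0)
        # independent per-spot ML
        for i in range(n):
            lls = [sc.spot_log_likelihood(y[i], y[i].sum(), np.array([k]),
                                          tiny_profile, eff)
                   for k in range(3)]
            assert field.labels[i] == int(np.argmax(lls))

    def test_huge_nu_collapses_to_best_single_label(self, tiny_profile):
        rng = np.random.default_rng(3)
        n = 6
        coords = pd.DataFrame({"spot_id": [f"s{i}" for i in range(n)],
                               "x": np.arange(n, dtype=float), "y": 0.0,
                               "slice": 0})
        y = np.stack([rng.poisson(100 * tiny_profile.count_mean[i % 3])
                      for i in range(n)]).astype(float)
        spots = sc.SpotDataset(counts=y, coords=coords,
                               cell_counts=np.ones(n, int))
        eff = sc.PlatformEffects.null(8, n)
        graph = sc.build_neighbor_graph(spots, radius=1.01)
        field = sc.icm_map_labels(spots, graph, tiny_profile, eff, nu=1e6,
                                  n_restarts=3, seed=0)
        assert len(set(field.labels)) == 1
        # the single shared label maximizes the total likelihood
        totals = [sum(sc.spot_log_likelihood(y[i], y[i].sum(), np.array([k]),
                                             tiny_profile, eff)
                      for i in range(n)) for k in range(3)]
        assert field.labels[0] == int(np.argmax(totals))

    def test_icm_matches_bruteforce_on_small_instances(self):
        from spotcell.benchmarks import icm_bruteforce_study

        out = icm_bruteforce_study(seed=0, n_instances=5)
        assert out["global_hits"] >= 4
        assert out["locally_optimal"] == 5

    def test_missing_type_robustness(self, tiny_profile):
        # delete one type from the reference: labels stay in range
        prof2 = sc.ReferenceProfile(count_mean=tiny_profile.count_mean[:2],
                                    log_mean=tiny_profile.log_mean[:2],
                                    type_names=tiny_profile.type_names[:2],
                                    gene_names=tiny_profile.gene_names)
        rng = np.random.default_rng(4)
        n = 8
        coords = pd.DataFrame({"spot_id": [f"s{i}" for i in range(n)],
                               "x": np.arange(n, dtype=float), "y": 0.0,
                               "slice": 0})
        y = np.stack([rng.poisson(150 * tiny_profile.count_mean[2])
                      for _ in range(n)]).astype(float)
        spots = sc.SpotDataset(counts=y, coords=coords,
                               cell_counts=np.ones(n, int))
        graph = sc.build_neighbor_graph(spots, radius=1.01)
        field = sc.icm_map_labels(spots, graph, prof2,
                                  sc.PlatformEffects.null(8, n), nu=10.0,
                                  n_restarts=2, seed=0)
        assert set(field.labels) <= {0, 1}
        assert np.isfinite(field.energy)


class TestClassifySpotMultiplicity:
    def test_singlet_and_doublet_recovery(self, tiny_profile):
        eff = sc.PlatformEffects.null(8, 1)
        ok1 = ok2 = 0
        n_trials = 100
        for s in range(n_trials):
            rng = np.random.default_rng(1000 + s)
            p1 = tiny_profile.count_mean[0]
            y1 = rng.multinomial(500, p1 / p1.sum())
            m1, _ = sc.classify_spot_multiplicity(y1, tiny_profile, eff)
            ok1 += m1 == 1
            pm = tiny_profile.count_mean[0] + tiny_profile.count_mean[1]
            y2 = rng.multinomial(500, pm / pm.sum())
            m2, types = sc.classify_spot_multiplicity(y2, tiny_profile, eff)
            ok2 += (m2 == 2 and set(types) == {0, 1})
        assert ok1 >= 90
        assert ok2 >= 90

    def test_identical_profiles_tie_break_to_singlet(self):
        cm = np.tile(np.full(6, 1 / 6), (2, 1))
        prof = sc.ReferenceProfile(count_mean=cm, log_mean=np.zeros((2, 6)),
                                   type_names=["A", "B"],
                                   gene_names=[f"g{i}" for i in range(6)])
        eff = sc.PlatformEffects.null(6, 1)
        m, _ = sc.classify_spot_multiplicity(np.full(6, 10.0), prof, eff)
        assert m == 1


def test_potts_smoothing_reduces_error():
    """Coherent labels: typing error at nu=10 <= error at nu=0 (paired)."""
    from spotcell.benchmarks import potts_benefit_study

    out = potts_benefit_study(seed=7, n_seeds=3)
    assert out["mean_err_nu10"] <= out["mean_err_nu0"]
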