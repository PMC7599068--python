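"""Occupancy model: binning, pooling, Dirichlet posterior, KL, shifts,
convergence, and the multivariate KS test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurotopo import occupancy as occ
from neurotopo import synthetic


def _table(larva_id, zs, xs, genotype="wt"):
    n = len(zs)
    return pd.DataFrame({
        "larva_id": [larva_id] * n,
        "genotype": [genotype] * n,
        "side": ["left"] * n,
        "x_um": xs,
        "y_um": [0.0] * n,
        "z_um": zs,
        "marker": ["negative"] * n,
        "label": ["IO"] * n,
    })


class TestAssignBins:
    def test_extremes_land_in_edge_bins(self):
        cells = _table("l0", zs=[0.0, 10.0, 60.0], xs=[0.0, 5.0, 40.0])
        binned = occ.assign_bins(cells)
        assert binned["z_bin"].iloc[0] == 0
        assert binned["z_bin"].iloc[2] == 14  # dorsal-most, top edge closed
        assert binned["x_bin"].iloc[0] == 0  # at midline
        assert binned["x_bin"].iloc[2] == 3  # lateral-most

    def test_fractional_position_half_open(self):
        # fraction 0.5 of the DV extent -> floor(0.5 * 15) = 7
        cells = _table("l0", zs=[0.0, 30.0, 60.0], xs=[0.0, 1.0, 2.0])
        binned = occ.assign_bins(cells, z_extent=(0.0, 60.0), x_extent=(0.0, 2.0))
        assert binned["z_bin"].iloc[1] == 7

    def test_per_larva_normalisation(self):
        """Each larva's extent is anchored to its own first/last cell."""
        cells = pd.concat([
            _table("a", zs=[0.0, 30.0], xs=[0.0, 10.0]),
            _table("b", zs=[100.0, 130.0], xs=[0.0, 10.0]),
        ], ignore_index=True)
        binned = occ.assign_bins(cells)
        assert list(binned["z_bin"]) == [0, 14, 0, 14]

    def test_zero_extent_errors(self):
        cells = _table("l0", zs=[5.0, 5.0], xs=[0.0, 3.0])
        with pytest.raises(ValueError, match="DV extent"):
            occ.assign_bins(cells)

    def test_generator_round_trip(self, base_grid):
        """Generated coordinates re-bin to exactly the sampled bins when
        binning is anchored to the generator's nominal extents."""
        truth = synthetic.SyntheticTruth(base_grid, n_larvae=5,
                                         cells_per_larva=(20, 40), seed=9)
        cells = synthetic.gen_occupancy_dataset(truth)
        binned = occ.assign_bins(cells,
                                 z_extent=synthetic.DV_EXTENT_UM,
                                 x_extent=synthetic.ML_EXTENT_UM)
        grid = occ.pool_counts(binned)
        # empirical distribution concentrates on truth's support
        support = base_grid > 0
        assert grid.counts[~support].sum() == 0
        assert grid.n_cells == len(cells)

    def test_degenerate_grid_round_trip(self):
        """All probability mass in bin (0, 0): every cell re-bins there."""
        grid = np.zeros((15, 4))
        grid[0, 0] = 1.0
        truth = synthetic.SyntheticTruth(grid, n_larvae=5,
                                         cells_per_larva=(10, 10), seed=2)
        cells = synthetic.gen_occupancy_dataset(truth)
        binned = occ.assign_bins(cells,
                                 z_extent=synthetic.DV_EXTENT_UM,
                                 x_extent=synthetic.ML_EXTENT_UM)
        assert len(cells) == 50
        assert (binned["z_bin"] == 0).all()
        assert (binned["x_bin"] == 0).all()


class TestPoolAndEmpirical:
    def test_pooling_additivity(self, base_grid):
        truth = synthetic.SyntheticTruth(base_grid, n_larvae=4,
                                         cells_per_larva=(15, 25), seed=3)
        cells = synthetic.gen_occupancy_dataset(truth)
        binned = occ.assign_bins(cells, z_extent=synthetic.DV_EXTENT_UM,
                                 x_extent=synthetic.ML_EXTENT_UM)
        total = occ.pool_counts(binned)
        per_larva = [occ.pool_counts(g) for _, g in binned.groupby("larva_id")]
        np.testing.assert_array_equal(
            total.counts, np.sum([g.counts for g in per_larva], axis=0))

    def test_uniform_grid_frequencies_within_3se(self, uniform_grid):
        truth = synthetic.SyntheticTruth(uniform_grid, n_larvae=19,
                                         cells_per_larva=(15, 15), seed=1)
        cells = synthetic.gen_occupancy_dataset(truth)
        binned = occ.assign_bins(cells, z_extent=synthetic.DV_EXTENT_UM,
                                 x_extent=synthetic.ML_EXTENT_UM)
        freq = occ.empirical_distribution(occ.pool_counts(binned))
        n = len(cells)
        se = np.sqrt((1 / 60) * (1 - 1 / 60) / n)
        assert np.abs(freq - 1 / 60).max() <= 3 * se

    def test_empirical_normalisation(self):
        counts = np.zeros((15, 4), dtype=int)
        counts[2, 1] = 30
        counts[10, 3] = 10
        p = occ.empirical_distribution(occ.OccupancyGrid(counts))
        assert p[2, 1] == 0.75 and p[10, 3] == 0.25
        assert abs(p.sum() - 1.0) < 1e-12

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            occ.empirical_distribution(occ.OccupancyGrid(np.zeros((15, 4), int)))


class TestPosterior:
    def test_flat_prior_no_data(self):
        post = occ.posterior_sample(np.zeros((15, 4), int), alpha_prior=1.0,
                                    n_samples=4000, seed=0)
        se = post.samples.std(axis=0).max() / np.sqrt(post.n_samples)
        assert np.abs(post.samples.mean(axis=0) - 1 / 60).max() < 3 * np.sqrt(
            (1 / 60) * (59 / 60) / 61 / post.n_samples) * 60 + 3 * se

    def test_conjugate_closed_form_mean(self):
        counts = np.zeros((15, 4), int)
        counts[7, 2] = 1000
        post = occ.posterior_sample(counts, alpha_prior=1.0, n_samples=8000, seed=1)
        expected = 1001.0 / 1060.0
        mc_se = post.samples[:, 7 * 4 + 2].std() / np.sqrt(post.n_samples)
        assert abs(post.samples[:, 7 * 4 + 2].mean() - expected) < 4 * mc_se

    def test_mcmc_matches_direct(self):
        rng = np.random.default_rng(5)
        counts = rng.multinomial(300, np.full(60, 1 / 60)).reshape(15, 4)
        direct = occ.posterior_sample(counts, n_samples=3000, seed=10)
        mcmc = occ.posterior_sample(counts, n_samples=3000, method="mcmc", seed=11)
        se = np.sqrt(direct.samples.var(axis=0) / direct.n_samples
                     + mcmc.samples.var(axis=0) / mcmc.n_samples)
        diff = np.abs(direct.samples.mean(axis=0) - mcmc.samples.mean(axis=0))
        assert np.all(diff < 4 * se)

    def test_samples_are_probability_vectors(self):
        counts = np.arange(60).reshape(15, 4)
        for method in ("direct", "mcmc"):
            post = occ.posterior_sample(counts, n_samples=500, method=method, seed=2)
            assert np.all(post.samples >= 0)
            np.testing.assert_allclose(post.samples.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            occ.posterior_sample(np.zeros((15, 4), int), alpha_prior=0.0)


class TestDivergenceAndShift:
    def test_kl_self_is_zero(self):
        post = occ.posterior_sample(np.eye(15, 4, dtype=int) * 5, n_samples=1000,
                                    seed=3)
        summ = occ.kl_posterior(post, post)
        assert summ.kl_mean == 0.0
        assert summ.kl_ci_low == summ.kl_ci_high == 0.0

    def test_kl_two_bin_hand_computed(self):
        """Degenerate single-vector sample sets against the direct formula."""
        p = np.array([[0.7, 0.3]])
        q = np.array([[0.4, 0.6]])
        make = lambda v: occ.PosteriorSampleSet(
            samples=v, grid_shape=(1, 2), alpha_prior=1.0, method="direct", seed=0)
        expected = 0.7 * np.log(0.7 / 0.4) + 0.3 * np.log(0.3 / 0.6)
        summ = occ.kl_posterior(make(p), make(q))
        assert summ.kl_mean == pytest.approx(expected, rel=1e-12)

    def test_kl_nonnegative_random_pairs(self):
        rng = np.random.default_rng(8)
        a = rng.dirichlet(np.ones(60), 500)
        b = rng.dirichlet(np.ones(60), 500)
        assert np.all(occ.kl_divergence(a, b) >= 0)

    def test_identical_posteriors_shift_straddles_zero(self, base_grid):
        counts = np.random.default_rng(0).multinomial(
            400, base_grid.ravel()).reshape(15, 4)
        pa = occ.posterior_sample(counts, n_samples=3000, seed=1)
        pb = occ.posterior_sample(counts, n_samples=3000, seed=2)
        s = occ.axis_shift(pa, pb, "DV")
        assert s.ci_low < 0 < s.ci_high
        assert abs(s.shift_mean) < 0.5

    def test_extreme_shift_is_axis_length(self):
        top = np.zeros((15, 4), int)
        top[14, 0] = 1000
        bottom = np.zeros((15, 4), int)
        bottom[0, 0] = 1000
        pa = occ.posterior_sample(top, n_samples=2000, seed=1)
        pb = occ.posterior_sample(bottom, n_samples=2000, seed=2)
        s = occ.axis_shift(pa, pb, "DV")
        assert s.shift_mean == pytest.approx(14.0, abs=0.1)
        assert abs(s.shift_mean) <= 14.0

    def test_unknown_axis(self, base_grid):
        counts = (base_grid * 100).astype(int)
        p = occ.posterior_sample(counts, n_samples=100, seed=0)
        with pytest.raises(ValueError, match="axis"):
            occ.axis_shift(p, p, "AP")

    def test_differential_map_conservation(self, base_grid):
        shifted = synthetic.shift_grid(base_grid, dz=-1)
        diff = occ.differential_map(base_grid, shifted)
        assert abs(diff.sum()) < 1e-12
        np.testing.assert_allclose(
            occ.differential_map(base_grid, base_grid), 0.0, atol=1e-15)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_differential_entries_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.dirichlet(np.ones(60)).reshape(15, 4)
        b = rng.dirichlet(np.ones(60)).reshape(15, 4)
        d = occ.differential_map(a, b)
        assert np.all(d >= -1.0) and np.all(d <= 1.0)
        assert abs(d.sum()) < 1e-12


class TestConvergence:
    def test_identical_grids_converge_immediately(self, base_grid):
        # large identical counts: posterior KL floor ~ support/N is tiny
        counts = (base_grid * 5000).astype(int)
        g = occ.OccupancyGrid(counts)
        report = occ.convergence_check(g, g, sample_sizes=(500, 1000, 2000), seed=4)
        assert report["converged"]
        assert max(report["kl_means"]) < 0.05

    def test_kl_sequence_stabilises(self, base_grid):
        rng = np.random.default_rng(1)
        ga = occ.OccupancyGrid(rng.multinomial(300, base_grid.ravel()).reshape(15, 4))
        gb = occ.OccupancyGrid(rng.multinomial(300, base_grid.ravel()).reshape(15, 4))
        report = occ.convergence_check(ga, gb,
                                       sample_sizes=(1000, 5000, 20000), seed=7)
        m = report["kl_means"]
        assert abs(m[2] - m[1]) <= abs(m[1] - m[0]) + 0.01 * m[1]
        assert report["sample_sizes"][-1] == 20000

    def test_needs_three_sizes(self, base_grid):
        g = occ.OccupancyGrid((base_grid * 100).astype(int))
        with pytest.raises(ValueError):
            occ.convergence_check(g, g, sample_sizes=(100, 200))


class TestMultivariateKS:
    def test_identical_samples_k_zero(self):
        pts = np.array([[0, 0], [1, 2], [3, 1], [4, 3], [2, 2], [0, 3]], float)
        res = occ.mks_test(pts, pts, n_perm=99, seed=0)
        assert res["k"] == 0.0
        assert res["p"] == 1.0

    def test_fully_separated_k_one(self):
        """Opposite quadrants with dominating corner points -> k = 1."""
        a = np.array([[0, 0], [-1, 0], [0, -1], [-2, -2], [-1, -1]], float)
        b = a + 10.0
        res = occ.mks_test(a, b, n_perm=99, seed=0)
        assert res["k"] == 1.0
        assert res["p"] <= 0.05

    def test_statistic_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 15, size=(30, 2)).astype(float)
        b = rng.integers(0, 15, size=(40, 2)).astype(float)
        r1 = occ.mks_test(a, b, n_perm=199, seed=5)
        r2 = occ.mks_test(b, a, n_perm=199, seed=5)
        assert 0.0 <= r1["k"] <= 1.0
        assert r1["k"] == pytest.approx(r2["k"], abs=1e-12)

    def test_sample_size_and_perm_guards(self):
        a = np.zeros((4, 2))
        b = np.zeros((10, 2))
        with pytest.raises(ValueError, match=">= 5"):
            occ.mks_test(a, b)
        with pytest.raises(ValueError, match="n_perm"):
            occ.mks_test(b, b, n_perm=10)
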