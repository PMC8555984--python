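import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechpatch.spatial_model import (
    ChannelField,
    ClusterMode,
    ClusterModelParams,
    PatchSamplerParams,
    channel_count_histogram,
    counts_to_currents_to_counts,
    nearest_neighbor_stats,
    sample_patches,
    simulate_channel_field,
    zero_truncated_poisson_mean,
)


def make_field(points, arena_side=50.0):
    points = np.asarray(points, dtype=float)
    params = ClusterModelParams(arena_side=arena_side, channel_density=1.0, seed=0)
    return ChannelField(
        points=points, parent_index=np.arange(len(points)), params=params
    )


class TestClusterModelParams:
    def test_invalid_density(self):
        with pytest.raises(ValueError):
            ClusterModelParams(channel_density=0.0)

    def test_invalid_arena(self):
        with pytest.raises(ValueError):
            ClusterModelParams(arena_side=-1.0)

    def test_invalid_poisson_mean(self):
        with pytest.raises(ValueError):
            ClusterModelParams(cluster_mode="poisson", poisson_mean=0.0)

    def test_parent_density_matches_channel_density(self):
        p = ClusterModelParams(channel_density=1.75)
        assert p.parent_density == 1.75
        p = ClusterModelParams(
            channel_density=1.75, cluster_mode="poisson", poisson_mean=5.0
        )
        assert p.parent_density == pytest.approx(0.35)


class TestSimulateChannelField:
    def test_expected_count_fixed_one(self):
        # Poisson oracle: mean = rho*A = 4375, sd = sqrt(mean)
        params = ClusterModelParams(
            arena_side=50.0, channel_density=1.75, seed=42
        )
        field = simulate_channel_field(params)
        assert abs(field.n_points - 4375) < 3 * np.sqrt(4375)

    def test_expected_count_poisson_mode(self):
        params = ClusterModelParams(
            arena_side=50.0,
            channel_density=1.75,
            cluster_mode="poisson",
            poisson_mean=5.0,
            seed=7,
        )
        field = simulate_channel_field(params)
        # var of total = kappa*A*(lam + lam^2) for a Poisson number of
        # Poisson clusters; kappa*A = 875, lam = 5 -> sd ~ 162
        assert abs(field.n_points - 4375) < 3 * np.sqrt(875 * (5 + 25))

    def test_populated_cluster_mean_lambda_one(self):
        params = ClusterModelParams(
            arena_side=50.0,
            channel_density=1.75,
            cluster_mode="poisson",
            poisson_mean=1.0,
            seed=3,
        )
        field = simulate_channel_field(params)
        sizes = np.bincount(field.parent_index)
        populated = sizes[sizes > 0]
        # zero-truncated Poisson(1) mean, 1/(1-exp(-1)) ~ 1.582
        assert np.mean(populated) == pytest.approx(
            zero_truncated_poisson_mean(1.0), rel=0.02
        )

    def test_zero_sigma_daughters_on_parents(self):
        params = ClusterModelParams(displacement_sigma=0.0, seed=5)
        field = simulate_channel_field(params)
        # fixed_one with zero displacement: points coincide with parents,
        # which are uniform in the arena
        assert np.all(field.points >= 0.0)
        assert np.all(field.points <= params.arena_side)

    def test_reproducible(self):
        params = ClusterModelParams(seed=11)
        a = simulate_channel_field(params)
        b = simulate_channel_field(params)
        np.testing.assert_array_equal(a.points, b.points)


class TestSamplePatches:
    def test_empty_field_all_zero(self):
        field = make_field(np.empty((0, 2)))
        sampler = PatchSamplerParams(n_circles=50, seed=0)
        samples = sample_patches(field, sampler)
        assert np.all(samples.counts == 0)

    def test_single_point_always_inside_large_circles(self):
        field = make_field([[25.0, 25.0]])
        sampler = PatchSamplerParams(
            n_circles=20, radius_mean=100.0, radius_sd=0.0, seed=0
        )
        samples = sample_patches(field, sampler)
        assert np.all(samples.counts == 1)

    def test_counts_poisson_at_fixed_radius(self):
        params = ClusterModelParams(arena_side=50.0, channel_density=1.75, seed=21)
        field = simulate_channel_field(params)
        sampler = PatchSamplerParams(
            n_circles=4000, radius_mean=0.8, radius_sd=0.0, seed=22
        )
        samples = sample_patches(field, sampler)
        mean_expected = 1.75 * np.pi * 0.8**2  # ~3.52
        assert samples.counts.mean() == pytest.approx(mean_expected, rel=0.1)
        zero_expected = np.exp(-mean_expected)  # ~0.030
        se = np.sqrt(zero_expected * (1 - zero_expected) / 4000)
        assert abs(samples.zero_fraction - zero_expected) < 4 * se

    def test_radii_positive(self):
        field = make_field([[1.0, 1.0]])
        sampler = PatchSamplerParams(
            n_circles=500, radius_mean=0.1, radius_sd=0.5, seed=1
        )
        samples = sample_patches(field, sampler)
        assert np.all(samples.radii > 0)


class TestCountsToCurrentsToCounts:
    def test_zero_count_roundtrip(self):
        sampler = PatchSamplerParams(seed=0)
        currents, reverted = counts_to_currents_to_counts(np.array([0, 0]), sampler)
        assert np.all(currents == 0)
        assert np.all(reverted == 0)

    def test_noiseless_roundtrip_identity(self):
        sampler = PatchSamplerParams(
            current_mean=0.98, current_sd=0.0, reference_current=0.98, seed=0
        )
        counts = np.array([0, 1, 2, 5, 17])
        currents, reverted = counts_to_currents_to_counts(counts, sampler)
        assert currents[3] == pytest.approx(4.9)
        np.testing.assert_array_equal(reverted, counts)

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_noiseless_identity_property(self, counts):
        sampler = PatchSamplerParams(
            current_mean=1.3, current_sd=0.0, reference_current=1.3, seed=0
        )
        _, reverted = counts_to_currents_to_counts(np.array(counts), sampler)
        np.testing.assert_array_equal(reverted, counts)

    def test_monte_carlo_oracle(self):
        # brute-force oracle with the same formula on an independent rng
        sampler = PatchSamplerParams(
            current_mean=0.98, current_sd=0.22, reference_current=0.98, seed=123
        )
        counts = np.full(10_000, 10)
        _, reverted = counts_to_currents_to_counts(counts, sampler)

        oracle_rng = np.random.default_rng(99)
        draws = oracle_rng.normal(0.98, 0.22, 10_000)
        oracle = np.maximum(np.floor(np.abs(10 * draws / 0.98) + 0.5) * np.sign(draws), 0)
        assert reverted.mean() == pytest.approx(oracle.mean(), rel=0.02)
        assert reverted.std() == pytest.approx(oracle.std(), rel=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            counts_to_currents_to_counts(np.array([-1]), PatchSamplerParams(seed=0))


class TestNearestNeighborStats:
    def test_two_points(self):
        field = make_field([[0.0, 0.0], [0.1, 0.0]])  # 100 nm apart
        nn = nearest_neighbor_stats(field, cutoff=100.0)
        np.testing.assert_allclose(nn.distances, [100.0, 100.0])
        assert nn.mean_nn == pytest.approx(100.0)
        assert nn.fraction_within == 1.0

    def test_fewer_than_two_points(self):
        with pytest.raises(ValueError):
            nearest_neighbor_stats(make_field([[0.0, 0.0]]))

    def test_fixed_one_mean_nn_closed_form(self):
        # infinite-plane oracle: mean NN = 1/(2 sqrt(rho)) = 378 nm
        means = []
        for seed in range(3):
            params = ClusterModelParams(
                arena_side=50.0, channel_density=1.75, seed=seed
            )
            nn = nearest_neighbor_stats(simulate_channel_field(params))
            means.append(nn.mean_nn)
        oracle = 1.0 / (2.0 * np.sqrt(1.75)) * 1000.0
        assert np.mean(means) == pytest.approx(oracle, rel=0.05)
        # finite-arena value sits slightly above the infinite-plane form
        assert np.mean(means) > oracle

    def test_high_density_mean_nn(self):
        params = ClusterModelParams(
            arena_side=10.0, channel_density=100.0, displacement_sigma=0.0, seed=2
        )
        nn = nearest_neighbor_stats(simulate_channel_field(params))
        assert nn.mean_nn == pytest.approx(50.0, rel=0.05)

    def test_fraction_within_closed_form(self):
        # P(NN <= r) = 1 - exp(-rho pi r^2) for a Poisson process
        params = ClusterModelParams(arena_side=50.0, channel_density=1.75, seed=8)
        field = simulate_channel_field(params)
        assert field.n_points >= 4000
        nn = nearest_neighbor_stats(field, cutoff=100.0)
        expected = 1.0 - np.exp(-1.75 * np.pi * 0.1**2)
        se = np.sqrt(expected * (1 - expected) / field.n_points)
        assert abs(nn.fraction_within - expected) < 3 * se


class TestChannelCountHistogram:
    def test_simple(self):
        values, freqs = channel_count_histogram(np.array([0, 0, 1, 1]))
        np.testing.assert_array_equal(values, [0, 1])
        np.testing.assert_allclose(freqs, [0.5, 0.5])

    def test_all_equal(self):
        values, freqs = channel_count_histogram(np.array([3, 3, 3]))
        assert freqs[3] == 1.0
        assert freqs[:3].sum() == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            channel_count_histogram(np.array([], dtype=int))

    def test_matches_poisson_pmf(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        mu = 3.52
        counts = rng.poisson(mu, 20_000)
        values, freqs = channel_count_histogram(counts)
        pmf = sps.poisson.pmf(values, mu)
        se = np.sqrt(pmf * (1 - pmf) / counts.size)
        assert np.all(np.abs(freqs - pmf) < 4 * se + 1e-4)

    @given(st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_frequencies_sum_to_one(self, counts):
        _, freqs = channel_count_histogram(np.array(counts))
        assert freqs.sum() == pytest.approx(1.0)


class TestZeroTruncatedPoisson:
    def test_closed_form(self):
        assert zero_truncated_poisson_mean(1.0) == pytest.approx(
            1.0 / (1.0 - np.exp(-1.0))
        )

    def test_against_simulation(self):
        rng = np.random.default_rng(17)
        draws = rng.poisson(1.0, 1_000_000)
        sim = draws[draws > 0].mean()
        assert sim == pytest.approx(zero_truncated_poisson_mean(1.0), rel=0.01)
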