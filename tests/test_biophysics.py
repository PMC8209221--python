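"""Length and angle distribution correctness, checked against independent
oracles: closed-form moments, adaptive quadrature, and KS tests against
numerically-constructed CDFs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from tethersample import (
    AngleHistogram,
    BiophysicalConstants,
    ConfigurationError,
    InputError,
    InvalidSpecError,
    ModelConfig,
    WlcDistribution,
    standin_nick_histogram,
)
from tethersample.biophysics import (
    JointKind,
    polar_angle_from_uniform,
    sample_deviation_angle,
    sample_ds_length,
    sample_nick_angle,
    sample_ss_length_uniform,
    sample_ss_length_wlc,
    wlc_for_domain,
    wlc_pdf,
)

CONST = BiophysicalConstants()


class TestDsLength:
    @pytest.mark.parametrize("n_nt,expected", [(1, 0.34), (6, 2.04), (10, 3.4)])
    def test_rigid_rod_length(self, n_nt, expected):
        assert sample_ds_length(n_nt, CONST) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [0, -3, 2.5, "6"])
    def test_invalid_nucleotide_counts(self, bad):
        with pytest.raises(InvalidSpecError):
            sample_ds_length(bad, CONST)


class TestUniformSsLength:
    def test_support_bound(self, rng):
        draws = sample_ss_length_uniform(6, CONST, rng, size=5000)
        assert np.all(draws >= 0) and np.all(draws <= 6 * 0.68)

    def test_mean_matches_uniform_midpoint(self, rng):
        # oracle: mean of U(0, L) is L/2 = 3.4 nm for a 10-nt strand
        draws = sample_ss_length_uniform(10, CONST, rng, size=100_000)
        se = 6.8 / np.sqrt(12) / np.sqrt(draws.size)
        assert abs(draws.mean() - 3.4) < 3 * se

    def test_seed_reproducibility(self):
        a = sample_ss_length_uniform(1, CONST, np.random.default_rng(42))
        b = sample_ss_length_uniform(1, CONST, np.random.default_rng(42))
        assert a == b


class TestWlcDistribution:
    def test_density_zero_at_origin(self):
        d = WlcDistribution(L=4.08, s=2.0)
        assert wlc_pdf(0.0, d) == 0.0

    def test_density_zero_beyond_contour(self):
        d = WlcDistribution(L=4.08, s=2.0)
        assert d.pdf(4.08) == 0.0
        assert d.pdf(10.0) == 0.0

    def test_negative_distance_rejected(self):
        d = WlcDistribution(L=4.08, s=2.0)
        with pytest.raises(InvalidSpecError):
            d.pdf(-0.1)

    @pytest.mark.parametrize("t", [0.5, 1.0, 2.04, 5.0, 20.0])
    def test_normalization_by_quadrature(self, t):
        # oracle: adaptive quadrature of the density over its support
        d = WlcDistribution(L=t * 2.0, s=2.0)
        integral, _ = integrate.quad(d.pdf, 0.0, d.L, limit=200)
        assert abs(integral - 1.0) < 1e-3

    def test_mode_matches_dense_grid_scan(self):
        # oracle: independent dense-grid argmax over the support
        d = WlcDistribution(L=4.08, s=2.0)
        fine = np.linspace(0, d.L * (1 - 1e-9), 200_001)
        oracle_mode = fine[np.argmax(d.pdf(fine))]
        coarse = np.linspace(0, d.L * (1 - 1e-9), 4096)
        assert abs(coarse[np.argmax(d.pdf(coarse))] - oracle_mode) < d.L / 1000

    def test_sampler_support(self, rng):
        d = wlc_for_domain(6, CONST)
        draws = d.sample(rng, size=20_000)
        assert np.all(draws >= 0) and np.all(draws < d.L)

    def test_sampler_mean_matches_quadrature(self, rng):
        # oracle: E[R] = integral of R * p(R) dR by adaptive quadrature
        d = wlc_for_domain(6, CONST)
        mean_oracle, _ = integrate.quad(lambda R: R * d.pdf(R), 0.0, d.L, limit=200)
        draws = sample_ss_length_wlc(6, CONST, rng, size=100_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - mean_oracle) < 3 * se

    def test_sampler_distribution_ks(self, rng):
        # oracle: numeric CDF built independently by cumulative quadrature
        d = wlc_for_domain(6, CONST)
        grid = np.linspace(0.0, d.L * (1 - 1e-9), 20_000)
        cdf_grid = integrate.cumulative_trapezoid(d.pdf(grid), grid, initial=0.0)
        cdf_grid /= cdf_grid[-1]
        draws = d.sample(rng, size=10_000)
        result = stats.ks_1samp(draws, lambda x: np.interp(x, grid, cdf_grid))
        assert result.pvalue > 0.01

    @pytest.mark.parametrize("L,s", [(0, 2.0), (-1, 2.0), (4.08, 0)])
    def test_invalid_parameters(self, L, s):
        with pytest.raises(InvalidSpecError):
            WlcDistribution(L=L, s=s)


class TestPolarAngle:
    @pytest.mark.parametrize(
        "x,hemisphere,expected",
        [(0.5, False, np.pi / 2), (1.0, False, 0.0), (0.0, False, np.pi), (1.0, True, 0.0)],
    )
    def test_transform_fixed_points(self, x, hemisphere, expected):
        assert polar_angle_from_uniform(x, hemisphere) == pytest.approx(expected, abs=1e-12)

    def test_full_sphere_cosine_uniform(self):
        rng = np.random.default_rng(0)
        angles = sample_deviation_angle(JointKind.SS_SS, ModelConfig(), rng, size=100_000)
        result = stats.kstest(np.cos(angles), stats.uniform(loc=-1, scale=2).cdf)
        assert result.pvalue > 0.01

    def test_hemisphere_support(self, rng):
        angles = sample_deviation_angle(JointKind.TETHER, ModelConfig(), rng, size=50_000)
        assert np.all(angles >= 0) and np.all(angles < np.pi / 2)


class TestNickAngleHistogram:
    def test_single_bin_support(self, rng):
        hist = AngleHistogram(bin_edges=(20.0, 30.0), weights=(1.0,))
        draws = sample_nick_angle(hist, rng, size=5000)
        assert np.all(draws >= np.deg2rad(20)) and np.all(draws <= np.deg2rad(30))

    def test_bin_frequencies_match_weights(self, rng):
        # oracle: multinomial with p = (0.75, 0.25)
        hist = AngleHistogram(bin_edges=(0.0, 10.0, 20.0), weights=(3.0, 1.0))
        draws = np.rad2deg(sample_nick_angle(hist, rng, size=100_000))
        frac = np.mean(draws < 10.0)
        se = np.sqrt(0.75 * 0.25 / draws.size)
        assert abs(frac - 0.75) < 4 * se

    def test_standin_mass_concentrated_between_20_and_30_degrees(self, rng):
        hist = standin_nick_histogram()
        draws = np.rad2deg(hist.sample(rng, size=50_000))
        assert np.all((draws >= 10) & (draws <= 40))
        assert np.mean((draws >= 20) & (draws <= 30)) > 0.5

    @pytest.mark.parametrize(
        "edges,weights",
        [
            ((0.0, 10.0), (0.0,)),  # zero total mass
            ((10.0, 5.0), (1.0,)),  # non-monotone edges
            ((0.0, 10.0, 200.0), (1.0, 1.0)),  # out of [0, 180]
            ((0.0, 10.0), (1.0, 1.0)),  # weight/edge length mismatch
            ((0.0, 10.0), (-1.0,)),  # negative weight
        ],
    )
    def test_invalid_histograms(self, edges, weights):
        with pytest.raises(InputError):
            AngleHistogram(bin_edges=edges, weights=weights)

    @given(
        st.lists(st.floats(1.0, 179.0), min_size=2, max_size=8, unique=True),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_samples_stay_within_outer_edges(self, edges, seed):
        edges = sorted(edges)
        hist = AngleHistogram(bin_edges=tuple(edges), weights=tuple([1.0] * (len(edges) - 1)))
        draws = np.rad2deg(hist.sample(np.random.default_rng(seed), size=200))
        assert np.all(draws >= edges[0]) and np.all(draws <= edges[-1])


class TestModelConfig:
    def test_nicked_model_requires_histogram(self):
        with pytest.raises(ConfigurationError, match="histogram"):
            ModelConfig.from_name("WN")

    @pytest.mark.parametrize("name", ["UU", "UN", "WU", "WN"])
    def test_name_round_trip(self, name, nick_hist):
        hist = nick_hist if name in ("UN", "WN") else None
        assert ModelConfig.from_name(name, nick_histogram=hist).name == name

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig.from_name("XX")

    def test_negative_z_floor_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(z_floor=-1.0)

    def test_nick_joint_under_uniform_model_matches_flexible_joint(self):
        # Under UU the nick joint must be distributionally identical to ss-ss.
        cfg = ModelConfig.from_name("UU")
        a = sample_deviation_angle(JointKind.DS_NICK, cfg, np.random.default_rng(1), size=50_000)
        b = sample_deviation_angle(JointKind.SS_SS, cfg, np.random.default_rng(2), size=50_000)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_nick_joint_under_nicked_model_uses_histogram(self, rng):
        hist = AngleHistogram(bin_edges=(20.0, 30.0), weights=(1.0,))
        cfg = ModelConfig.from_name("WN", nick_histogram=hist)
        draws = sample_deviation_angle(JointKind.DS_NICK, cfg, rng, size=2000)
        assert np.all(draws >= np.deg2rad(20)) and np.all(draws <= np.deg2rad(30))


def test_angle_samplers_return_values_in_0_pi(rng):
    cfg = ModelConfig.from_name("WN", nick_histogram=standin_nick_histogram())
    for kind in JointKind:
        draws = np.atleast_1d(sample_deviation_angle(kind, cfg, rng, size=10_000))
        assert np.all(draws >= 0) and np.all(draws <= np.pi)


def test_identical_seed_gives_bit_identical_streams(nick_hist):
    cfg = ModelConfig.from_name("WN", nick_histogram=nick_hist)
    streams = []
    for _ in range(2):
        r = np.random.default_rng(7)
        streams.append(
            np.concatenate(
                [
                    np.atleast_1d(sample_ss_length_wlc(6, CONST, r, size=100)),
                    np.atleast_1d(sample_deviation_angle(JointKind.DS_NICK, cfg, r, size=100)),
                ]
            )
        )
    np.testing.assert_array_equal(streams[0], streams[1])
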