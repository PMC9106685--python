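import numpy as np
import pytest

from stereomotion import cue_integration as ci
from stereomotion import geometry as geo
from stereomotion import image_statistics as ist


def consistent_stimulus(size=40.0, amplitude=80.0, duration=1.5):
    traj = geo.triangular_trajectory(amplitude, duration, 60.0)
    return geo.CueStimulus(traj, traj, size)


class TestSampleSegments:
    def test_default_stride_gives_18_segments(self):
        seg = ci.sample_segments(consistent_stimulus(), 5)
        assert seg.n_segments == 18
        np.testing.assert_allclose(seg.t_end - seg.t_start, 5 / 60.0)

    def test_constant_speed_segments(self):
        stim = consistent_stimulus()
        seg = ci.sample_segments(stim, 5)
        v = stim.geometry.viewing_distance
        m_start = v - geo.size_from_angle(0, v)  # placeholder 0
        # per-segment net displacement from the disparity samples
        i = stim.geometry.interocular_separation
        # invert disparity to position
        pos = (i / 2.0) / np.tan(seg.disp_start / (2 * geo.ARCMIN_PER_RAD))
        pos_end = (i / 2.0) / np.tan(seg.disp_end / (2 * geo.ARCMIN_PER_RAD))
        net = np.abs(pos - pos_end)
        expected = 4 * 80.0 / 1.5 * (5 / 60.0)
        # all segments move at the constant triangular speed except the two
        # that contain a direction reversal at their midpoint (net ~ 0)
        big = net > expected / 2
        assert big.sum() == 16
        np.testing.assert_allclose(net[big], expected, rtol=1e-9)
        np.testing.assert_allclose(net[~big], 0.0, atol=1e-9)

    def test_full_duration_stride_single_segment(self):
        seg = ci.sample_segments(consistent_stimulus(), 90)
        assert seg.n_segments == 1
        assert seg.t_start[0] == 0.0
        assert seg.t_end[0] == pytest.approx(1.5)

    def test_too_long_stride_rejected(self):
        with pytest.raises(ValueError):
            ci.sample_segments(consistent_stimulus(), 91)


class TestCdMeasurementWeights:
    def test_noiseless_limit_delta(self, small_dists):
        grid = small_dists.signal_grid
        w = ci.cd_measurement_weights(300.0, 307.0, None, grid)
        assert np.count_nonzero(w.weights) == 1
        b = np.argmax(w.weights)
        assert grid.cd_edges[b] <= -7.0 < grid.cd_edges[b + 1]

    def test_weights_sum_to_one(self, small_dists):
        noise = ci.NoiseModel(0.35, 3.0)
        w = ci.cd_measurement_weights(300.0, 307.0, noise, small_dists.signal_grid)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert 0.99 < w.coverage <= 1.0

    def test_gaussian_moment_oracle(self, small_dists):
        noise = ci.NoiseModel(0.35, 3.0)
        grid = small_dists.signal_grid
        w = ci.cd_measurement_weights(300.0, 307.0, noise, grid)
        centers = 0.5 * (grid.cd_edges[:-1] + grid.cd_edges[1:])
        assert np.sum(w.weights * centers) == pytest.approx(-7.0, abs=1e-5)
        var = np.sum(w.weights * (centers + 7.0) ** 2)
        assert var == pytest.approx(2 * 0.35**2, rel=0.02)


class TestCsMeasurementWeights:
    def test_noiseless_limit_delta(self, small_dists):
        w = ci.cs_measurement_weights(180.0, 185.0, None, small_dists.signal_grid)
        assert np.count_nonzero(w.weights) == 1
        grid = small_dists.signal_grid
        b = np.argmax(w.weights)
        assert grid.cs_edges[b] <= 185.0 / 180.0 < grid.cs_edges[b + 1]

    def test_monte_carlo_oracle_total_variation(self, small_dists):
        # empirical ratio of two noisy sizes vs the analytic bin masses
        noise = ci.NoiseModel(0.35, 3.0)
        grid = small_dists.signal_grid
        w = ci.cs_measurement_weights(180.0, 180.0, noise, grid)
        rng = np.random.default_rng(8)
        n = 1_000_000
        ratio = (180.0 + rng.normal(0, 3.0, n)) / (180.0 + rng.normal(0, 3.0, n))
        counts, _ = np.histogram(ratio, bins=grid.cs_edges)
        empirical = counts / n
        tv = 0.5 * np.sum(np.abs(empirical - w.weights * w.coverage))
        assert tv < 0.01

    def test_larger_baseline_narrows_distribution(self, small_dists):
        noise = ci.NoiseModel(0.35, 3.0)
        grid = small_dists.signal_grid
        centers = 0.5 * (grid.cs_edges[:-1] + grid.cs_edges[1:])

        def sd(size):
            w = ci.cs_measurement_weights(size, size, noise, grid)
            mean = np.sum(w.weights * centers)
            return np.sqrt(np.sum(w.weights * (centers - mean) ** 2))

        assert sd(45.0) > sd(180.0) > sd(270.0)

    def test_working_regime_enforced(self, small_dists):
        noise = ci.NoiseModel(0.35, 3.0)
        with pytest.raises(ValueError):
            ci.cs_measurement_weights(8.0, 180.0, noise, small_dists.signal_grid)


class TestRatioDistribution:
    def test_pdf_integrates_to_cdf(self):
        z = np.linspace(0.8, 1.25, 2001)
        pdf = ci.ratio_of_gaussians_pdf(z, 182.0, 180.0, 3.0)
        integral = np.trapezoid(pdf, z)
        cdf_mass = ci.ratio_of_gaussians_cdf(1.25, 182.0, 180.0, 3.0) - ci.ratio_of_gaussians_cdf(
            0.8, 182.0, 180.0, 3.0
        )
        assert integral == pytest.approx(float(cdf_mass), rel=1e-4)


class TestWeightedPosterior:
    def test_delta_weight_reduces_to_conditional(self, small_dists):
        tab = small_dists.posterior_cd
        b = int(tab.signal_bin(-7.0))
        w = np.zeros(tab.n_signal_bins)
        w[b] = 1.0
        joint = ci.weighted_posterior(
            ci.MeasurementWeights("cd", w), tab
        )
        np.testing.assert_allclose(joint, tab.conditional(b), atol=1e-14)

    def test_output_normalised(self, small_dists):
        noise = ci.NoiseModel(0.35, 3.0)
        w = ci.cd_measurement_weights(300.0, 307.0, noise, small_dists.signal_grid)
        joint = ci.weighted_posterior(w, small_dists.posterior_cd)
        assert joint.sum() == pytest.approx(1.0, abs=1e-12)

    def test_three_bin_hand_mixture(self):
        sg = ist.SignalGrid(
            cd_edges=np.array([-3.0, -2.0, -1.0, 0.0]), cs_edges=np.array([0.9, 1.1])
        )
        scg = ist.SceneGrid(
            v_edges=np.array([500.0, 1000.0]), m_edges=np.array([-50.0, 0.0, 50.0])
        )
        counts = np.array([[[4, 0]], [[1, 1]], [[0, 4]]], dtype=np.int64)
        tab = ist.PosteriorTable("cd", sg, scg, counts)
        w = ci.MeasurementWeights("cd", np.array([0.5, 0.25, 0.25]))
        joint = ci.weighted_posterior(w, tab)
        # 0.5*[1,0] + 0.25*[0.5,0.5] + 0.25*[0,1] = [0.625, 0.375]
        np.testing.assert_allclose(joint[0], [0.625, 0.375])

    def test_all_weight_unsupported_rejected(self):
        sg = ist.SignalGrid(
            cd_edges=np.array([-2.0, -1.0, 0.0]), cs_edges=np.array([0.9, 1.1])
        )
        scg = ist.SceneGrid(
            v_edges=np.array([500.0, 1000.0]), m_edges=np.array([-50.0, 50.0])
        )
        counts = np.array([[[5]], [[0]]], dtype=np.int64)
        tab = ist.PosteriorTable("cd", sg, scg, counts)
        with pytest.raises(ValueError):
            ci.weighted_posterior(ci.MeasurementWeights("cd", np.array([0.0, 1.0])), tab)


class TestCombineCues:
    def test_uniform_cue_is_neutral(self, rng):
        p = rng.dirichlet(np.ones(12)).reshape(3, 4)
        flat = np.full((3, 4), 1.0 / 12)
        np.testing.assert_allclose(ci.combine_cues(p, flat), p, atol=1e-14)

    def test_self_combination_preserves_mode(self, rng):
        p = rng.dirichlet(np.ones(12)).reshape(3, 4)
        combined = ci.combine_cues(p, p)
        assert np.unravel_index(np.argmax(combined), p.shape) == np.unravel_index(
            np.argmax(p), p.shape
        )

    def test_two_by_two_hand_example(self):
        p = np.array([[0.4, 0.1], [0.3, 0.2]])
        q = np.array([[0.25, 0.25], [0.25, 0.25]])
        out = ci.combine_cues(p, q)
        np.testing.assert_allclose(out, p)
        r = np.array([[0.5, 0.5], [0.0, 0.0]])
        out2 = ci.combine_cues(p, r)
        np.testing.assert_allclose(out2, np.array([[0.8, 0.2], [0.0, 0.0]]))

    def test_printed_denominator_variant(self):
        p = np.array([[0.6, 0.4]])
        q = np.array([[0.5, 0.5]])
        out = ci.combine_cues(p, q, printed_denominator=True)
        np.testing.assert_allclose(out, (p * q) / (p + q).sum())
        assert out.sum() != pytest.approx(1.0)

    def test_irreconcilable_rejected(self):
        p = np.array([[1.0, 0.0]])
        q = np.array([[0.0, 1.0]])
        with pytest.raises(ValueError):
            ci.combine_cues(p, q)

    def test_entropy_never_increases(self, obs_dists, rng):
        noise = ci.NoiseModel(0.35, 1.0)
        stim = consistent_stimulus()
        seg = ci.sample_segments(stim, 5)
        grid = obs_dists.signal_grid

        def entropy(p):
            p = p[p > 0]
            return -np.sum(p * np.log(p))

        for k in range(0, 18, 4):
            d0 = seg.disp_start[k] + rng.normal(0, noise.n_disparity)
            d1 = seg.disp_end[k] + rng.normal(0, noise.n_disparity)
            s0 = seg.size_start[k] + rng.normal(0, noise.n_size)
            s1 = seg.size_end[k] + rng.normal(0, noise.n_size)
            p_cd = ci.weighted_posterior(
                ci.cd_measurement_weights(d0, d1, noise, grid), obs_dists.posterior_cd
            )
            p_cs = ci.weighted_posterior(
                ci.cs_measurement_weights(s0, s1, noise, grid), obs_dists.posterior_cs
            )
            combined = ci.combine_cues(p_cd, p_cs)
            assert entropy(combined) <= min(entropy(p_cd), entropy(p_cs)) + 0.05


class TestKernelAgreement:
    def test_batch_kernel_matches_composed_path(self, obs_dists):
        noise = ci.NoiseModel(0.35, 3.0)
        stim = consistent_stimulus()
        seg = ci.sample_segments(stim, 5)
        est = ci.estimate_segments(seg, noise, obs_dists, np.random.default_rng(0))
        # replay identical noisy measurements through the step-by-step API
        rng = np.random.default_rng(0)
        n = seg.n_segments
        d0 = seg.disp_start + rng.normal(0, noise.n_disparity, n)
        d1 = seg.disp_end + rng.normal(0, noise.n_disparity, n)
        s0 = seg.size_start + rng.normal(0, noise.n_size, n)
        s1 = seg.size_end + rng.normal(0, noise.n_size, n)
        grid = obs_dists.signal_grid
        mc = obs_dists.scene_grid.m_centers
        vc = obs_dists.scene_grid.v_centers
        for k in (0, 7, 13):
            p_cd = ci.weighted_posterior(
                ci.cd_measurement_weights(d0[k], d1[k], noise, grid),
                obs_dists.posterior_cd,
            )
            p_cs = ci.weighted_posterior(
                ci.cs_measurement_weights(s0[k], s1[k], noise, grid),
                obs_dists.posterior_cs,
            )
            combined = ci.combine_cues(p_cd, p_cs)
            assert est.m_cd[k] == pytest.approx(np.sum(p_cd.sum(axis=0) * mc), abs=1e-4)
            assert est.v_cs[k] == pytest.approx(np.sum(p_cs.sum(axis=1) * vc), abs=1e-2)
            assert est.m_combined[k] == pytest.approx(
                np.sum(combined.sum(axis=0) * mc), abs=1e-4
            )


class TestEstimateSpeed:
    def test_near_noiseless_bias_within_15_percent(self, obs_dists):
        noise = ci.NoiseModel(1e-4, 1e-3)
        speed = ci.estimate_speed(consistent_stimulus(), noise, obs_dists, np.random.default_rng(0))
        assert speed == pytest.approx(213.33, rel=0.15)

    def test_nonnegative_and_small_for_zero_amplitude(self, obs_dists):
        traj = geo.sample_waveform(1e-6, 1.5, 60.0)
        stim = geo.CueStimulus(traj, traj, 40.0)
        noise = ci.NoiseModel(0.35, 3.0)
        speeds = [
            ci.estimate_speed(stim, noise, obs_dists, np.random.default_rng(i))
            for i in range(10)
        ]
        assert all(s >= 0.0 for s in speeds)

    def test_deterministic_for_fixed_rng(self, obs_dists):
        noise = ci.NoiseModel(0.35, 3.0)
        a = ci.estimate_speed(consistent_stimulus(), noise, obs_dists, np.random.default_rng(5))
        b = ci.estimate_speed(consistent_stimulus(), noise, obs_dists, np.random.default_rng(5))
        assert a == b

    def test_direction_reversal_invariance(self, obs_dists):
        noise = ci.NoiseModel(0.35, 1.0)
        fwd = consistent_stimulus()
        rev_traj = geo.sample_waveform(80.0, 1.5, 60.0, phase=np.pi)
        rev = geo.CueStimulus(rev_traj, rev_traj, 40.0)
        n = 500
        sf = np.array(
            [ci.estimate_speed(fwd, noise, obs_dists, np.random.default_rng(i)) for i in range(n)]
        )
        sr = np.array(
            [
                ci.estimate_speed(rev, noise, obs_dists, np.random.default_rng(10_000 + i))
                for i in range(n)
            ]
        )
        se = np.sqrt(sf.var() / n + sr.var() / n)
        assert abs(sf.mean() - sr.mean()) < 4 * se

    def test_cs_reliability_rises_with_surface_size(self, obs_dists):
        # the mechanism behind the PSE shift: bigger surfaces give narrower
        # CS measurement distributions per segment
        noise = ci.NoiseModel(0.35, 3.0)
        grid = obs_dists.signal_grid
        centers = 0.5 * (grid.cs_edges[:-1] + grid.cs_edges[1:])
        sds = []
        for size in (10.0, 40.0, 60.0):
            stim = consistent_stimulus(size=size)
            seg = ci.sample_segments(stim, 5)
            w = ci.cs_measurement_weights(
                seg.size_start[0], seg.size_end[0], noise, grid
            )
            mean = np.sum(w.weights * centers)
            sds.append(np.sqrt(np.sum(w.weights * (centers - mean) ** 2)))
        assert sds[0] > sds[1] > sds[2]
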