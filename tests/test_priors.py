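"""Prior components: Beta-Bernoulli loads, Gaussian-increment motion,
parameter priors and posterior assembly."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import invgamma, poisson

from emitrack.core import AcquisitionTiming, CameraModel, ConfigError, ImageStack, Optics, SystemState, validate_config
from emitrack.forward_model import camera_sample, expected_image, log_likelihood
from emitrack.priors import (
    LoadsPrior,
    MotionPrior,
    ParamPriors,
    loads_log_prior,
    motion_log_prob,
    params_log_prior,
    sample_track,
    state_log_posterior,
)

TIM = AcquisitionTiming.regular(4, 0.1, 0.114)
BOUNDS = np.array([[-500.0, 2500.0], [-500.0, 2500.0], [-800.0, 800.0]])


class TestLoadsPrior:
    def test_all_zero_closed_form(self):
        assert loads_log_prior(np.zeros(10), LoadsPrior(10, 1.0)) == pytest.approx(10 * np.log(0.9))

    def test_permutation_invariance(self):
        prior = LoadsPrior(6, 2.0)
        b = np.array([1, 0, 1, 0, 0, 1])
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert loads_log_prior(rng.permutation(b), prior) == pytest.approx(loads_log_prior(b, prior))

    def test_expected_active_count_is_gamma(self):
        # truncated construction: E[sum b] = M * (gamma/M) = gamma exactly;
        # Monte-Carlo mean within 3 standard errors
        prior = LoadsPrior(50, 5.0)
        rng = np.random.default_rng(1)
        counts = rng.binomial(prior.M, prior.p_active, size=20_000)
        se = np.sqrt(prior.gamma * (1 - prior.p_active) / counts.size)
        assert counts.mean() == pytest.approx(5.0, abs=3 * se)

    def test_gamma_at_least_m_rejected(self):
        with pytest.raises(ConfigError):
            LoadsPrior(5, 5.0)

    def test_count_prior_approaches_poisson(self):
        # Binomial(M, gamma/M) -> Poisson(gamma) for growing truncation
        prior = LoadsPrior(1000, 5.0)
        rng = np.random.default_rng(2)
        counts = rng.binomial(prior.M, prior.p_active, size=50_000)
        ks = np.arange(15)
        emp = np.array([(counts == k).mean() for k in ks])
        assert np.abs(emp - poisson.pmf(ks, 5.0)).max() < 0.01


class TestMotionPrior:
    def make(self, D=5e4):
        return MotionPrior(D, BOUNDS)

    def test_zero_displacement_maximizes_transitions(self):
        prior = self.make()
        flat = np.tile([1000.0, 1000.0, 0.0], (TIM.n_frames * 2, 1))
        still = motion_log_prob(flat.reshape(TIM.n_frames, 2, 3), prior, TIM)
        rng = np.random.default_rng(3)
        for _ in range(5):
            moved = flat + np.vstack([[0, 0, 0], rng.normal(0, 50, (flat.shape[0] - 1, 3))])
            assert motion_log_prob(moved.reshape(TIM.n_frames, 2, 3), prior, TIM) < still

    def test_markov_additivity(self):
        # the log-prob decomposes into initial term plus per-step terms
        prior = self.make()
        tim2 = AcquisitionTiming.regular(3, 0.1, 0.114)
        rng = np.random.default_rng(4)
        track = np.array([1000.0, 1000.0, 0.0]) + rng.normal(0, 60, (3, 1, 3))
        total = motion_log_prob(track, prior, tim2)
        from emitrack.core import subexposure_times

        t = subexposure_times(tim2, 1).ravel()
        flat = track.reshape(3, 3)
        expect = prior.log_init_density
        for i in range(2):
            var = 2 * prior.diffusion * (t[i + 1] - t[i])
            d2 = np.sum((flat[i + 1] - flat[i]) ** 2)
            expect += -1.5 * np.log(2 * np.pi * var) - d2 / (2 * var)
        assert total == pytest.approx(expect, rel=1e-12)

    def test_out_of_bounds_start_is_impossible(self):
        prior = self.make()
        track = np.tile([-5000.0, 0.0, 0.0], (TIM.n_frames * 2, 1)).reshape(TIM.n_frames, 2, 3)
        assert motion_log_prob(track, prior, TIM) == -np.inf

    def test_entropy_of_simulated_tracks(self):
        # mean negative transition log-prob of Brownian tracks simulated at
        # the same D matches the Gaussian entropy rate within MC error
        D = 5e4
        prior = self.make(D)
        rng = np.random.default_rng(5)
        from emitrack.core import subexposure_times

        t = subexposure_times(TIM, 2).ravel()
        dts = np.diff(t)
        n_tracks, vals = 400, []
        for _ in range(n_tracks):
            track = sample_track(prior, TIM, 2, rng)
            lp = motion_log_prob(track, prior, TIM) - prior.log_init_density
            vals.append(-lp / dts.size)
        entropy = np.mean([3 * (0.5 * np.log(2 * np.pi * np.e * 2 * D * dt)) for dt in dts])
        se = np.std(vals) / np.sqrt(n_tracks)
        assert np.mean(vals) == pytest.approx(entropy, abs=4 * se)

    def test_nonpositive_diffusion_rejected(self):
        with pytest.raises(ValueError):
            MotionPrior(0.0, BOUNDS)


HYPER = ParamPriors(d_shape=2.0, d_scale=1e5, h_shape=2.0, h_scale=2.5e4, f_shape=1.0, f_scale=0.02)


class TestParamPriors:
    def test_shape_one_is_exponential(self):
        # Gamma(1, scale) log-density is linear in the parameter
        f = np.array([0.01, 0.02, 0.03])
        vals = [params_log_prior(1e5, [1.0], [x], HYPER, include_brightness=False) for x in f]
        diffs = np.diff(vals)
        assert diffs[0] == pytest.approx(diffs[1], rel=1e-9)

    def test_matches_scipy_densities(self):
        got = params_log_prior(8e4, np.array([4e4, 6e4]), np.array([0.01, 0.02]), HYPER)
        expect = (
            invgamma.logpdf(8e4, 2.0, scale=1e5)
            + gamma_dist.logpdf([4e4, 6e4], 2.0, scale=2.5e4).sum()
            + gamma_dist.logpdf([0.01, 0.02], 1.0, scale=0.02).sum()
        )
        assert got == pytest.approx(float(expect), rel=1e-12)

    def test_per_frame_independence(self):
        h1 = np.array([4e4, 6e4])
        h2 = np.array([8e4, 6e4])
        F = np.array([0.01, 0.01])
        d1 = params_log_prior(1e5, h1, F, HYPER) - params_log_prior(1e5, h2, F, HYPER)
        expect = gamma_dist.logpdf(4e4, 2.0, scale=2.5e4) - gamma_dist.logpdf(8e4, 2.0, scale=2.5e4)
        assert d1 == pytest.approx(float(expect), rel=1e-9)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            params_log_prior(-1.0, [1.0], [0.0], HYPER)


class TestPosteriorAssembly:
    def setup_method(self):
        cam = CameraModel(100.0, 49.0, 2.2, 2.0, 133.0, 8, 8)
        opt = Optics(1.45, 665.0, 110.0, 400.0)
        self.cfg = validate_config(cam, opt, TIM).with_model(M=3, gamma=1.0, K=2)
        rng = np.random.default_rng(6)
        self.tracks = 500 + 30 * rng.standard_normal((3, 4, 2, 3))
        self.state = SystemState(
            np.array([1, 1, 0]), self.tracks, 5e4, np.full(4, 5000.0), np.full(4, 0.01)
        )
        u = expected_image(self.state, self.cfg)
        self.data = ImageStack(camera_sample(u, cam, rng=7), TIM, cam)

    def test_additivity_of_components(self):
        from emitrack.priors import LoadsPrior as LP
        from emitrack.priors import MotionPrior as MP

        cfg, st = self.cfg, self.state
        total = state_log_posterior(st, self.data, cfg)
        parts = log_likelihood(self.data.values, expected_image(st, cfg), self.data.camera)
        parts += loads_log_prior(st.loads, LP(3, 1.0))
        motion = MP(st.diffusion, cfg.init_bounds)
        for m in range(3):
            parts += motion_log_prob(st.tracks[m], motion, TIM)
        parts += params_log_prior(st.diffusion, st.brightness, st.background, ParamPriors.from_config(cfg))
        assert total == pytest.approx(parts, abs=1e-10 * abs(parts))

    def test_invariant_under_joint_relabeling(self):
        st2 = self.state.copy()
        st2.tracks = st2.tracks[[1, 0, 2]]
        st2.loads = st2.loads[[1, 0, 2]]
        a = state_log_posterior(self.state, self.data, self.cfg)
        b = state_log_posterior(st2, self.data, self.cfg)
        assert a == pytest.approx(b, rel=1e-12)

    def test_likelihood_terms_equal_when_u_identical(self):
        # states differing only in an inactive track differ by
        # data-independent (motion prior) terms only
        st2 = self.state.copy()
        st2.tracks[2] = st2.tracks[2] + 40.0
        cfg = self.cfg
        u1 = expected_image(self.state, cfg)
        u2 = expected_image(st2, cfg)
        np.testing.assert_array_equal(u1, u2)
        d_total = state_log_posterior(st2, self.data, cfg) - state_log_posterior(self.state, self.data, cfg)
        motion = MotionPrior(self.state.diffusion, cfg.init_bounds)
        d_prior = motion_log_prob(st2.tracks[2], motion, TIM) - motion_log_prob(self.state.tracks[2], motion, TIM)
        assert d_total == pytest.approx(d_prior, rel=1e-9)
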