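"""MCMC over the joint posterior of loads, tracks, diffusion, brightness
and background, plus posterior summaries (MAP estimate, count posterior,
credible intervals).

The target density is :func:`emitrack.priors.state_log_posterior`.  One
sweep performs, in order:

* per active emitter: blocked Metropolis-Hastings track updates —
  single-frame Brownian-bridge redraws over a red/black frame
  checkerboard (proposals from the motion-prior conditional, so
  acceptance reduces to a likelihood ratio) alternating sweep-by-sweep
  with whole-frame random-walk jitters, longer bridge windows of 3 and 7
  frames cycled in, plus a whole-track translation;
* load flips on a random slot subset: births propose a fresh prior track
  whose start is drawn from a residual-image-informed mixture proposal
  (with the exact Hastings correction) while the background flux drops to
  conserve expected photons; deaths are the reverse move;
* a residual-guided relocation of one active track, and a reversible
  split/merge pair exchanging two active tracks with their midpoint
  track — both flux-compensated — for crossing between emitter-count
  modes that single flips cannot reach;
* a joint Gibbs draw of the diffusion coefficient and all inactive tracks:
  D from its Inverse-Gamma full conditional given the *active* increments,
  inactive tracks refreshed from the motion prior at the new D — jointly
  an exact Gibbs update of the full-dimension target, because the
  inactive-track prior factors cancel;
* a joint rescale of (D, track shapes) exploiting Brownian scale
  invariance, which moves D along the D/roughness ridge;
* random-walk updates on the log of background flux (and brightness,
  unless held fixed).

:func:`run_chain` tempers the likelihood during early burn-in (a
geometric inverse-temperature ramp) and starts from the best of several
short pilot segments; retained samples always target the untempered
posterior.  Every move satisfies detailed balance with respect to that
target; with the likelihood disabled (``run.prior_only``) the chain must
reproduce the priors exactly, which the test suite checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln, ndtr

from .core import Config, ImageStack, SystemState, subexposure_times
from .forward_model import frame_log_likelihood, psf_lateral_width
from .priors import LoadsPrior, MotionPrior, ParamPriors, loads_log_prior, params_log_prior, sample_track

__all__ = [
    "Chain",
    "TrackEstimate",
    "init_state",
    "sweep",
    "run_chain",
    "map_estimate",
    "credible_intervals",
    "track_credible_intervals",
    "diffusion_conditional",
    "sample_diffusion_conditional",
]

_LOG2PI_LOCAL = float(np.log(2.0 * np.pi))
_WINDOW_SCHEDULE = (1, 3, 7)
_JITTER_SD = (25.0, 25.0, 80.0)  # nm; lateral vs axial proposal scales
_TRANSLATE_SD = (30.0, 30.0, 100.0)
_LOGSTEP_SD = 0.08  # log-scale RW for brightness/background
_LOGSTEP_BIG_SD = 1.0  # occasional large step (tail exploration)
_LOGSTEP_BIG_PROB = 0.2


# --------------------------------------------------------------------------
# conjugate diffusion conditional


def diffusion_conditional(tracks_active: np.ndarray, config: Config) -> tuple[float, float]:
    """(shape, scale) of D's Inverse-Gamma full conditional given the active
    tracks' increments: each scalar increment is Normal(0, 2*D*dt)."""
    hyper = ParamPriors.from_config(config)
    t = subexposure_times(config.timing, config.model.K).ravel()
    dt = np.diff(t)
    shape, scale = hyper.d_shape, hyper.d_scale
    tracks_active = np.asarray(tracks_active, float)
    if tracks_active.size:
        flat = tracks_active.reshape(tracks_active.shape[0], t.size, 3)
        d2 = np.sum(np.diff(flat, axis=1) ** 2, axis=2)  # (B, L-1)
        shape += flat.shape[0] * dt.size * 3 / 2.0
        scale += float(np.sum(d2 / (4.0 * dt)))
    return shape, scale


def sample_diffusion_conditional(tracks_active: np.ndarray, config: Config, rng) -> float:
    """Draw D from its Inverse-Gamma full conditional (see
    :func:`diffusion_conditional`)."""
    shape, scale = diffusion_conditional(tracks_active, config)
    return scale / rng.gamma(shape)


# --------------------------------------------------------------------------
# initialization


def init_state(data: ImageStack, config: Config, seed: int) -> SystemState:
    """Deterministic initial state: no active emitters (they are recruited
    during burn-in); background from the frame-wise lower-quartile pixel
    intensity inverted through the camera model; brightness from the peak
    excess intensity (or the configured fixed value); D at a quarter of
    its prior mean; candidate tracks drawn from the motion prior."""
    if data.values.size == 0:
        raise ValueError("empty image stack")
    rng = np.random.default_rng(seed)
    cam, m = data.camera, config.model
    exp = data.timing.exposures
    q25 = np.quantile(data.values.reshape(data.n_frames, -1), 0.25, axis=1)
    F = np.maximum((q25 - cam.offset) / cam.gain, 0.0) / (cam.pixel_area * exp)
    F = np.maximum(F, 1e-4 * m.f_prior_mean)
    if m.constant_background:
        F[:] = F.mean()
    if m.fixed_brightness is not None:
        h = np.full(data.n_frames, m.fixed_brightness)
    else:
        peak = float(data.values.max() - np.median(q25)) / cam.gain
        h = np.full(data.n_frames, max(peak / (0.3 * float(exp.mean())), 1.0))
    # start at a conservative (small) diffusion: early track proposals stay
    # smooth, so residual-guided recruitment sees sharp structure; D is
    # Gibbs-resampled every sweep, so the init only shapes early burn-in
    D = m.d_prior_mean / 4.0
    motion = MotionPrior(D, config.init_bounds)
    tracks = np.stack([sample_track(motion, data.timing, m.K, rng) for _ in range(m.M)])
    return SystemState(np.zeros(m.M, np.int8), tracks, D, h, F)


# --------------------------------------------------------------------------
# the sampler core


class _Sampler:
    """Mutable sampling state with per-emitter image caches.

    ``tracks`` are stored flat, (M, L, 3) with L = N*K sub-exposure times;
    ``g[m, n]`` caches the expected-photon image of emitter m in frame n
    (valid while m is active).  Expected images are always reassembled as
    background + sum of cached emitter images, so caches never drift.
    """

    def __init__(self, data: ImageStack, config: Config, state: SystemState, rng: np.random.Generator):
        self.data = data
        self.config = config
        self.rng = rng
        self.cam = data.camera
        self.optics = config.optics
        self.timing = data.timing
        self.K = config.model.K
        self.N = data.n_frames
        self.prior_only = config.run.prior_only
        self.t = subexposure_times(self.timing, self.K).ravel()
        self.L = self.t.size
        self.dts = np.diff(self.t)
        self.exposures = self.timing.exposures
        self.bounds = config.init_bounds
        self.lat_area = float(np.prod(self.bounds[:2, 1] - self.bounds[:2, 0]))
        self.hyper = ParamPriors.from_config(config)
        self.loads_prior = LoadsPrior(config.model.M, config.model.gamma)
        self.motion_log_init = float(-np.sum(np.log(self.bounds[:, 1] - self.bounds[:, 0])))
        self.w = data.values

        self.loads = state.loads.copy()
        self.tracks = state.tracks.reshape(state.M, self.L, 3).copy()
        self.D = float(state.diffusion)
        self.h = state.brightness.copy()
        self.F = state.background.copy()
        # precomputed constants for the likelihood hot path
        self.w_shifted = self.w - self.cam.offset
        self.read_variance = self.cam.read_variance
        self.noise_gain2 = self.cam.excess_noise * self.cam.gain**2
        # precomputed pixel-edge coordinates for the separable PSF integrals
        s = self.cam.pixel_size
        self._col_edges = s * np.arange(self.cam.n_cols + 1)
        self._row_edges = s * np.arange(self.cam.n_rows + 1)
        self._all_frames = np.arange(self.N)
        self.g = np.zeros((state.M, self.N, self.cam.n_rows, self.cam.n_cols))
        for m in np.flatnonzero(self.loads):
            self.g[m] = self._render_track(self.tracks[m])
        self._refresh_caches()
        self.accepted: dict[str, list[int]] = {}
        # inverse-temperature on the likelihood; run_chain anneals this from
        # a small value up to 1 during early burn-in so spurious structures
        # melt before the chain commits (retained samples are always beta=1)
        self.beta = 1.0

    # -- caches and likelihood -------------------------------------------

    def _render_track(self, track_flat: np.ndarray) -> np.ndarray:
        """Expected-photon images of one emitter for all frames, (N, R, C),
        batched over the N*K sub-exposure positions."""
        return self._render_frames(self._all_frames, track_flat.reshape(self.L, 3))

    def _render(self, n: int, track_slice: np.ndarray) -> np.ndarray:
        """Expected-photon image of K sub-positions in frame n."""
        if self.prior_only:
            return np.zeros((self.cam.n_rows, self.cam.n_cols))
        sig = psf_lateral_width(track_slice[:, 2], self.optics)[:, None]
        nc = self.cam.n_cols + 1
        shifted = np.empty((track_slice.shape[0], nc + self.cam.n_rows + 1))
        shifted[:, :nc] = self._col_edges[None, :] - track_slice[:, 0:1]
        shifted[:, nc:] = self._row_edges[None, :] - track_slice[:, 1:2]
        c = ndtr(shifted / sig)
        img = np.einsum("kr,kc->rc", c[:, nc + 1 :] - c[:, nc:-1], c[:, 1:nc] - c[:, : nc - 1])
        img *= self.h[n] * self.exposures[n] / self.K
        return img

    def _bg(self) -> np.ndarray:
        return self.F * self.cam.pixel_area * self.exposures

    def _refresh_caches(self) -> None:
        """Reassemble the total expected image and per-frame log-likelihood
        from the per-emitter caches (also clears fp drift once per sweep)."""
        self.u = np.empty((self.N, self.cam.n_rows, self.cam.n_cols))
        self.u[:] = self._bg()[:, None, None]
        for m in np.flatnonzero(self.loads):
            self.u += self.g[m]
        self.ll = np.array([self._frame_ll(self.u[n], n) for n in range(self.N)])

    def _frame_ll(self, u_n: np.ndarray, n: int) -> float:
        if self.prior_only:
            return 0.0
        # inlined Normal log-density with precomputed offset-corrected data
        var = self.read_variance + self.noise_gain2 * u_n
        resid = self.w_shifted[n] - self.cam.gain * u_n
        return float(-0.5 * (np.sum(np.log(var) + resid * resid / var) + u_n.size * _LOG2PI_LOCAL))

    def _stack_ll(self, u: np.ndarray) -> float:
        if self.prior_only:
            return 0.0
        return frame_log_likelihood(self.w, u, self.cam)

    def _tally(self, name: str, accepted: bool) -> None:
        acc = self.accepted.setdefault(name, [0, 0])
        acc[1] += 1
        acc[0] += int(accepted)

    def _in_bounds(self, pos: np.ndarray) -> bool:
        return bool(np.all(pos >= self.bounds[:, 0]) and np.all(pos <= self.bounds[:, 1]))

    # -- track moves ------------------------------------------------------

    def _propose_bridge(self, m: int, i0: int, i1: int) -> np.ndarray | None:
        """Propose sub-positions [i0, i1) from the motion-prior conditional
        given the anchors just outside the window (Brownian bridge); returns
        None when an initial position lands out of bounds (prior zero)."""
        rng, t, D = self.rng, self.t, self.D
        new = np.empty((i1 - i0, 3))
        if i0 == 0 and i1 == self.L:
            x = rng.uniform(self.bounds[:, 0], self.bounds[:, 1])
            new[0] = x
            for j in range(1, self.L):
                x = x + rng.standard_normal(3) * np.sqrt(2.0 * D * (t[j] - t[j - 1]))
                new[j] = x
            return new
        if i0 == 0:
            x = self.tracks[m, i1].copy()
            for j in range(i1 - 1, -1, -1):
                x = x + rng.standard_normal(3) * np.sqrt(2.0 * D * (t[j + 1] - t[j]))
                new[j] = x
            return new if self._in_bounds(new[0]) else None
        if i1 == self.L:
            x = self.tracks[m, i0 - 1].copy()
            for j in range(i0, self.L):
                x = x + rng.standard_normal(3) * np.sqrt(2.0 * D * (t[j] - t[j - 1]))
                new[j - i0] = x
            return new
        x, tx = self.tracks[m, i0 - 1].copy(), t[i0 - 1]
        b, tb = self.tracks[m, i1], t[i1]
        for j in range(i0, i1):
            tj = t[j]
            frac = (tj - tx) / (tb - tx)
            mean = x + (b - x) * frac
            var = 2.0 * D * (tj - tx) * (tb - tj) / (tb - tx)
            x = mean + rng.standard_normal(3) * np.sqrt(var)
            tx = tj
            new[j - i0] = x
        return new

    def _per_frame_ll(self, u: np.ndarray) -> np.ndarray:
        if self.prior_only:
            return np.zeros(self.N)
        var = self.cam.read_variance + self.cam.excess_noise * self.cam.gain**2 * u
        resid = self.w - self.cam.offset - self.cam.gain * u
        per_pixel = np.log(var) + resid * resid / var
        return -0.5 * per_pixel.sum(axis=(1, 2)) - 0.5 * (u.shape[1] * u.shape[2]) * np.log(2.0 * np.pi)

    def _apply_track(self, m: int, frames: range, new_flat: np.ndarray, new_imgs) -> None:
        self.tracks[m, frames.start * self.K : frames.stop * self.K] = new_flat
        for j, n in enumerate(frames):
            img = new_imgs[j]
            self.u[n] += img - self.g[m, n]
            self.g[m, n] = img
            self.ll[n] = self._frame_ll(self.u[n], n)

    def _bridge_move(self, m: int, n0: int, n1: int) -> None:
        i0, i1 = n0 * self.K, n1 * self.K
        new = self._propose_bridge(m, i0, i1)
        if new is None:
            self._tally("bridge", False)
            return
        frames = range(n0, n1)
        new_imgs = [self._render(n, new[(n - n0) * self.K : (n - n0 + 1) * self.K]) for n in frames]
        delta = self.beta * sum(
            self._frame_ll(self.u[n] - self.g[m, n] + img, n) - self.ll[n] for n, img in zip(frames, new_imgs)
        )
        ok = delta >= 0 or np.log(self.rng.random()) < delta
        if ok:
            self._apply_track(m, frames, new, new_imgs)
        self._tally("bridge", ok)

    def _step_cost(self, d: np.ndarray, dt: float) -> float:
        """Quadratic exponent of one 3-D increment (constants cancel in
        symmetric moves): ||d||^2 / (4*D*dt)."""
        return (d[0] * d[0] + d[1] * d[1] + d[2] * d[2]) / (4.0 * self.D * dt)

    def _render_frames(self, frames: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Batched per-frame images: ``pos`` is (len(frames)*K, 3)."""
        nf = frames.size
        if self.prior_only:  # images never touch the target; skip the work
            return np.zeros((nf, self.cam.n_rows, self.cam.n_cols))
        z = pos[:, 2]
        sig = (self.optics.in_focus_width * np.sqrt(1.0 + (z / self.optics.axial_scale) ** 2))[:, None]
        nc = self.cam.n_cols + 1
        shifted = np.empty((pos.shape[0], nc + self.cam.n_rows + 1))
        shifted[:, :nc] = self._col_edges[None, :] - pos[:, 0:1]
        shifted[:, nc:] = self._row_edges[None, :] - pos[:, 1:2]
        c = ndtr(shifted / sig)
        iy = (c[:, nc + 1 :] - c[:, nc:-1]).reshape(nf, self.K, -1)
        ix = (c[:, 1:nc] - c[:, : nc - 1]).reshape(nf, self.K, -1)
        imgs = np.einsum("nkr,nkc->nrc", iy, ix)
        imgs *= (self.h[frames] * self.exposures[frames] / self.K)[:, None, None]
        return imgs

    def _ll_frames(self, u_sub: np.ndarray, frames: np.ndarray) -> np.ndarray:
        if self.prior_only:
            return np.zeros(frames.size)
        var = self.read_variance + self.noise_gain2 * u_sub
        resid = self.w_shifted[frames] - self.cam.gain * u_sub
        per = np.log(var) + resid * resid / var
        return -0.5 * (per.sum(axis=(1, 2)) + u_sub.shape[1] * u_sub.shape[2] * _LOG2PI_LOCAL)

    def _accept_frames(self, m: int, frames: np.ndarray, ok: np.ndarray, pos: np.ndarray, imgs, u_new, ll_new):
        K = self.K
        for idx in np.flatnonzero(ok):
            n = frames[idx]
            self.tracks[m, n * K : (n + 1) * K] = pos[idx * K : (idx + 1) * K]
            self.g[m, n] = imgs[idx]
            self.u[n] = u_new[idx]
            self.ll[n] = ll_new[idx]

    def _bridge_pass(self, m: int) -> None:
        """Single-frame bridge moves over a red/black frame checkerboard:
        within one parity class the windows share no anchor positions, so
        proposals are independent and render/likelihood batch across
        frames."""
        for parity in (0, 1):
            frames = np.arange(parity, self.N, 2)
            if frames.size == 0:
                continue
            pos = np.empty((frames.size * self.K, 3))
            valid = np.ones(frames.size, bool)
            for idx, n in enumerate(frames):
                prop = self._propose_bridge(m, n * self.K, (n + 1) * self.K)
                if prop is None:
                    valid[idx] = False
                    prop = self.tracks[m, n * self.K : (n + 1) * self.K]
                pos[idx * self.K : (idx + 1) * self.K] = prop
            imgs = self._render_frames(frames, pos)
            u_new = self.u[frames] - self.g[m, frames] + imgs
            ll_new = self._ll_frames(u_new, frames)
            delta = self.beta * (ll_new - self.ll[frames])
            ok = valid & ((delta >= 0) | (np.log(self.rng.random(frames.size)) < delta))
            self._accept_frames(m, frames, ok, pos, imgs, u_new, ll_new)
            acc = self.accepted.setdefault("bridge", [0, 0])
            acc[1] += frames.size
            acc[0] += int(ok.sum())

    def _jitter_pass(self, m: int) -> None:
        """Whole-frame jitter over the same checkerboard; the motion-prior
        delta involves only the steps into the two neighboring frames,
        which belong to the other parity class and stay fixed."""
        K = self.K
        for parity in (0, 1):
            frames = np.arange(parity, self.N, 2)
            if frames.size == 0:
                continue
            deltas = self.rng.standard_normal((frames.size, 3)) * _JITTER_SD
            pos = np.empty((frames.size * K, 3))
            dprior = np.zeros(frames.size)
            valid = np.ones(frames.size, bool)
            for idx, n in enumerate(frames):
                i0, i1 = n * K, (n + 1) * K
                block = self.tracks[m, i0:i1] + deltas[idx]
                pos[idx * K : (idx + 1) * K] = block
                if n == 0 and not self._in_bounds(block[0]):
                    valid[idx] = False
                    continue
                if i0 > 0:
                    d_old = self.tracks[m, i0] - self.tracks[m, i0 - 1]
                    dprior[idx] += self._step_cost(d_old, self.dts[i0 - 1]) - self._step_cost(
                        d_old + deltas[idx], self.dts[i0 - 1]
                    )
                if i1 < self.L:
                    d_old = self.tracks[m, i1] - self.tracks[m, i1 - 1]
                    dprior[idx] += self._step_cost(d_old, self.dts[i1 - 1]) - self._step_cost(
                        d_old - deltas[idx], self.dts[i1 - 1]
                    )
            imgs = self._render_frames(frames, pos)
            u_new = self.u[frames] - self.g[m, frames] + imgs
            ll_new = self._ll_frames(u_new, frames)
            logr = self.beta * (ll_new - self.ll[frames]) + dprior
            ok = valid & ((logr >= 0) | (np.log(self.rng.random(frames.size)) < logr))
            self._accept_frames(m, frames, ok, pos, imgs, u_new, ll_new)
            acc = self.accepted.setdefault("jitter", [0, 0])
            acc[1] += frames.size
            acc[0] += int(ok.sum())

    def _set_track(self, m: int, new_flat: np.ndarray, new_g: np.ndarray, u_new: np.ndarray) -> None:
        self.tracks[m] = new_flat
        self.g[m] = new_g
        self.u = u_new
        self.ll = self._per_frame_ll(u_new)

    def _translate_move(self, m: int) -> None:
        delta = self.rng.standard_normal(3) * _TRANSLATE_SD
        new = self.tracks[m] + delta
        if not self._in_bounds(new[0]):
            self._tally("translate", False)
            return
        new_g = self._render_track(new)
        u_new = self.u - self.g[m] + new_g
        delta_ll = self.beta * (self._stack_ll(u_new) - float(self.ll.sum()))
        ok = delta_ll >= 0 or np.log(self.rng.random()) < delta_ll
        if ok:
            self._set_track(m, new, new_g, u_new)
        self._tally("translate", ok)

    # -- load flips -------------------------------------------------------

    def _residual_weights(self, exclude: int | None = None) -> np.ndarray | None:
        if self.prior_only:
            return None
        u = self.u if exclude is None else self.u - self.g[exclude]
        r = np.clip(self.w - self.cam.offset - self.cam.gain * u, 0.0, None).sum(axis=0)
        s = r.sum()
        return r / s if s > 0 else None

    def _start_proposal_logpdf(self, pos: np.ndarray, weights: np.ndarray | None) -> float:
        """Lateral log-density of the birth start proposal: a 50/50 mixture
        of uniform-over-box and residual-weighted pixels (z is uniform and
        cancels against the prior)."""
        p_unif = 1.0 / self.lat_area
        if weights is None:
            return float(np.log(p_unif))
        s = self.cam.pixel_size
        c, r = int(np.floor(pos[0] / s)), int(np.floor(pos[1] / s))
        dens = 0.5 * p_unif
        if 0 <= r < self.cam.n_rows and 0 <= c < self.cam.n_cols:
            dens += 0.5 * weights[r, c] / self.cam.pixel_area
        return float(np.log(dens))

    def _sample_start(self, weights: np.ndarray | None) -> np.ndarray:
        z = self.rng.uniform(self.bounds[2, 0], self.bounds[2, 1])
        if weights is None or self.rng.random() < 0.5:
            x = self.rng.uniform(self.bounds[0, 0], self.bounds[0, 1])
            y = self.rng.uniform(self.bounds[1, 0], self.bounds[1, 1])
        else:
            flat = self.rng.choice(weights.size, p=weights.ravel())
            r, c = divmod(int(flat), self.cam.n_cols)
            s = self.cam.pixel_size
            x = (c + self.rng.random()) * s
            y = (r + self.rng.random()) * s
        return np.array([x, y, z])

    def _prior_track(self, start: np.ndarray | None = None) -> np.ndarray:
        # fast in-sampler equivalent of priors.sample_track
        if start is None:
            start = self.rng.uniform(self.bounds[:, 0], self.bounds[:, 1])
        flat = np.empty((self.L, 3))
        flat[0] = start
        sd = np.sqrt(2.0 * self.D * self.dts)
        flat[1:] = start + np.cumsum(self.rng.standard_normal((self.L - 1, 3)) * sd[:, None], axis=0)
        return flat

    def _log_prior_odds(self) -> float:
        q = self.loads_prior.p_active
        return float(np.log(q) - np.log1p(-q))

    def _flux_compensation(self, g: np.ndarray) -> np.ndarray:
        """Background-flux decrement absorbing emitter images ``g`` into the
        uniform background: per frame it conserves the frame's expected
        photon count; in constant-background mode a single scalar conserves
        the total (keeping the frames tied)."""
        denom = self.cam.n_pixels * self.cam.pixel_area * self.exposures
        if self.config.model.constant_background:
            return np.full(self.N, g.sum() / denom.sum())
        return g.sum(axis=(1, 2)) / denom

    def _f_prior_delta(self, f_new: np.ndarray, f_old: np.ndarray) -> float:
        if np.any(f_new <= 0):
            return -np.inf
        hy = self.hyper
        return float(
            np.sum((hy.f_shape - 1.0) * (np.log(f_new) - np.log(f_old)) - (f_new - f_old) / hy.f_scale)
        )

    def _birth_move(self, m: int) -> None:
        """Flip b_m on with a fresh prior track (start drawn from the
        residual-informed proposal) while lowering the background flux to
        conserve expected photons — a deterministic, unit-Jacobian shear
        pairing with the matching death move.  The compensation lets the
        chain exchange diffuse out-of-focus emitters with background, the
        direction in which the two are nearly unidentifiable."""
        weights = self._residual_weights()
        start = self._sample_start(weights)
        track = self._prior_track(start=start)
        new_g = self._render_track(track)
        df = self._flux_compensation(new_g) if not self.prior_only else 0.0
        f_new = self.F - df
        dprior_f = self._f_prior_delta(f_new, self.F) if not self.prior_only else 0.0
        if not np.isfinite(dprior_f):
            self._tally("birth", False)
            return
        u_new = self.u + new_g - (df * self.cam.pixel_area * self.exposures)[:, None, None] if not self.prior_only else self.u
        delta_ll = self.beta * (self._stack_ll(u_new) - float(self.ll.sum()))
        # Hastings factor: log p_unif(start) - log q(start) = -log(area) - log q
        logr = (
            delta_ll
            + dprior_f
            + self._log_prior_odds()
            - self._start_proposal_logpdf(start, weights)
            - np.log(self.lat_area)
        )
        ok = logr >= 0 or np.log(self.rng.random()) < logr
        if ok:
            self.loads[m] = 1
            if not self.prior_only:
                self.F = f_new
            self._set_track(m, track, new_g, u_new)
        self._tally("birth", ok)

    def _death_move(self, m: int) -> None:
        weights = self._residual_weights(exclude=m)
        start = self.tracks[m, 0]
        df = self._flux_compensation(self.g[m]) if not self.prior_only else 0.0
        f_new = self.F + df
        dprior_f = self._f_prior_delta(f_new, self.F) if not self.prior_only else 0.0
        u_new = self.u - self.g[m] + (df * self.cam.pixel_area * self.exposures)[:, None, None] if not self.prior_only else self.u
        delta_ll = self.beta * (self._stack_ll(u_new) - float(self.ll.sum()))
        logr = (
            delta_ll
            + dprior_f
            - self._log_prior_odds()
            + self._start_proposal_logpdf(start, weights)
            + np.log(self.lat_area)
        )
        ok = logr >= 0 or np.log(self.rng.random()) < logr
        if ok:
            self.loads[m] = 0
            if not self.prior_only:
                self.F = f_new
            self._set_track(m, self._prior_track(), np.zeros_like(self.g[m]), u_new)
        self._tally("death", ok)

    def _relocate_move(self, m: int) -> None:
        """Independence proposal replacing an active emitter's entire track
        with a fresh motion-prior draw started from the residual-informed
        proposal (residual computed without emitter m, so the forward and
        reverse proposal densities share one residual image).  Lets tracks
        escape poor modes that local jitter cannot leave."""
        weights = self._residual_weights(exclude=m)
        start = self._sample_start(weights)
        track = self._prior_track(start=start)
        new_g = self._render_track(track)
        u_new = self.u - self.g[m] + new_g
        delta_ll = self.beta * (self._stack_ll(u_new) - float(self.ll.sum()))
        logr = (
            delta_ll
            + self._start_proposal_logpdf(self.tracks[m, 0], weights)
            - self._start_proposal_logpdf(start, weights)
        )
        ok = logr >= 0 or np.log(self.rng.random()) < logr
        if ok:
            self._set_track(m, track, new_g, u_new)
        self._tally("relocate", ok)

    # -- split / merge ----------------------------------------------------
    #
    # Crowded data admit metastable states where k+1 model emitters
    # interleave k true ones; plain flips cannot escape because a lone
    # death leaves a localized photon deficit.  The reversible pair below
    # exchanges (two active tracks) <-> (their midpoint track), with the
    # separation path drawn from a Brownian difference density and the
    # background compensating the net flux, so the move is dimension- and
    # photon-preserving.

    _SPLIT_START_SD = (250.0, 250.0, 400.0)  # nm, split separation at t0

    def _delta_logpdf(self, delta: np.ndarray) -> float:
        """Log-density of a separation path: Normal start (per-coordinate
        scales above), increments Normal(0, 4*D*dt) — the difference of two
        independent motion-prior tracks given D."""
        sd0 = np.asarray(self._SPLIT_START_SD)
        out = float(np.sum(-0.5 * np.log(2.0 * np.pi * sd0**2) - 0.5 * (delta[0] / sd0) ** 2))
        var = 4.0 * self.D * self.dts
        d2 = np.sum(np.diff(delta, axis=0) ** 2, axis=1)
        out += float(np.sum(-1.5 * np.log(2.0 * np.pi * var) - d2 / (2.0 * var)))
        return out

    def _sample_delta(self) -> np.ndarray:
        delta = np.empty((self.L, 3))
        delta[0] = self.rng.standard_normal(3) * self._SPLIT_START_SD
        steps = self.rng.standard_normal((self.L - 1, 3)) * np.sqrt(4.0 * self.D * self.dts)[:, None]
        delta[1:] = delta[0] + np.cumsum(steps, axis=0)
        return delta

    def _motion_logpdf(self, track: np.ndarray) -> float:
        if not self._in_bounds(track[0]):
            return -np.inf
        var = 2.0 * self.D * self.dts
        d2 = np.sum(np.diff(track, axis=0) ** 2, axis=1)
        return self.motion_log_init + float(np.sum(-1.5 * np.log(2.0 * np.pi * var) - d2 / (2.0 * var)))

    def _apply_pair_change(self, f_new: np.ndarray, u_new: np.ndarray) -> None:
        self.F = f_new
        self.u = u_new
        self.ll = self._per_frame_ll(u_new)

    def _merge_move(self) -> None:
        active = np.flatnonzero(self.loads)
        A = active.size
        if A < 2:
            return
        i, j = self.rng.choice(active, size=2, replace=False)
        tau_i, tau_j = self.tracks[i], self.tracks[j]
        merged = 0.5 * (tau_i + tau_j)
        delta = tau_j - tau_i
        new_g = self._render_track(merged)
        dg = new_g - self.g[i] - self.g[j]
        df = self._flux_compensation(dg)  # negative: background rises
        f_new = self.F - df
        dprior_f = self._f_prior_delta(f_new, self.F)
        if not np.isfinite(dprior_f):
            self._tally("merge", False)
            return
        u_new = self.u + dg - (df * self.cam.pixel_area * self.exposures)[:, None, None]
        delta_ll = self.beta * (self._stack_ll(u_new) - float(self.ll.sum()))
        dmotion = self._motion_logpdf(merged) - self._motion_logpdf(tau_i) - self._motion_logpdf(tau_j)
        logr = (
            delta_ll
            + dprior_f
            + dmotion
            - self._log_prior_odds()
            + self._delta_logpdf(delta)
            + np.log(A / (self.config.model.M - A + 1.0))
        )
        ok = np.isfinite(logr) and (logr >= 0 or np.log(self.rng.random()) < logr)
        if ok:
            self.loads[j] = 0
            self.tracks[i] = merged
            self.tracks[j] = self._prior_track()
            self.g[i] = new_g
            self.g[j] = 0.0
            self._apply_pair_change(f_new, u_new)
        self._tally("merge", ok)

    def _split_move(self) -> None:
        active = np.flatnonzero(self.loads)
        inactive = np.flatnonzero(self.loads == 0)
        A = active.size
        if A < 1 or inactive.size < 1:
            return
        i = int(self.rng.choice(active))
        j = int(self.rng.choice(inactive))
        delta = self._sample_delta()
        tau_i = self.tracks[i] - 0.5 * delta
        tau_j = self.tracks[i] + 0.5 * delta
        dmotion = self._motion_logpdf(tau_i) + self._motion_logpdf(tau_j) - self._motion_logpdf(self.tracks[i])
        if not np.isfinite(dmotion):
            self._tally("split", False)
            return
        g_i, g_j = self._render_track(tau_i), self._render_track(tau_j)
        dg = g_i + g_j - self.g[i]
        df = self._flux_compensation(dg)
        f_new = self.F - df
        dprior_f = self._f_prior_delta(f_new, self.F)
        if not np.isfinite(dprior_f):
            self._tally("split", False)
            return
        u_new = self.u + dg - (df * self.cam.pixel_area * self.exposures)[:, None, None]
        delta_ll = self.beta * (self._stack_ll(u_new) - float(self.ll.sum()))
        logr = (
            delta_ll
            + dprior_f
            + dmotion
            + self._log_prior_odds()
            - self._delta_logpdf(delta)
            - np.log((A + 1.0) / (self.config.model.M - A))
        )
        ok = np.isfinite(logr) and (logr >= 0 or np.log(self.rng.random()) < logr)
        if ok:
            self.loads[j] = 1
            self.tracks[i] = tau_i
            self.tracks[j] = tau_j
            self.g[i] = g_i
            self.g[j] = g_j
            self._apply_pair_change(f_new, u_new)
        self._tally("split", ok)

    # -- parameter moves --------------------------------------------------

    def _scale_move(self) -> None:
        """Joint rescale of every track's shape about its start point by a
        factor c together with D' = c^2 D.  Brownian scaling leaves the
        standardized increments unchanged, so the motion-prior ratio cancels
        the position Jacobian exactly and the acceptance reduces to the
        likelihood ratio times the D-prior ratio times c^2.  This moves D in
        ~10% steps along the D/track-roughness ridge, which otherwise mixes
        only by slow diffusion."""
        c = float(np.exp(self.rng.standard_normal() * 0.06))
        d_new = c * c * self.D
        starts = self.tracks[:, :1, :]
        tracks_new = starts + c * (self.tracks - starts)
        active = np.flatnonzero(self.loads)
        new_g = {m: self._render_track(tracks_new[m]) for m in active}
        u_new = self.u.copy()
        for m in active:
            u_new += new_g[m] - self.g[m]
        delta_ll = self.beta * (self._stack_ll(u_new) - float(self.ll.sum()))
        hy = self.hyper
        d_prior = (-hy.d_shape - 1.0) * np.log(d_new / self.D) - hy.d_scale * (1.0 / d_new - 1.0 / self.D)
        logr = delta_ll + d_prior + 2.0 * np.log(c)
        ok = logr >= 0 or np.log(self.rng.random()) < logr
        if ok:
            self.D = d_new
            self.tracks = tracks_new
            for m in active:
                self.g[m] = new_g[m]
            self.u = u_new
            self.ll = self._per_frame_ll(u_new)
        self._tally("scale", ok)

    def _update_diffusion(self) -> None:
        """Joint Gibbs draw of (D, inactive tracks): D from its conditional
        given the active increments, inactive tracks refreshed from the
        motion prior at the new D (the inactive prior factors cancel, so
        the block is accepted with probability one)."""
        active = np.flatnonzero(self.loads)
        self.D = sample_diffusion_conditional(self.tracks[active], self.config, self.rng)
        for m in np.flatnonzero(self.loads == 0):
            self.tracks[m] = self._prior_track()
        self._tally("diffusion", True)

    def _log_step(self) -> float:
        """Log-scale RW step size: a symmetric two-component mixture, so
        small steps refine while occasional large ones cross the prior's
        tails (the proposal stays symmetric in log space)."""
        return _LOGSTEP_BIG_SD if self.rng.random() < _LOGSTEP_BIG_PROB else _LOGSTEP_SD

    def _gamma_logpdf(self, x: float, shape: float, scale: float) -> float:
        return (shape - 1.0) * np.log(x) - x / scale - gammaln(shape) - shape * np.log(scale)

    def _update_background(self) -> None:
        groups = [list(range(self.N))] if self.config.model.constant_background else [[n] for n in range(self.N)]
        area = self.cam.pixel_area
        for frames in groups:
            f_old = float(self.F[frames[0]])
            f_new = f_old * np.exp(self.rng.standard_normal() * self._log_step())
            # constant-background mode ties the frames together; its
            # effective prior is the product of the per-frame Gamma factors
            dprior = len(frames) * (
                self._gamma_logpdf(f_new, self.hyper.f_shape, self.hyper.f_scale)
                - self._gamma_logpdf(f_old, self.hyper.f_shape, self.hyper.f_scale)
            )
            new_ll = []
            u_new = {}
            for n in frames:
                u_new[n] = self.u[n] + (f_new - f_old) * area * self.exposures[n]
                new_ll.append(self._frame_ll(u_new[n], n))
            # log-scale RW needs the Jacobian factor f_new/f_old
            logr = self.beta * (sum(new_ll) - sum(self.ll[n] for n in frames)) + dprior + np.log(f_new / f_old)
            ok = logr >= 0 or np.log(self.rng.random()) < logr
            if ok:
                self.F[frames] = f_new
                for n, v in zip(frames, new_ll):
                    self.u[n] = u_new[n]
                    self.ll[n] = v
            self._tally("background", ok)

    def _update_brightness(self) -> None:
        active = np.flatnonzero(self.loads)
        for n in range(self.N):
            h_old = self.h[n]
            h_new = h_old * np.exp(self.rng.standard_normal() * self._log_step())
            scale = h_new / h_old
            bg_n = self.F[n] * self.cam.pixel_area * self.exposures[n]
            u_n = bg_n + scale * (self.u[n] - bg_n)
            new_ll = self._frame_ll(u_n, n)
            dprior = self._gamma_logpdf(h_new, self.hyper.h_shape, self.hyper.h_scale) - self._gamma_logpdf(
                h_old, self.hyper.h_shape, self.hyper.h_scale
            )
            logr = self.beta * (new_ll - self.ll[n]) + dprior + np.log(scale)
            ok = logr >= 0 or np.log(self.rng.random()) < logr
            if ok:
                self.h[n] = h_new
                for m in active:
                    self.g[m, n] *= scale
                self.u[n] = u_n
                self.ll[n] = new_ll
            self._tally("brightness", ok)

    # -- one sweep --------------------------------------------------------

    def sweep(self, index: int) -> None:
        # bridge and jitter passes alternate by sweep parity: bridges
        # redraw from the motion-prior conditional (global shape), jitters
        # refine locally; alternating halves the per-sweep cost
        win = _WINDOW_SCHEDULE[(index // 2) % len(_WINDOW_SCHEDULE)]
        for m in list(np.flatnonzero(self.loads)):
            if index % 2 == 0:
                if win == 1:
                    self._bridge_pass(m)
                else:
                    phase = int(self.rng.integers(win))
                    n0 = -phase
                    while n0 < self.N:
                        a, b = max(n0, 0), min(n0 + win, self.N)
                        if b > a:
                            self._bridge_move(m, a, b)
                        n0 += win
            else:
                self._jitter_pass(m)
            self._translate_move(m)
        # load flips on a random slot subset (direction-symmetric selection,
        # so each flip kernel keeps detailed balance); full passes add cost
        # without measurably faster recruitment
        M = self.config.model.M
        for m in self.rng.choice(M, size=min(M, 4), replace=False):
            if self.loads[m] == 0:
                self._birth_move(int(m))
            else:
                self._death_move(int(m))
        if not self.prior_only:
            active = np.flatnonzero(self.loads)
            if active.size:
                self._relocate_move(int(self.rng.choice(active)))
            for _ in range(2):
                if self.rng.random() < 0.5:
                    self._merge_move()
                else:
                    self._split_move()
        self._update_diffusion()
        self._scale_move()
        self._scale_move()
        self._update_background()
        if self.config.model.fixed_brightness is None:
            self._update_brightness()
        if index % 16 == 15:
            self._refresh_caches()  # clears incremental fp drift periodically

    # -- bookkeeping ------------------------------------------------------

    def snapshot(self) -> SystemState:
        return SystemState(
            self.loads.copy(),
            self.tracks.reshape(self.config.model.M, self.N, self.K, 3).copy(),
            self.D,
            self.h.copy(),
            self.F.copy(),
        )

    def log_posterior(self) -> float:
        out = loads_log_prior(self.loads, self.loads_prior)
        # motion prior over all M candidate tracks, vectorized
        starts = self.tracks[:, 0]
        if np.any(starts < self.bounds[:, 0]) or np.any(starts > self.bounds[:, 1]):
            return -np.inf
        var = 2.0 * self.D * self.dts
        d2 = np.sum(np.diff(self.tracks, axis=1) ** 2, axis=2)  # (M, L-1)
        out += self.config.model.M * self.motion_log_init
        out += float(np.sum(-1.5 * np.log(2.0 * np.pi * var)[None, :] - d2 / (2.0 * var)[None, :]))
        out += params_log_prior(
            self.D, self.h, self.F, self.hyper, include_brightness=self.config.model.fixed_brightness is None
        )
        if not self.prior_only:
            out += float(np.sum(self.ll))
        return out


def sweep(state: SystemState, data: ImageStack, config: Config, rng: np.random.Generator) -> SystemState:
    """One full MCMC pass over every block of the state; returns the new
    state (functional interface around the cached sampler core)."""
    s = _Sampler(data, config, state, rng)
    s.sweep(0)
    return s.snapshot()


# --------------------------------------------------------------------------
# chains and summaries


@dataclass
class Chain:
    """Ordered posterior samples with bookkeeping.

    ``tracks`` holds all M candidate tracks per retained sample,
    (S, M, N, K, 3); ``log_posterior`` is recomputable from each stored
    sample via :func:`emitrack.priors.state_log_posterior`.
    """

    loads: np.ndarray  # (S, M)
    tracks: np.ndarray  # (S, M, N, K, 3)
    diffusion: np.ndarray  # (S,)
    brightness: np.ndarray  # (S, N)
    background: np.ndarray  # (S, N)
    log_posterior: np.ndarray  # (S,)
    config: Config
    seed: int
    iterations: int
    burn_in: int
    acceptance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.log_posterior.size

    @property
    def active_counts(self) -> np.ndarray:
        """Posterior samples of B = sum of loads."""
        return self.loads.sum(axis=1)

    def state(self, i: int) -> SystemState:
        return SystemState(self.loads[i], self.tracks[i], float(self.diffusion[i]), self.brightness[i], self.background[i])

    def acceptance_rates(self) -> dict[str, float]:
        return {k: (a / t if t else np.nan) for k, (a, t) in self.acceptance.items()}


def run_chain(data: ImageStack, config: Config, start: SystemState | None = None) -> Chain:
    """Run the configured number of sweeps, discard burn-in, return the
    retained chain.  Fully reproducible from ``config.run.seed``; passing
    ``start`` resumes from a previous state (e.g. ``chain.state(-1)``).
    """
    run = config.run
    burn = run.effective_burn_in
    state = init_state(data, config, run.seed) if start is None else start
    anneal_len = 0 if (run.prior_only or start is not None) else (3 * burn) // 5
    beta0 = 0.05

    def beta_at(i: int) -> float:
        if i >= anneal_len or anneal_len == 0:
            return 1.0
        return beta0 ** (1.0 - i / anneal_len)  # geometric ramp beta0 -> 1

    first_sweep = 0
    pilots = 1 if (run.prior_only or start is not None) else max(run.pilots, 1)
    pilot_len = burn // 4
    if pilots > 1 and pilot_len >= 20:
        # independent annealed pilot segments; continue from the best end
        # state by log-posterior
        best = None
        for k in range(pilots):
            pilot = _Sampler(data, config, state, np.random.default_rng([run.seed, k]))
            for i in range(pilot_len):
                pilot.beta = beta_at(i)
                pilot.sweep(i)
            lp = pilot.log_posterior()
            if best is None or lp > best[0]:
                best = (lp, pilot.snapshot())
        state = best[1]
        first_sweep = pilot_len
    rng = np.random.default_rng(run.seed)
    s = _Sampler(data, config, state, rng)
    kept = run.iterations - burn
    if kept == 0:
        warnings.warn("iterations == burn_in: retained chain is empty", stacklevel=2)
    M, N, K = config.model.M, data.n_frames, config.model.K
    loads = np.empty((kept, M), np.int8)
    tracks = np.empty((kept, M, N, K, 3))
    diffusion = np.empty(kept)
    brightness = np.empty((kept, N))
    background = np.empty((kept, N))
    logpost = np.empty(kept)
    for i in range(first_sweep, run.iterations):
        s.beta = beta_at(i)
        s.sweep(i)
        j = i - burn
        if j >= 0:
            loads[j] = s.loads
            tracks[j] = s.tracks.reshape(M, N, K, 3)
            diffusion[j] = s.D
            brightness[j] = s.h
            background[j] = s.F
            logpost[j] = s.log_posterior()
            if not np.isfinite(logpost[j]):
                raise RuntimeError(
                    f"non-finite log-posterior at iteration {i} (B={int(s.loads.sum())}, D={s.D:.3g}); "
                    "check data scaling and prior settings"
                )
    return Chain(
        loads,
        tracks,
        diffusion,
        brightness,
        background,
        logpost,
        config,
        run.seed,
        run.iterations,
        burn,
        {k: tuple(v) for k, v in s.accepted.items()},
    )


@dataclass
class TrackEstimate:
    """MAP summary: the highest-posterior sample among those carrying the
    modal emitter count, with the posterior over counts and percentile CIs.

    ``tracks`` is (B_map, N, K, 3) (active emitters only); ``track_ci`` is
    (B_map, N, 3, 2) per-frame per-coordinate 2.5/97.5 percentile bounds
    (z interval on |z|), or None for short chains.  Percentile intervals
    need not contain the MAP point; lower <= upper always holds.
    """

    tracks: np.ndarray
    diffusion: float
    brightness: np.ndarray
    background: np.ndarray
    log_posterior: float
    count_posterior: dict[int, float]
    sample_index: int
    track_ci: np.ndarray | None = None
    diffusion_ci: tuple[float, float] | None = None

    @property
    def n_emitters(self) -> int:
        return self.tracks.shape[0]

    def trackset(self):
        """Frame-resolution view (per-frame mean of sub-exposure samples)."""
        from .core import TrackSet

        return TrackSet(self.tracks.mean(axis=2))


def map_estimate(chain: Chain) -> TrackEstimate:
    """Two-stage MAP: first the modal emitter count by sample frequency
    (ties toward the smaller count), then the highest-log-posterior sample
    among those carrying it (ties by first occurrence)."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    counts = chain.active_counts
    values, freq = np.unique(counts, return_counts=True)
    b_map = int(values[np.argmax(freq)])
    idx_pool = np.flatnonzero(counts == b_map)
    best = int(idx_pool[np.argmax(chain.log_posterior[idx_pool])])
    active = np.flatnonzero(chain.loads[best])
    post = {int(v): float(f) / counts.size for v, f in zip(values, freq)}
    est = TrackEstimate(
        tracks=chain.tracks[best][active].copy(),
        diffusion=float(chain.diffusion[best]),
        brightness=chain.brightness[best].copy(),
        background=chain.background[best].copy(),
        log_posterior=float(chain.log_posterior[best]),
        count_posterior=post,
        sample_index=best,
    )
    if len(chain) >= 40:
        est.track_ci = track_credible_intervals(chain, est)
        lo, hi = np.percentile(chain.diffusion, [2.5, 97.5])
        est.diffusion_ci = (float(lo), float(hi))
    return est


def credible_intervals(chain: Chain, quantity: str) -> np.ndarray:
    """2.5th-97.5th percentile intervals for 'diffusion' (shape (2,)),
    'brightness' or 'background' (shape (N, 2)); track intervals via
    :func:`track_credible_intervals`.  Requires >= 40 retained samples."""
    if len(chain) < 40:
        raise ValueError(f"need >= 40 retained samples for percentile intervals, got {len(chain)}")
    arr = {"diffusion": chain.diffusion, "brightness": chain.brightness, "background": chain.background}.get(quantity)
    if arr is None:
        raise KeyError(f"unknown quantity {quantity!r}")
    return np.percentile(arr, [2.5, 97.5], axis=0).T if arr.ndim == 2 else np.percentile(arr, [2.5, 97.5])


def track_credible_intervals(chain: Chain, estimate: TrackEstimate) -> np.ndarray:
    """Per-frame per-coordinate 95% CIs around the MAP tracks.

    Sample-to-sample emitter labels are arbitrary, so each sample's active
    positions are matched to the MAP tracks frame by frame with a gateless
    nearest-position assignment; percentiles are taken over the matched
    positions (|z| for the axial coordinate).  Returns (B, N, 3, 2).
    """
    if len(chain) < 40:
        raise ValueError("need >= 40 retained samples")
    B = estimate.n_emitters
    N = chain.tracks.shape[2]
    map_pos = estimate.tracks.mean(axis=2)  # (B, N, 3)
    matched: list[list[list[np.ndarray]]] = [[[] for _ in range(N)] for _ in range(B)]
    for i in range(len(chain)):
        active = np.flatnonzero(chain.loads[i])
        if active.size == 0 or B == 0:
            continue
        pos = chain.tracks[i][active].mean(axis=2)  # (A, N, 3)
        for n in range(N):
            d = np.linalg.norm(map_pos[:, n, :2][:, None, :] - pos[:, n, :2][None, :, :], axis=-1)
            rows, cols = linear_sum_assignment(d)
            for r, c in zip(rows, cols):
                matched[r][n].append(pos[c, n])
    ci = np.full((B, N, 3, 2), np.nan)
    for b in range(B):
        for n in range(N):
            if len(matched[b][n]) < 2:
                continue
            arr = np.array(matched[b][n])
            arr[:, 2] = np.abs(arr[:, 2])
            ci[b, n, :, 0] = np.percentile(arr, 2.5, axis=0)
            ci[b, n, :, 1] = np.percentile(arr, 97.5, axis=0)
    return ci
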