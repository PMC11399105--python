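"""Prior components of the joint posterior.

Emitter number is handled nonparametrically through a truncated
Beta-Bernoulli construction: each of M candidate emitters carries a load
``b_m ~ Bernoulli(gamma/M)``, so the active count is Binomial(M, gamma/M)
a priori, converging to Poisson(gamma) as M grows — the truncation becomes
immaterial once the posterior count sits well below M.

Tracks follow a Gaussian-increment (Brownian) motion prior at sub-exposure
resolution: each coordinate steps by Normal(0, 2*D*dt) between consecutive
sub-exposure times, with a uniform initial position over the field of view
expanded by a margin (emitters may sit outside the imaged region) and
|z| <= z_max.  All M candidate tracks — active or not — carry the motion
prior, which keeps load flips dimension-preserving.

D has an Inverse-Gamma prior (conjugate to the increments); per-frame
brightness and background fluxes have independent Gamma priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import invgamma

from .core import AcquisitionTiming, Config, ConfigError, ImageStack, SystemState, subexposure_times
from .forward_model import expected_image, log_likelihood

__all__ = [
    "LoadsPrior",
    "MotionPrior",
    "ParamPriors",
    "loads_log_prior",
    "motion_log_prob",
    "params_log_prior",
    "state_log_posterior",
]


@dataclass(frozen=True)
class LoadsPrior:
    """Truncated Beta-Bernoulli loads: P(b_m = 1) = gamma/M."""

    M: int
    gamma: float  # expected number of active emitters

    def __post_init__(self):
        if not self.M >= 1:
            raise ConfigError("M", "must be >= 1")
        if not 0 < self.gamma < self.M:
            raise ConfigError("gamma", "need 0 < gamma < M")

    @property
    def p_active(self) -> float:
        return self.gamma / self.M


@dataclass(frozen=True)
class MotionPrior:
    """Brownian motion prior: per-coordinate transition variance 2*D*dt,
    uniform initial position over ``init_bounds`` ((3, 2) lower/upper)."""

    diffusion: float  # nm^2/s
    init_bounds: np.ndarray

    def __post_init__(self):
        if not self.diffusion > 0:
            raise ValueError("diffusion must be > 0")
        b = np.asarray(self.init_bounds, float)
        object.__setattr__(self, "init_bounds", b)
        if b.shape != (3, 2) or not np.all(b[:, 1] > b[:, 0]):
            raise ConfigError("init_bounds", "need (3, 2) bounds with upper > lower")

    @property
    def log_init_density(self) -> float:
        return float(-np.sum(np.log(self.init_bounds[:, 1] - self.init_bounds[:, 0])))

    def in_bounds(self, position: np.ndarray) -> bool:
        return bool(np.all(position >= self.init_bounds[:, 0]) and np.all(position <= self.init_bounds[:, 1]))


def loads_log_prior(b: np.ndarray, prior: LoadsPrior) -> float:
    """Log-probability of a loads vector under independent Bernoulli(gamma/M)."""
    b = np.asarray(b)
    if b.size != prior.M or not np.all((b == 0) | (b == 1)):
        raise ValueError("loads must be a 0/1 vector of length M")
    q = prior.p_active
    k = int(np.sum(b))
    return k * np.log(q) + (prior.M - k) * np.log1p(-q)


def increment_stats(track: np.ndarray, timing: AcquisitionTiming, K: int) -> tuple[int, float]:
    """Sufficient statistics of a track's Gaussian increments for D:
    (number of scalar increments n, sum of d^2/(4*dt)).  The conditional of
    D given tracks is Inverse-Gamma(shape + n/2, scale + SS)."""
    t = subexposure_times(timing, K).ravel()
    flat = np.asarray(track, float).reshape(t.size, 3)
    dt = np.diff(t)
    d2 = np.sum(np.diff(flat, axis=0) ** 2, axis=1)
    return 3 * dt.size, float(np.sum(d2 / (4.0 * dt)))


def motion_log_prob(track: np.ndarray, prior: MotionPrior, timing: AcquisitionTiming, K: int | None = None) -> float:
    """Log-density of one emitter's sub-exposure track under the motion prior.

    ``track`` is (N, K, 3) (or flat (N*K, 3)); the density is the uniform
    initial term times independent Normal(0, 2*D*dt) increments per
    coordinate between consecutive sub-exposure times, crossing dead time
    between frames as a single longer step.
    """
    track = np.asarray(track, float)
    if track.ndim == 3:
        K = track.shape[1]
        flat = track.reshape(-1, 3)
    else:
        if K is None:
            raise ValueError("flat tracks need K")
        flat = track
    if not np.all(np.isfinite(flat)):
        raise ValueError("track positions must be finite")
    t = subexposure_times(timing, K).ravel()
    if flat.shape[0] != t.size:
        raise ValueError(f"track has {flat.shape[0]} sub-positions, timing expects {t.size}")
    if not prior.in_bounds(flat[0]):
        return -np.inf
    out = prior.log_init_density
    if t.size > 1:
        var = 2.0 * prior.diffusion * np.diff(t)
        d2 = np.sum(np.diff(flat, axis=0) ** 2, axis=1)
        out += float(np.sum(-1.5 * np.log(2.0 * np.pi * var) - d2 / (2.0 * var)))
    return out


def sample_track(prior: MotionPrior, timing: AcquisitionTiming, K: int, rng, start: np.ndarray | None = None) -> np.ndarray:
    """Draw one track from the motion prior, (N, K, 3)."""
    t = subexposure_times(timing, K)
    L = t.size
    flat = np.empty((L, 3))
    if start is None:
        lo, hi = prior.init_bounds[:, 0], prior.init_bounds[:, 1]
        start = rng.uniform(lo, hi)
    flat[0] = start
    if L > 1:
        sd = np.sqrt(2.0 * prior.diffusion * np.diff(t.ravel()))
        steps = rng.standard_normal((L - 1, 3)) * sd[:, None]
        flat[1:] = start + np.cumsum(steps, axis=0)
    return flat.reshape(t.shape + (3,))


@dataclass(frozen=True)
class ParamPriors:
    """Hyperparameters of the parameter priors (see module docstring)."""

    d_shape: float
    d_scale: float  # Inverse-Gamma scale; prior mean = d_scale / (d_shape - 1)
    h_shape: float
    h_scale: float  # Gamma scale; prior mean = h_shape * h_scale
    f_shape: float
    f_scale: float

    def __post_init__(self):
        for name in ("d_shape", "d_scale", "h_shape", "h_scale", "f_shape", "f_scale"):
            if not getattr(self, name) > 0:
                raise ConfigError(name, "must be > 0")

    @classmethod
    def from_config(cls, config: Config) -> "ParamPriors":
        m = config.model
        return cls(
            d_shape=m.d_prior_shape,
            d_scale=m.d_prior_mean * (m.d_prior_shape - 1.0),
            h_shape=m.h_prior_shape,
            h_scale=m.h_prior_mean / m.h_prior_shape,
            f_shape=m.f_prior_shape,
            f_scale=m.f_prior_mean / m.f_prior_shape,
        )


def params_log_prior(
    D: float, h: np.ndarray, F: np.ndarray, hyper: ParamPriors, include_brightness: bool = True
) -> float:
    """Joint log-prior of diffusion, per-frame brightness and background.

    Brightness and background are a priori independent across frames (their
    time courses may vary substantially).  When brightness is held fixed in
    the model it contributes no prior term (``include_brightness=False``).
    """
    h = np.asarray(h, float)
    F = np.asarray(F, float)
    if not D > 0 or np.any(h <= 0) or np.any(F < 0):
        raise ValueError("need D > 0, brightness > 0, background >= 0")
    out = float(invgamma.logpdf(D, hyper.d_shape, scale=hyper.d_scale))
    if include_brightness:
        out += float(np.sum(gamma_dist.logpdf(h, hyper.h_shape, scale=hyper.h_scale)))
    out += float(np.sum(gamma_dist.logpdf(F, hyper.f_shape, scale=hyper.f_scale)))
    return out


def state_log_posterior(state: SystemState, data: ImageStack, config: Config) -> float:
    """Unnormalized log-posterior: likelihood + loads prior + motion prior
    over all M candidate tracks + parameter priors.

    Inactive tracks carry the motion prior too (they are well-defined latent
    proposals), so the density lives on a fixed-dimension space regardless
    of the active count.  With ``run.prior_only`` the likelihood term is
    dropped (sampler-validation mode).
    """
    loads = LoadsPrior(config.model.M, config.model.gamma)
    motion = MotionPrior(state.diffusion, config.init_bounds)
    hyper = ParamPriors.from_config(config)
    out = loads_log_prior(state.loads, loads)
    for m in range(state.M):
        out += motion_log_prob(state.tracks[m], motion, config.timing)
    out += params_log_prior(
        state.diffusion,
        state.brightness,
        state.background,
        hyper,
        include_brightness=config.model.fixed_brightness is None,
    )
    if not config.run.prior_only:
        out += log_likelihood(data.values, expected_image(state, config), data.camera)
    return out
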