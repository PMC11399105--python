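"""Shared domain types, coordinate conventions and configuration validation.

Conventions used throughout the package:

* Lateral positions are continuous, in nanometres, with the origin at the
  outer corner of the pixel in row 1, column 1.  ``x`` runs along columns,
  ``y`` along rows.  Pixel regions are half-open rectangles
  ``[x_min, x_max) x [y_min, y_max)`` so every point belongs to exactly one
  pixel, and pixels are indexed row-major and 1-based in all user-facing
  interfaces.
* The axial coordinate ``z`` is signed internally; because a symmetric
  defocus model makes the sign unidentifiable from a single focal plane,
  only ``|z|`` is reported at I/O boundaries.
* Times are in seconds; every frame ``n`` has an integration window
  ``[t_n_min, t_n_max]``; windows are strictly increasing and may be
  separated by dead time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfigError",
    "CameraModel",
    "Optics",
    "AcquisitionTiming",
    "ImageStack",
    "TrackSet",
    "SystemState",
    "ModelConfig",
    "RunConfig",
    "Config",
    "validate_config",
    "pixel_region",
    "containing_pixel",
    "subexposure_times",
]


class ConfigError(ValueError):
    """A configuration invariant is violated; ``field`` names the culprit."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _require(ok: bool, field_name: str, message: str) -> None:
    if not ok:
        raise ConfigError(field_name, message)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera parameters and sensor geometry.

    The measurement model is ``w ~ Normal(offset + gain*u,
    read_variance + excess_noise*gain**2*u)`` for ``u`` expected incident
    photons, so ``offset`` and ``read_variance`` are in counts and counts^2,
    ``gain`` in counts/photon and ``excess_noise`` dimensionless (>= 1;
    electron multiplication gives ~2).
    """

    offset: float
    read_variance: float
    gain: float
    excess_noise: float
    pixel_size: float  # nm
    n_rows: int
    n_cols: int

    def __post_init__(self):
        _require(self.read_variance > 0, "read_variance", "must be > 0")
        _require(self.gain > 0, "gain", "must be > 0")
        _require(self.excess_noise >= 1, "excess_noise", "must be >= 1")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(int(self.n_rows) >= 1, "n_rows", "must be >= 1")
        _require(int(self.n_cols) >= 1, "n_cols", "must be >= 1")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_area(self) -> float:
        """nm^2 monitored by one pixel."""
        return self.pixel_size**2

    @property
    def fov_size(self) -> tuple[float, float]:
        """(width along x, height along y) in nm."""
        return (self.n_cols * self.pixel_size, self.n_rows * self.pixel_size)


@dataclass(frozen=True)
class Optics:
    """Objective and PSF-width model parameters.

    ``in_focus_width`` is the lateral Gaussian PSF width at ``z = 0`` and
    ``axial_scale`` the defocus length over which the width grows by sqrt(2):
    ``sigma(z) = in_focus_width * sqrt(1 + (z/axial_scale)**2)``.
    """

    numerical_aperture: float
    wavelength: float  # nm
    in_focus_width: float  # nm
    axial_scale: float  # nm

    def __post_init__(self):
        _require(self.numerical_aperture > 0, "numerical_aperture", "must be > 0")
        _require(self.wavelength > 0, "wavelength", "must be > 0")
        _require(self.in_focus_width > 0, "in_focus_width", "must be > 0")
        _require(self.axial_scale > 0, "axial_scale", "must be > 0")

    @property
    def diffraction_limit(self) -> float:
        """Nominal Rayleigh limit 0.61*wavelength/NA, in nm."""
        return 0.61 * self.wavelength / self.numerical_aperture


@dataclass(frozen=True)
class AcquisitionTiming:
    """Per-frame integration windows (seconds), strictly increasing and
    non-overlapping; dead time between exposures is allowed."""

    t_start: np.ndarray  # (N,)
    t_end: np.ndarray  # (N,)

    def __post_init__(self):
        t0 = np.asarray(self.t_start, float)
        t1 = np.asarray(self.t_end, float)
        object.__setattr__(self, "t_start", t0)
        object.__setattr__(self, "t_end", t1)
        _require(t0.ndim == 1 and t0.shape == t1.shape, "timing", "t_start/t_end must be 1-D and equal length")
        _require(t0.size >= 1, "n_frames", "need at least one frame")
        _require(bool(np.all(t0 < t1)), "exposure", "every frame needs t_start < t_end")
        if t0.size > 1:
            _require(bool(np.all(t1[:-1] <= t0[1:])), "exposure", "integration windows overlap")

    @classmethod
    def regular(cls, n_frames: int, exposure: float, period: float | None = None, t0: float = 0.0) -> "AcquisitionTiming":
        period = exposure if period is None else period
        starts = t0 + period * np.arange(n_frames)
        return cls(starts, starts + exposure)

    @property
    def n_frames(self) -> int:
        return self.t_start.size

    @property
    def exposures(self) -> np.ndarray:
        """Integration durations per frame (s)."""
        return self.t_end - self.t_start


def subexposure_times(timing: AcquisitionTiming, K: int) -> np.ndarray:
    """Midpoint quadrature times: (N, K) array, K midpoints per exposure.

    The time integral of the photon flux over each exposure is approximated
    at these K midpoints; motion between them is carried by the motion model.
    """
    if K < 1:
        raise ConfigError("K", "need at least one sub-exposure position")
    frac = (np.arange(K) + 0.5) / K
    return timing.t_start[:, None] + timing.exposures[:, None] * frac[None, :]


@dataclass(frozen=True)
class ImageStack:
    """Measured counts, (N, n_rows, n_cols), with timing and camera metadata.

    Values may be any finite reals: the EMCCD read-out model is a Normal, so
    negative counts (e.g. after upstream offset handling) are legal data.
    """

    values: np.ndarray
    timing: AcquisitionTiming
    camera: CameraModel

    def __post_init__(self):
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        _require(v.ndim == 3, "values", "expect (n_frames, n_rows, n_cols)")
        _require(v.shape[0] == self.timing.n_frames, "values", f"{v.shape[0]} frames but timing has {self.timing.n_frames}")
        _require(
            v.shape[1:] == (self.camera.n_rows, self.camera.n_cols),
            "values",
            f"frame shape {v.shape[1:]} does not match camera ({self.camera.n_rows}, {self.camera.n_cols})",
        )
        _require(bool(np.all(np.isfinite(v))), "values", "non-finite counts")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


class TrackSet:
    """A set of tracks on a common frame axis.

    ``positions`` is (M, N, 3) in nm; a missing detection is marked by
    ``present[m, n] = False`` (its coordinates are NaN).  2-D tracks (no
    axial information) carry NaN in the z column for all frames.
    """

    def __init__(self, positions: np.ndarray, present: np.ndarray | None = None):
        pos = np.array(positions, float, copy=True)
        if pos.ndim == 2:
            pos = pos[None]
        if pos.shape[-1] == 2:
            pos = np.concatenate([pos, np.full(pos.shape[:-1] + (1,), np.nan)], axis=-1)
        if pos.ndim != 3 or pos.shape[-1] != 3:
            raise ValueError("positions must be (M, N, 2 or 3)")
        if present is None:
            present = np.isfinite(pos[..., 0])
        present = np.asarray(present, bool)
        if present.shape != pos.shape[:2]:
            raise ValueError("present flags must be (M, N)")
        if pos.shape[0] and not np.all(present.any(axis=1)):
            raise ValueError("every track needs at least one present frame")
        if np.any(~np.isfinite(pos[..., :2][present])):
            raise ValueError("present frames need finite lateral positions")
        pos[~present] = np.nan
        self.positions = pos
        self.present = present

    @property
    def n_tracks(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def has_z(self) -> bool:
        return bool(np.any(np.isfinite(self.positions[..., 2])))

    @property
    def complete(self) -> bool:
        """True when no track misses a detection in any frame."""
        return bool(np.all(self.present))

    def __len__(self) -> int:
        return self.n_tracks

    def __repr__(self) -> str:  # pragma: no cover
        d = 3 if self.has_z else 2
        return f"TrackSet({self.n_tracks} tracks, {self.n_frames} frames, {d}D)"


@dataclass
class SystemState:
    """Every unknown of the joint model.

    ``loads`` are the M binary indicators recruiting model emitters;
    ``tracks`` holds all M candidate tracks at sub-exposure resolution,
    (M, N, K, 3) in nm (inactive emitters keep well-defined tracks so that
    load flips preserve dimension); ``diffusion`` in nm^2/s is shared;
    ``brightness`` (photons/s per emitter) and ``background`` (photon flux,
    photons/(nm^2 s)) are per frame.
    """

    loads: np.ndarray  # (M,) 0/1
    tracks: np.ndarray  # (M, N, K, 3) nm
    diffusion: float  # nm^2/s
    brightness: np.ndarray  # (N,) photons/s
    background: np.ndarray  # (N,) photons/(nm^2 s)

    def __post_init__(self):
        self.loads = np.asarray(self.loads, np.int8)
        self.tracks = np.asarray(self.tracks, float)
        self.brightness = np.asarray(self.brightness, float)
        self.background = np.asarray(self.background, float)
        if self.tracks.ndim != 4 or self.tracks.shape[0] != self.loads.size:
            raise ValueError("tracks must be (M, N, K, 3) matching loads")
        if not np.all((self.loads == 0) | (self.loads == 1)):
            raise ValueError("loads must be 0 or 1")
        if not self.diffusion > 0:
            raise ValueError("diffusion must be > 0")
        if not np.all(self.brightness > 0):
            raise ValueError("brightness must be > 0")
        if not np.all(self.background >= 0):
            raise ValueError("background must be >= 0")

    @property
    def M(self) -> int:
        return self.loads.size

    @property
    def active_count(self) -> int:
        """B = sum of loads, the number of recruited emitters."""
        return int(self.loads.sum())

    @property
    def active(self) -> np.ndarray:
        return np.flatnonzero(self.loads == 1)

    def copy(self) -> "SystemState":
        return SystemState(
            self.loads.copy(), self.tracks.copy(), self.diffusion, self.brightness.copy(), self.background.copy()
        )


# --------------------------------------------------------------------------
# pixel geometry


def pixel_region(p: int, camera: CameraModel) -> tuple[float, float, float, float]:
    """Half-open region [x_min, x_max) x [y_min, y_max) of 1-based pixel p.

    Pixels are row-major: p = 1 is (row 1, col 1) at the coordinate origin.
    """
    if not 1 <= p <= camera.n_pixels:
        raise IndexError(f"pixel index {p} outside 1..{camera.n_pixels}")
    r, c = divmod(p - 1, camera.n_cols)
    s = camera.pixel_size
    return (c * s, (c + 1) * s, r * s, (r + 1) * s)


def containing_pixel(x: float, y: float, camera: CameraModel) -> int:
    """1-based index of the pixel whose half-open region contains (x, y)."""
    s = camera.pixel_size
    c = int(np.floor(x / s))
    r = int(np.floor(y / s))
    if not (0 <= c < camera.n_cols and 0 <= r < camera.n_rows):
        raise IndexError(f"position ({x}, {y}) nm outside the field of view")
    return r * camera.n_cols + c + 1


# --------------------------------------------------------------------------
# full configuration


@dataclass(frozen=True)
class ModelConfig:
    """Model-structure settings and prior hyperparameters.

    M truncates the latent-feature emitter pool (posterior active count must
    stay well below it); gamma is the a-priori expected number of active
    emitters; K the sub-exposure positions per frame capturing motion blur.
    D carries an Inverse-Gamma(shape, scale=(shape-1)*mean) prior (conjugate
    to the Gaussian motion increments); brightness and background carry
    independent per-frame Gamma(shape, scale=mean/shape) priors.
    """

    M: int = 50
    K: int = 4
    gamma: float = 5.0
    z_max: float | None = None  # nm; default 2 * optics.axial_scale
    init_margin_px: float = 2.0  # initial-position box extends this far outside the FOV
    d_prior_shape: float = 2.0
    d_prior_mean: float = 1e5  # nm^2/s
    h_prior_shape: float = 2.0
    h_prior_mean: float = 5e4  # photons/s
    f_prior_shape: float = 1.0
    f_prior_mean: float = 0.02  # photons/(nm^2 s)
    fixed_brightness: float | None = None  # photons/s; None => estimated per frame
    constant_background: bool = False  # tie F_n across frames

    def __post_init__(self):
        _require(int(self.M) >= 1, "M", "must be >= 1")
        _require(int(self.K) >= 1, "K", "must be >= 1")
        _require(self.gamma > 0, "gamma", "must be > 0")
        _require(self.gamma < self.M, "gamma", "expected count must be < truncation M")
        for name in ("d_prior_shape", "d_prior_mean", "h_prior_shape", "h_prior_mean", "f_prior_shape", "f_prior_mean"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.d_prior_shape > 1, "d_prior_shape", "must be > 1 for a finite prior mean")
        if self.fixed_brightness is not None:
            _require(self.fixed_brightness > 0, "fixed_brightness", "must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Sampler run-length settings.

    ``prior_only`` disables the likelihood (sampler-validation mode: the
    chain must then reproduce the priors).  ``pilots`` > 1 starts burn-in
    with that many short independent pilot segments and continues from the
    highest-posterior end state — cheap protection against committing to a
    poor mode early (0 or 1 disables).
    """

    iterations: int = 3000
    burn_in: int | None = None  # default: iterations // 2
    seed: int = 0
    prior_only: bool = False
    pilots: int = 3

    def __post_init__(self):
        _require(int(self.iterations) >= 1, "iterations", "must be >= 1")
        if self.burn_in is not None:
            _require(0 <= int(self.burn_in) <= self.iterations, "burn_in", "must lie in [0, iterations]")

    @property
    def effective_burn_in(self) -> int:
        return self.iterations // 2 if self.burn_in is None else int(self.burn_in)


@dataclass(frozen=True)
class Config:
    """Validated bundle of instrument, model and run settings."""

    camera: CameraModel
    optics: Optics
    timing: AcquisitionTiming
    model: ModelConfig = field(default_factory=ModelConfig)
    run: RunConfig = field(default_factory=RunConfig)

    @property
    def pixel_area(self) -> float:
        return self.camera.pixel_area

    @property
    def diffraction_limit(self) -> float:
        return self.optics.diffraction_limit

    @property
    def z_max(self) -> float:
        return 2.0 * self.optics.axial_scale if self.model.z_max is None else self.model.z_max

    @property
    def init_bounds(self) -> np.ndarray:
        """(3, 2) lower/upper bounds of the uniform initial-position box:
        FOV expanded by ``init_margin_px`` pixels laterally, |z| <= z_max."""
        m = self.model.init_margin_px * self.camera.pixel_size
        w, h = self.camera.fov_size
        return np.array([[-m, w + m], [-m, h + m], [-self.z_max, self.z_max]])

    def with_run(self, **kw) -> "Config":
        return replace(self, run=replace(self.run, **kw))

    def with_model(self, **kw) -> "Config":
        return replace(self, model=replace(self.model, **kw))


def validate_config(
    camera: CameraModel,
    optics: Optics,
    timing: AcquisitionTiming,
    model: ModelConfig | None = None,
    run: RunConfig | None = None,
) -> Config:
    """Validate instrument settings and return a configuration with derived
    quantities (pixel area, nominal diffraction limit) attached.

    The dataclass constructors enforce the per-type invariants and raise
    :class:`ConfigError` naming the offending field; this function exists so
    callers get a single entry point and a single bundled object.
    """
    return Config(camera, optics, timing, model or ModelConfig(), run or RunConfig())
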