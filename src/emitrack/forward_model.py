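"""Deterministic imaging model and the stochastic camera measurement model.

The expected photon count of pixel ``p`` in frame ``n`` is the space-time
integral of the photon flux over the pixel region and the integration
window.  The flux is a spatially uniform background plus one 2-D Gaussian
PSF per active emitter whose width grows with defocus,

    sigma(z) = sigma0 * sqrt(1 + (z / d_z)**2).

The time integral is approximated by K midpoint sub-exposure positions per
frame (motion blur); the pixel integral is exact for each sub-position via
axis-separable differences of the Gaussian cumulative integral.  The camera
maps expected photons ``u`` to recorded counts through the EMCCD read-out
model

    w | u ~ Normal(mu + xi*u, upsilon + f*xi**2*u),

with offset ``mu``, read variance ``upsilon``, overall gain ``xi`` and
excess noise factor ``f``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .core import AcquisitionTiming, CameraModel, Config, ImageStack, Optics, SystemState, pixel_region

__all__ = [
    "psf_lateral_width",
    "emitter_frame_photons",
    "emitter_pixel_photons",
    "expected_image",
    "flux_decomposition",
    "background_photons",
    "camera_sample",
    "log_likelihood",
    "frame_log_likelihood",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def psf_lateral_width(z, optics: Optics):
    """Lateral PSF width sigma(z) in nm; even in z, sigma(0) = sigma0."""
    z = np.asarray(z, float)
    return optics.in_focus_width * np.sqrt(1.0 + (z / optics.axial_scale) ** 2)


def _edge_integrals(centers: np.ndarray, sigma: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-sub-position integrals of a unit 1-D Gaussian over the bins
    delimited by ``edges``: (K, len(edges)-1)."""
    zed = (edges[None, :] - centers[:, None]) / sigma[:, None]
    c = ndtr(zed)
    return c[:, 1:] - c[:, :-1]


def emitter_frame_photons(
    positions: np.ndarray,
    brightness: float,
    camera: CameraModel,
    exposure: float,
    optics: Optics,
) -> np.ndarray:
    """Expected photons from one emitter in one frame, per pixel.

    ``positions`` are the K sub-exposure (x, y, z) samples in nm;
    ``brightness`` the emission rate in photons/s; ``exposure`` the
    integration duration in s.  Returns an (n_rows, n_cols) image summing
    (brightness*exposure/K) times the exact pixel integral of the
    unit-mass Gaussian at each sub-position.
    """
    if not brightness > 0:
        raise ValueError("brightness must be > 0")
    pos = np.atleast_2d(np.asarray(positions, float))
    K = pos.shape[0]
    sig = psf_lateral_width(pos[:, 2], optics)
    s = camera.pixel_size
    col_edges = s * np.arange(camera.n_cols + 1)
    row_edges = s * np.arange(camera.n_rows + 1)
    ix = _edge_integrals(pos[:, 0], sig, col_edges)  # (K, n_cols)
    iy = _edge_integrals(pos[:, 1], sig, row_edges)  # (K, n_rows)
    return (brightness * exposure / K) * np.einsum("kr,kc->rc", iy, ix)


def emitter_pixel_photons(
    positions: np.ndarray,
    brightness: float,
    p: int,
    camera: CameraModel,
    exposure: float,
    optics: Optics,
) -> float:
    """Expected photons on a single 1-based pixel ``p`` (see
    :func:`emitter_frame_photons` for the semantics)."""
    if not brightness > 0:
        raise ValueError("brightness must be > 0")
    x0, x1, y0, y1 = pixel_region(p, camera)
    pos = np.atleast_2d(np.asarray(positions, float))
    sig = psf_lateral_width(pos[:, 2], optics)
    ix = ndtr((x1 - pos[:, 0]) / sig) - ndtr((x0 - pos[:, 0]) / sig)
    iy = ndtr((y1 - pos[:, 1]) / sig) - ndtr((y0 - pos[:, 1]) / sig)
    return float(brightness * exposure / pos.shape[0] * np.sum(ix * iy))


def background_photons(background: np.ndarray, camera: CameraModel, timing: AcquisitionTiming) -> np.ndarray:
    """Expected background photons per pixel and frame, (N,): flux *
    pixel area * exposure (spatially uniform within a frame)."""
    return np.asarray(background, float) * camera.pixel_area * timing.exposures


def flux_decomposition(state: SystemState, config: Config) -> tuple[np.ndarray, np.ndarray]:
    """Background and per-emitter expected-photon images.

    Returns ``(back, emitters)`` with ``back`` of shape (N, R, C) and
    ``emitters`` of shape (M, N, R, C); the total expected image is exactly
    ``back + sum_m loads[m] * emitters[m]`` (flux additivity; the loads
    simply switch emitter contributions on and off).
    """
    cam, timing, optics = config.camera, config.timing, config.optics
    N = timing.n_frames
    bpp = background_photons(state.background, cam, timing)
    back = np.broadcast_to(bpp[:, None, None], (N, cam.n_rows, cam.n_cols)).copy()
    emitters = np.zeros((state.M, N, cam.n_rows, cam.n_cols))
    exp = timing.exposures
    for m in range(state.M):
        for n in range(N):
            emitters[m, n] = emitter_frame_photons(state.tracks[m, n], state.brightness[n], cam, exp[n], optics)
    return back, emitters


def expected_image(state: SystemState, config: Config) -> np.ndarray:
    """Expected photons per frame and pixel, (N, n_rows, n_cols)."""
    cam, timing, optics = config.camera, config.timing, config.optics
    bpp = background_photons(state.background, cam, timing)
    u = np.broadcast_to(bpp[:, None, None], (timing.n_frames, cam.n_rows, cam.n_cols)).copy()
    exp = timing.exposures
    for m in state.active:
        for n in range(timing.n_frames):
            u[n] += emitter_frame_photons(state.tracks[m, n], state.brightness[n], cam, exp[n], optics)
    return u


def camera_sample(u: np.ndarray, camera: CameraModel, rng) -> np.ndarray:
    """Draw recorded counts from the EMCCD read-out model, elementwise
    independently; ``rng`` is a seed or :class:`numpy.random.Generator`."""
    u = np.asarray(u, float)
    if np.any(u < 0):
        raise ValueError("expected photon counts must be >= 0")
    rng = np.random.default_rng(rng)
    mean = camera.offset + camera.gain * u
    var = camera.read_variance + camera.excess_noise * camera.gain**2 * u
    return rng.normal(mean, np.sqrt(var))


def log_likelihood(w: np.ndarray, u: np.ndarray, camera: CameraModel) -> float:
    """Total Normal log-likelihood of counts ``w`` given expected photons
    ``u`` under the EMCCD read-out model."""
    w = np.asarray(w, float)
    u = np.asarray(u, float)
    if w.shape != u.shape:
        raise ValueError(f"shape mismatch: data {w.shape} vs expectation {u.shape}")
    return frame_log_likelihood(w, u, camera)


def frame_log_likelihood(w: np.ndarray, u: np.ndarray, camera: CameraModel) -> float:
    # hot path of the sampler: no validation, any matching shapes
    var = camera.read_variance + camera.excess_noise * camera.gain**2 * u
    resid = w - camera.offset - camera.gain * u
    return float(-0.5 * np.sum(np.log(var) + resid * resid / var) - 0.5 * w.size * _LOG2PI)


def standardized_residuals(stack: ImageStack, u: np.ndarray) -> np.ndarray:
    """(w - mu - xi*u)/sqrt(upsilon + f*xi^2*u); Normal(0,1) under the model."""
    cam = stack.camera
    var = cam.read_variance + cam.excess_noise * cam.gain**2 * u
    return (stack.values - cam.offset - cam.gain * u) / np.sqrt(var)
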