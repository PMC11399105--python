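"""Synthetic ground-truth movie generation.

Movies are built in two steps: emitter tracks are drawn at sub-exposure
resolution from a chosen motion model, then rendered through the same
forward model the inference uses (pixel-integrated Gaussian PSF with
defocus and motion blur, spatially uniform background, EMCCD read-out
noise).  Ground truth is therefore exact with respect to the model at the
rendering resolution K.

Default scenario parameters describe a widefield EMCCD acquisition at
133 nm pixels, 22 frames of 100 ms exposure on a 114 ms period, NA 1.45
optics at 665 nm emission (nominal diffraction limit 280 nm), diffusion
5e4 nm^2/s, brightness 5000 photons/s and background 0.01 photons/(nm^2 s).

Controlled-crowding scenarios place two emitters whose tracks share the
same increment realization but start a fixed offset apart, so the realized
per-frame mean separation can be dialed exactly — down to 0 nm, where the
two tracks coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    AcquisitionTiming,
    CameraModel,
    Config,
    ImageStack,
    Optics,
    SystemState,
    TrackSet,
    subexposure_times,
    validate_config,
)
from .forward_model import camera_sample, expected_image

__all__ = [
    "Scenario",
    "default_camera",
    "default_optics",
    "default_timing",
    "simulate_tracks",
    "place_for_mean_displacement",
    "render_stack",
    "tracks_to_trackset",
    "make_fixture",
    "FIXTURES",
]

MOTION_MODELS = ("brownian", "directed", "confined", "immobile")


def default_camera(n_rows: int = 16, n_cols: int = 16) -> CameraModel:
    return CameraModel(
        offset=100.0, read_variance=49.0, gain=2.2, excess_noise=2.0, pixel_size=133.0, n_rows=n_rows, n_cols=n_cols
    )


def default_optics() -> Optics:
    return Optics(numerical_aperture=1.45, wavelength=665.0, in_focus_width=110.0, axial_scale=400.0)


def default_timing(n_frames: int = 22) -> AcquisitionTiming:
    return AcquisitionTiming.regular(n_frames, exposure=0.100, period=0.114)


@dataclass(frozen=True)
class Scenario:
    """Everything needed to simulate one movie."""

    motion: str = "brownian"
    diffusion: float = 5e4  # nm^2/s
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # nm/s, directed motion
    confinement_radius: float = 500.0  # nm, confined motion
    n_emitters: int = 1
    brightness: float = 5000.0  # photons/s per emitter
    background: float = 0.01  # photons/(nm^2 s)
    camera: CameraModel = field(default_factory=default_camera)
    optics: Optics = field(default_factory=default_optics)
    timing: AcquisitionTiming = field(default_factory=default_timing)
    K: int = 4
    seed: int = 0
    starts: tuple | None = None  # (B, 3) nm; default: spread over the central FOV
    target_mean_displacement: float | None = None  # nm, 2-emitter scenarios
    shared_increments: bool = True  # displacement scenarios copy increments

    def __post_init__(self):
        if self.motion not in MOTION_MODELS:
            raise ValueError(f"unknown motion model {self.motion!r}; choose from {MOTION_MODELS}")
        if self.n_emitters < 0:
            raise ValueError("n_emitters must be >= 0")
        if self.diffusion < 0 or self.brightness <= 0 or self.background < 0:
            raise ValueError("rates must be positive (background may be 0)")
        if self.target_mean_displacement is not None:
            if self.n_emitters != 2:
                raise ValueError("target mean displacement applies to 2-emitter scenarios")
            if self.target_mean_displacement < 0:
                raise ValueError("target mean displacement must be >= 0")

    def config(self, **model_kw) -> Config:
        return validate_config(self.camera, self.optics, self.timing).with_model(K=self.K, **model_kw)


def _default_starts(scenario: Scenario, rng) -> np.ndarray:
    w, h = scenario.camera.fov_size
    lo = np.array([0.2 * w, 0.2 * h, -100.0])
    hi = np.array([0.8 * w, 0.8 * h, 100.0])
    return rng.uniform(lo, hi, size=(scenario.n_emitters, 3))


def _increments(scenario: Scenario, dts: np.ndarray, rng) -> np.ndarray:
    """(L-1, 3) motion-model increments for one track."""
    if scenario.motion == "immobile" or scenario.diffusion == 0:
        steps = np.zeros((dts.size, 3))
    else:
        steps = rng.standard_normal((dts.size, 3)) * np.sqrt(2.0 * scenario.diffusion * dts)[:, None]
    if scenario.motion == "directed":
        steps = steps + np.asarray(scenario.drift, float)[None, :] * dts[:, None]
    return steps


def _reflect_confined(start: np.ndarray, steps: np.ndarray, radius: float) -> np.ndarray:
    """Cumulative path reflected at a sphere of ``radius`` about ``start``."""
    path = np.empty((steps.shape[0] + 1, 3))
    path[0] = start
    pos = start.copy()
    for i, s in enumerate(steps):
        pos = pos + s
        r = np.linalg.norm(pos - start)
        if r > radius:  # radial reflection at the boundary
            pos = start + (pos - start) * (2.0 * radius - r) / r
        path[i + 1] = pos
    return path


def simulate_tracks(scenario: Scenario, rng=None) -> np.ndarray:
    """Ground-truth tracks at sub-exposure resolution, (B, N, K, 3) nm."""
    rng = np.random.default_rng(scenario.seed if rng is None else rng)
    t = subexposure_times(scenario.timing, scenario.K)
    dts = np.diff(t.ravel())
    if scenario.target_mean_displacement is not None:
        return place_for_mean_displacement(scenario, scenario.target_mean_displacement, rng)
    starts = np.asarray(scenario.starts, float) if scenario.starts is not None else _default_starts(scenario, rng)
    if starts.shape != (scenario.n_emitters, 3):
        raise ValueError(f"starts must be ({scenario.n_emitters}, 3)")
    out = np.empty((scenario.n_emitters, t.size, 3))
    for b in range(scenario.n_emitters):
        steps = _increments(scenario, dts, rng)
        if scenario.motion == "confined":
            out[b] = _reflect_confined(starts[b], steps, scenario.confinement_radius)
        else:
            out[b, 0] = starts[b]
            out[b, 1:] = starts[b] + np.cumsum(steps, axis=0)
    return out.reshape(scenario.n_emitters, *t.shape, 3)


def realized_mean_displacement(tracks: np.ndarray) -> float:
    """Per-frame mean separation between a pair of tracks (positions are
    frame means of the sub-exposure samples), in nm."""
    if tracks.shape[0] != 2:
        raise ValueError("mean displacement is defined for a pair of tracks")
    frame_pos = tracks.mean(axis=2)  # (2, N, 3)
    return float(np.mean(np.linalg.norm(frame_pos[0, :, :2] - frame_pos[1, :, :2], axis=1)))


def place_for_mean_displacement(
    scenario: Scenario, target: float, rng=None, tol: float = 0.02, max_iter: int = 60
) -> np.ndarray:
    """Two-emitter tracks whose realized per-frame mean lateral separation
    matches ``target`` (nm) within ``tol`` relative.

    One track is generated; the second starts a lateral offset away and, by
    default, reuses the first track's increment realization so the
    separation is constant through time and any target — including 0 — is
    realizable.  With independent increments
    (``scenario.shared_increments=False``) the offset magnitude is found by
    bisection, and targets below the irreducible separation of two
    independent walks are reported unreachable.
    """
    rng = np.random.default_rng(scenario.seed if rng is None else rng)
    if scenario.n_emitters != 2:
        raise ValueError("needs a 2-emitter scenario")
    if target < 0:
        raise ValueError("target must be >= 0")
    t = subexposure_times(scenario.timing, scenario.K)
    dts = np.diff(t.ravel())
    w, h = scenario.camera.fov_size
    start1 = np.array([0.5 * w, 0.5 * h, 0.0]) if scenario.starts is None else np.asarray(scenario.starts, float)[0]
    theta = rng.uniform(0.0, 2.0 * np.pi)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    steps1 = _increments(scenario, dts, rng)
    steps2 = steps1 if scenario.shared_increments else _increments(scenario, dts, rng)

    def build(offset_mag: float) -> np.ndarray:
        tr = np.empty((2, t.size, 3))
        tr[0, 0] = start1 - 0.5 * offset_mag * direction
        tr[1, 0] = start1 + 0.5 * offset_mag * direction
        tr[0, 1:] = tr[0, 0] + np.cumsum(steps1, axis=0)
        tr[1, 1:] = tr[1, 0] + np.cumsum(steps2, axis=0)
        return tr.reshape(2, *t.shape, 3)

    if target == 0 and scenario.shared_increments:
        return build(0.0)
    lo_val = realized_mean_displacement(build(0.0))
    if target < lo_val * (1.0 - tol) and lo_val > 0:
        if scenario.shared_increments and lo_val == 0:
            pass
        elif not scenario.shared_increments:
            raise ValueError(
                f"target {target} nm below the irreducible mean separation {lo_val:.1f} nm of independent tracks"
            )
    # bracket then bisect on the offset magnitude (monotone for s >= 0 when
    # increments are shared; effectively monotone otherwise)
    lo, hi = 0.0, max(2.0 * target, 1.0)
    for _ in range(max_iter):
        if realized_mean_displacement(build(hi)) >= target:
            break
        hi *= 2.0
    else:
        raise ValueError("could not bracket the target mean displacement")
    tracks = build(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        tracks = build(mid)
        got = realized_mean_displacement(tracks)
        if target > 0 and abs(got - target) <= tol * target:
            return tracks
        if got < target:
            lo = mid
        else:
            hi = mid
    got = realized_mean_displacement(tracks)
    if target == 0 and got <= 1e-9:
        return tracks
    if target > 0 and abs(got - target) <= tol * target:
        return tracks
    raise ValueError(f"target mean displacement {target} nm unreachable (best realized {got:.1f} nm)")


def render_stack(truth: np.ndarray, scenario: Scenario, rng=None) -> tuple[ImageStack, np.ndarray]:
    """Render ground-truth tracks into a noisy stack.

    ``truth`` is (B, N, K, 3) at sub-exposure resolution.  Builds a
    SystemState with every load on, constant brightness and background,
    pushes it through the forward model and adds EMCCD read-out noise.
    Returns ``(stack, expected)`` where ``expected`` is the noiseless
    expected-photon image (N, rows, cols).
    """
    rng = np.random.default_rng(scenario.seed + 1 if rng is None else rng)
    truth = np.asarray(truth, float)
    B = truth.shape[0]
    N = scenario.timing.n_frames
    state = SystemState(
        loads=np.ones(B, np.int8) if B else np.zeros(0, np.int8),
        tracks=truth.reshape(B, N, scenario.K, 3) if B else np.zeros((0, N, scenario.K, 3)),
        diffusion=max(scenario.diffusion, 1e-12),
        brightness=np.full(N, scenario.brightness),
        background=np.full(N, scenario.background),
    )
    cfg = scenario.config(M=max(B, 1), gamma=min(max(B, 1) / 2.0, max(B, 0.5)))
    u = expected_image(state, cfg)
    values = camera_sample(u, scenario.camera, rng)
    return ImageStack(values, scenario.timing, scenario.camera), u


def tracks_to_trackset(truth: np.ndarray) -> TrackSet:
    """Frame-resolution view of sub-exposure tracks: the per-frame position
    is the mean of the K sub-exposure samples (the exposure-averaged
    position a localization estimates)."""
    truth = np.asarray(truth, float)
    return TrackSet(truth.mean(axis=2))


def _displacement_scenario(target: float, seed: int) -> Scenario:
    return Scenario(
        n_emitters=2,
        camera=default_camera(16, 16),
        target_mean_displacement=target,
        seed=seed,
    )


FIXTURES: dict[str, Scenario] = {
    "one-emitter": Scenario(n_emitters=1, camera=default_camera(16, 16), starts=((1050.0, 1100.0, 0.0),), seed=11),
    "three-emitter": Scenario(
        n_emitters=3,
        camera=default_camera(20, 20),
        starts=((660.0, 700.0, 0.0), (2000.0, 660.0, 0.0), (1330.0, 2000.0, 0.0)),
        seed=13,
    ),
    "background-only": Scenario(n_emitters=0, camera=default_camera(12, 12), seed=5),
    "displacement-724": _displacement_scenario(724.0, 21),
    "displacement-579": _displacement_scenario(579.0, 22),
    "displacement-434": _displacement_scenario(434.0, 23),
    "displacement-289": _displacement_scenario(289.0, 24),
    "displacement-145": _displacement_scenario(145.0, 25),
    "displacement-0": _displacement_scenario(0.0, 26),
}


def make_fixture(name: str, seed: int | None = None) -> tuple[ImageStack, TrackSet, Scenario]:
    """Deterministic named benchmark scenario.

    Returns ``(stack, truth, scenario)``; ``truth`` is the frame-resolution
    ground-truth track set.  ``seed`` overrides the fixture's fixed seed to
    draw an independent replicate of the same scenario.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    scenario = FIXTURES[name]
    if seed is not None:
        scenario = replace(scenario, seed=int(seed))
    truth = simulate_tracks(scenario)
    stack, _ = render_stack(truth, scenario)
    if truth.shape[0] == 0:
        return stack, None, scenario
    return stack, tracks_to_trackset(truth), scenario
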