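"""Track-comparison metrics: gated distance, optimal set pairing, tracking
error, its dual-view variant, and localization resolution.

The gated Euclidean distance between two tracks is
``d_eps(psi, phi) = sum_n min(||psi_n - phi_n||, eps)`` with gate ``eps``;
a frame where either track misses a detection contributes ``eps``.  Two
track *sets* are compared by the pairing distance: the minimum total gated
distance over one-to-one pairings, a linear assignment problem in which a
track left unmatched costs ``eps * N`` (it fails localization in every
frame).  Tracking error divides the pairing distance by N times the number
of reference tracks; when two views of the same specimen are compared (no
ground truth) the divisor doubles, since each view contributes half the
discrepancy.  Localization resolution instead re-pairs positions frame by
frame, ignoring track identity, and so is blind to mislinked but correctly
localized tracks.

Axial positions are compared as |z| vs |z| (the defocus model cannot sign
z); tracks of mixed dimensionality are compared on their shared (lateral)
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import TrackSet

__all__ = [
    "PairingResult",
    "gated_track_distance",
    "pair_track_sets",
    "tracking_error",
    "dual_view_tracking_error",
    "localization_resolution",
]


def _shared_coordinates(a: TrackSet, b: TrackSet) -> tuple[np.ndarray, np.ndarray]:
    """Positions of both sets on their shared coordinates, z as |z|."""
    pa, pb = a.positions.copy(), b.positions.copy()
    if a.has_z and b.has_z:
        pa[..., 2] = np.abs(pa[..., 2])
        pb[..., 2] = np.abs(pb[..., 2])
        return pa, pb
    return pa[..., :2], pb[..., :2]


def _frame_distances(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean distances between one track each; NaN where
    either is absent."""
    return np.sqrt(np.sum((pa - pb) ** 2, axis=-1))


def gated_track_distance(psi: TrackSet | np.ndarray, phi: TrackSet | np.ndarray, eps: float) -> float:
    """Gated Euclidean distance between two single tracks.

    ``psi``/``phi`` may be (N, 2 or 3) arrays (NaN rows = missing
    detections) or single-track :class:`TrackSet` objects.  With a finite
    gate, a frame missing in either track contributes ``eps``; with
    ``eps = inf`` missing detections are disallowed (the gate would make
    the distance infinite, and complete tracks are expected there).
    """
    ta = psi if isinstance(psi, TrackSet) else TrackSet(np.asarray(psi, float)[None])
    tb = phi if isinstance(phi, TrackSet) else TrackSet(np.asarray(phi, float)[None])
    if ta.n_tracks != 1 or tb.n_tracks != 1:
        raise ValueError("gated_track_distance compares single tracks; use pair_track_sets for sets")
    if ta.n_frames != tb.n_frames:
        raise ValueError(f"frame axes differ: {ta.n_frames} vs {tb.n_frames}")
    if not eps > 0:
        raise ValueError("gate must be > 0")
    pa, pb = _shared_coordinates(ta, tb)
    d = _frame_distances(pa[0], pb[0])
    absent = ~(ta.present[0] & tb.present[0])
    if np.isinf(eps):
        if absent.any():
            raise ValueError("infinite gate requires complete tracks (no missing detections)")
        return float(np.sum(d))
    d = np.where(absent, eps, np.minimum(d, eps))
    return float(np.sum(d))


@dataclass(frozen=True)
class PairingResult:
    """Outcome of the optimal pairing between two track sets."""

    pairs: tuple[tuple[int, int], ...]  # (index in set 1, index in set 2)
    unmatched_1: tuple[int, ...]
    unmatched_2: tuple[int, ...]
    total: float  # minimum total gated distance, nm
    gate: float  # nm (may be inf)


def _pair_cost_matrix(psi: TrackSet, phi: TrackSet, eps: float) -> np.ndarray:
    pa, pb = _shared_coordinates(psi, phi)
    # (M1, M2, N) distance tensor
    d = np.sqrt(np.sum((pa[:, None, :, :] - pb[None, :, :, :]) ** 2, axis=-1))
    both = psi.present[:, None, :] & phi.present[None, :, :]
    if np.isinf(eps):
        if not (psi.complete and phi.complete):
            raise ValueError("infinite gate requires complete tracks (no missing detections)")
        return d.sum(axis=-1)
    d = np.where(both, np.minimum(d, eps), eps)
    return d.sum(axis=-1)


def pair_track_sets(psi: TrackSet, phi: TrackSet, eps: float) -> PairingResult:
    """Minimum-total-gated-distance pairing between two track sets.

    Solves the assignment problem on the gated-track-distance matrix.  With
    a finite gate each set is augmented with dummy partners costing
    ``eps * N``, so leaving a track unmatched is itself an option and the
    reported total includes ``eps * N`` per unmatched track.  With an
    infinite gate, min(M1, M2) pairs are always formed (a dummy would cost
    infinity) and surplus tracks are reported unmatched.  Ties are broken
    toward lowest index pairs.
    """
    if psi.n_frames != phi.n_frames:
        raise ValueError(f"frame axes differ: {psi.n_frames} vs {phi.n_frames}")
    if not eps > 0:
        raise ValueError("gate must be > 0")
    m1, m2, N = psi.n_tracks, phi.n_tracks, psi.n_frames
    cost = _pair_cost_matrix(psi, phi, eps)
    if np.isinf(eps):
        rows, cols = linear_sum_assignment(cost)
        pairs = sorted(zip(rows.tolist(), cols.tolist()))
        total = float(cost[rows, cols].sum())
    else:
        # square augmentation: dummies absorb unmatched tracks at eps*N each
        size = m1 + m2
        big = np.full((size, size), eps * N, float)
        big[:m1, :m2] = cost
        big[m1:, m2:] = 0.0
        rows, cols = linear_sum_assignment(big)
        pairs = sorted((int(r), int(c)) for r, c in zip(rows, cols) if r < m1 and c < m2)
        n_unmatched = (m1 - len(pairs)) + (m2 - len(pairs))
        total = float(sum(cost[r, c] for r, c in pairs) + eps * N * n_unmatched)
    matched1 = {r for r, _ in pairs}
    matched2 = {c for _, c in pairs}
    return PairingResult(
        pairs=tuple(pairs),
        unmatched_1=tuple(i for i in range(m1) if i not in matched1),
        unmatched_2=tuple(j for j in range(m2) if j not in matched2),
        total=total,
        gate=float(eps),
    )


def tracking_error(psi: TrackSet, phi_ref: TrackSet, eps: float) -> float:
    """Pairing distance per reference track per frame, in nm.

    ``phi_ref`` is the reference set (ground truth when available); the
    pairing distance is divided by N * M_ref so the result compares
    directly with per-frame localization scales such as the diffraction
    limit.
    """
    if phi_ref.n_tracks < 1:
        raise ValueError("reference track set is empty")
    res = pair_track_sets(psi, phi_ref, eps)
    return res.total / (psi.n_frames * phi_ref.n_tracks)


def dual_view_tracking_error(psi_view1: TrackSet, psi_view2: TrackSet) -> float:
    """Tracking error between two views of the same specimen, in nm.

    Both views are estimates of the same unknown tracks, so each carries
    half the discrepancy: the pairing distance (computed with an infinite
    gate — both views must supply complete tracks) is divided by
    ``2 * N * M``.  When the views disagree on the track count, M is taken
    as the mean of the two counts by convention.
    """
    if not (psi_view1.complete and psi_view2.complete):
        raise ValueError("dual-view comparison requires complete tracks in both views")
    res = pair_track_sets(psi_view1, psi_view2, np.inf)
    M = 0.5 * (psi_view1.n_tracks + psi_view2.n_tracks)
    if M == 0:
        raise ValueError("both track sets are empty")
    return res.total / (2.0 * psi_view1.n_frames * M)


def localization_resolution(psi: TrackSet, phi: TrackSet) -> float:
    """Mean distance under optimal per-frame pairing, ignoring identity.

    Positions present in each frame are paired by a per-frame minimum-total
    assignment without a gate, so mislinked but correctly localized tracks
    are not penalized.  Undefined (raises) when the two sets present
    different numbers of positions in any frame.  Equals the tracking error
    whenever there are no mislinks, false positives or false negatives;
    never exceeds it (frame-wise re-pairing relaxes the track-wise pairing).
    """
    if psi.n_frames != phi.n_frames:
        raise ValueError(f"frame axes differ: {psi.n_frames} vs {phi.n_frames}")
    pa, pb = _shared_coordinates(psi, phi)
    total, count = 0.0, 0
    for n in range(psi.n_frames):
        ia = np.flatnonzero(psi.present[:, n])
        ib = np.flatnonzero(phi.present[:, n])
        if ia.size != ib.size:
            raise ValueError(f"frame {n}: {ia.size} vs {ib.size} positions — localization resolution is undefined")
        if ia.size == 0:
            continue
        d = np.sqrt(np.sum((pa[ia, n][:, None, :] - pb[ib, n][None, :, :]) ** 2, axis=-1))
        r, c = linear_sum_assignment(d)
        total += float(d[r, c].sum())
        count += ia.size
    if count == 0:
        raise ValueError("no positions to compare")
    return total / count
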