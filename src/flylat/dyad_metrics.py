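"""Per-frame dyadic geometry: Distance, signed Position, unsigned Orientation.

For a focal fly A and its partner B on one frame:

* Distance — Euclidean distance between centroids (mm); symmetric.
* Position — signed angle from A's heading vector to the A->B centroid
  vector, wrapped to (-180, 180]. 0 means the partner is dead ahead of the
  focal fly, positive means the partner is on the focal fly's left, negative
  on its right; values near +/-180 mean the focal fly is in front of its
  partner. Position is focal-specific: the two members of a dyad have
  independent Position series.
* Orientation — unsigned circular difference of the two body headings, in
  [0, 180]: 0 when the flies are parallel, 180 when antiparallel; symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track_data import Track


@dataclass
class DyadSeries:
    """Per-frame dyadic geometry for one focal/partner pair.

    Arrays are aligned to the frames where *both* flies are tracked.
    ``valid`` marks frames where Position is defined (non-coincident
    centroids and a defined focal heading); Distance and Orientation are
    defined on every common frame.
    """

    focal_id: str
    partner_id: str
    frame: np.ndarray
    distance: np.ndarray
    position: np.ndarray  # NaN where invalid
    orientation: np.ndarray
    valid: np.ndarray


@dataclass
class PolarHistogram:
    """Normalized 2-D histogram on (angle, distance) bins."""

    angle_bin_edges: np.ndarray
    radius_bin_edges: np.ndarray
    density: np.ndarray  # shape (n_angle_bins, n_radius_bins), sums to 1
    n_frames: int

    @property
    def empty(self) -> bool:
        return self.n_frames == 0


def _common_frames(focal: Track, partner: Track):
    frames, ia, ib = np.intersect1d(focal.frame, partner.frame, return_indices=True)
    return frames, ia, ib


def wrap_signed(angle_deg: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180], mapping the -180 boundary to +180."""
    a = np.mod(np.asarray(angle_deg, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(a == -180.0, 180.0, a)


def dyad_distance(focal: Track, partner: Track) -> DyadSeries:
    """Centroid distance per common frame (Position/Orientation left NaN).

    Convenience wrapper over :func:`dyad_series` retained for callers that
    only need Distance; frames where either fly is untracked are absent.
    """
    return dyad_series(focal, partner, compute_angles=False)


def _heading_vectors(track: Track, idx: np.ndarray, source: str):
    """Unit heading vectors for selected row indices.

    ``source="body"`` uses the tracker's body-axis heading;
    ``source="displacement"`` uses the direction of the displacement
    arriving at the frame (previous frame -> current), undefined on the
    first frame, across gaps, or when stationary.
    """
    if source == "body":
        h = np.radians(track.heading[idx])
        return np.cos(h), np.sin(h), np.ones(len(idx), dtype=bool)
    if source == "displacement":
        dx = np.diff(track.x)
        dy = np.diff(track.y)
        contiguous = np.diff(track.frame) == 1
        norm = np.hypot(dx, dy)
        ok_step = contiguous & (norm > 0)
        ux = np.full(len(track), np.nan)
        uy = np.full(len(track), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux[1:] = np.where(ok_step, dx / np.where(norm > 0, norm, np.nan), np.nan)
            uy[1:] = np.where(ok_step, dy / np.where(norm > 0, norm, np.nan), np.nan)
        sel_ux, sel_uy = ux[idx], uy[idx]
        ok = np.isfinite(sel_ux)
        return sel_ux, sel_uy, ok
    raise ValueError(f"unknown heading_source {source!r}")


def dyad_series(
    focal: Track,
    partner: Track,
    heading_source: str = "body",
    compute_angles: bool = True,
) -> DyadSeries:
    """Full per-frame dyadic geometry for one focal/partner pair."""
    frames, ia, ib = _common_frames(focal, partner)
    dx = partner.x[ib] - focal.x[ia]
    dy = partner.y[ib] - focal.y[ia]
    dist = np.hypot(dx, dy)
    n = len(frames)
    if not compute_angles:
        nanarr = np.full(n, np.nan)
        return DyadSeries(
            focal.fly_id, partner.fly_id, frames, dist, nanarr.copy(), nanarr.copy(),
            np.zeros(n, dtype=bool),
        )
    hx, hy, h_ok = _heading_vectors(focal, ia, heading_source)
    valid = h_ok & (dist > 0)
    with np.errstate(invalid="ignore"):
        raw = np.degrees(np.arctan2(hx * dy - hy * dx, hx * dx + hy * dy))
    position = np.where(valid, wrap_signed(raw), np.nan)
    ori = circular_heading_difference(focal.heading[ia], partner.heading[ib])
    return DyadSeries(
        focal.fly_id, partner.fly_id, frames, dist, position, ori, valid
    )


def relative_position(
    focal: Track, partner: Track, heading_source: str = "body"
) -> np.ndarray:
    """Signed Position of the partner relative to the focal fly, per common frame.

    Positive: partner on the focal fly's left; negative: on its right; NaN
    where undefined (coincident centroids or undefined focal heading).
    """
    return dyad_series(focal, partner, heading_source).position


def relative_orientation(focal: Track, partner: Track) -> np.ndarray:
    """Unsigned heading difference in [0, 180] per common frame."""
    return dyad_series(focal, partner).orientation


def circular_heading_difference(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Unsigned circular difference of two heading series, degrees in [0, 180]."""
    d = np.abs(np.mod(np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float), 360.0))
    return np.minimum(d, 360.0 - d)


def position_side_bias(positions: np.ndarray) -> float:
    """Left/right occupancy bias (n_left - n_right) / (n_left + n_right).

    Left = Position > 0. Frames at exactly 0 or 180 degrees (dead ahead /
    dead behind, no side) and NaN frames are excluded. NaN when no sided
    frames remain.
    """
    p = np.asarray(positions, dtype=float)
    p = p[np.isfinite(p)]
    left = np.count_nonzero((p > 0) & (p < 180.0))
    right = np.count_nonzero(p < 0)
    total = left + right
    if total == 0:
        return np.nan
    return (left - right) / total


def polar_joint_density(
    angles: np.ndarray,
    distances: np.ndarray,
    angle_bins: np.ndarray | float = 5.0,
    radius_bins: np.ndarray | float = 1.0,
    max_radius: float = 25.4,
    angle_range: tuple[float, float] = (-180.0, 180.0),
) -> PolarHistogram:
    """Joint (angle, distance) occupancy as a normalized polar histogram.

    ``angle_bins``/``radius_bins`` may be bin widths (degrees / mm) or
    explicit edge arrays. Distances are capped at ``max_radius`` (arena
    diameter by default). NaN frames are dropped; an empty input yields an
    all-zero histogram flagged via ``n_frames = 0``.
    """
    a = np.asarray(angles, dtype=float)
    d = np.asarray(distances, dtype=float)
    ok = np.isfinite(a) & np.isfinite(d)
    a, d = a[ok], np.minimum(d[ok], max_radius)
    if np.isscalar(angle_bins):
        angle_edges = np.arange(angle_range[0], angle_range[1] + 1e-9, float(angle_bins))
    else:
        angle_edges = np.asarray(angle_bins, dtype=float)
    if np.isscalar(radius_bins):
        radius_edges = np.arange(0.0, max_radius + float(radius_bins), float(radius_bins))
    else:
        radius_edges = np.asarray(radius_bins, dtype=float)
    counts, _, _ = np.histogram2d(a, d, bins=[angle_edges, radius_edges])
    total = counts.sum()
    density = counts / total if total > 0 else counts
    return PolarHistogram(angle_edges, radius_edges, density, int(total))
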