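"""Per-fly asymmetry indices: circling (C) and wing use (W), plus velocity.

The circling index of a trajectory is the signed ratio

    C = sum(turn angles) / sum(|turn angles|),

where each turn angle is the signed angle between the displacement vector
arriving at a frame and the displacement vector leaving it, wrapped to
(-180, 180) degrees; anticlockwise deviations are positive, clockwise
negative. C = -1 means every deviation was clockwise, +1 every deviation
anticlockwise, and |C| measures the strength of the individual side
preference regardless of its direction.

The wing-use index is the analogous signed ratio of summed right-wing minus
left-wing opening degrees over total opening degrees: positive W means
predominantly right-wing use.

Undefined indices (no valid turns, no wing opening) propagate as NaN, never
as 0 — a zero would fake perfect symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track_data import Track

#: Default minimum displacement (mm) for a step to count toward a turn.
#: Roughly the tracking noise floor at 10 fps in a ~25 mm arena.
DEFAULT_MIN_STEP = 0.1


@dataclass
class TurnSeries:
    """Signed turn angles for one fly, one entry per interior frame triple.

    ``turn[i]`` is the angle between displacement (i -> i+1) and displacement
    (i+1 -> i+2); entries are NaN where ``valid`` is False (sub-threshold
    step, frame gap, or an exact 180-degree reversal, whose sign is
    undefined).
    """

    fly_id: str
    turn: np.ndarray
    valid: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def valid_turns(self) -> np.ndarray:
        return self.turn[self.valid]


@dataclass
class AsymmetryIndex:
    """A signed lateralization index in [-1, 1] with its absolute value.

    ``signed`` is NaN (undefined) when no events contributed; ``kind`` is
    ``"circling"`` or ``"wing"``.
    """

    fly_id: str
    signed: float
    absolute: float
    n_events: int
    kind: str

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.signed))


def signed_turn_angles(
    dx1: np.ndarray, dy1: np.ndarray, dx2: np.ndarray, dy2: np.ndarray
) -> np.ndarray:
    """Signed angle (degrees) from vector 1 to vector 2, in [-180, 180].

    Positive = anticlockwise. Vectorized over any matching shape.
    """
    cross = dx1 * dy2 - dy1 * dx2
    dot = dx1 * dx2 + dy1 * dy2
    return np.degrees(np.arctan2(cross, dot))


def compute_turn_series(track: Track, min_step: float = DEFAULT_MIN_STEP) -> TurnSeries:
    """Extract the signed turn-angle series from a track.

    A frame triple is invalid when either displacement is shorter than
    ``min_step``, when either step spans a gap in the frame numbering, or
    when the turn is an exact 180-degree reversal. Tracks shorter than three
    frames yield an empty series.
    """
    n = len(track)
    if n < 3:
        return TurnSeries(track.fly_id, np.empty(0), np.empty(0, dtype=bool))
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    step_len = np.hypot(dx, dy)
    contiguous = np.diff(track.frame) == 1
    # a zero-length displacement is directionless even at min_step = 0
    step_ok = contiguous & (step_len > 0) & (step_len >= min_step)
    turn = signed_turn_angles(dx[:-1], dy[:-1], dx[1:], dy[1:])
    valid = step_ok[:-1] & step_ok[1:] & (np.abs(turn) < 180.0)
    turn = np.where(valid, turn, np.nan)
    return TurnSeries(track.fly_id, turn, valid)


def circling_index(turns: TurnSeries) -> AsymmetryIndex:
    """Circling asymmetry C = sum(turns) / sum(|turns|) over valid entries.

    Negative C: clockwise preference; positive C: anticlockwise preference.
    Undefined (NaN) when there are no valid turns or the total magnitude
    is zero.
    """
    vals = turns.valid_turns()
    total = np.sum(np.abs(vals))
    if vals.size == 0 or total == 0:
        signed = np.nan
    else:
        signed = float(np.sum(vals) / total)
    return AsymmetryIndex(
        fly_id=turns.fly_id,
        signed=signed,
        absolute=abs(signed) if np.isfinite(signed) else np.nan,
        n_events=turns.n_valid,
        kind="circling",
    )


def circling_from_positions(
    x: np.ndarray, y: np.ndarray, min_step: float = DEFAULT_MIN_STEP
) -> np.ndarray:
    """Batch circling index for gap-free position arrays of shape (n_flies, n_frames).

    Fast path for simulation studies; agrees with the per-Track route
    (:func:`compute_turn_series` + :func:`circling_index`) exactly on
    contiguous tracks.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    dx = np.diff(x, axis=1)
    dy = np.diff(y, axis=1)
    step_len = np.hypot(dx, dy)
    step_ok = (step_len > 0) & (step_len >= min_step)
    turn = signed_turn_angles(dx[:, :-1], dy[:, :-1], dx[:, 1:], dy[:, 1:])
    valid = step_ok[:, :-1] & step_ok[:, 1:] & (np.abs(turn) < 180.0)
    turn = np.where(valid, turn, 0.0)
    num = np.sum(turn, axis=1)
    den = np.sum(np.abs(turn), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def wing_signed_sums(
    track: Track, min_open: float = 0.0
) -> tuple[float, float, int]:
    """Summed right- and left-wing opening degrees over threshold.

    Returns ``(sum_right, sum_left, n_events)`` where ``n_events`` counts
    frames contributing a positive amount to either sum. Openings below
    ``min_open`` (or exactly zero) are ignored.
    """
    wr = np.nan_to_num(track.wing_right, nan=0.0)
    wl = np.nan_to_num(track.wing_left, nan=0.0)
    mask_r = (wr >= min_open) & (wr > 0)
    mask_l = (wl >= min_open) & (wl > 0)
    sum_right = float(np.sum(wr[mask_r]))
    sum_left = float(np.sum(wl[mask_l]))
    n_events = int(np.count_nonzero(mask_r | mask_l))
    return sum_right, sum_left, n_events


def wing_index(
    sums: tuple[float, float, int], fly_id: str = ""
) -> AsymmetryIndex:
    """Wing-use asymmetry W = (right - left) / (right + left).

    Positive W: predominantly right-wing use. Undefined (NaN) when the fly
    never opened a wing.
    """
    sum_right, sum_left, n_events = sums
    total = sum_right + sum_left
    signed = (sum_right - sum_left) / total if total > 0 else np.nan
    return AsymmetryIndex(
        fly_id=fly_id,
        signed=float(signed) if np.isfinite(signed) else np.nan,
        absolute=abs(signed) if np.isfinite(signed) else np.nan,
        n_events=n_events,
        kind="wing",
    )


@dataclass
class VelocitySeries:
    """Per-frame speed (mm/s) with validity mask and trial mean."""

    fly_id: str
    speed: np.ndarray  # length len(track)-1, NaN across gaps
    valid: np.ndarray

    @property
    def mean(self) -> float:
        if not np.any(self.valid):
            return np.nan
        return float(np.mean(self.speed[self.valid]))


def velocity_series(track: Track) -> VelocitySeries:
    """Frame-to-frame speed; steps across tracking gaps are excluded."""
    n = len(track)
    if n < 2:
        return VelocitySeries(track.fly_id, np.empty(0), np.empty(0, dtype=bool))
    disp = np.hypot(np.diff(track.x), np.diff(track.y))
    dt = np.diff(track.t)
    valid = (np.diff(track.frame) == 1) & (dt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = np.where(valid, disp / np.where(dt > 0, dt, np.nan), np.nan)
    return VelocitySeries(track.fly_id, speed, valid)


def windowed_index_series(
    track: Track,
    window_s: float = 600.0,
    min_step: float = DEFAULT_MIN_STEP,
) -> list[AsymmetryIndex]:
    """Circling index per non-overlapping time window (stability check).

    Windows with no valid turns yield NaN indices.
    """
    out: list[AsymmetryIndex] = []
    if len(track) == 0:
        return out
    t0 = track.t[0]
    n_win = int(np.ceil((track.t[-1] - t0 + 1e-12) / window_s))
    for k in range(max(n_win, 1)):
        sel = (track.t >= t0 + k * window_s) & (track.t < t0 + (k + 1) * window_s)
        sub = Track(
            fly_id=f"{track.fly_id}:w{k}",
            frame=track.frame[sel],
            t=track.t[sel],
            x=track.x[sel],
            y=track.y[sel],
            heading=track.heading[sel],
            wing_left=track.wing_left[sel],
            wing_right=track.wing_right[sel],
        )
        out.append(circling_index(compute_turn_series(sub, min_step)))
    return out
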