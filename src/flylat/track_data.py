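"""Canonical data model and I/O for per-frame fly tracking tables.

A :class:`Track` holds one fly's kinematic record: centroid position in mm,
body heading in degrees, and the opening angle of each wing relative to the
body midline. The internal coordinate convention is mathematical: y axis up,
angles in degrees measured counter-clockwise-positive, headings in [0, 360).
Files produced by image-based trackers (pixel origin top-left, y down) must
be read with ``convention="y-down"``, which negates y and reflects headings
so that all downstream sign conventions (clockwise turns negative, partner
on the right negative) hold in one frame.

The on-disk format is tidy CSV, one row per fly per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, DataError, SchemaError

logger = logging.getLogger(__name__)

TRACK_COLUMNS = [
    "fly_id",
    "frame",
    "t",
    "x_mm",
    "y_mm",
    "heading_deg",
    "wing_left_deg",
    "wing_right_deg",
]

META_COLUMNS = ["fly_id", "arena_id", "strain", "sex", "context", "partner_id"]

#: Social contexts: single female/male, and the three dyad kinds.
SOLO_CONTEXTS = ("F", "M")
DYAD_CONTEXTS = ("FF", "MM", "FM")

STRAINS = ("RAL-69", "RAL-136", "RAL-338", "RAL-535", "RAL-796")


@dataclass
class ArenaConfig:
    """Circular arena and recording parameters.

    Defaults match a 2.54 cm arena filmed at 10 frames/s for 60 minutes
    (36,000 frames).
    """

    diameter: float = 25.4  # mm
    fps: float = 10.0  # Hz
    duration: float = 3600.0  # s

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ConfigError(f"arena diameter must be > 0, got {self.diameter}")
        if self.fps <= 0:
            raise ConfigError(f"fps must be > 0, got {self.fps}")
        n = self.duration * self.fps
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ConfigError(
                f"duration * fps must give a positive integer frame count, got {n}"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class Track:
    """One fly's per-frame kinematic record.

    All arrays share one length and are aligned by ``frame``. Frames must be
    strictly increasing; gaps (dropped frames) are permitted and are treated
    as breaks by downstream turn/velocity computations.
    """

    fly_id: str
    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    wing_left: np.ndarray
    wing_right: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        for name in ("t", "x", "y", "heading", "wing_left", "wing_right"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.frame)
        for name in ("t", "x", "y", "heading", "wing_left", "wing_right"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{self.fly_id}: field {name!r} length mismatch")
        if n > 1 and not np.all(np.diff(self.frame) > 0):
            bad = int(self.frame[np.where(np.diff(self.frame) <= 0)[0][0] + 1])
            raise DataError(
                f"{self.fly_id}: frames not strictly increasing at frame {bad}"
            )
        wl, wr = self.wing_left, self.wing_right
        for name, w in (("wing_left", wl), ("wing_right", wr)):
            finite = np.isfinite(w)
            if np.any((w[finite] < 0) | (w[finite] > 180)):
                raise DataError(f"{self.fly_id}: {name} outside [0, 180] degrees")

    def __len__(self) -> int:
        return len(self.frame)

    def in_arena(self, arena: ArenaConfig, center: tuple[float, float] = (0.0, 0.0)) -> bool:
        """True when every centroid lies within the arena disk (1e-6 mm slack)."""
        r2 = (self.x - center[0]) ** 2 + (self.y - center[1]) ** 2
        return bool(np.all(r2 <= arena.radius**2 + 1e-6))


@dataclass
class FlyMeta:
    """Experimental-design labels for one fly."""

    fly_id: str
    arena_id: str
    strain: str
    sex: str  # {F, M}
    context: str  # {F, M, FF, MM, FM}
    partner_id: str = ""  # empty for single flies

    def __post_init__(self) -> None:
        if self.context in SOLO_CONTEXTS and self.partner_id:
            raise ConsistencyError(
                f"{self.fly_id}: single-fly context {self.context!r} with partner_id set"
            )
        if self.context in DYAD_CONTEXTS and not self.partner_id:
            raise ConsistencyError(
                f"{self.fly_id}: dyad context {self.context!r} without partner_id"
            )
        expected = {"F": "F", "M": "M", "FF": "F", "MM": "M"}.get(self.context)
        if expected is not None and self.sex != expected:
            raise ConsistencyError(
                f"{self.fly_id}: sex {self.sex!r} inconsistent with context {self.context!r}"
            )
        if self.sex not in ("F", "M"):
            raise ConsistencyError(f"{self.fly_id}: unknown sex {self.sex!r}")

    @property
    def is_dyad(self) -> bool:
        return self.context in DYAD_CONTEXTS


def _reflect_heading(heading: np.ndarray) -> np.ndarray:
    """Heading after negating the y axis (mirror about x)."""
    return np.mod(-heading, 360.0)


def read_tracks(path: str | Path, convention: str = "y-up") -> dict[str, Track]:
    """Read a tidy tracks CSV into one :class:`Track` per fly.

    Parameters
    ----------
    path
        CSV with columns ``fly_id, frame, t, x_mm, y_mm, heading_deg,
        wing_left_deg, wing_right_deg``.
    convention
        ``"y-up"`` for files already in the mathematical frame, ``"y-down"``
        for image-origin files; the latter negates y and reflects headings so
        that internally angles are counter-clockwise-positive.
    """
    if convention not in ("y-up", "y-down"):
        raise ConfigError(f"unknown coordinate convention {convention!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    tracks: dict[str, Track] = {}
    for fly_id, g in df.groupby("fly_id", sort=False):
        y = g["y_mm"].to_numpy(dtype=float)
        heading = g["heading_deg"].to_numpy(dtype=float)
        if convention == "y-down":
            y = -y
            heading = _reflect_heading(heading)
        tracks[str(fly_id)] = Track(
            fly_id=str(fly_id),
            frame=g["frame"].to_numpy(),
            t=g["t"].to_numpy(dtype=float),
            x=g["x_mm"].to_numpy(dtype=float),
            y=y,
            heading=heading,
            wing_left=g["wing_left_deg"].to_numpy(dtype=float),
            wing_right=g["wing_right_deg"].to_numpy(dtype=float),
        )
    return tracks


def write_tracks(tracks: dict[str, Track] | list[Track], path: str | Path) -> None:
    """Write Tracks as canonical tidy CSV (y-up convention).

    Round-trips bit-exactly through :func:`read_tracks` on the canonical
    dialect. Refuses non-finite coordinates, naming the offending fly/frame.
    """
    if isinstance(tracks, dict):
        tracks = list(tracks.values())
    frames = []
    for tr in tracks:
        bad = ~(np.isfinite(tr.x) & np.isfinite(tr.y))
        if np.any(bad):
            f = int(tr.frame[np.where(bad)[0][0]])
            raise DataError(f"{tr.fly_id}: non-finite coordinate at frame {f}")
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": tr.fly_id,
                    "frame": tr.frame,
                    "t": tr.t,
                    "x_mm": tr.x,
                    "y_mm": tr.y,
                    "heading_deg": tr.heading,
                    "wing_left_deg": tr.wing_left,
                    "wing_right_deg": tr.wing_right,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=TRACK_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_metadata(path: str | Path) -> dict[str, FlyMeta]:
    """Read per-fly metadata, validating partner symmetry and sex/context.

    Logs the number of flies per (strain, sex, context) design cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if df["fly_id"].duplicated().any():
        dup = df.loc[df["fly_id"].duplicated(), "fly_id"].iloc[0]
        raise DataError(f"{path}: duplicate fly_id {dup!r}")
    meta = {
        str(r.fly_id): FlyMeta(
            fly_id=str(r.fly_id),
            arena_id=str(r.arena_id),
            strain=str(r.strain),
            sex=str(r.sex),
            context=str(r.context),
            partner_id=str(r.partner_id),
        )
        for r in df.itertuples(index=False)
    }
    validate_partner_symmetry(meta)
    counts = df.groupby(["strain", "sex", "context"]).size()
    logger.info("metadata design cells:\n%s", counts.to_string())
    return meta


def validate_partner_symmetry(meta: dict[str, FlyMeta]) -> None:
    """Every dyad link must be mutual: A's partner is B and B's partner is A."""
    offending = []
    for fid, m in meta.items():
        if not m.partner_id:
            continue
        p = meta.get(m.partner_id)
        if p is None or p.partner_id != fid:
            offending.append((fid, m.partner_id))
    if offending:
        pairs = "; ".join(f"{a}->{b}" for a, b in offending)
        raise ConsistencyError(f"asymmetric partner links: {pairs}")


def write_metadata(meta: dict[str, FlyMeta] | list[FlyMeta], path: str | Path) -> None:
    """Write metadata as canonical CSV."""
    if isinstance(meta, dict):
        meta = list(meta.values())
    out = pd.DataFrame(
        [
            {
                "fly_id": m.fly_id,
                "arena_id": m.arena_id,
                "strain": m.strain,
                "sex": m.sex,
                "context": m.context,
                "partner_id": m.partner_id,
            }
            for m in meta
        ],
        columns=META_COLUMNS,
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
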