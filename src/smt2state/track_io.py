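"""Track and cell-outline tables: reading, writing, filtering, pre-processing.

Track tables are plain CSV with header ``track_id,frame,x_um,y_um[,cell_id]``;
cell outlines are CSV with header
``cell_id,center_x_um,center_y_um,orientation_rad,length_um,width_um``.
Coordinates are in micrometres with an arbitrary per-field-of-view origin;
frame indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    ArgumentError,
    DegenerateInputError,
    TrackFormatError,
    TrackValidationError,
)

TRACK_COLUMNS = ("track_id", "frame", "x_um", "y_um")
OUTLINE_COLUMNS = (
    "cell_id",
    "center_x_um",
    "center_y_um",
    "orientation_rad",
    "length_um",
    "width_um",
)


@dataclass(frozen=True)
class Detection:
    """A single localization: frame index and position in µm."""

    frame: int
    x: float
    y: float
    cell_id: str | None = None

    def __post_init__(self):
        if self.frame < 0:
            raise ArgumentError(f"frame must be >= 0, got {self.frame}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ArgumentError(f"non-finite coordinates ({self.x}, {self.y})")


@dataclass
class Track:
    """An ordered trajectory of detections with strictly increasing frames."""

    track_id: int | str
    detections: list[Detection]

    def __post_init__(self):
        if len(self.detections) < 1:
            raise ArgumentError(f"track {self.track_id} has no detections")
        frames = [d.frame for d in self.detections]
        for a, b in zip(frames, frames[1:]):
            if b <= a:
                raise TrackValidationError(
                    f"track {self.track_id}: frames not strictly increasing "
                    f"({a} then {b})"
                )

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in µm."""
        return np.array([(d.x, d.y) for d in self.detections], dtype=float)


@dataclass
class TrackSet:
    """A collection of tracks plus acquisition metadata.

    frame_interval is Δt in seconds (default 20 ms stream acquisition);
    localization_precision is the per-axis localization sd σ in µm.
    """

    tracks: list[Track]
    frame_interval: float = 0.02
    localization_precision: float = 0.04
    condition: str = ""

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ArgumentError("frame_interval must be > 0")
        if self.localization_precision < 0:
            raise ArgumentError("localization_precision must be >= 0")

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def n_detections(self) -> int:
        return sum(len(t) for t in self.tracks)


@dataclass(frozen=True)
class CellOutline:
    """Spherocylinder cell parameterization: pole-to-pole length L and width W."""

    cell_id: int | str
    center: tuple[float, float]
    orientation: float
    length: float
    width: float

    def __post_init__(self):
        if not (self.length >= self.width > 0):
            raise ArgumentError(
                f"cell {self.cell_id}: need length >= width > 0, "
                f"got L={self.length}, W={self.width}"
            )


STANDARD_CELL = CellOutline("standard", (0.0, 0.0), 0.0, 3.0, 1.0)


# ---------------------------------------------------------------------------
# Readers / writers


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise TrackFormatError(f"{path}: missing required column '{col}'")


def read_tracks(
    path,
    frame_interval: float = 0.02,
    precision: float = 0.04,
    condition: str = "",
) -> TrackSet:
    """Read a track-table CSV into a TrackSet.

    Rows are grouped by ``track_id``; within a track, frames must be
    strictly increasing in file order (duplicates or reversals raise
    TrackValidationError naming the offending track).
    """
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, path)
    has_cell = "cell_id" in df.columns
    tracks: list[Track] = []
    for tid, g in df.groupby("track_id", sort=False):
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise TrackValidationError(
                f"{path}: track {tid} has non-monotone or duplicated frames"
            )
        dets = [
            Detection(
                frame=int(r.frame),
                x=float(r.x_um),
                y=float(r.y_um),
                cell_id=str(r.cell_id) if has_cell and not pd.isna(r.cell_id) else None,
            )
            for r in g.itertuples()
        ]
        tracks.append(Track(track_id=tid, detections=dets))
    return TrackSet(
        tracks=tracks,
        frame_interval=frame_interval,
        localization_precision=precision,
        condition=condition,
    )


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet as a track-table CSV (coordinates to 6 decimals)."""
    rows = []
    any_cell = any(d.cell_id is not None for t in ts.tracks for d in t.detections)
    for t in ts.tracks:
        for d in t.detections:
            row = {"track_id": t.track_id, "frame": d.frame, "x_um": d.x, "y_um": d.y}
            if any_cell:
                row["cell_id"] = d.cell_id if d.cell_id is not None else ""
            rows.append(row)
    cols = list(TRACK_COLUMNS) + (["cell_id"] if any_cell else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")


def read_outlines(path) -> list[CellOutline]:
    df = pd.read_csv(path)
    _require_columns(df, OUTLINE_COLUMNS, path)
    return [
        CellOutline(
            cell_id=r.cell_id,
            center=(float(r.center_x_um), float(r.center_y_um)),
            orientation=float(r.orientation_rad),
            length=float(r.length_um),
            width=float(r.width_um),
        )
        for r in df.itertuples()
    ]


def write_outlines(outlines: list[CellOutline], path) -> None:
    rows = [
        {
            "cell_id": c.cell_id,
            "center_x_um": c.center[0],
            "center_y_um": c.center[1],
            "orientation_rad": c.orientation,
            "length_um": c.length,
            "width_um": c.width,
        }
        for c in outlines
    ]
    pd.DataFrame(rows, columns=list(OUTLINE_COLUMNS)).to_csv(
        path, index=False, float_format="%.6f"
    )


# ---------------------------------------------------------------------------
# Pre-processing


def filter_min_length(ts: TrackSet, min_frames: int = 5) -> TrackSet:
    """Keep only tracks with at least ``min_frames`` detections (order preserved).

    The default of 5 detections (4 displacement steps) matches the
    minimum-track-length rule applied by the upstream tracking tools.
    """
    if min_frames < 2:
        raise ArgumentError(f"min_frames must be >= 2, got {min_frames}")
    return replace(ts, tracks=[t for t in ts.tracks if len(t) >= min_frames])


def crop_to_single_molecule(movie_length: int, keep: int = 2001) -> tuple[int, int]:
    """Trailing window of ``keep`` frames as inclusive 0-based (first, last).

    Initial frames of a stream acquisition are above the single-molecule
    level; the analysis keeps only the last ``keep`` frames.
    """
    if keep > movie_length:
        raise ArgumentError(
            f"cannot keep {keep} frames of a {movie_length}-frame movie"
        )
    if keep < 1:
        raise ArgumentError("keep must be >= 1")
    return movie_length - keep, movie_length - 1


def estimate_onset_from_decay(counts_per_frame) -> int:
    """Frame index where the per-frame spot count decays to single-molecule level.

    Fits N(t) = A·exp(−t/τ) + B by least squares and returns the smallest
    frame t with fitted N(t) <= B + 1. Diagnostic companion to
    :func:`crop_to_single_molecule`.
    """
    counts = np.asarray(counts_per_frame, dtype=float)
    if counts.size == 0:
        raise ArgumentError("empty counts sequence")
    if np.any(counts < 0):
        raise ArgumentError("counts must be non-negative")
    if not np.any(counts > 0):
        raise DegenerateInputError("all-zero counts: no decay to fit")
    if counts.max() == counts.min():
        return 0

    t = np.arange(counts.size, dtype=float)

    def model(t, a, tau, b):
        return a * np.exp(-t / tau) + b

    a0 = max(counts.max() - counts.min(), 1e-6)
    p0 = (a0, max(counts.size / 5.0, 1.0), counts.min())
    try:
        popt, _ = curve_fit(
            model,
            t,
            counts,
            p0=p0,
            bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise DegenerateInputError(f"decay fit failed: {exc}") from exc
    a, tau, b = popt
    if a <= 1.0:
        return 0
    onset = int(np.ceil(tau * np.log(a)))
    return int(np.clip(onset, 0, counts.size - 1))


def link_detections(
    detections: list[Detection], max_radius: float, max_gap: int = 0
) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Plumbing replacement for a full tracking package, intended for synthetic
    fixtures only: per frame, candidate (track end, detection) pairs within
    ``max_radius`` are assigned in order of increasing distance (ties broken
    toward the smaller track id); unassigned detections open new tracks.
    Single-detection tracks are returned as-is.
    """
    if max_radius <= 0:
        raise ArgumentError("max_radius must be > 0")
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)

    open_tracks: list[list[Detection]] = []  # index == track_id
    for frame in sorted(by_frame):
        dets = by_frame[frame]
        candidates = []
        for tid, tdets in enumerate(open_tracks):
            last = tdets[-1]
            if frame - last.frame > max_gap + 1 or frame <= last.frame:
                continue
            for di, d in enumerate(dets):
                dist = math.hypot(d.x - last.x, d.y - last.y)
                if dist <= max_radius:
                    candidates.append((dist, tid, di))
        candidates.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tid, di in candidates:
            if tid in used_tracks or di in used_dets:
                continue
            open_tracks[tid].append(dets[di])
            used_tracks.add(tid)
            used_dets.add(di)
        for di, d in enumerate(dets):
            if di not in used_dets:
                open_tracks.append([d])
    return [Track(track_id=tid, detections=dets) for tid, dets in enumerate(open_tracks)]
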