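"""Standardized-cell localization maps and zone statistics.

Localizations from many differently sized and oriented cells are projected
into one standardized rod cell (3 × 1 µm) via per-cell normalized
coordinates: x_rel along the long axis (±1 at the poles), y_rel along the
short axis. Probability heat maps, optionally folded by the cell's two
mirror symmetries, and septal/lateral/polar zone fractions quantify the
localization patterns and their condition-dependent shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, EmptySampleError
from .track_io import CellOutline, Detection, TrackSet

#: margin (µm) by which the outline is dilated before rejecting points
DILATION_UM = 0.2
#: relative-coordinate clamp applied before rejection
CLAMP_REL = 1.05

SEPTAL_MAX = 0.2
POLAR_MIN = 0.8


@dataclass(frozen=True)
class RelativeLocalization:
    x_rel: float  # long axis, ±1 at poles
    y_rel: float  # short axis
    weight: float = 1.0


@dataclass
class HeatMap:
    """Probability grid over the standardized cell; probs sum to 1."""

    probs: np.ndarray  # shape (nx, ny)
    counts: np.ndarray
    symmetrized: bool
    extent: tuple = (-1.0, 1.0, -1.0, 1.0)


@dataclass
class ZoneStats:
    fractions: dict[str, float]  # septal / lateral / polar, sum to 1
    counts: dict[str, int]
    n: int


class OutsideCellError(ArgumentError):
    """Localization falls outside the dilated cell outline."""


def _to_cell_frame(d: Detection, c: CellOutline) -> tuple[float, float]:
    ct, st = math.cos(c.orientation), math.sin(c.orientation)
    dx, dy = d.x - c.center[0], d.y - c.center[1]
    return ct * dx + st * dy, -st * dx + ct * dy


def normalize_localization(d: Detection, c: CellOutline) -> RelativeLocalization:
    """Map a detection into standardized-cell coordinates.

    Rotates by −orientation, translates by −center, then scales each axis to
    [−1, 1]. Points within the outline dilated by ``DILATION_UM`` are clamped
    to the unit box; farther points raise :class:`OutsideCellError`.
    """
    xp, yp = _to_cell_frame(d, c)
    x_rel = 2.0 * xp / c.length
    y_rel = 2.0 * yp / c.width
    if (
        abs(xp) > c.length / 2.0 + DILATION_UM
        or abs(yp) > c.width / 2.0 + DILATION_UM
        or abs(x_rel) > CLAMP_REL
        or abs(y_rel) > CLAMP_REL
    ):
        raise OutsideCellError(
            f"point ({d.x:.3f}, {d.y:.3f}) outside dilated outline of cell {c.cell_id}"
        )
    return RelativeLocalization(
        x_rel=float(np.clip(x_rel, -1.0, 1.0)),
        y_rel=float(np.clip(y_rel, -1.0, 1.0)),
    )


def denormalize_localization(
    loc: RelativeLocalization, c: CellOutline, frame: int = 0
) -> Detection:
    """Inverse of :func:`normalize_localization` for interior points."""
    xp = loc.x_rel * c.length / 2.0
    yp = loc.y_rel * c.width / 2.0
    ct, st = math.cos(c.orientation), math.sin(c.orientation)
    return Detection(
        frame=frame,
        x=ct * xp - st * yp + c.center[0],
        y=st * xp + ct * yp + c.center[1],
        cell_id=str(c.cell_id),
    )


def normalize_trackset(
    ts: TrackSet, outlines: list[CellOutline] | CellOutline
) -> tuple[list[RelativeLocalization], int]:
    """Normalize every detection of every track; returns (locs, n_rejected).

    With a list of outlines, each detection is matched to its outline by
    ``cell_id``; a single outline is applied to all detections. Detections
    outside the dilated outline are dropped and counted.
    """
    if isinstance(outlines, CellOutline):
        lookup = None
        single = outlines
    else:
        lookup = {str(c.cell_id): c for c in outlines}
        single = None
    locs: list[RelativeLocalization] = []
    rejected = 0
    for t in ts.tracks:
        for d in t.detections:
            if single is not None:
                c = single
            else:
                c = lookup.get(str(d.cell_id)) if d.cell_id is not None else None
                if c is None:
                    rejected += 1
                    continue
            try:
                locs.append(normalize_localization(d, c))
            except OutsideCellError:
                rejected += 1
    return locs, rejected


def build_heatmap(
    locs: list[RelativeLocalization],
    bins: tuple[int, int] = (60, 20),
    symmetrize: bool = True,
) -> HeatMap:
    """2-D probability histogram over the standardized cell.

    With ``symmetrize`` each count also contributes to its three mirror
    images (reflection about both axes), since a rod cell population has no
    intrinsic left/right or up/down labeling; the folded map is exactly
    invariant under both reflections.
    """
    if not locs:
        raise EmptySampleError("no localizations to map")
    x = np.array([l.x_rel for l in locs])
    y = np.array([l.y_rel for l in locs])
    w = np.array([l.weight for l in locs])
    counts, _, _ = np.histogram2d(
        x, y, bins=bins, range=[[-1.0, 1.0], [-1.0, 1.0]], weights=w
    )
    if symmetrize:
        counts = counts + counts[::-1, :] + counts[:, ::-1] + counts[::-1, ::-1]
    probs = counts / counts.sum()
    return HeatMap(probs=probs, counts=counts, symmetrized=symmetrize)


def zone_fractions(
    locs: list[RelativeLocalization],
    septal_max: float = SEPTAL_MAX,
    polar_min: float = POLAR_MIN,
) -> ZoneStats:
    """Septal (|x_rel| < septal_max) / polar (|x_rel| > polar_min) / lateral split."""
    if not locs:
        raise EmptySampleError("no localizations")
    if not (0.0 < septal_max < polar_min < 1.0):
        raise ArgumentError("need 0 < septal_max < polar_min < 1")
    ax = np.abs(np.array([l.x_rel for l in locs]))
    septal = int(np.sum(ax < septal_max))
    polar = int(np.sum(ax > polar_min))
    lateral = ax.size - septal - polar
    n = ax.size
    return ZoneStats(
        fractions={
            "septal": septal / n,
            "lateral": lateral / n,
            "polar": polar / n,
        },
        counts={"septal": septal, "lateral": lateral, "polar": polar},
        n=n,
    )
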