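"""Synthetic two-state switching-diffusion trajectories on a rod-cell membrane.

Generates TrackSets with the statistical structure the downstream analysis
assumes: molecules alternate between a slow (substrate-engaged) and a fast
(freely diffusive) state, diffuse in the 2-D projection of a spherocylinder
cell with reflective boundaries, are observed with Gaussian localization
error, and disappear by fluorophore bleaching. Ground truth (hidden states,
slow-state segments, noiseless positions) is returned alongside for use as
an oracle in recovery tests.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ArgumentError
from .track_io import STANDARD_CELL, CellOutline, Detection, Track, TrackSet

SLOW, FAST = 0, 1
ZONES = ("septal", "lateral", "polar")

#: |x_rel| boundaries separating septal / lateral / polar zones
ZONE_SEPTAL_MAX = 0.2
ZONE_POLAR_MIN = 0.8


@dataclass
class SimConfig:
    """Full specification of the two-state generative model.

    ``f_slow`` is the stationary slow-state occupancy. When
    ``mean_state_dwell_fast`` is None (default) it is derived from
    ``mean_state_dwell_slow`` so that the discretized two-state chain is
    exactly stationary at ``f_slow``; an explicit value overrides this (and
    the occupancy then follows from the two dwell times instead).

    ``confine=False`` disables the reflective boundary (initial positions are
    still drawn inside the cell). Confinement suppresses the apparent fast-state
    coefficient in a 1 µm-wide cell, so parameter-recovery experiments that
    check the fitter against the configured D use the unconfined variant.
    """

    D_slow: float = 0.08
    D_fast: float = 0.57
    f_slow: float = 0.5
    mean_state_dwell_slow: float = 0.5
    mean_state_dwell_fast: float | None = None
    frame_interval: float = 0.02
    localization_precision: float = 0.04
    bleach_half_life: float = 1.2
    n_tracks: int = 1000
    max_frames_per_track: int = 300
    cell: CellOutline = field(default_factory=lambda: STANDARD_CELL)
    confine: bool = True
    zone_bias: dict[str, tuple[float, float, float]] | None = None
    condition: str = ""
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.f_slow <= 1.0):
            raise ArgumentError(f"f_slow must be in [0, 1], got {self.f_slow}")
        if not (self.D_fast >= self.D_slow >= 0.0):
            raise ArgumentError("need D_fast >= D_slow >= 0")
        for name in ("mean_state_dwell_slow", "frame_interval", "bleach_half_life"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be > 0")
        if self.mean_state_dwell_fast is not None and self.mean_state_dwell_fast <= 0:
            raise ArgumentError("mean_state_dwell_fast must be > 0")
        if self.localization_precision < 0:
            raise ArgumentError("localization_precision must be >= 0")
        if self.n_tracks < 1 or self.max_frames_per_track < 2:
            raise ArgumentError("need n_tracks >= 1 and max_frames_per_track >= 2")
        if self.zone_bias is not None:
            for state, w in self.zone_bias.items():
                if state not in ("slow", "fast"):
                    raise ArgumentError(f"unknown zone_bias state '{state}'")
                if len(w) != 3 or min(w) < 0 or sum(w) <= 0:
                    raise ArgumentError("zone_bias weights must be 3 non-negative values")

    def switch_probabilities(self) -> tuple[float, float]:
        """Per-frame (slow→fast, fast→slow) switching probabilities."""
        if self.f_slow >= 1.0:
            return 0.0, 1.0
        if self.f_slow <= 0.0:
            return 1.0, 0.0
        p_sf = 1.0 - math.exp(-self.frame_interval / self.mean_state_dwell_slow)
        if self.mean_state_dwell_fast is None:
            # detailed balance: f_slow·p_sf = (1−f_slow)·p_fs
            p_fs = min(1.0, p_sf * self.f_slow / (1.0 - self.f_slow))
        else:
            p_fs = 1.0 - math.exp(-self.frame_interval / self.mean_state_dwell_fast)
        return p_sf, p_fs


@dataclass
class GroundTruth:
    """Hidden truth underlying a simulated TrackSet (oracle for recovery tests)."""

    states: dict = field(default_factory=dict)  # track_id -> int array, per frame
    true_xy: dict = field(default_factory=dict)  # track_id -> (n, 2) noiseless µm
    slow_segments: list = field(default_factory=list)  # (track_id, start_idx, n_frames)

    def slow_step_fraction(self) -> float:
        """Fraction of displacement steps whose starting state is slow."""
        n_slow = n_tot = 0
        for s in self.states.values():
            if len(s) < 2:
                continue
            n_slow += int(np.sum(s[:-1] == SLOW))
            n_tot += len(s) - 1
        if n_tot == 0:
            raise ArgumentError("no steps in ground truth")
        return n_slow / n_tot

    def slow_frame_fraction(self) -> float:
        n_slow = sum(int(np.sum(s == SLOW)) for s in self.states.values())
        n_tot = sum(len(s) for s in self.states.values())
        return n_slow / n_tot


# ---------------------------------------------------------------------------
# Spherocylinder geometry (cell frame: centered, long axis along x)


def _inside(x: float, y: float, half_len: float, radius: float) -> bool:
    if abs(x) <= half_len:
        return abs(y) <= radius
    return (abs(x) - half_len) ** 2 + y * y <= radius * radius


def _reflect(x: float, y: float, half_len: float, radius: float) -> tuple[float, float]:
    """Reflect a point back into the spherocylinder (mirror at the boundary)."""
    for _ in range(64):
        if _inside(x, y, half_len, radius):
            return x, y
        if abs(x) <= half_len:
            y = math.copysign(2.0 * radius - abs(y), y)
        else:
            cx = math.copysign(half_len, x)
            vx, vy = x - cx, y
            rho = math.hypot(vx, vy)
            if rho == 0.0:
                return x, y
            scale = (2.0 * radius - rho) / rho
            x, y = cx + vx * scale, vy * scale
    # pathological step size: clamp radially toward the nearest cap center
    cx = math.copysign(half_len, x) if abs(x) > half_len else 0.0
    vx, vy = x - cx, y
    rho = math.hypot(vx, vy)
    return cx + vx * radius / rho, vy * radius / rho


def _zone_of(x: float, half_total: float) -> int:
    x_rel = abs(x) / half_total
    if x_rel < ZONE_SEPTAL_MAX:
        return 0
    if x_rel > ZONE_POLAR_MIN:
        return 2
    return 1


def _sample_initial(rng, cell: CellOutline, weights) -> tuple[float, float]:
    """Uniform point in the 2-D projected outline, optionally zone-weighted."""
    half_len = (cell.length - cell.width) / 2.0
    radius = cell.width / 2.0
    half_total = cell.length / 2.0
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        zone = int(rng.choice(3, p=w / w.sum()))
    else:
        zone = None
    for _ in range(100000):
        x = rng.uniform(-half_total, half_total)
        y = rng.uniform(-radius, radius)
        if not _inside(x, y, half_len, radius):
            continue
        if zone is None or _zone_of(x, half_total) == zone:
            return x, y
    raise ArgumentError("initial-position sampling failed (empty zone?)")


# ---------------------------------------------------------------------------


def _simulate_track(rng, cfg: SimConfig, p_sf: float, p_fs: float):
    """One molecule: returns (true_xy, obs_xy, states) or None if bleached early."""
    dt = cfg.frame_interval
    half_len = (cfg.cell.length - cfg.cell.width) / 2.0
    radius = cfg.cell.width / 2.0
    # bleaching: geometric lifetime, per-frame survival 2^(−Δt/half_life)
    p_surv = 2.0 ** (-dt / cfg.bleach_half_life)
    n_frames = min(int(rng.geometric(1.0 - p_surv)), cfg.max_frames_per_track)
    if n_frames < 2:
        return None

    state = SLOW if rng.random() < cfg.f_slow else FAST
    bias = None
    if cfg.zone_bias is not None:
        bias = cfg.zone_bias.get("slow" if state == SLOW else "fast")
    x, y = _sample_initial(rng, cfg.cell, bias)

    sd = (math.sqrt(2.0 * cfg.D_slow * dt), math.sqrt(2.0 * cfg.D_fast * dt))
    steps = rng.standard_normal((n_frames - 1, 2))
    switch_u = rng.random(n_frames - 1)

    true_xy = np.empty((n_frames, 2))
    states = np.empty(n_frames, dtype=np.int8)
    true_xy[0] = (x, y)
    states[0] = state
    for i in range(n_frames - 1):
        s = sd[state]
        x, y = x + steps[i, 0] * s, y + steps[i, 1] * s
        if cfg.confine:
            x, y = _reflect(x, y, half_len, radius)
        p_switch = p_sf if state == SLOW else p_fs
        if switch_u[i] < p_switch:
            state = FAST if state == SLOW else SLOW
        true_xy[i + 1] = (x, y)
        states[i + 1] = state

    sigma = cfg.localization_precision
    if sigma > 0:
        noise = rng.standard_normal((n_frames, 2)) * sigma
        # keep observations inside the outline dilated by 4σ
        norm = np.hypot(noise[:, 0], noise[:, 1])
        over = norm > 3.9 * sigma
        if np.any(over):
            noise[over] *= (3.9 * sigma / norm[over])[:, None]
        obs_xy = true_xy + noise
    else:
        obs_xy = true_xy.copy()
    return true_xy, obs_xy, states


def _to_lab_frame(xy: np.ndarray, cell: CellOutline) -> np.ndarray:
    c, s = math.cos(cell.orientation), math.sin(cell.orientation)
    rot = np.array([[c, -s], [s, c]])
    return xy @ rot.T + np.asarray(cell.center)


def _slow_segments(track_id, states) -> list[tuple]:
    segs = []
    start = None
    for i, st in enumerate(states):
        if st == SLOW and start is None:
            start = i
        elif st != SLOW and start is not None:
            segs.append((track_id, start, i - start))
            start = None
    if start is not None:
        segs.append((track_id, start, len(states) - start))
    return segs


def simulate_trackset(cfg: SimConfig) -> tuple[TrackSet, GroundTruth]:
    """Simulate ``cfg.n_tracks`` molecules; identical config ⇒ identical output.

    Per-track RNG streams are derived from ``cfg.seed`` and the track index,
    so individual tracks are reproducible independently of batch size.
    """
    p_sf, p_fs = cfg.switch_probabilities()
    tracks: list[Track] = []
    truth = GroundTruth()
    for i in range(cfg.n_tracks):
        rng = np.random.default_rng([cfg.seed, i])
        out = _simulate_track(rng, cfg, p_sf, p_fs)
        if out is None:
            continue
        true_xy, obs_xy, states = out
        lab = _to_lab_frame(obs_xy, cfg.cell)
        dets = [
            Detection(frame=j, x=float(lab[j, 0]), y=float(lab[j, 1]),
                      cell_id=str(cfg.cell.cell_id))
            for j in range(len(lab))
        ]
        tid = i
        tracks.append(Track(track_id=tid, detections=dets))
        truth.states[tid] = states
        truth.true_xy[tid] = _to_lab_frame(true_xy, cfg.cell)
        truth.slow_segments.extend(_slow_segments(tid, states))
    ts = TrackSet(
        tracks=tracks,
        frame_interval=cfg.frame_interval,
        localization_precision=cfg.localization_precision,
        condition=cfg.condition,
    )
    return ts, truth


def condition_seed(base_seed: int, label: str) -> int:
    """Deterministic, order-independent per-condition seed."""
    digest = hashlib.sha256(f"{base_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:8], "little")


def simulate_conditions(
    base: SimConfig,
    overrides: list[tuple],
    return_truth: bool = False,
) -> list:
    """One TrackSet per (label, f_slow, zone_bias) override.

    All conditions share the diffusion coefficients and acquisition settings
    of ``base``; seeds are derived from ``base.seed`` and the label so that
    permuting the override order leaves every per-label output unchanged.
    """
    if not overrides:
        raise ArgumentError("overrides must be non-empty")
    labels = [o[0] for o in overrides]
    if len(set(labels)) != len(labels):
        raise ArgumentError(f"duplicate condition labels: {labels}")
    out = []
    for label, f_slow, zone_bias in overrides:
        cfg = replace(
            base,
            f_slow=f_slow,
            zone_bias=zone_bias,
            condition=label,
            seed=condition_seed(base.seed, label),
        )
        ts, truth = simulate_trackset(cfg)
        out.append((ts, truth) if return_truth else ts)
    return out
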