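"""Pooled Gaussian-mixture fitting across experimental conditions.

Frame-to-frame displacement components (dx and dy pooled as independent
zero-mean draws) from several conditions are fit jointly: component standard
deviations are shared globally — the M-step pools responsibility-weighted
second moments over all conditions — while the mixture weights are free per
condition. This holds the diffusion coefficients at one value for all
conditions so that only the population sizes differ, which is what makes
condition-to-condition comparisons of the slow/static fraction meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConvergenceError, EmptySampleError, SampleSizeError
from .track_io import TrackSet, filter_min_length

_EM_TOL = 1e-8
_EM_MAX_ITER = 2000
_MIN_PER_COMPONENT = 100


@dataclass
class DisplacementSample:
    """Per-condition 1-D displacement components (µm), both axes pooled."""

    components: dict[str, np.ndarray]
    frame_interval: float

    def __post_init__(self):
        for label, d in self.components.items():
            d = np.asarray(d, dtype=float)
            if d.size == 0:
                raise EmptySampleError(f"condition '{label}' has no displacements")
            if not np.all(np.isfinite(d)):
                raise ArgumentError(f"condition '{label}' has non-finite displacements")
            self.components[label] = d

    @property
    def labels(self) -> list[str]:
        return list(self.components)


@dataclass
class PooledGMMFit:
    """Shared-σ mixture: sigma ascending; weights per condition sum to 1."""

    K: int
    sigma: np.ndarray  # shared component sd, µm, ascending
    weights: dict[str, np.ndarray]  # per-condition fractions
    loglik: float
    n: dict[str, int]
    frame_interval: float
    n_iter: int = 0

    @property
    def D(self) -> np.ndarray:
        """Implied apparent diffusion coefficients D_i = σ_i² / (2·Δt)."""
        return self.sigma**2 / (2.0 * self.frame_interval)

    def f_slow(self, label: str) -> float:
        return float(self.weights[label][0])


def extract_displacements(
    ts_list: list[TrackSet], min_frames: int = 5
) -> DisplacementSample:
    """dx and dy of every consecutive-frame step of every surviving track.

    All TrackSets must share the same frame interval; condition labels must
    be distinct.
    """
    if not ts_list:
        raise ArgumentError("ts_list must be non-empty")
    dts = {ts.frame_interval for ts in ts_list}
    if len(dts) != 1:
        raise ArgumentError(f"mismatched frame intervals: {sorted(dts)}")
    labels = [ts.condition for ts in ts_list]
    if len(set(labels)) != len(labels):
        raise ArgumentError(f"duplicate condition labels: {labels}")
    components: dict[str, np.ndarray] = {}
    for ts in ts_list:
        parts = []
        for t in filter_min_length(ts, min_frames).tracks:
            consec = np.diff(t.frames) == 1
            d = np.diff(t.xy, axis=0)[consec]
            if d.size:
                parts.append(d.ravel())
        if not parts:
            raise EmptySampleError(f"condition '{ts.condition}' has no steps")
        components[ts.condition] = np.concatenate(parts)
    return DisplacementSample(components=components, frame_interval=dts.pop())


def fit_pooled_gmm(
    s: DisplacementSample,
    K: int = 2,
    init_sigma: np.ndarray | None = None,
    max_iter: int = _EM_MAX_ITER,
    tol: float = _EM_TOL,
) -> PooledGMMFit:
    """EM for the zero-mean shared-variance Gaussian mixture.

    E-step responsibilities use each condition's own weights; the variance
    M-step pools squared displacements over all conditions, the weight
    M-step is per condition. K defaults to 2 (slow + fast), the setting used
    for condition comparisons.
    """
    if K < 1:
        raise ArgumentError("K must be >= 1")
    for label, d in s.components.items():
        if d.size < _MIN_PER_COMPONENT * K:
            raise SampleSizeError(
                f"condition '{label}': need >= {_MIN_PER_COMPONENT * K} components "
                f"for K={K}, got {d.size}"
            )

    pooled_abs = np.sort(np.abs(np.concatenate(list(s.components.values()))))
    if init_sigma is not None:
        sigma = np.sort(np.asarray(init_sigma, dtype=float))
        if sigma.size != K or np.any(sigma <= 0):
            raise ArgumentError("init_sigma must be K positive values")
    else:
        groups = np.array_split(pooled_abs, K)
        sigma = np.array([max(np.sqrt(np.mean(g**2)), 1e-9) for g in groups])
    weights = {label: np.full(K, 1.0 / K) for label in s.components}

    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll = 0.0
        num_var = np.zeros(K)
        den_var = np.zeros(K)
        new_weights = {}
        for label, d in s.components.items():
            log_dens = (
                np.log(weights[label])
                - 0.5 * np.log(2.0 * np.pi * sigma**2)
                - d[:, None] ** 2 / (2.0 * sigma**2)
            )
            log_norm = np.logaddexp.reduce(log_dens, axis=1)
            gamma = np.exp(log_dens - log_norm[:, None])
            ll += float(log_norm.sum())
            wsum = gamma.sum(axis=0)
            num_var += (gamma * d[:, None] ** 2).sum(axis=0)
            den_var += wsum
            new_weights[label] = wsum / d.size
        if ll < ll_prev - 1e-9 * max(1.0, abs(ll_prev)):
            raise AssertionError(
                f"EM log-likelihood decreased: {ll_prev} -> {ll} at iter {n_iter}"
            )
        if n_iter > 1 and abs(ll - ll_prev) <= tol * max(1.0, abs(ll_prev)):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
        sigma = np.sqrt(np.maximum(num_var / np.maximum(den_var, 1e-300), 1e-18))
        weights = new_weights

    order = np.argsort(sigma)
    sigma = sigma[order]
    weights = {label: w[order] / w.sum() for label, w in weights.items()}
    fit = PooledGMMFit(
        K=K,
        sigma=sigma,
        weights=weights,
        loglik=ll_prev,
        n={label: d.size for label, d in s.components.items()},
        frame_interval=s.frame_interval,
        n_iter=n_iter,
    )
    if not converged:
        raise ConvergenceError(
            f"pooled GMM did not converge in {max_iter} iterations", last_fit=fit
        )
    return fit


def relative_change(f_ref: float, f_cond: float) -> float:
    """Signed relative change in percent: 100·(f_cond − f_ref)/f_ref."""
    if f_ref == 0:
        raise ArgumentError("reference fraction is zero")
    return 100.0 * (f_cond - f_ref) / f_ref


def population_shift_table(fit: PooledGMMFit, reference: str) -> pd.DataFrame:
    """Slow-fraction shift of every condition against ``reference``.

    Columns: condition, f_slow_pct, abs_change_pp, rel_change_pct (signed,
    1 decimal to match conventional reporting precision).
    """
    if reference not in fit.weights:
        raise ArgumentError(
            f"reference '{reference}' not among conditions {list(fit.weights)}"
        )
    f_ref = fit.f_slow(reference) * 100.0
    rows = []
    for label in fit.weights:
        f_c = fit.f_slow(label) * 100.0
        rows.append(
            {
                "condition": label,
                "f_slow_pct": round(f_c, 1),
                "abs_change_pp": round(f_c - f_ref, 1),
                "rel_change_pct": round(relative_change(f_ref, f_c), 1),
            }
        )
    return pd.DataFrame(rows)
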