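"""Jump-distance (squared-displacement) mixture analysis.

For 2-D Brownian motion the single-interval jump distance r is Rayleigh
distributed, so u = r² is exponential with mean 4·D_app·Δt per diffusive
component. A K-component Rayleigh mixture on r is therefore fit as an
exponential mixture on u, which has closed-form EM updates. Model order is
chosen by BIC and fit quality is summarized by the coefficient of
determination between the empirical and fitted CDFs of u.

Fitted coefficients are *apparent* (inflated by localization error,
D_app = D + σ²/Δt); an optional correction is exposed but off by default,
matching how such coefficients are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, ConvergenceError, EmptySampleError, SampleSizeError
from .track_io import TrackSet, filter_min_length

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000
_MIN_PER_COMPONENT = 50


@dataclass
class JumpSample:
    """Single-interval jump distances of a TrackSet (consecutive frames only)."""

    jumps: np.ndarray  # r, µm
    frame_interval: float
    localization_precision: float = 0.0
    condition: str = ""

    def __post_init__(self):
        self.jumps = np.asarray(self.jumps, dtype=float)
        if np.any(self.jumps < 0) or not np.all(np.isfinite(self.jumps)):
            raise ArgumentError("jumps must be finite and non-negative")

    @property
    def squared(self) -> np.ndarray:
        """u = r² in µm²."""
        return self.jumps**2

    @property
    def n(self) -> int:
        return self.jumps.size


@dataclass
class MixtureFit:
    """Converged K-component fit: D ascending, fractions summing to 1."""

    K: int
    D: np.ndarray  # apparent diffusion coefficients, µm²/s, ascending
    f: np.ndarray  # fractions, sum to 1
    loglik: float
    bic: float
    r2: float
    n: int
    n_iter: int = 0
    frame_interval: float = 0.02
    localization_precision: float = 0.0

    @property
    def D_slow(self) -> float:
        return float(self.D[0])

    @property
    def f_slow(self) -> float:
        return float(self.f[0])

    def corrected_D(self) -> np.ndarray:
        """D with the static localization-error term σ²/Δt removed (may clip at 0)."""
        return np.maximum(
            self.D - self.localization_precision**2 / self.frame_interval, 0.0
        )


def extract_jumps(ts: TrackSet, min_frames: int = 5) -> JumpSample:
    """Lag-1 jump distances from all tracks surviving the length filter.

    Only consecutive-frame detection pairs contribute; steps across frame
    gaps are skipped (not interpolated) to avoid lag mixing.
    """
    filtered = filter_min_length(ts, min_frames)
    jumps = []
    for t in filtered.tracks:
        frames = t.frames
        xy = t.xy
        consec = np.diff(frames) == 1
        d = np.diff(xy, axis=0)
        r = np.hypot(d[:, 0], d[:, 1])[consec]
        if r.size:
            jumps.append(r)
    if not jumps:
        raise EmptySampleError(
            f"no jumps after min_frames={min_frames} filter "
            f"({len(ts.tracks)} tracks in)"
        )
    return JumpSample(
        jumps=np.concatenate(jumps),
        frame_interval=ts.frame_interval,
        localization_precision=ts.localization_precision,
        condition=ts.condition,
    )


def _mixture_loglik(u: np.ndarray, m: np.ndarray, f: np.ndarray) -> float:
    dens = (f / m) * np.exp(-u[:, None] / m)
    return float(np.sum(np.log(np.maximum(dens.sum(axis=1), 1e-300))))


def mixture_cdf(u: np.ndarray, D: np.ndarray, f: np.ndarray, dt: float) -> np.ndarray:
    """F(u) = 1 − Σ f_i · exp(−u / (4·D_i·Δt))."""
    m = 4.0 * np.asarray(D) * dt
    return 1.0 - np.exp(-u[:, None] / m) @ np.asarray(f)


def cdf_r2(u: np.ndarray, D: np.ndarray, f: np.ndarray, dt: float) -> float:
    """R² between the empirical CDF of u (at all sample points) and the model CDF."""
    us = np.sort(u)
    ecdf = np.arange(1, us.size + 1) / us.size
    model = mixture_cdf(us, D, f, dt)
    ss_res = float(np.sum((ecdf - model) ** 2))
    ss_tot = float(np.sum((ecdf - ecdf.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_rayleigh_mixture(
    s: JumpSample,
    K: int,
    init_means: np.ndarray | None = None,
    max_iter: int = _EM_MAX_ITER,
    tol: float = _EM_TOL,
) -> MixtureFit:
    """Maximum-likelihood K-component exponential-mixture fit of u = r² by EM.

    Components are initialized from a K-quantile split of u unless
    ``init_means`` is given. The EM log-likelihood is asserted non-decreasing
    every iteration. BIC uses 2K−1 free parameters.
    """
    if not (1 <= K <= 3):
        raise ArgumentError(f"K must be in 1..3, got {K}")
    u = s.squared
    n = u.size
    if n < _MIN_PER_COMPONENT * K:
        raise SampleSizeError(f"need >= {_MIN_PER_COMPONENT * K} jumps for K={K}, got {n}")

    if init_means is not None:
        m = np.sort(np.asarray(init_means, dtype=float))
        if m.size != K or np.any(m <= 0):
            raise ArgumentError("init_means must be K positive values")
    else:
        groups = np.array_split(np.sort(u), K)
        m = np.array([max(g.mean(), 1e-12) for g in groups])
    f = np.full(K, 1.0 / K)

    ll_prev = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E-step
        log_dens = np.log(f / m) - u[:, None] / m
        log_norm = np.logaddexp.reduce(log_dens, axis=1)
        gamma = np.exp(log_dens - log_norm[:, None])
        ll = float(log_norm.sum())
        if ll < ll_prev - 1e-9 * max(1.0, abs(ll_prev)):
            raise AssertionError(
                f"EM log-likelihood decreased: {ll_prev} -> {ll} at iter {n_iter}"
            )
        if n_iter > 1 and abs(ll - ll_prev) <= tol * max(1.0, abs(ll_prev)):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
        # M-step (closed form for exponential components)
        weight = gamma.sum(axis=0)
        m = np.maximum((gamma * u[:, None]).sum(axis=0) / np.maximum(weight, 1e-300), 1e-12)
        f = weight / n

    dt = s.frame_interval
    order = np.argsort(m)
    m, f = m[order], f[order]
    f = f / f.sum()
    D = m / (4.0 * dt)
    bic = -2.0 * ll_prev + (2 * K - 1) * np.log(n)
    fit = MixtureFit(
        K=K,
        D=D,
        f=f,
        loglik=ll_prev,
        bic=float(bic),
        r2=cdf_r2(u, D, f, dt),
        n=n,
        n_iter=n_iter,
        frame_interval=dt,
        localization_precision=s.localization_precision,
    )
    if not converged:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations (K={K})", last_fit=fit
        )
    return fit


def select_model(s: JumpSample, K_max: int = 3) -> MixtureFit:
    """Fit K = 1..K_max and return the fit with minimal BIC (ties → smaller K)."""
    if K_max < 1:
        raise ArgumentError("K_max must be >= 1")
    best: MixtureFit | None = None
    for K in range(1, K_max + 1):
        fit = fit_rayleigh_mixture(s, K)
        if best is None or fit.bic < best.bic:
            best = fit
    assert best is not None
    return best
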