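import numpy as np
import pytest

from smt2state.diffusion_fit import (
    JumpSample,
    cdf_r2,
    extract_jumps,
    fit_rayleigh_mixture,
    mixture_cdf,
    select_model,
)
from smt2state.errors import ArgumentError, EmptySampleError, SampleSizeError
from smt2state.track_io import TrackSet
from smt2state.trajectory_sim import SimConfig, simulate_trackset

from tests.conftest import make_track

DT = 0.02


def mixture_jumps(rng, n, D, f, dt=DT):
    """Direct draws from the exponential mixture of u = r² (oracle generator)."""
    comp = rng.choice(len(D), size=n, p=f)
    u = rng.exponential(4 * np.asarray(D)[comp] * dt)
    return JumpSample(jumps=np.sqrt(u), frame_interval=dt)


def sim_sample(seed, D=(0.08, 0.57), f_slow=0.474, n_tracks=400):
    cfg = SimConfig(
        D_slow=D[0], D_fast=D[1], f_slow=f_slow, localization_precision=0.0,
        mean_state_dwell_slow=0.2, n_tracks=n_tracks, confine=False, seed=seed,
    )
    ts, _ = simulate_trackset(cfg)
    return extract_jumps(ts)


class TestExtractJumps:
    def test_five_detections_four_jumps(self):
        ts = TrackSet([make_track("t", [(0.1 * i, 0.0) for i in range(5)])])
        s = extract_jumps(ts)
        assert s.n == 4

    def test_pythagoras(self):
        ts = TrackSet([make_track("t", [(0.0, 0.0), (0.1, 0.0)] + [(0.1, 0.0)] * 3)])
        s = extract_jumps(ts)
        assert s.jumps[0] == pytest.approx(0.1)
        assert s.squared[0] == pytest.approx(0.01)

    def test_gap_steps_skipped(self):
        t = make_track("g", [(0.0, 0.0)] * 6, frames=[0, 1, 2, 5, 6, 7])
        s = extract_jumps(TrackSet([t]))
        assert s.n == 4  # steps 0-1, 1-2, 5-6, 6-7; the 2→5 gap is dropped

    def test_recount_oracle(self, rng):
        lengths = rng.integers(2, 25, size=100)
        tracks = [
            make_track(i, rng.normal(size=(n, 2)).tolist()) for i, n in enumerate(lengths)
        ]
        s = extract_jumps(TrackSet(tracks), min_frames=5)
        expected = sum(n - 1 for n in lengths if n >= 5)
        assert s.n == expected

    def test_empty_after_filter(self):
        ts = TrackSet([make_track("t", [(0.0, 0.0), (0.1, 0.0)])])
        with pytest.raises(EmptySampleError):
            extract_jumps(ts, min_frames=5)


class TestFitRayleighMixture:
    def test_single_component_analytic_moment(self):
        s = sim_sample(seed=1, D=(0.5, 0.5), f_slow=1.0, n_tracks=1300)
        assert s.n >= 1e5
        assert np.mean(s.squared) == pytest.approx(4 * 0.5 * DT, rel=0.02)
        fit = fit_rayleigh_mixture(s, 1)
        assert fit.D[0] == pytest.approx(0.5, rel=0.02)

    def test_k1_closed_form(self, rng):
        # K = 1 MLE is exactly mean(u)/(4Δt)
        s = mixture_jumps(rng, 5000, D=[0.3], f=[1.0])
        fit = fit_rayleigh_mixture(s, 1)
        assert fit.D[0] == pytest.approx(np.mean(s.squared) / (4 * DT), rel=1e-9)

    def test_two_population_recovery_printed_values(self):
        # printed two-population setting: D = (0.08, 0.57), f = (.474, .526)
        s = sim_sample(seed=2)
        assert s.n >= 2e4
        fit = fit_rayleigh_mixture(s, 2)
        assert fit.D[0] == pytest.approx(0.08, rel=0.10)
        assert fit.D[1] == pytest.approx(0.57, rel=0.10)
        assert fit.f[0] == pytest.approx(0.474, abs=0.03)

    def test_em_matches_grid_search_mle(self, rng):
        s = mixture_jumps(rng, 500, D=[0.08, 0.57], f=[0.45, 0.55])
        fit = fit_rayleigh_mixture(s, 2)
        # independent brute-force likelihood grid over (D1, D2, f1)
        u = s.squared
        d1g = np.linspace(0.02, 0.20, 91)
        d2g = np.linspace(0.30, 0.90, 121)
        f1g = np.linspace(0.05, 0.95, 91)
        best = (-np.inf, None)
        e1 = np.exp(-u[:, None] / (4 * d1g * DT)) / (4 * d1g * DT)  # (n, d1)
        e2 = np.exp(-u[:, None] / (4 * d2g * DT)) / (4 * d2g * DT)  # (n, d2)
        for f1 in f1g:
            dens = f1 * e1[:, :, None] + (1 - f1) * e2[:, None, :]
            ll = np.log(dens).sum(axis=0)
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            if ll[i, j] > best[0]:
                best = (ll[i, j], (d1g[i], d2g[j], f1))
        d1, d2, f1 = best[1]
        assert fit.D[0] == pytest.approx(d1, rel=0.05)
        assert fit.D[1] == pytest.approx(d2, rel=0.05)
        assert fit.f[0] == pytest.approx(f1, rel=0.05)

    def test_fractions_sum_to_one(self):
        s = sim_sample(seed=3, n_tracks=100)
        fit = fit_rayleigh_mixture(s, 2)
        assert abs(fit.f.sum() - 1.0) < 1e-9
        assert np.all(np.diff(fit.D) >= 0)

    def test_init_permutation_invariance(self, rng):
        s = mixture_jumps(rng, 8000, D=[0.08, 0.57], f=[0.5, 0.5])
        a = fit_rayleigh_mixture(s, 2, init_means=np.array([0.002, 0.04]))
        b = fit_rayleigh_mixture(s, 2, init_means=np.array([0.04, 0.002]))
        assert np.allclose(a.D, b.D, rtol=1e-6)
        assert np.allclose(a.f, b.f, rtol=1e-6)

    def test_equal_components_match_single_component_likelihood(self, rng):
        s = mixture_jumps(rng, 4000, D=[0.2], f=[1.0])
        one = fit_rayleigh_mixture(s, 1)
        u = s.squared
        m = 4 * one.D[0] * DT
        ll2 = np.sum(
            np.log(0.5 / m * np.exp(-u / m) + 0.5 / m * np.exp(-u / m))
        )
        assert ll2 == pytest.approx(one.loglik, rel=1e-12)

    def test_sample_size_guard(self, rng):
        s = mixture_jumps(rng, 60, D=[0.1], f=[1.0])
        with pytest.raises(SampleSizeError):
            fit_rayleigh_mixture(s, 2)

    def test_bad_k(self, rng):
        s = mixture_jumps(rng, 500, D=[0.1], f=[1.0])
        with pytest.raises(ArgumentError):
            fit_rayleigh_mixture(s, 4)

    def test_corrected_d(self, rng):
        s = mixture_jumps(rng, 5000, D=[0.3], f=[1.0])
        s.localization_precision = 0.04
        fit = fit_rayleigh_mixture(s, 1)
        assert fit.corrected_D()[0] == pytest.approx(fit.D[0] - 0.04**2 / DT)

    @pytest.mark.parametrize(
        "D1,D2,f1", [(0.08, 0.57, 0.474), (0.06, 0.54, 0.493), (0.09, 0.57, 0.40), (0.06, 0.54, 0.65)]
    )
    def test_recovery_across_printed_parameter_sets(self, D1, D2, f1):
        # printed slow/fast parameter sets: D within 10%, f within 3 points
        # in >= 90% of seeded runs (10 seeds per set)
        ok = 0
        for seed in range(10):
            s = sim_sample(seed=100 + seed, D=(D1, D2), f_slow=f1, n_tracks=400)
            fit = fit_rayleigh_mixture(s, 2)
            if (
                abs(fit.D[0] - D1) <= 0.10 * D1
                and abs(fit.D[1] - D2) <= 0.10 * D2
                and abs(fit.f[0] - f1) <= 0.03
            ):
                ok += 1
        assert ok >= 9


class TestSelectModel:
    def test_two_population_selects_k2_high_r2(self):
        s = sim_sample(seed=4)
        fit = select_model(s, K_max=3)
        assert fit.K == 2
        assert fit.r2 >= 0.98

    def test_kmax_one_returns_k1(self):
        s = sim_sample(seed=5, n_tracks=100)
        fit = select_model(s, K_max=1)
        assert fit.K == 1

    def test_single_population_prefers_k1(self):
        for seed in range(5):
            s = sim_sample(seed=200 + seed, D=(0.3, 0.3), f_slow=1.0, n_tracks=150)
            assert select_model(s, K_max=2).K == 1

    def test_cdf_r2_perfect_on_model_cdf(self, rng):
        s = mixture_jumps(rng, 20000, D=[0.08, 0.57], f=[0.5, 0.5])
        r2 = cdf_r2(s.squared, np.array([0.08, 0.57]), np.array([0.5, 0.5]), DT)
        assert r2 > 0.999

    def test_mixture_cdf_limits(self):
        u = np.array([0.0, 1e9])
        F = mixture_cdf(u, np.array([0.1, 0.5]), np.array([0.4, 0.6]), DT)
        assert F[0] == pytest.approx(0.0)
        assert F[1] == pytest.approx(1.0)
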