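"""WHAM solver, free-energy projections, heat capacity, overlap metrics.

All oracles here are analytic or quadrature-based: umbrella windows over
known 1D potentials are sampled exactly (Gaussian or inverse-CDF), so the
reconstruction can be compared against the closed-form potential.
"""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from foldswitchlab.wham import (KB, FreeEnergySurface, UmbrellaWindowData,
                                WhamError, heat_capacity,
                                histogram_overlap_report, project_fes,
                                wham_solve)

T0 = 300.0
BETA = 1.0 / (KB * T0)


def harmonic_windows(kappa=2.0, k_bias=5.0, centers=(-2, -1, 0, 1, 2),
                     n=20_000, seed=0):
    """Exact Gaussian samples from biased harmonic ensembles."""
    rng = np.random.default_rng(seed)
    wins = []
    for q0 in centers:
        var = 1.0 / (BETA * (kappa + k_bias))
        mean = k_bias * q0 / (kappa + k_bias)
        x = rng.normal(mean, np.sqrt(var), n)
        wins.append(UmbrellaWindowData(q0=q0, k=k_bias, temperature=T0,
                                       q_series=x,
                                       e_series=0.5 * kappa * x ** 2))
    return wins


def double_well(x):
    """Asymmetric quartic double well (kcal/mol): basins near ±1."""
    return 2.5 * (x ** 2 - 1.0) ** 2 + 0.6 * x


def sample_potential(u, lo, hi, n, rng, bias=None):
    """Exact inverse-CDF sampling from exp(-beta (u + bias)) on [lo, hi]."""
    xs = np.linspace(lo, hi, 4001)
    en = u(xs) + (bias(xs) if bias else 0.0)
    p = np.exp(-BETA * (en - en.min()))
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.uniform(size=n), cdf, xs)


class TestWhamSolve:
    def test_single_unbiased_window_gives_uniform_weights(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 500)
        w = UmbrellaWindowData(q0=0.0, k=0.0, temperature=T0, q_series=x,
                               e_series=np.zeros_like(x))
        res = wham_solve([w])
        weights = res.weights(T0)
        np.testing.assert_allclose(weights, 1.0 / len(x), rtol=1e-12)

    def test_recovers_harmonic_potential_within_tenth_kcal(self):
        res = wham_solve(harmonic_windows())
        fes = project_fes(res, ("qdiff",), T0, bins=40,
                          ranges=((-2.2, 2.2),))
        x = fes.centers[0][fes.mask]
        f = fes.f[fes.mask]
        target = 0.5 * 2.0 * x ** 2
        target -= target.min()
        assert np.abs(f - target).max() < 0.1

    def test_offsets_stable_under_doubling_sample_counts(self):
        w1 = harmonic_windows(n=8000, seed=3)
        w2 = harmonic_windows(n=16000, seed=3)
        f1 = wham_solve(w1).offsets
        f2 = wham_solve(w2).offsets
        np.testing.assert_allclose(f1, f2, atol=0.05)

    def test_disjoint_histograms_raise_with_gap_location(self):
        rng = np.random.default_rng(0)
        wa = UmbrellaWindowData(q0=0.0, k=5.0, temperature=T0,
                                q_series=rng.normal(0, 0.05, 200),
                                e_series=np.zeros(200))
        wb = UmbrellaWindowData(q0=3.0, k=5.0, temperature=T0,
                                q_series=rng.normal(3, 0.05, 200),
                                e_series=np.zeros(200))
        with pytest.raises(WhamError, match="0.000.*3.000"):
            wham_solve([wa, wb])

    def test_equilibration_discard_respected(self):
        x = np.concatenate([np.full(10, 5.0), np.zeros(10)])
        w = UmbrellaWindowData(q0=0.0, k=0.0, temperature=T0, q_series=x,
                               e_series=np.zeros(20),
                               equilibration_discard=10)
        res = wham_solve([w])
        assert np.all(res.q == 0.0)
        with pytest.raises(WhamError):
            UmbrellaWindowData(q0=0, k=0, temperature=T0,
                               q_series=np.zeros(5), e_series=np.zeros(5),
                               equilibration_discard=5)


class TestProjection:
    def test_uniform_weights_give_flat_surface(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 400_000)
        w = UmbrellaWindowData(q0=0.0, k=0.0, temperature=T0, q_series=x,
                               e_series=np.zeros_like(x))
        fes = project_fes(wham_solve([w]), ("qdiff",), T0, bins=10,
                          ranges=((0, 1),))
        assert np.nanmax(fes.f) < 0.01  # flat to sampling noise

    def test_two_basin_weights_reproduce_hand_computed_barrier(self):
        # constructed weights: 3 bins with populations 100 / 1 / 50
        q = np.concatenate([np.full(100, 0.1), np.full(1, 0.5),
                            np.full(50, 0.9)])
        w = UmbrellaWindowData(q0=0.0, k=0.0, temperature=T0, q_series=q,
                               e_series=np.zeros_like(q))
        fes = project_fes(wham_solve([w]), ("qdiff",), T0, bins=3,
                          ranges=((0, 1),))
        f = fes.f
        assert f[0] == pytest.approx(0.0)
        assert f[1] == pytest.approx(-KB * T0 * np.log(1 / 100), rel=1e-9)
        assert f[2] == pytest.approx(-KB * T0 * np.log(50 / 100), rel=1e-9)

    def test_2d_marginal_equals_direct_1d(self):
        rng = np.random.default_rng(4)
        wins = harmonic_windows(n=4000, seed=5)
        for w in wins:
            w.aux["rmsd"] = np.abs(w.q_series) + rng.normal(0, 0.1,
                                                            len(w.q_series))
        res = wham_solve(wins)
        f1 = project_fes(res, ("qdiff",), T0, bins=12, ranges=((-2, 2),))
        f2 = project_fes(res, ("qdiff", "rmsd"), T0,
                         bins=(12, 8), ranges=((-2, 2), (-2, 5)))
        # marginalize the 2D surface over the second axis
        p2 = np.where(f2.mask, np.exp(-f2.f / (KB * T0)), 0.0)
        marg = -KB * T0 * np.log(p2.sum(axis=1))
        valid = np.isfinite(marg) & f1.mask
        delta = (marg - f1.f)[valid]
        np.testing.assert_allclose(delta - delta[0], 0.0, atol=1e-9)

    def test_unsampled_bins_are_masked_not_zero(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.4, 0.6, 100)
        w = UmbrellaWindowData(q0=0.5, k=0.0, temperature=T0, q_series=x,
                               e_series=np.zeros_like(x))
        fes = project_fes(wham_solve([w]), ("qdiff",), T0, bins=10,
                          ranges=((0, 1),))
        assert np.isnan(fes.f[0]) and not fes.mask[0]
        assert fes.mask[4] or fes.mask[5]


class TestTwoBasin:
    def test_umbrella_deltag_matches_quadrature_and_unbiased_run(self):
        rng = np.random.default_rng(7)
        wins = []
        for q0 in np.linspace(-1.4, 1.4, 9):
            x = sample_potential(double_well, -2.0, 2.0, 6000, rng,
                                 bias=lambda v, q0=q0: 0.5 * 8.0 * (v - q0) ** 2)
            wins.append(UmbrellaWindowData(
                q0=q0, k=8.0, temperature=T0, q_series=x,
                e_series=double_well(x)))
        res = wham_solve(wins)
        w = res.weights(T0)
        p_left = w[res.q < 0].sum()
        p_right = w[res.q >= 0].sum()
        dg_wham = -KB * T0 * np.log(p_right / p_left)
        # quadrature oracle
        zl = quad(lambda x: np.exp(-BETA * double_well(x)), -2.0, 0.0)[0]
        zr = quad(lambda x: np.exp(-BETA * double_well(x)), 0.0, 2.0)[0]
        dg_exact = -KB * T0 * np.log(zr / zl)
        assert dg_wham == pytest.approx(dg_exact, abs=0.1)
        # long unbiased equilibrium run agrees too
        xeq = sample_potential(double_well, -2.0, 2.0, 200_000, rng)
        dg_eq = -KB * T0 * np.log((xeq >= 0).mean() / (xeq < 0).mean())
        assert dg_wham == pytest.approx(dg_eq, abs=0.15)


class TestHeatCapacity:
    def test_harmonic_total_energy_gives_flat_kb(self):
        # total (kinetic + potential) energy of a 1D oscillator: C_v = k_B
        rng = np.random.default_rng(8)
        wins = []
        for t in (250.0, 300.0, 350.0):
            x2 = rng.normal(0, np.sqrt(KB * t / 2.0), 30_000) ** 2
            p2 = rng.normal(0, np.sqrt(KB * t / 2.0), 30_000) ** 2
            e = x2 + p2  # ½κx² + ½p²/m with unit-variance scaling
            wins.append(UmbrellaWindowData(q0=0.0, k=0.0, temperature=t,
                                           q_series=e, e_series=e))
        res = wham_solve(wins)
        temps, cv, _ = heat_capacity(res, np.linspace(260, 340, 9))
        np.testing.assert_allclose(cv, KB, rtol=0.05)

    def test_two_state_model_matches_closed_form(self):
        de, g0, g1 = 2.0, 1.0, 8.0
        rng = np.random.default_rng(9)
        wins = []
        for t in (120.0, 200.0, 280.0, 360.0):
            b = 1.0 / (KB * t)
            p1 = g1 * np.exp(-b * de) / (g0 + g1 * np.exp(-b * de))
            e = np.where(rng.uniform(size=60_000) < p1, de, 0.0)
            wins.append(UmbrellaWindowData(q0=0.0, k=0.0, temperature=t,
                                           q_series=e, e_series=e))
        res = wham_solve(wins)
        temps = np.linspace(140, 340, 21)
        _, cv, peaks = heat_capacity(res, temps)

        def cv_exact(t):
            b = 1.0 / (KB * t)
            z = g0 + g1 * np.exp(-b * de)
            e1 = de * g1 * np.exp(-b * de) / z
            e2 = de ** 2 * g1 * np.exp(-b * de) / z
            return (e2 - e1 ** 2) / (KB * t * t)

        np.testing.assert_allclose(cv, [cv_exact(t) for t in temps],
                                   rtol=0.06)
        # analytic peak: ~ dE / (k_B ln g1/g0) up to the usual shift
        t_peak_exact = temps[np.argmax([cv_exact(t) for t in temps])]
        assert abs(peaks[0] - t_peak_exact) <= 20.0

    def test_peak_finder_returns_both_maxima_in_order(self):
        t = np.linspace(100, 500, 81)
        cv = (np.exp(-((t - 200.0) / 30) ** 2)
              + 0.6 * np.exp(-((t - 400.0) / 25) ** 2))
        res_t = t
        from scipy.signal import argrelmax
        peaks = res_t[argrelmax(cv)[0]]
        np.testing.assert_allclose(peaks, [200.0, 400.0], atol=5.0)


class TestOverlap:
    def test_identical_histograms_overlap_fully(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 50_000)
        wa = UmbrellaWindowData(q0=0.0, k=1.0, temperature=T0, q_series=x,
                                e_series=np.zeros_like(x))
        wb = UmbrellaWindowData(q0=0.01, k=1.0, temperature=T0,
                                q_series=x.copy(),
                                e_series=np.zeros_like(x))
        rep = histogram_overlap_report([wa, wb])
        assert rep[0]["overlap"] > 0.98
        assert rep[0]["ok"]

    def test_disjoint_histograms_flagged(self):
        wa = UmbrellaWindowData(q0=0.0, k=1.0, temperature=T0,
                                q_series=np.random.default_rng(0).normal(0, 0.05, 100),
                                e_series=np.zeros(100))
        wb = UmbrellaWindowData(q0=5.0, k=1.0, temperature=T0,
                                q_series=np.random.default_rng(1).normal(5, 0.05, 100),
                                e_series=np.zeros(100))
        rep = histogram_overlap_report([wa, wb])
        assert rep[0]["overlap"] < 0.02
        assert not rep[0]["ok"]
        assert rep[0]["left_trapped"] is False  # on-center, just far apart

    def test_gaussians_one_sigma_apart_match_quadrature(self):
        rng = np.random.default_rng(11)
        xa = rng.normal(0, 1, 400_000)
        xb = rng.normal(1, 1, 400_000)
        wa = UmbrellaWindowData(q0=0.0, k=1.0, temperature=T0, q_series=xa,
                                e_series=np.zeros_like(xa))
        wb = UmbrellaWindowData(q0=1.0, k=1.0, temperature=T0, q_series=xb,
                                e_series=np.zeros_like(xb))
        rep = histogram_overlap_report([wa, wb], bins=200)
        exact = quad(lambda x: min(norm.pdf(x, 0, 1), norm.pdf(x, 1, 1)),
                     -6, 7)[0]
        assert rep[0]["overlap"] == pytest.approx(exact, rel=0.02)

    def test_off_center_window_annotated_as_trapped(self):
        rng = np.random.default_rng(12)
        wa = UmbrellaWindowData(q0=0.0, k=1.0, temperature=T0,
                                q_series=rng.normal(0.5, 0.2, 1000),
                                e_series=np.zeros(1000))
        wb = UmbrellaWindowData(q0=0.6, k=1.0, temperature=T0,
                                q_series=rng.normal(0.6, 0.2, 1000),
                                e_series=np.zeros(1000))
        rep = histogram_overlap_report([wa, wb])
        assert rep[0]["left_trapped"] is True
        assert rep[0]["right_trapped"] is False
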