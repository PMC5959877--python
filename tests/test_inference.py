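"""Predictive-distribution layer: oracles, limiting forms, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringstf._angles import UNIFORM_DENSITY, angle_grid, wrap_deg
from ringstf import inference as inf


GRID = angle_grid(720)  # 0.5 deg; fine enough for 1e-10 agreement checks
DX = 360.0 / 720


def integral(dist):
    return np.sum(dist.density) * DX


# ---------------------------------------------------------------- oracles


def quadrature_kernel(a1, center, grid):
    """Direct quadrature of N exp(a1 cos(pi/180 (theta-center)))."""
    raw = np.exp(a1 * np.cos(np.deg2rad(grid - center)))
    return raw / (raw.sum() * (360.0 / grid.size))


def enumerate_runlengths(n, eps):
    """P(l) by summing over all 2^n change/no-change sequences.

    Change point i sits between trial i and i+1 (the last one between
    trial n and n+1); the run length is the count of trials after the
    most recent change.
    """
    probs = np.zeros(n + 1)
    for bits in range(2**n):
        p = 1.0
        last_change = 0  # trials since last change, counted from the end
        run = n
        for i in range(n):  # i = 0 is the boundary closest to trial n+1
            change = (bits >> i) & 1
            p *= eps if change else (1.0 - eps)
            if change and run == n:
                run = i
        probs[run] += p
    return probs


def enumerate_predictive(history, kernel, eps, grid):
    """Average of per-segment product densities over change configurations."""
    n = len(history)
    dx = 360.0 / grid.size
    out = np.zeros(grid.size)
    for bits in range(2**n):
        p = 1.0
        run = n
        for i in range(n):
            change = (bits >> i) & 1
            p *= eps if change else (1.0 - eps)
            if change and run == n:
                run = i
        if run == 0:
            comp = np.full(grid.size, UNIFORM_DENSITY)
        else:
            comp = np.ones(grid.size)
            for theta in history[n - run:]:
                comp = comp * np.exp(kernel.log_unnormalized(wrap_deg(grid - theta)))
            comp = comp / (comp.sum() * dx)
        out += p * comp
    return out / (out.sum() * dx)


# ---------------------------------------------------------------- kernels


class TestKernelDensity:
    def test_zero_amplitudes_give_uniform(self):
        k = inf.TuningKernel((0.0,))
        d = inf.kernel_density(k, 30.0, GRID)
        assert np.allclose(d.density, UNIFORM_DENSITY, atol=1e-14)

    def test_peaked_and_even_about_center(self):
        k = inf.TuningKernel((1.5,))
        d = inf.kernel_density(k, 0.0, GRID)
        assert GRID[np.argmax(d.density)] == 0.0
        # even: f(theta) == f(-theta)
        flipped = d.density[::-1]
        assert np.allclose(np.roll(d.density, -1)[::-1], np.roll(flipped, 0)[::-1])
        i_pos = np.searchsorted(GRID, 45.0)
        i_neg = np.searchsorted(GRID, -45.0)
        assert d.density[i_pos] == pytest.approx(d.density[i_neg], rel=1e-12)

    def test_matches_direct_quadrature(self):
        k = inf.TuningKernel((1.0,))
        d = inf.kernel_density(k, 0.0, GRID)
        oracle = quadrature_kernel(1.0, 0.0, GRID)
        for angle in (0.0, 90.0, 180.0):
            i = np.searchsorted(GRID, angle) % GRID.size
            assert d.density[i] == pytest.approx(oracle[i], abs=1e-12)

    def test_self_conjugacy(self):
        k = inf.TuningKernel((2.0,))
        a, b = 17.0, -61.0
        fa = inf.kernel_density(k, a, GRID)
        fb = inf.kernel_density(k, b, GRID)
        ia = np.argmin(np.abs(GRID - b))
        ib = np.argmin(np.abs(GRID - a))
        assert fa.density[ia] == pytest.approx(fb.density[ib], rel=1e-12)

    def test_nonuniform_grid_rejected(self):
        bad = np.array([-180.0, -90.0, 0.0, 45.0])
        with pytest.raises(ValueError, match="grid"):
            inf.kernel_density(inf.TuningKernel(), 0.0, bad)


# ------------------------------------------------------------ run lengths


class TestRunLengthPrior:
    def test_direct_substitution(self):
        assert np.allclose(inf.runlength_prior(2, 0.5).probs, [0.5, 0.25, 0.25])

    def test_certain_change(self):
        p = inf.runlength_prior(6, 1.0).probs
        assert p[0] == 1.0 and np.all(p[1:] == 0.0)

    @pytest.mark.parametrize("n,eps", [(5, 0.1), (4, 0.35), (6, 0.9)])
    def test_matches_enumeration(self, n, eps):
        assert np.allclose(
            inf.runlength_prior(n, eps).probs, enumerate_runlengths(n, eps), atol=1e-14
        )

    def test_sums_to_one(self):
        for n in range(0, 9):
            assert inf.runlength_prior(n, 0.37).probs.sum() == pytest.approx(1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            inf.runlength_prior(3, 1.5)


# ---------------------------------------------------------- predict_exact


class TestPredictExact:
    def test_empty_history_is_uniform(self):
        d = inf.predict_exact(inf.TargetHistory(()), inf.TuningKernel(), 0.3, GRID)
        assert np.all(d.density == UNIFORM_DENSITY)

    def test_eps_one_is_uniform(self):
        h = inf.TargetHistory((10.0, -40.0, 100.0))
        d = inf.predict_exact(h, inf.TuningKernel(), 1.0, GRID)
        assert np.allclose(d.density, UNIFORM_DENSITY, atol=1e-15)

    @pytest.mark.parametrize("eps", [0.1, 0.5, 0.9])
    def test_matches_changepoint_enumeration(self, eps):
        rng = np.random.default_rng(5)
        hist = tuple(rng.uniform(-180, 180, size=3))
        k = inf.TuningKernel((1.0,))
        d = inf.predict_exact(hist, k, eps, GRID)
        oracle = enumerate_predictive(hist, k, eps, GRID)
        assert np.max(np.abs(d.density - oracle)) <= 1e-10

    def test_eps_zero_equals_static(self):
        rng = np.random.default_rng(6)
        hist = tuple(rng.uniform(-180, 180, size=6))
        k = inf.TuningKernel()
        d0 = inf.predict_exact(hist, k, 0.0, GRID)
        ds = inf.predict_static(hist, k, GRID)
        assert np.max(np.abs(d0.density - ds.density)) <= 1e-12


# --------------------------------------------------------- predict_static


class TestPredictStatic:
    def test_single_observation_is_kernel(self):
        k = inf.TuningKernel()
        d = inf.predict_static((25.0,), k, GRID)
        f = inf.kernel_density(k, 25.0, GRID)
        assert np.allclose(d.density, f.density, atol=1e-14)

    def test_batch_equals_iterative(self):
        k = inf.TuningKernel()
        hist = (-120.0, 33.0, 8.0, 90.0)
        batch = inf.predict_static(hist, k, GRID)
        d = inf.predict_static(hist[:1], k, GRID)
        for theta in hist[1:]:
            d = inf.static_update(d, theta, k)
        assert np.max(np.abs(batch.density - d.density)) <= 1e-12

    def test_repeated_targets_sharpen(self):
        k = inf.TuningKernel((1.0,))
        peaks = [
            inf.predict_static((0.0,) * n, k, GRID).density.max() for n in range(1, 6)
        ]
        assert np.all(np.diff(peaks) > 0)

    def test_permutation_invariance(self):
        k = inf.TuningKernel()
        hist = (12.0, -44.0, 170.0, -3.0)
        d1 = inf.predict_static(hist, k, GRID)
        d2 = inf.predict_static(hist[::-1], k, GRID)
        assert np.max(np.abs(d1.density - d2.density)) <= 1e-12


# ---------------------------------------------------------- predict_rapid


class TestPredictRapid:
    def test_eps_one_uniform(self):
        d = inf.predict_rapid(50.0, inf.TuningKernel(), 1.0, GRID)
        assert np.allclose(d.density, UNIFORM_DENSITY, atol=1e-15)

    def test_mixture_pointwise(self):
        k = inf.TuningKernel()
        d = inf.predict_rapid(0.0, k, 0.8, GRID)
        f = inf.kernel_density(k, 0.0, GRID)
        assert np.allclose(d.density, 0.8 / 360.0 + 0.2 * f.density, atol=1e-14)

    def test_exactly_reproduces_single_target_mixture(self):
        # with a one-target history the run-length mixture IS the
        # two-term mixture, so the truncation is exact there
        k = inf.TuningKernel()
        d1 = inf.predict_rapid(30.0, k, 0.85, GRID)
        dx = inf.predict_exact((30.0,), k, 0.85, GRID)
        assert np.max(np.abs(d1.density - dx.density)) <= 1e-12

    def test_truncation_error_vanishes_on_eps_ladder(self):
        k = inf.TuningKernel()
        hist = (-75.0, 30.0)
        errs = []
        for eps in (0.9, 0.99, 0.999):
            d1 = inf.predict_rapid(hist, k, eps, GRID)
            dx = inf.predict_exact(hist, k, eps, GRID)
            errs.append(np.max(np.abs(d1.density - dx.density)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    @pytest.mark.parametrize("eps", [0.7, 0.8, 0.9, 0.99])
    def test_order_two_closer_than_order_one(self, eps):
        k = inf.TuningKernel()
        hist = (-20.0, 35.0)
        exact = inf.predict_exact(hist, k, eps, GRID).density
        e1 = np.max(np.abs(inf.predict_rapid(hist, k, eps, GRID, order=1).density - exact))
        e2 = np.max(np.abs(inf.predict_rapid(hist, k, eps, GRID, order=2).density - exact))
        assert e2 <= e1

    def test_bad_order(self):
        with pytest.raises(ValueError, match="order"):
            inf.predict_rapid(0.0, inf.TuningKernel(), 0.9, GRID, order=3)


# ------------------------------------------------------- predict_small_eps


class TestPredictSmallEps:
    def test_eps_zero_reduces_to_static(self):
        k = inf.TuningKernel()
        hist = (5.0, -60.0, 120.0)
        d = inf.predict_small_eps(hist, k, 0.0, GRID)
        ds = inf.predict_static(hist, k, GRID)
        assert np.max(np.abs(d.density - ds.density)) <= 1e-12

    def test_single_observation_mixture(self):
        # n = 1: L ~ (1 - eps) f + eps P0, already normalized
        k = inf.TuningKernel()
        eps = 0.05
        d = inf.predict_small_eps((40.0,), k, eps, GRID)
        f = inf.kernel_density(k, 40.0, GRID)
        expected = (1.0 - eps) * f.density + eps * UNIFORM_DENSITY
        assert np.allclose(d.density, expected, atol=1e-12)

    def test_better_than_rapid_at_small_eps(self):
        k = inf.TuningKernel()
        rng = np.random.default_rng(11)
        hist = tuple(rng.uniform(-180, 180, size=3))
        eps = 0.01
        exact = inf.predict_exact(hist, k, eps, GRID).density
        e_small = np.max(np.abs(inf.predict_small_eps(hist, k, eps, GRID).density - exact))
        e_rapid = np.max(np.abs(inf.predict_rapid(hist, k, eps, GRID, order=1).density - exact))
        assert e_small <= e_rapid

    def test_warns_above_validity_range(self):
        with pytest.warns(UserWarning, match="eps"):
            inf.predict_small_eps((0.0,), inf.TuningKernel(), 0.3, GRID)


# ------------------------------------------------------------- properties


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    angles=st.lists(st.floats(-180.0, 179.9), min_size=0, max_size=6),
    eps=st.floats(0.0, 1.0),
)
def test_every_prediction_is_a_density(angles, eps):
    """Nonnegative, Riemann-normalized output for any history and hazard."""
    k = inf.TuningKernel()
    d = inf.predict_exact(tuple(angles), k, eps, GRID)
    assert np.all(d.density >= 0)
    assert integral(d) == pytest.approx(1.0, abs=1e-10)
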