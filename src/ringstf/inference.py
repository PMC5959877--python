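"""Sequential Bayesian prediction of the next working-memory target.

An observer who has seen targets theta_1..theta_n assumes the hidden
target-generating distribution changes between trials with probability
``eps`` (the environmental hazard rate).  Conditioning on the run
length -- the number of most recent trials over which the distribution
has not changed -- yields a predictive density for the next target:
a mixture, over run lengths l = 0..n, of the normalized product of
tuning-kernel densities centered on the last l targets, weighted by
the geometric run-length prior.

Limits of the hazard rate give the observer families used throughout:
eps = 0 weights every observation equally (static environment); eps
near 1 keeps only the previous target, giving the two-term mixture
``eps/360 + (1-eps) f_{theta_n}(theta)`` that drives serial bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._angles import UNIFORM_DENSITY, angle_grid, grid_spacing, wrap_deg

__all__ = [
    "TuningKernel",
    "TargetHistory",
    "PredictiveDistribution",
    "RunLengthPosterior",
    "kernel_density",
    "runlength_prior",
    "predict_exact",
    "predict_static",
    "predict_rapid",
    "predict_small_eps",
]


@dataclass(frozen=True)
class TuningKernel:
    """Exponential-of-cosines family of self-conjugate tuning densities.

    f_{theta'}(theta) = N * exp(sum_j a_j cos(j * pi/180 * (theta - theta')))

    with theta in degrees, so the j-th harmonic has period 360/j degrees.
    The normalization N is fixed on each evaluation grid so the density
    Riemann-integrates to one.  Shift invariance plus evenness make the
    family self-conjugate: f_{theta'}(theta) = f_theta(theta').

    The default single harmonic a_1 = 2 gives a central lobe comparable
    to the kernel the facilitation dynamics itself expresses.
    """

    harmonic_amplitudes: tuple = (2.0,)

    def __post_init__(self):
        amps = tuple(float(a) for a in self.harmonic_amplitudes)
        if not all(np.isfinite(amps)):
            raise ValueError("harmonic amplitudes must be finite")
        object.__setattr__(self, "harmonic_amplitudes", amps)

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonic_amplitudes)

    def log_unnormalized(self, delta_deg) -> np.ndarray:
        """Log of the unnormalized kernel at wrapped offsets (degrees)."""
        d = np.deg2rad(np.asarray(delta_deg, dtype=float))
        out = np.zeros_like(d)
        for j, a in enumerate(self.harmonic_amplitudes, start=1):
            out += a * np.cos(j * d)
        return out


@dataclass(frozen=True)
class TargetHistory:
    """Sequence theta_1..theta_n of presented targets, degrees in [-180, 180)."""

    angles: tuple = ()

    def __post_init__(self):
        object.__setattr__(
            self, "angles", tuple(float(wrap_deg(a)) for a in self.angles)
        )

    def __len__(self) -> int:
        return len(self.angles)


@dataclass
class PredictiveDistribution:
    """Gridded density (1/deg) over the next target angle."""

    grid: np.ndarray
    density: np.ndarray
    uniform_level: float = UNIFORM_DENSITY

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density shapes differ")

    @property
    def dx(self) -> float:
        return grid_spacing(self.grid)

    def integral(self) -> float:
        return float(np.sum(self.density) * self.dx)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"angle_deg": self.grid, "density": self.density}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class RunLengthPosterior:
    """P(l_n = l | eps) for l = 0..n; geometric with an atom at l = n."""

    probs: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    @property
    def n(self) -> int:
        return len(self.probs) - 1


def _check_grid(grid) -> tuple:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("invalid grid: empty")
    return grid, grid_spacing(grid)


def _normalize(values: np.ndarray, dx: float) -> np.ndarray:
    total = np.sum(values) * dx
    if not np.isfinite(total) or total <= 0:
        raise ValueError("cannot normalize a non-positive density")
    return values / total


def kernel_density(kernel: TuningKernel, center: float, grid) -> PredictiveDistribution:
    """Normalized tuning density f_center(theta) on a uniform periodic grid."""
    grid, dx = _check_grid(grid)
    logf = kernel.log_unnormalized(wrap_deg(grid - center))
    f = np.exp(logf - logf.max())
    return PredictiveDistribution(grid, _normalize(f, dx))


def runlength_prior(n: int, eps: float) -> RunLengthPosterior:
    """Geometric run-length probabilities eps(1-eps)^l, capped at l = n."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must lie in [0, 1]")
    probs = np.empty(n + 1)
    l = np.arange(n)
    probs[:n] = eps * (1.0 - eps) ** l
    probs[n] = (1.0 - eps) ** n
    return RunLengthPosterior(probs)


def _component_log_products(history, kernel: TuningKernel, grid: np.ndarray):
    """Cumulative log-products of kernels over the last l targets, l=0..n.

    Row l holds sum_{j=n-l+1..n} log f_{theta_j}(theta) (unnormalized).
    """
    angles = history.angles if isinstance(history, TargetHistory) else tuple(history)
    n = len(angles)
    out = np.zeros((n + 1, grid.size))
    acc = np.zeros(grid.size)
    for l, theta_j in enumerate(reversed(angles), start=1):
        acc = acc + kernel.log_unnormalized(wrap_deg(grid - theta_j))
        out[l] = acc
    return out


def predict_exact(history, kernel: TuningKernel, eps: float, grid) -> PredictiveDistribution:
    """Full run-length mixture predictive distribution.

    Each run-length component is the normalized product of the kernel
    densities of the last l observations (l = 0 gives the uniform
    density); components are mixed with the geometric run-length prior.
    Per-component normalization implements the sequence-probability
    divisors of the mixture, so the result integrates to one with no
    further rescaling.
    """
    grid, dx = _check_grid(grid)
    angles = history.angles if isinstance(history, TargetHistory) else tuple(history)
    n = len(angles)
    weights = runlength_prior(n, eps).probs
    if n == 0 or eps == 1.0:
        # the l = 0 component carries all the weight: exactly uniform
        return PredictiveDistribution(grid, np.full(grid.size, UNIFORM_DENSITY))
    logs = _component_log_products(angles, kernel, grid)
    density = weights[0] * np.full(grid.size, UNIFORM_DENSITY)
    for l in range(1, n + 1):
        if weights[l] == 0.0:
            continue
        comp = np.exp(logs[l] - logs[l].max())
        density += weights[l] * _normalize(comp, dx)
    return PredictiveDistribution(grid, _normalize(density, dx))


def predict_static(history, kernel: TuningKernel, grid) -> PredictiveDistribution:
    """Static-environment (eps -> 0) limit: normalized product of all kernels.

    Order-free, hence invariant under permutations of the history; the
    iterative one-step update multiplies in the newest kernel and
    renormalizes, which reproduces this batch product exactly.  An empty
    history returns the uniform density.
    """
    grid, dx = _check_grid(grid)
    angles = history.angles if isinstance(history, TargetHistory) else tuple(history)
    if len(angles) == 0:
        return PredictiveDistribution(grid, np.full(grid.size, UNIFORM_DENSITY))
    logp = np.zeros(grid.size)
    for theta_j in angles:
        logp += kernel.log_unnormalized(wrap_deg(grid - theta_j))
    return PredictiveDistribution(grid, _normalize(np.exp(logp - logp.max()), dx))


def static_update(
    dist: PredictiveDistribution, new_target: float, kernel: TuningKernel
) -> PredictiveDistribution:
    """One-step iterative form of the static limit: multiply and renormalize."""
    f = kernel_density(kernel, new_target, dist.grid)
    return PredictiveDistribution(dist.grid, _normalize(dist.density * f.density, dist.dx))


def predict_rapid(
    prev_target, kernel: TuningKernel, eps: float, grid, order: int = 1
) -> PredictiveDistribution:
    """Rapid-change (eps near 1) truncation of the run-length mixture.

    Order 1 is the two-term mixture eps/360 + (1-eps) f_{theta_n}(theta),
    already normalized.  Order 2 adds the eps(1-eps)^2 term carrying the
    normalized product of the kernels at the last two targets, then
    renormalizes.  ``prev_target`` may be a single angle or the history
    sequence (its last one or two entries are used).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if not 0.0 < eps <= 1.0:
        raise ValueError("eps must lie in (0, 1]")
    grid, dx = _check_grid(grid)
    if np.isscalar(prev_target) or isinstance(prev_target, float):
        angles = (float(prev_target),)
    else:
        angles = tuple(
            prev_target.angles if isinstance(prev_target, TargetHistory) else prev_target
        )
    if len(angles) == 0:
        raise ValueError("rapid-limit update requires at least one past target")
    f_n = kernel_density(kernel, angles[-1], grid).density
    if order == 1:
        density = eps * UNIFORM_DENSITY + (1.0 - eps) * f_n
        return PredictiveDistribution(grid, density)
    if len(angles) < 2:
        raise ValueError("order-2 update requires the two most recent targets")
    pair = _normalize(
        np.exp(
            kernel.log_unnormalized(wrap_deg(grid - angles[-1]))
            + kernel.log_unnormalized(wrap_deg(grid - angles[-2]))
        ),
        dx,
    )
    density = (
        eps * UNIFORM_DENSITY
        + eps * (1.0 - eps) * f_n
        + eps * (1.0 - eps) ** 2 * pair
    )
    return PredictiveDistribution(grid, _normalize(density, dx))


def predict_small_eps(history, kernel: TuningKernel, eps: float, grid) -> PredictiveDistribution:
    """Slowly-changing environment: O(eps) truncation of the mixture.

    L ~ (1 - n*eps) * prod_{j=1..n} f_j / P0  +  eps * sum_{l=0..n-1}
    prod over the last l targets, renormalized on the grid.  At eps = 0
    this reduces to the static product.
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must lie in [0, 1]")
    if eps > 0.2:
        warnings.warn(
            "small-eps truncation is first order in eps; eps > 0.2 is unreliable",
            stacklevel=2,
        )
    grid, dx = _check_grid(grid)
    angles = history.angles if isinstance(history, TargetHistory) else tuple(history)
    n = len(angles)
    # log of the *normalized* kernel relative to the uniform level, so the
    # l-th product term carries its absolute scale (f_j / P0)
    log_ratio = np.zeros((n, grid.size))
    for i, theta_j in enumerate(angles):
        raw = kernel.log_unnormalized(wrap_deg(grid - theta_j))
        z = np.log(np.sum(np.exp(raw - raw.max())) * dx) + raw.max()
        log_ratio[i] = raw - z - np.log(UNIFORM_DENSITY)
    density = (1.0 - n * eps) * np.exp(np.sum(log_ratio, axis=0))
    acc = np.zeros(grid.size)  # l = 0 term: empty product = 1
    density = density + eps * np.exp(acc)
    for l in range(1, n):
        acc = acc + log_ratio[n - l]
        density = density + eps * np.exp(acc)
    if np.any(density < 0):
        density = np.clip(density, 0.0, None)
    return PredictiveDistribution(grid, _normalize(density, dx))


def default_grid() -> np.ndarray:
    """The 2000-point (0.18 deg) grid used by the fine simulation profile."""
    return angle_grid(2000)
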