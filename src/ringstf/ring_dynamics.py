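"""Particle-on-a-potential abstraction of the remembered angle.

During one trial the stored angle theta(t) performs drift-diffusion on
the ring,

    d theta = -U'(theta) dt + sigma_theta dxi(t),

where the potential U encodes the observer's prediction for the trial:
the stationary density of this process is the Boltzmann form
chi * exp(-2 U / sigma_theta^2), and matching it to a predictive
distribution L gives U = (sigma_theta^2 / 2) ln(chi / L).  Minima of U
therefore sit at the peaks of the prediction and attract the memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import UNIFORM_DENSITY, grid_spacing, wrap_deg
from .inference import PredictiveDistribution

__all__ = [
    "PotentialField",
    "ParticleConfig",
    "AngleTrajectory",
    "potential_from_predictive",
    "stationary_density",
    "simulate_particle",
    "simulate_particle_ensemble",
]


@dataclass
class PotentialField:
    """Potential U(theta) on a uniform periodic degree grid.

    Only dU/dtheta and the normalized Boltzmann density are consumed, so
    U is meaningful up to an additive constant; chi records the
    normalizer of the density map for bookkeeping.
    """

    grid: np.ndarray
    values: np.ndarray
    chi: float = UNIFORM_DENSITY

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values shapes differ")

    @property
    def dx(self) -> float:
        return grid_spacing(self.grid)

    def gradient(self) -> np.ndarray:
        """Centered periodic finite-difference dU/dtheta at the grid nodes."""
        return (np.roll(self.values, -1) - np.roll(self.values, 1)) / (2.0 * self.dx)


@dataclass
class ParticleConfig:
    """Noise amplitude (deg / sqrt(ms)), integration step (ms) and seed."""

    sigma_theta: float = 1.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.sigma_theta < 0:
            raise ValueError("sigma_theta must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class AngleTrajectory:
    """Sampled path: wrapped angles plus unwrapped displacement (degrees)."""

    times: np.ndarray
    angles: np.ndarray
    displacement: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time": self.times,
                "angle_deg": self.angles,
                "displacement_deg": self.displacement,
            }
        ).to_csv(path, index=False)


def potential_from_predictive(
    dist: PredictiveDistribution, sigma_theta: float
) -> PotentialField:
    """Potential whose stationary density reproduces ``dist``.

    U = (sigma_theta^2 / 2) * ln(chi / L) with chi set to the uniform
    level, so a uniform prediction maps to a flat (zero) potential.
    """
    density = np.asarray(dist.density, dtype=float)
    if np.any(density <= 0):
        raise ValueError("degenerate distribution: density must be strictly positive")
    chi = UNIFORM_DENSITY
    values = 0.5 * sigma_theta**2 * (np.log(chi) - np.log(density))
    return PotentialField(dist.grid, values, chi=chi)


def stationary_density(U: PotentialField, sigma_theta: float) -> PredictiveDistribution:
    """Boltzmann stationary density chi * exp(-2 U / sigma_theta^2)."""
    if sigma_theta <= 0:
        raise ValueError("degenerate: sigma_theta must be > 0 for a density")
    logp = -2.0 * U.values / sigma_theta**2
    p = np.exp(logp - logp.max())
    p /= np.sum(p) * U.dx
    return PredictiveDistribution(U.grid, p)


def _drift_interpolator(U: PotentialField):
    """Linear interpolant of -dU/dtheta on the periodic grid."""
    drift = -U.gradient()
    x = U.grid
    dx = U.dx
    x_ext = np.concatenate([x, [x[0] + 360.0]])
    d_ext = np.concatenate([drift, [drift[0]]])
    x0 = x[0]

    def f(theta):
        pos = (np.asarray(theta) - x0) % 360.0 + x0
        return np.interp(pos, x_ext, d_ext)

    return f, dx


def simulate_particle(
    U: PotentialField, config: ParticleConfig, theta0: float, duration: float,
    record_every: int = 1,
) -> AngleTrajectory:
    """Euler-Maruyama path of the angle in potential U (durations in ms)."""
    traj = simulate_particle_ensemble(
        U, config, np.array([theta0]), duration, record_every=record_every
    )
    return AngleTrajectory(traj.times, traj.angles[:, 0], traj.displacement[:, 0])


@dataclass
class EnsembleTrajectory:
    times: np.ndarray
    angles: np.ndarray        # shape (n_times, n_paths), wrapped
    displacement: np.ndarray  # shape (n_times, n_paths), unwrapped


def simulate_particle_ensemble(
    U: PotentialField,
    config: ParticleConfig,
    theta0: np.ndarray,
    duration: float,
    record_every: int = 1,
) -> EnsembleTrajectory:
    """Vectorized Euler-Maruyama over an ensemble of initial angles.

    Wrapped positions are kept for occupancy statistics and the
    unwrapped displacement alongside, so variance-versus-time remains
    well defined when paths cross the branch cut.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    drift_at, _ = _drift_interpolator(U)
    rng = np.random.default_rng(config.seed)
    dt = config.dt
    n_steps = int(round(duration / dt))
    theta = wrap_deg(np.asarray(theta0, dtype=float)).copy()
    disp = np.zeros_like(theta)
    amp = config.sigma_theta * np.sqrt(dt)
    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    angles = np.empty((n_rec, theta.size))
    displacement = np.empty((n_rec, theta.size))
    times[0], angles[0], displacement[0] = 0.0, theta, disp
    k = 1
    for i in range(1, n_steps + 1):
        step = drift_at(theta) * dt + amp * rng.standard_normal(theta.size)
        theta = wrap_deg(theta + step)
        disp = disp + step
        if i % record_every == 0:
            times[k] = i * dt
            angles[k] = theta
            displacement[k] = disp
            k += 1
    return EnsembleTrajectory(times[:k], angles[:k], displacement[:k])
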