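"""Trial schedules and target-sequence generators for delayed response.

Every trial is cue (T_C = 150 ms), delay (T_D, possibly varying), a
global inactivating input (T_A = 500 ms) that erases the bump after
the response, and an intertrial interval (T_I).  Targets come from one
of three generative laws: the 20-angle uniform probability mass
function used for bias curves, the continuous uniform density used for
ensemble statistics, or a first-order chain in which theta_{n+1} is
drawn from an even mixture of a uniform density and a von Mises
(concentration 25) centered at theta_n - mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._angles import wrap_deg
from .inference import TargetHistory

__all__ = [
    "TrialSchedule",
    "TargetSampler",
    "sample_targets",
    "build_schedule",
    "stimulus_field",
    "PMF20_ANGLES",
    "ITI_LADDER_MS",
    "DELAY_LADDER_MS",
]

PMF20_ANGLES = -180.0 + 18.0 * np.arange(20)
ITI_LADDER_MS = np.arange(1000.0, 5000.0 + 1, 200.0)
DELAY_LADDER_MS = np.arange(0.0, 5000.0 + 1, 200.0)


@dataclass
class TrialSchedule:
    """Per-trial timing and targets; durations in ms, angles in degrees."""

    theta: np.ndarray
    T_D: np.ndarray
    T_I: np.ndarray
    T_C: float = 150.0
    T_A: float = 500.0
    I_0: float = 1.0
    I_1: float = 1.0
    I_R: float = 2.0

    def __post_init__(self):
        self.theta = wrap_deg(np.asarray(self.theta, dtype=float))
        self.T_D = np.asarray(self.T_D, dtype=float)
        self.T_I = np.asarray(self.T_I, dtype=float)
        if not (len(self.theta) == len(self.T_D) == len(self.T_I)):
            raise ValueError("theta, T_D, T_I must have equal length")
        if np.any(self.T_D < 0) or np.any(self.T_I < 0) or self.T_C < 0 or self.T_A < 0:
            raise ValueError("durations must be >= 0")

    @property
    def n_trials(self) -> int:
        return len(self.theta)

    @property
    def t_start(self) -> np.ndarray:
        """Cumulative trial start times t_n (ms), t_1 = 0."""
        block = self.T_C + self.T_D + self.T_A + self.T_I
        return np.concatenate([[0.0], np.cumsum(block[:-1])])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "t_start_ms": self.t_start,
                "T_C": self.T_C,
                "T_D": self.T_D,
                "T_A": self.T_A,
                "T_I": self.T_I,
                "theta_deg": self.theta,
            }
        ).to_csv(path, index=False)


@dataclass
class TargetSampler:
    """Generative law for target sequences.

    mode 'correlated' draws theta_{n+1} | theta_n from
    (1 - w) N_v exp(concentration cos(theta_n - theta_{n+1} - mu)) + w / 360
    with mixture weight w (the sampler's own change rate, distinct from
    the observer's hazard rate), so positive mu shifts the conditional
    mode to theta_n - mu.
    """

    mode: str = "uniform_density"
    mixture_weight: float = 0.5
    concentration: float = 25.0
    mu: float = 0.0

    def __post_init__(self):
        if self.mode not in ("uniform_pmf_20", "uniform_density", "correlated"):
            raise ValueError(f"unknown sampler mode: {self.mode!r}")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must lie in [0, 1]")


def sample_targets(sampler: TargetSampler, n_trials: int, seed: int = 0) -> TargetHistory:
    """Draw a reproducible sequence of target angles (degrees)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if sampler.mode == "uniform_pmf_20":
        return TargetHistory(tuple(rng.choice(PMF20_ANGLES, size=n_trials)))
    if sampler.mode == "uniform_density":
        return TargetHistory(tuple(rng.uniform(-180.0, 180.0, size=n_trials)))
    # first-order chain: offsets from the fixed conditional mixture
    angles = np.empty(n_trials)
    angles[0] = rng.uniform(-180.0, 180.0)
    use_uniform = rng.random(n_trials - 1) < sampler.mixture_weight
    vm = np.rad2deg(rng.vonmises(0.0, sampler.concentration, size=n_trials - 1))
    uni = rng.uniform(-180.0, 180.0, size=n_trials - 1)
    for i in range(1, n_trials):
        if use_uniform[i - 1]:
            angles[i] = uni[i - 1]
        else:
            angles[i] = wrap_deg(angles[i - 1] - sampler.mu + vm[i - 1])
    return TargetHistory(tuple(angles))


def _draw_durations(spec, n: int, ladder: np.ndarray, rng) -> np.ndarray:
    """Either a fixed duration or the uniform pmf over a ladder."""
    if isinstance(spec, str):
        if spec != "ladder":
            raise ValueError(f"unknown duration spec: {spec!r}")
        return rng.choice(ladder, size=n)
    val = float(spec)
    if val < 0:
        raise ValueError("durations must be >= 0")
    return np.full(n, val)


def build_schedule(
    n_trials: int,
    delay_spec=2000.0,
    iti_spec=1500.0,
    sampler: TargetSampler | None = None,
    seed: int = 0,
) -> TrialSchedule:
    """Assemble a schedule from duration specs and a target sampler.

    ``delay_spec`` / ``iti_spec`` are fixed values (ms) or "ladder" for
    the uniform pmfs over {0, 200, ..., 5000} ms and {1000, 1200, ...,
    5000} ms respectively.
    """
    if sampler is None:
        sampler = TargetSampler("uniform_pmf_20")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = root.spawn(3)
    theta = sample_targets(sampler, n_trials, seed=ss[0]).angles
    rng_d = np.random.default_rng(ss[1])
    rng_i = np.random.default_rng(ss[2])
    T_D = _draw_durations(delay_spec, n_trials, DELAY_LADDER_MS, rng_d)
    T_I = _draw_durations(iti_spec, n_trials, ITI_LADDER_MS, rng_i)
    return TrialSchedule(theta=np.asarray(theta), T_D=T_D, T_I=T_I)


def stimulus_field(schedule: TrialSchedule, t: float, grid_deg) -> np.ndarray:
    """External input I(x, t) at time t (ms) on a degree grid.

    Peaked drive I_0 exp[I_1 (cos(x - theta_n) - 1)] during the cue,
    zero during the delay, the uniform inactivating input -I_R after
    the response, zero through the intertrial interval.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    grid = np.deg2rad(np.asarray(grid_deg, dtype=float))
    starts = schedule.t_start
    i = int(np.searchsorted(starts, t, side="right") - 1)
    i = max(i, 0)
    local = t - starts[i]
    cue_end = schedule.T_C
    delay_end = cue_end + schedule.T_D[i]
    inact_end = delay_end + schedule.T_A
    if local < cue_end:
        th = np.deg2rad(schedule.theta[i])
        return schedule.I_0 * np.exp(schedule.I_1 * (np.cos(grid - th) - 1.0))
    if local < delay_end:
        return np.zeros_like(grid)
    if local < inact_end:
        return np.full_like(grid, -schedule.I_R)
    return np.zeros_like(grid)
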