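"""Low-dimensional bump + facilitation dynamics and the projected noise.

Projecting the full field onto the bump's translation mode yields a
two-variable system for the bump position theta(t) and the center
theta_q(t) of the facilitation laid down in the current trial,

    d theta = -[A_n(t) Ubar'(theta - theta_n)
               + A_{n+1}(t) Ubar'(theta - theta_q(t))] dt + sigma dxi
    tau d theta_q / dt = -d(theta_q - theta)

where A_n, A_{n+1} are the slowly rising/decaying facilitation
amplitudes of the previous and current trial, Ubar is the potential a
stationary facilitation plateau of half-width a imprints (closed form
in the Heaviside limit), d() is the shorter-arc circular difference
scaled by (1 + beta), and sigma = sqrt(2 D) with D the projected
diffusion coefficient of the bump.  Time in the projected system runs
in units of tau_u; the public interface uses milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import wrap_bias, wrap_rad
from .neural_field import BumpProfile, FieldParams, TrialResult, stationary_bump

__all__ = [
    "ReducedParams",
    "ReducedState",
    "facilitation_amplitude",
    "amplitude_at_trial_end",
    "potential_gradient",
    "circular_difference",
    "diffusion_coefficient",
    "simulate_reduced",
]


@dataclass
class ReducedParams:
    """Parameters of the reduced system (times in ms, sigma per sqrt(tau_u))."""

    half_width: float  # bump half-width a, radians
    beta: float = 0.01
    q_plus: float = 2.0
    tau: float = 1000.0
    tau_u: float = 10.0
    sigma: float = 0.0  # noise amplitude, rad / sqrt(tau_u unit)
    dt: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.half_width < np.pi:
            raise ValueError("half_width must lie in (0, pi)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @classmethod
    def from_field(cls, params: FieldParams, sigma: float | None = None, **kw):
        """Derive the reduced parameters from the field model's.

        sigma defaults to sqrt(2 D) with D the projected diffusion
        coefficient of the matching bump.
        """
        bump = stationary_bump(params)
        if sigma is None:
            sigma = float(np.sqrt(2.0 * diffusion_coefficient(bump, params.sigma_W)))
        return cls(
            half_width=bump.half_width_rad,
            beta=params.beta,
            q_plus=params.q_plus,
            tau=params.tau,
            tau_u=params.tau_u,
            sigma=sigma,
            dt=params.dt,
            **kw,
        )


@dataclass
class ReducedState:
    """Bump position, facilitation center (deg) and the two amplitudes."""

    theta: float = 0.0
    theta_q: float = 0.0
    A_prev: float = 0.0
    A_curr: float = 0.0


def facilitation_amplitude(
    t: float, trial_start: float, cue_plus_delay: float, tau: float = 1000.0
) -> float:
    """Closed-form amplitude A_n(t) of the facilitation from one trial.

    tau dA/dt = 1 - A while the bump is up (cue + delay), then -A
    afterwards; integrated exactly, so A rises as 1 - exp(-t'/tau) and
    decays as exp(-dt/tau) from its value at the response.  Zero before
    the trial starts.
    """
    if t <= trial_start:
        return 0.0
    up = min(t - trial_start, cue_plus_delay)
    A = 1.0 - np.exp(-up / tau)
    down = t - trial_start - cue_plus_delay
    if down > 0:
        A *= np.exp(-down / tau)
    return float(A)


def amplitude_at_trial_end(T_C: float, T_D: float, T_I: float, tau: float = 1000.0) -> float:
    """A_n at the start of the next trial: (1 - e^-(T_C+T_D)/tau) e^-T_I/tau."""
    return float((1.0 - np.exp(-(T_C + T_D) / tau)) * np.exp(-T_I / tau))


def potential_gradient(delta, a: float, beta: float = 0.01, q_plus: float = 2.0):
    """Drift -dUbar/dtheta at wrapped offset delta (radians).

    Heaviside closed form for a unit-amplitude facilitation plateau of
    half-width a:

      (beta q_plus) / (2 (1+beta) tan a) *
          [sign(delta)(1 - cos delta) - tan(a) sin(delta)]

    supported on |delta| < 2a and identically zero outside; odd in
    delta, and attracting toward delta = 0 for the wide-bump branch.
    """
    d = np.asarray(delta, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    ta = np.tan(a)
    out = (
        beta
        * q_plus
        / (2.0 * (1.0 + beta) * ta)
        * (np.sign(d) * (1.0 - np.cos(d)) - ta * np.sin(d))
    )
    out[np.abs(d) >= 2.0 * a] = 0.0
    return float(out[0]) if scalar else out


def circular_difference(dq, beta: float = 0.01):
    """Shorter signed arc scaled by (1 + beta); input/output radians."""
    return (1.0 + beta) * wrap_rad(dq)


def diffusion_coefficient(bump: BumpProfile, sigma_W: float) -> float:
    """Projected diffusion coefficient D = sigma^2 / 2 of the bump.

    The projected position noise is d theta = <V, dW> / <V, U'>, so its
    variance rate is sigma^2 = int int V(x) C(x-y) V(y) dy dx /
    [int U'(x) V(x) dx]^2 with C = sigma_W^2 cos(x-y), and D = sigma^2/2.
    Heaviside mode uses the delta-pair null vector, collapsing to
    D = sigma_W^2 / (8 sin^2 a); sigmoid mode evaluates the quadratures
    with V = F'(U) U'.  Units: rad^2 per tau_u time unit.
    """
    if sigma_W == 0.0:
        return 0.0
    a = bump.half_width_rad
    if bump.mode == "heaviside":
        return sigma_W**2 / (8.0 * np.sin(a) ** 2)
    x = np.deg2rad(np.asarray(bump.grid_deg, dtype=float))
    dx = 2.0 * np.pi / x.size
    V = bump.null_vector
    dU = np.gradient(bump.U_shape, x)
    # <V, C V> = sigma_W^2 [ (int V cos)^2 + (int V sin)^2 ]
    vc = np.sum(V * np.cos(x)) * dx
    vs = np.sum(V * np.sin(x)) * dx
    num = sigma_W**2 * (vc**2 + vs**2)
    den = (np.sum(dU * V) * dx) ** 2
    if den < 1e-20:
        raise ValueError("degenerate projection: flat bump")
    return float(0.5 * num / den)


def simulate_reduced(
    schedule, params: ReducedParams, seed: int = 0, record: bool = False
) -> list[TrialResult]:
    """Run the reduced system through a trial schedule.

    During each cue period theta is clamped to the presented target;
    theta_q restarts at the target with A_curr = 0.  The previous
    trial's facilitation is anchored at the previous *target* (its
    center has relaxed there by trial end) with amplitude given by the
    closed form.  Between the response and the next cue no bump exists,
    so only the amplitudes evolve (analytically).  Responses are read
    at the end of each delay.  Internally radians / tau_u units.
    """
    rng = np.random.default_rng(seed)
    dt_u = params.dt / params.tau_u  # step in tau_u units
    tau_q = params.tau / params.tau_u
    noise_amp = params.sigma * np.sqrt(dt_u)
    a, beta, qp = params.half_width, params.beta, params.q_plus
    results: list[TrialResult] = []
    rows = []
    prev_theta = np.nan  # radians anchor of the previous trial's plateau
    A_prev0 = 0.0
    for i in range(schedule.n_trials):
        theta_n = float(np.deg2rad(schedule.theta[i]))
        T_D, T_I = float(schedule.T_D[i]), float(schedule.T_I[i])
        up_ms = schedule.T_C + T_D
        # cue: theta clamped; theta_q restarts at the new bump location
        theta = theta_n
        theta_q = theta_n
        # delay: integrate the coupled SDE
        n_steps = int(round(T_D / params.dt))
        t_ms = schedule.T_C  # time since trial start at delay onset
        have_prev = np.isfinite(prev_theta)
        for k in range(n_steps):
            t_ms = schedule.T_C + k * params.dt
            A_curr = 1.0 - np.exp(-t_ms / params.tau)
            drift = A_curr * potential_gradient(wrap_rad(theta - theta_q), a, beta, qp)
            if have_prev:
                A_p = A_prev0 * np.exp(-t_ms / params.tau)
                drift += A_p * potential_gradient(wrap_rad(theta - prev_theta), a, beta, qp)
            theta = wrap_rad(theta + drift * dt_u + noise_amp * rng.standard_normal())
            # the center of a *rising* deposit is its amplitude-weighted
            # centroid, which relaxes at ((1+beta)/tau)/A(t): fresh
            # facilitation is laid down at the bump's current position,
            # so a young profile re-centers fast; at stationarity
            # (A -> 1) this reduces to the bare rate (1+beta)/tau
            gain = min(dt_u / (tau_q * max(A_curr, 1e-12)), 1.0)
            theta_q = wrap_rad(
                theta_q - circular_difference(wrap_rad(theta_q - theta), beta) * gain
            )
        r_deg = float(np.rad2deg(theta))
        A_curr_end = 1.0 - np.exp(-up_ms / params.tau)
        results.append(
            TrialResult(
                i + 1,
                float(schedule.theta[i]),
                r_deg,
                float(wrap_bias(r_deg - schedule.theta[i])),
                float(np.rad2deg(prev_theta)) if np.isfinite(prev_theta) else np.nan,
                T_D,
                T_I,
                True,
            )
        )
        if record:
            rows.append(
                ReducedState(
                    r_deg,
                    float(np.rad2deg(theta_q)),
                    A_prev0 * np.exp(-up_ms / params.tau) if np.isfinite(prev_theta) else 0.0,
                    A_curr_end,
                )
            )
        # hand over: the new plateau anchors at this trial's target.  The
        # amplitude decays over the whole bump-free gap -- the response
        # suppression window T_A as well as the intertrial interval --
        # since no activity refreshes the trace during either.
        prev_theta = theta_n
        A_prev0 = amplitude_at_trial_end(
            schedule.T_C, T_D, schedule.T_A + T_I, params.tau
        )
    if record:
        return results, rows
    return results
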