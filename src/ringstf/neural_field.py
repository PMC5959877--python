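"""Stochastic ring neural field with short-term facilitation (STF).

The network state is a normalized synaptic drive u(x,t) and a
facilitation variable q(x,t) on a periodic ring of orientation-tuned
locations x:

    tau_u du = [-u + w * ((1+q) F(u)) + I(x,t)] dt + dW(x,t)
    tau   dq/dt = -q + beta F(u) (q_plus - q)

with distance-dependent coupling w given by a sum of cosines (a single
cosine by default, so excitation and inhibition are merged into one
mean-free kernel), a sigmoidal or Heaviside firing-rate function F, and
spatially correlated noise <dW dW> = sigma_W^2 cos(x-y) dt.  A cue
nucleates a localized bump of activity whose peak stores the target;
facilitated synapses left behind by the previous trial's bump attract
the current one, producing serial bias.

All angles at the interface are degrees; internally the ring is
[-pi, pi) radians so the single-cosine kernel has unit frequency.  The
drift/noise timescale is the synaptic constant tau_u, i.e. one unit of
the projected dynamics corresponds to tau_u milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._angles import wrap_bias, wrap_deg

__all__ = [
    "FieldParams",
    "FieldState",
    "NoiseModel",
    "BumpProfile",
    "TrialResult",
    "stationary_bump",
    "stationary_stf",
    "noise_increment",
    "step",
    "run_trials",
    "bump_center",
    "delay_ensemble",
    "results_to_frame",
]


@dataclass
class FieldParams:
    """Network and integration parameters (times in ms, dx in degrees)."""

    tau_u: float = 10.0
    tau: float = 1000.0
    beta: float = 0.01
    q_plus: float = 2.0
    gamma: float = 20.0
    kappa: float = 0.1
    sigma_W: float = 0.005
    weight_harmonics: tuple = (0.0, 1.0)  # alpha_0, alpha_1, ...
    dx: float = 0.18
    dt: float = 0.1
    firing_rate_mode: str = "sigmoid"

    def __post_init__(self):
        if not (self.tau > self.tau_u > 0):
            raise ValueError("require tau > tau_u > 0")
        if self.beta < 0 or self.q_plus < 0:
            raise ValueError("beta and q_plus must be >= 0")
        if not 0 < self.kappa < 1:
            raise ValueError("kappa must lie in (0, 1)")
        n = 360.0 / self.dx
        if abs(n - round(n)) > 1e-9 or round(n) % 2:
            raise ValueError("dx must divide 360 into an even number of nodes")
        if self.firing_rate_mode not in ("sigmoid", "heaviside"):
            raise ValueError("firing_rate_mode must be 'sigmoid' or 'heaviside'")

    @property
    def n_grid(self) -> int:
        return int(round(360.0 / self.dx))

    def grid_deg(self) -> np.ndarray:
        return -180.0 + self.dx * np.arange(self.n_grid)

    def grid_rad(self) -> np.ndarray:
        return np.deg2rad(self.grid_deg())

    @classmethod
    def fast(cls, **kw) -> "FieldParams":
        """Coarse profile (dt = 0.5 ms, dx = 0.72 deg) for large sweeps."""
        kw.setdefault("dt", 0.5)
        kw.setdefault("dx", 0.72)
        return cls(**kw)

    def firing_rate(self, u: np.ndarray) -> np.ndarray:
        if self.firing_rate_mode == "heaviside":
            return (u > self.kappa).astype(float)
        return 1.0 / (1.0 + np.exp(-self.gamma * (u - self.kappa)))


@dataclass
class FieldState:
    """Synaptic drive and facilitation over the ring."""

    u: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.u.shape != self.q.shape:
            raise ValueError("u and q shapes differ")


@dataclass
class NoiseModel:
    """Spatially correlated white-in-time noise, C(x-y) = sigma_W^2 cos(x-y)."""

    sigma_W: float = 0.005
    seed: int = 0

    def correlation(self, delta_deg) -> np.ndarray:
        return self.sigma_W**2 * np.cos(np.deg2rad(np.asarray(delta_deg)))


@dataclass
class BumpProfile:
    """Stationary bump of the noiseless, facilitation-free field.

    In the Heaviside limit the bump is U(x) = 2 sin(a) cos(x) with the
    half-width a solving sin(2a) = kappa on the stable wide branch, and
    the adjoint null vector is the delta pair at +/-a (represented here
    by the half-width).  In sigmoid mode the profile solves the implicit
    convolution equation by fixed-point iteration and the null vector is
    F'(U) U'.
    """

    grid_deg: np.ndarray
    U_shape: np.ndarray
    half_width_rad: float
    mode: str
    null_vector: np.ndarray | None = None  # sigmoid mode only

    @property
    def half_width_deg(self) -> float:
        return float(np.rad2deg(self.half_width_rad))


@dataclass
class TrialResult:
    """One trial's outcome: presented target, recalled angle, wrapped bias."""

    trial: int
    theta: float
    response: float
    bias: float
    prev_theta: float
    T_D: float
    T_I: float
    valid: bool = True


def results_to_frame(results) -> "pandas.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "trial": [r.trial for r in results],
            "theta_deg": [r.theta for r in results],
            "response_deg": [r.response for r in results],
            "bias_deg": [r.bias for r in results],
            "prev_theta_deg": [r.prev_theta for r in results],
            "T_D_ms": [r.T_D for r in results],
            "T_I_ms": [r.T_I for r in results],
            "valid": [r.valid for r in results],
        }
    )


class _Coupling:
    """Precomputed cosine-basis projection implementing w * g on the grid.

    For w(x) = sum_k alpha_k cos(kx) the periodic convolution is exact in
    the truncated Fourier basis:  w*g = sum_k alpha_k pi [c_k cos(kx) +
    s_k sin(kx)] with c_k, s_k the cosine/sine quadratures of g -- two
    dot products per active harmonic, which is what makes long trial
    sequences affordable.  A constant field paired with a mean-free
    kernel (alpha_0 = 0) therefore maps exactly to zero.
    """

    def __init__(self, params: FieldParams):
        x = params.grid_rad()
        dx_rad = 2.0 * np.pi / params.n_grid
        rows, scales = [], []
        for k, alpha in enumerate(params.weight_harmonics):
            if alpha == 0.0:
                continue
            if k == 0:
                rows.append(np.ones_like(x))
                scales.append(alpha * dx_rad)
            else:
                # cos(k(x-y)) = cos kx cos ky + sin kx sin ky
                rows.append(np.cos(k * x))
                scales.append(alpha * dx_rad)
                rows.append(np.sin(k * x))
                scales.append(alpha * dx_rad)
        if not rows:
            raise ValueError("weight kernel has no nonzero harmonics")
        self.basis = np.array(rows)  # (m, n)
        self.scales = np.array(scales)[:, None]  # (m, 1)

    def __call__(self, g: np.ndarray) -> np.ndarray:
        if g.ndim == 1:
            return self.basis.T @ ((self.basis @ g) * self.scales[:, 0])
        return ((self.basis @ g.T) * self.scales).T @ self.basis


def stationary_bump(params: FieldParams) -> BumpProfile:
    """Self-consistent bump U = w * F(U) for the single-cosine kernel.

    Heaviside mode returns the closed form; sigmoid mode continues it by
    fixed-point iteration until the implicit equation holds pointwise.
    Raises if the threshold admits no suprathreshold solution.
    """
    if params.kappa >= 1.0:  # max of sin(2a) is 1
        raise ValueError("no bump: kappa too large")
    a = 0.5 * (np.pi - np.arcsin(params.kappa))  # stable wide branch
    x = params.grid_rad()
    U = 2.0 * np.sin(a) * np.cos(x)
    if params.firing_rate_mode == "heaviside":
        return BumpProfile(params.grid_deg(), U, a, "heaviside")
    conv = _Coupling(params)
    for _ in range(500):
        U_new = conv(params.firing_rate(U))
        if np.max(np.abs(U_new - U)) < 1e-13:
            U = U_new
            break
        U = U_new
    resid = np.max(np.abs(U - conv(params.firing_rate(U))))
    if resid > 1e-8 or U.max() < params.kappa:
        raise ValueError("no bump: fixed-point iteration failed to converge")
    # half-width where U crosses kappa (U = A cos x on this kernel)
    amp = U.max()
    half = float(np.arccos(np.clip(params.kappa / amp, -1.0, 1.0)))
    dU = np.gradient(U, x)
    Fp = params.gamma * params.firing_rate(U) * (1.0 - params.firing_rate(U))
    return BumpProfile(params.grid_deg(), U, half, "sigmoid", null_vector=Fp * dU)


def stationary_stf(params: FieldParams, bump: BumpProfile) -> np.ndarray:
    """Stationary facilitation profile under a clamped bump.

    Pointwise balance of the q-kinetics gives Q = beta F q_plus /
    (1 + beta F); in the Heaviside limit this is the plateau
    beta q_plus / (1 + beta) over the suprathreshold interval (-a, a).
    """
    F = params.firing_rate(bump.U_shape)
    return params.beta * F * params.q_plus / (1.0 + params.beta * F)


def noise_increment(model: NoiseModel, dt: float, grid_deg, rng=None) -> np.ndarray:
    """One spatially correlated increment with covariance C(x-y) dt.

    Built from two independent standard normals so that
    dW = sigma_W (cos(x) xi_1 + sin(x) xi_2) sqrt(dt) has exactly the
    cosine spatial correlation.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    x = np.deg2rad(np.asarray(grid_deg, dtype=float))
    xi = rng.standard_normal(2)
    return model.sigma_W * np.sqrt(dt) * (np.cos(x) * xi[0] + np.sin(x) * xi[1])


def step(
    state: FieldState,
    params: FieldParams,
    stimulus_field: np.ndarray | float = 0.0,
    dt: float | None = None,
    noise: np.ndarray | None = None,
) -> FieldState:
    """One Euler-Maruyama update of (u, q).

    ``noise`` is a pre-drawn increment for u (e.g. from
    :func:`noise_increment` with effective step dt/tau_u); omit it for
    deterministic stepping.  q is clipped to [0, q_plus] only when a
    numerical overshoot exceeds 1e-12.
    """
    if dt is None:
        dt = params.dt
    u, q = state.u, state.q
    F = params.firing_rate(u)
    conv = _Coupling(params)((1.0 + q) * F)
    du = (dt / params.tau_u) * (-u + conv + stimulus_field)
    if noise is not None:
        du = du + noise
    u_new = u + du
    q_new = q + (dt / params.tau) * (-q + params.beta * F * (params.q_plus - q))
    if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(q_new))):
        raise FloatingPointError("numerical blow-up in field step")
    over = (q_new < -1e-12) | (q_new > params.q_plus + 1e-12)
    if np.any(over):
        q_new = np.clip(q_new, 0.0, params.q_plus)
    return FieldState(u_new, q_new)


def bump_center(u: np.ndarray, params: FieldParams) -> float | None:
    """Readout: argmax location in degrees, or None if subthreshold.

    Ties are resolved by the circular centroid of the argmax set.
    """
    u = np.asarray(u)
    m = u.max()
    if m < params.kappa:
        return None
    grid = params.grid_deg()
    idx = np.flatnonzero(u >= m - 1e-12)
    if idx.size == 1:
        return float(grid[idx[0]])
    ang = np.deg2rad(grid[idx])
    return float(wrap_deg(np.rad2deg(np.arctan2(np.sin(ang).sum(), np.cos(ang).sum()))))


class _Engine:
    """Flat-array stepping loop shared by run_trials and delay_ensemble."""

    def __init__(self, params: FieldParams, seed: int, n_paths: int = 1):
        self.p = params
        self.x = params.grid_rad()
        self.cosx = np.cos(self.x)
        self.sinx = np.sin(self.x)
        self.conv = _Coupling(params)
        self.rng = np.random.default_rng(seed)
        self.dtu = params.dt / params.tau_u
        self.dtq = params.dt / params.tau
        self.namp = params.sigma_W * np.sqrt(self.dtu)
        self.n_paths = n_paths
        shape = (params.n_grid,) if n_paths == 1 else (n_paths, params.n_grid)
        self.u = np.zeros(shape)
        self.q = np.zeros(shape)

    def advance(self, n_steps: int, stim: np.ndarray | float = 0.0, noisy: bool = True):
        p, conv = self.p, self.conv
        u, q = self.u, self.q
        dtu, dtq, namp = self.dtu, self.dtq, self.namp
        cosx, sinx = self.cosx, self.sinx
        beta, qp = p.beta, p.q_plus
        gamma, kappa = p.gamma, p.kappa
        heavi = p.firing_rate_mode == "heaviside"
        rng = self.rng
        multi = u.ndim == 2
        for _ in range(n_steps):
            if heavi:
                F = (u > kappa).astype(float)
            else:
                F = 1.0 / (1.0 + np.exp(-gamma * (u - kappa)))
            c = conv((1.0 + q) * F)
            if noisy and namp > 0:
                if multi:
                    xi = rng.standard_normal((u.shape[0], 2))
                    dW = namp * (xi[:, :1] * cosx + xi[:, 1:] * sinx)
                else:
                    xi = rng.standard_normal(2)
                    dW = namp * (xi[0] * cosx + xi[1] * sinx)
                u = u + dtu * (-u + c + stim) + dW
            else:
                u = u + dtu * (-u + c + stim)
            q = q + dtq * (-q + beta * F * (qp - q))
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("numerical blow-up in field advance")
        if q.min() < -1e-12 or q.max() > qp + 1e-12:
            np.clip(q, 0.0, qp, out=q)
        self.u, self.q = u, q

    def steps(self, duration_ms: float) -> int:
        return int(round(duration_ms / self.p.dt))


def _cue_profile(params: FieldParams, theta_deg: float, I0: float, I1: float):
    x = params.grid_rad()
    return I0 * np.exp(I1 * (np.cos(x - np.deg2rad(theta_deg)) - 1.0))


def run_trials(
    schedule,
    params: FieldParams,
    seed: int = 0,
    burn_in_ms: float = 2000.0,
    quiescent_iti: bool = True,
) -> list[TrialResult]:
    """Run a sequence of delayed-response trials through the network.

    The field starts from rest and evolves under noise alone for the
    burn-in, then each trial applies the cue (T_C), the delay (T_D^n,
    readout of the bump peak at its end), the global inactivation (-I_R
    for T_A), and the intertrial interval.  Facilitation is never reset:
    its persistence across the intertrial interval is the carrier of
    serial bias.  A trial whose activity is entirely subthreshold at
    readout is flagged invalid rather than dropped.

    With the smooth (sigmoidal) firing rate at its default gain the
    quiescent state of the ring is not linearly stable, so left
    undriven the network re-nucleates a bump between trials and
    facilitation never decays.  ``quiescent_iti=True`` (default) keeps
    the post-response suppressive drive -I_R on through the intertrial
    interval -- modelling sustained fixation-period suppression -- so
    that activity is truly silent between trials and the facilitation
    trace decays at its own timescale, which is the regime the serial
    bias mechanism describes.
    """
    eng = _Engine(params, seed)
    iti_drive = -schedule.I_R if quiescent_iti else 0.0
    eng.advance(eng.steps(burn_in_ms), iti_drive)
    results: list[TrialResult] = []
    prev_theta = np.nan
    for i in range(schedule.n_trials):
        theta = float(schedule.theta[i])
        T_D = float(schedule.T_D[i])
        T_I = float(schedule.T_I[i])
        eng.advance(eng.steps(schedule.T_C), _cue_profile(params, theta, schedule.I_0, schedule.I_1))
        eng.advance(eng.steps(T_D))
        r = bump_center(eng.u, params)
        valid = r is not None
        if not valid:
            r = np.nan
        bias = float(wrap_bias(r - theta)) if valid else np.nan
        results.append(
            TrialResult(i + 1, theta, float(r), bias, prev_theta, T_D, T_I, valid)
        )
        eng.advance(eng.steps(schedule.T_A), -schedule.I_R)
        eng.advance(eng.steps(T_I), iti_drive)
        prev_theta = theta
    return results


def delay_ensemble(
    params: FieldParams,
    n_paths: int,
    delay_ms: float,
    seed: int = 0,
    cue_ms: float = 150.0,
    record_ms: float = 10.0,
    stf: bool = True,
    theta0: float = 0.0,
    I0: float = 1.0,
    I1: float = 1.0,
):
    """Ensemble of single delay periods aligned at delay onset.

    Each path starts from the stationary bump at ``theta0`` with q = 0,
    receives the cue for ``cue_ms`` (so facilitation builds as in a real
    trial), then runs the noisy delay.  Returns (times_ms, positions)
    with positions the unwrapped bump displacement in degrees, shape
    (n_times, n_paths); time 0 is delay onset.  ``stf=False`` simulates
    the static-synapse network (beta = 0).
    """
    if not stf:
        params = replace(params, beta=0.0)
    eng = _Engine(params, seed, n_paths=n_paths)
    bump = stationary_bump(params)
    eng.u = np.tile(bump.U_shape, (n_paths, 1))
    eng.q = np.zeros_like(eng.u)
    stim = _cue_profile(params, theta0, I0, I1)
    eng.advance(eng.steps(cue_ms), stim)
    rec_every = max(1, int(round(record_ms / params.dt)))
    n_steps = eng.steps(delay_ms)
    n_rec = n_steps // rec_every + 1
    grid = params.grid_deg()
    times = np.empty(n_rec)
    pos = np.empty((n_rec, n_paths))
    last = wrap_deg(grid[np.argmax(eng.u, axis=1)])
    disp = last - theta0
    times[0], pos[0] = 0.0, disp
    for k in range(1, n_rec):
        eng.advance(rec_every)
        cur = wrap_deg(grid[np.argmax(eng.u, axis=1)])
        disp = disp + wrap_bias(cur - last)
        last = cur
        times[k] = k * rec_every * params.dt
        pos[k] = disp
    return times, pos
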