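# Methods

`ringstf` models serial dependence ("interference") in visuospatial
working memory with three linked layers: a normative inference layer,
a mechanistic ring-network layer, and a low-dimensional reduction that
connects them.  This note records the models, the choices that were
genuinely open, the numerical conventions, and what the synthetic
protocols do and do not emulate.

## 1. Inference layer (`ringstf.inference`)

An observer who has seen targets θ₁..θₙ predicts the next one under
the assumption that the hidden target-generating distribution is
resampled between trials with hazard rate ε.  Conditioning on the run
length l (trials since the last change) gives

    L(θ) = Σ_{l=0..n} P(l | ε) · C_l · (1/360) Π_{j=n-l+1..n} f_{θ_j}(θ),

with P(l|ε) = ε(1−ε)^l for l < n and (1−ε)^n at l = n, and C_l the
grid normalizer of each run-length component.  Normalizing each
component (rather than once at the end) makes every conditional a
proper density and reproduces the rapid-change limit
ε/360 + (1−ε)f(θ) exactly; the mixture then integrates to one by
construction.

The tuning kernel family is the exponential of cosines
f(θ) ∝ exp(Σ_j a_j cos(jπ/180·(θ−θ′))), self-conjugate and
shift-invariant.  We adopt ω_j = jπ/180 (period 360°/j in degrees)
throughout; internally the ring is [−π, π) radians so the fundamental
has unit frequency.  The default single-harmonic amplitude a₁ = 2 is
a configuration default chosen so the kernel's central lobe is
comparable to the one the facilitation dynamics expresses; nothing
downstream depends on its exact value.

Limits: ε = 0 is the order-free product of all kernels (static
environment); small ε uses the first-order truncation in ε; ε ≈ 1
keeps one (order 1) or two (order 2) most recent targets.  All
outputs are densities on a uniform periodic grid (default 2000
points, 0.18°) in units of 1/deg, uniform level 1/360.

## 2. Particle layer (`ringstf.ring_dynamics`)

The remembered angle performs drift–diffusion
dθ = −U′(θ)dt + σ_θ dξ on the ring.  The stationary density is the
Boltzmann form χ·exp(−2U/σ_θ²), so a predictive distribution L maps
to the potential U = (σ_θ²/2)·ln(χ/L); we fix χ = 1/360 so a uniform
prediction gives a flat potential.  σ_θ carries no canonical value
and is configuration-only.  The simulator is Euler–Maruyama with a
centered-difference, linearly interpolated −U′; wrapped angles are
kept alongside the unwrapped displacement so variance-versus-time is
well defined over long delays.

## 3. Ring network with STF (`ringstf.neural_field`)

State: synaptic drive u(x,t) and facilitation q(x,t) on the ring,

    τ_u du = [−u + w∗((1+q)F(u)) + I(x,t)] dt + dW,
    τ dq/dt = −q + βF(u)(q₊ − q),

with w(x) = cos(x) (mean-free: merged excitation/inhibition),
F sigmoidal with gain γ = 20 and threshold κ = 0.1 (Heaviside in the
high-gain limit), τ_u = 10 ms, τ = 1000 ms, β = 0.01, q₊ = 2, and
noise white in time with spatial correlation σ_W² cos(x−y),
σ_W = 0.005.  The noise increment is built exactly as
σ_W(cos x·ξ₁ + sin x·ξ₂)√dt from two standard normals.

**Time units.**  The projected diffusion coefficient (below) carries
no τ_u, so the stochastic dynamics are integrated in units of the
synaptic time constant: an Euler–Maruyama step of dt milliseconds
advances the drift by dt/τ_u and the noise by σ_W√(dt/τ_u).  This is
the only reading under which the simulated bump diffusion matches the
projected coefficient and yields degree-scale response spreads; the
per-millisecond reading gives spreads several-fold too small.

**Convolution.**  For a cosine-sum kernel the periodic convolution is
exact in the truncated Fourier basis — two quadratures per active
harmonic — which is what makes ~10⁷-step trial sequences affordable.
A constant field maps exactly to zero through the mean-free kernel.

**Closed forms (Heaviside limit).**  The stationary bump is
U(x) = 2 sin(a) cos(x) with half-width a solving sin 2a = κ on the
stable wide branch, a = (π − arcsin κ)/2 ≈ 87.1° for κ = 0.1; the
stationary facilitation is the plateau βq₊/(1+β) on (−a, a).  The
sigmoid bump (fixed-point iteration from the Heaviside profile)
agrees with the closed form to ~0.1% in peak.

**Firing-rate regime for trial sequences.**  With the default sigmoid
the quiescent state u ≡ 0 is linearly unstable (growth rate
−1 + πF′(0) ≈ +5.6 per τ_u): left undriven, the network re-nucleates
a bump between trials out of noise (or even roundoff), seeded by the
residual facilitation, so the facilitation trace is continuously
refreshed and the serial bias neither decays with the intertrial
interval nor stays at the degree scale.  The Heaviside limit is
quiescent-stable, but a discretized Heaviside interface pins the bump
to the grid and suppresses its diffusion by more than an order of
magnitude on any affordable grid.  We therefore keep the smooth
sigmoid everywhere and hold the post-response suppressive input −I_R
on through the intertrial interval (`run_trials(quiescent_iti=True)`,
the default), modelling sustained fixation-period suppression between
trials.  Activity is then genuinely silent between trials and the
facilitation trace decays at its own timescale — the regime the
serial-bias mechanism describes.  The burn-in (2 s before trial 1)
runs under the same suppression.

**Trial protocol.**  Cue T_C = 150 ms with input
I₀·exp[I₁(cos(x−θₙ)−1)], I₀ = I₁ = 1; delay T_D (readout of the bump
peak at its end; argmax, ties broken by circular centroid; flagged
invalid if all activity is subthreshold); suppression −I_R = −2 for
T_A = 500 ms; then the intertrial interval.  Facilitation is never
reset between trials.

**Integration profiles.**  Reference profile dt = 0.1 ms, dx = 0.18°;
a coarse profile (dt = 0.5 ms, dx = 0.72°) is used for the large
ensemble sweeps.  On a fixed-seed noise-free trial pair the two
profiles agree in response to within the coarse readout resolution.

## 4. Reduction (`ringstf.reduction`)

Projecting the field dynamics onto the bump's translation mode gives
a two-variable system for the bump position θ(t) and the current
trial's facilitation center θ_q(t):

    dθ   = −[A_prev·Ū′(θ−θ_prev) + A_curr·Ū′(θ−θ_q)] dt + σ dξ,
    θ̇_q ∝ −d(θ_q − θ),

where Ū′ is the closed-form potential gradient of a unit facilitation
plateau of half-width a (zero outside |δ| < 2a, odd, attracting), and
d is the shorter-arc circular difference scaled by (1+β).  Only the
previous- and current-trial terms are kept; older deposits are
exponentially negligible.  During cues θ is clamped to the target;
between the response and the next cue no bump exists, so only the
amplitudes evolve (closed-form exponentials with timescale τ).  The
previous trial's plateau is anchored at the previous *target* (its
center has relaxed there by trial end).

Two refinements relative to the raw projection, both validated
directly against the network:

1.  *Amplitude decay through the suppression window.*  The previous
    trial's amplitude decays over the whole bump-free gap T_A + T_I,
    not T_I alone; the network's measured facilitation amplitude at
    the next trial's start (0.122 of plateau at T_D = 2000 ms,
    T_I = 1500 ms) matches the T_A-inclusive closed form (0.120), not
    the T_A-free one (0.197).

2.  *Centroid rate of a rising deposit.*  The rigid-profile center
    θ_q relaxes at ((1+β)/τ)/A_curr(t): fresh facilitation is laid at
    the bump's current position, so a young profile re-centers fast;
    at stationarity (A → 1) this reduces to the bare rate (1+β)/τ,
    which is also the clamped-bump relaxation rate λ_τ.  Without this
    the reduced model over-drags the bump early in the trial and
    underestimates the peak bias by ~20%.

With both, the noise-free reduced and network bias curves agree at
the peak to ~12% with the same shape and zero crossings (at 0° and at
the half-turn), and the closed-form drift itself matches the
network's instantaneous drift under a controlled offset facilitation
patch to ~1%.

**Projected diffusion.**  The position noise is
dθ = ⟨V, dW⟩/⟨V, U′⟩ with V the adjoint null vector (delta pair at
±a in the Heaviside limit, F′(U)U′ for the sigmoid), so the variance
rate is σ² = ⟨V,CV⟩/⟨U′,V⟩² and D = σ²/2 = σ_W²/(8 sin²a) in closed
form.  The simulated β = 0 network's displacement variance grows
linearly with slope 2D (within sampling error at 500 paths); with STF
the late-delay slope falls below half the early slope (two-phase
diffusion), because the bump's own deposit progressively pins it.

## 5. Protocols and analyses

Target laws: the 20-angle uniform pmf (−180°, −162°, …, 162°) for
bias curves; the continuous uniform density for ensemble statistics;
and a first-order chain whose conditional is the even mixture of a
uniform density and a von Mises (concentration 25) centered at
θₙ − μ (μ = 0 local, μ = 90 skewed; positive μ shifts the conditional
mode clockwise so responses err counter-clockwise toward the previous
target).  Duration ladders: T_I ∈ {1000, 1200, …, 5000} ms and
T_D ∈ {0, 200, …, 5000} ms.  The delay-ladder sentence in the source
protocol prints T_I for what is contextually the delay set; it is
implemented as the delay set.  The sampler's mixture weight and the
observer's hazard rate are distinct configuration keys even though
the field reuses one symbol for both.

Analyses: bias curves conditioned on θₙ − θₙ₊₁ (default 18° bins,
matching the 20-angle pmf); peak |mean bias| stratified by T_I or
T_D; response spread as the linear sd of the wrapped bias (the
convention the quoted σ values follow; the circular sd is reported
alongside and agrees to <1% at these spreads); ensemble variance of
the unwrapped displacement versus time with early (first 0.5 s) and
late (final half) slopes.  All bias statistics are invariant under a
global rotation, and wrapping uses the shorter arc (bias of
θ = 179°, r = −179° is +2°).

## 6. What the synthetic protocols do and do not emulate

The generators reproduce the task *structure* (timing, target laws,
suppression) and the model's own noise; they do not emulate sensory
or motor noise, lapses, eye-movement artifacts, or learning across
sessions.  Passing tests therefore validate the mechanism — that
facilitation carries a decaying, graded, attractive trace of the
previous target — not a fit to any behavioral dataset.

Ensemble sizes in the test-suite are scaled for a default run on one
CPU: the response-spread protocols use 300 trials (sd standard error
≈ 0.15°), the diffusion ensembles 500 paths; `scripts/acceptance.py`
runs the full 800-trial protocols.  Under the package defaults
(coarse profile, T_D = 2000 ms, T_I = 1500 ms — the delay and
intertrial interval for the ensemble protocols have no canonical
values) the uniform-protocol spread computes to ≈ 3.5° and
the correlated-protocol spread to ≈ 2.7°, with the correlated run
always narrower on matched seeds; both spreads, and their ratio, are
recomputed rather than asserted anywhere in the package.

## 7. Known limitations

- The degree-scale response spread is sensitive to the (unspecified)
  ensemble-protocol delay and intertrial interval through the
  bias-induced component of the variance.
- The Heaviside mode is provided for the closed forms and statics; it
  is not suitable for simulating diffusion on affordable grids (grid
  pinning), and the sigmoid mode is not suitable for undriven
  intertrial intervals (quiescent-state instability).  The defaults
  navigate both.
- The reduction keeps two facilitation terms and a rigid plateau
  shape; at strong facilitation or very short intertrial intervals
  its accuracy degrades.
- No spiking implementation, no separate excitatory/inhibitory
  populations, no multi-item memory, and no time-dependent
  Fokker–Planck solver (only the stationary density is used).
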