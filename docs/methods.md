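# Methods

`mucuswalk` models the encounter rate between bacteriophage T4 and a
run-and-tumble *E. coli* bacterium inside a mucus layer, treating the mucus
implicitly through two empirically calibrated effects: a mucin-concentration
dependent viscosity and, for the mucin-adherent wild-type phage, heavy-tailed
sticking times that make its motion subdiffusive. This note records the
models, the calibration relations, the numerical choices, and what the
synthetic experiments do and do not establish.

## Phage model: continuous-time random walk

The wild-type phage carries an Ig-like capsid domain (Hoc) that binds weakly
to mucin glycans. Its trajectory is modeled as a CTRW on a uniform time grid
of spacing τ_D (one free-diffusion step): the particle is stationary while a
waiting time τ has not elapsed; on the step where it elapses it takes a single
isotropic Gaussian step with per-axis standard deviation √(2·D·τ_D), draws a
new waiting time from the Pareto law

ψ(τ; ν, τ₀) = (ν/τ₀)(τ₀/τ)^(1+ν),  τ ≥ τ₀,

and repeats. For 0 < ν < 1 the mean waiting time is infinite and the ensemble
MSD grows as t^ν; the simulated anomalous exponent equals ν, which we verify
by regression (see below). Sampling is by CDF inversion, τ = τ₀·(1/U)^(1/ν).
The Δhoc mutant (no Hoc domain) has no waiting times and reduces to plain
Brownian motion with the same step rule.

Scheduling detail: waiting timers start at zero, so every walker takes its
first step at the first grid time; a new waiting time is measured from the
release instant, and the next displacement happens at the first grid time at
or after it. Redrawing from the release instant rather than from the end of
the displacement step shifts each renewal by at most one τ_D; at the
calibrated τ₀/τ_D ratios (~0.15) the ensemble MSD is insensitive to this
choice.

## Calibration from particle-tracking data

Published multi-particle-tracking measurements provide, per mucin
concentration (0–4% w/v): the wild type's anomalous MSD parameters (α, D_α)
and the mutant's standard diffusion constant D. Two consistency relations
turn these into CTRW parameters with ν = α:

τ_D = (D/D_α)^(1/(α−1)),   τ₀ = τ_D · sinc(ν)^(1/ν),

where sinc is the *normalized* sinc, sinc(x) = sin(πx)/(πx). The normalized
convention is the one that makes the two published notations of the
constraint (written once over ν and once over απ) agree and reproduces the
quoted millisecond-scale sticking times; it also closes continuously on
regular diffusion, since sinc(1) = 0 gives τ₀ → 0 as ν → 1. The relation
D_ν = D/τ_D^(ν−1) is the exact inverse of the τ_D extraction and is used as a
round-trip test (recovery of D_α to 1e-9 relative on every subdiffusive
table row). At 1% mucin the calibration gives τ_D ≈ 6.6 ms and τ₀ ≈ 0.98 ms;
the mean τ₀ across the five nonzero concentrations is 1.3 ms (≈ 0.001 s at
one significant figure, the precision this quantity is usually quoted at).

Rows with α ≥ 1 (0% mucin, and the mutant at most concentrations) have no
defined sticking time; they are treated as pure diffusion (ν = 1, τ₀ = 0)
with a warning, and the step time defaults to the common simulation step
0.01 s. For ν > 1 the sinc constraint leaves its domain of derivation (the
normalized sinc is negative on (1, 2)); since any finite waiting-time floor
yields normal diffusion there, the parameter helper uses τ₀ = τ_D, which
only rescales the MSD prefactor, not the exponent.

Mucus viscosity is extracted by microrheology with the mutant phage as probe:
η = kT/(6π·R_P·D), with kT = 4.28 pN·nm (37 °C) and the probe radius
R_P = kT/(6π·η_W·D₀) = 90 nm fixed by requiring the 0% solution to have the
viscosity of water (η_W = 0.69 mPa·s at 37 °C). Both constants are
overridable. The concentration dependence is summarized by two power-law fits
η_M = a·[mucin]^b + η_W — unweighted OLS of ln(η_M − η_W) on ln[mucin] over
the mean viscosities, on the regions 0.2–1% and 1–4% (the 1% point belongs to
both; the 0% point is always excluded). Natural logarithms reproduce the
published intercepts, so that convention is fixed here. The fitted exponents
are b = 0.65 ± 0.15 (sublinear) and b = 1.59 ± 0.20 (superlinear), the
familiar crossover of mucin-solution rheology near 1%.

The momentum relaxation times m/γ (~0.1 µs for the bacterium, ~0.1 ns for the
phage) are over four orders of magnitude below τ_D, so all dynamics are
integrated in the overdamped limit; no inertial integrator is provided.

## Bacterium model: run and tumble

The bacterium swims at constant speed v_B = 30 µm/s along a fixed direction
for an exponentially distributed run time (rate ω_T), then reorients
instantaneously. Zero-duration tumbles keep the exponential run statistics
exact and make the velocity-jump diffusion limit D_B = v_B²⟨τ_R⟩/3 hold
without tumble-time correction. Three regimes are studied: the standard
runner (ω_T = 1 s⁻¹), a frequent tumbler (ω_T = 100 s⁻¹) whose long-time
motion is diffusive with D_B = 3×10⁻¹² m²/s, and a static bacterium, which is
exactly immobile (thermal noise on a cell-sized body is negligible against
propulsion and is dropped entirely).

The default tumble-direction law draws the polar and azimuthal angles
independently and uniformly on [0, 2π) and maps them to
(cosλcosθ, cosλsinθ, sinλ). This yields exact unit vectors but is *not*
uniform on the sphere (it over-weights the poles). It is kept as the default
because successive run directions are independent under either law, so
long-time transport and encounter statistics are insensitive; an isotropic
(area-uniform) mode is available via `isotropic=True` / `--isotropic`-style
options for users who prefer the unbiased law.

Runs are discretized to the simulation grid: a run ends at the first step
boundary at or after its drawn duration (at least one step). At ω_T·dt = 0.01
(standard runner) the per-run discretization error is ≤1% of the mean run
time; at ω_T·dt = 1 (frequent tumbler) the discretization inflates the
effective D_B by about 8%, well inside the Monte-Carlo tolerances used.

## MSD estimation

The ensemble MSD is the replicate average of |x(t) − x(0)|² (ensemble-origin
mode, the default). A time-ensemble mode additionally averages over sliding
origins; the two agree for ergodic processes (Brownian motion, long-time
run-and-tumble) and are tested to agree there, but CTRW is weakly
non-ergodic — sliding-origin averaging of a subdiffusive CTRW follows a
different scaling law — so only the ensemble-origin estimator is expected to
(and does) recover α = ν, and no cross-mode agreement is asserted for CTRW.

(K_α, α) are extracted by OLS on log MSD vs log lag: K_α = exp(β₀), α = β₁.
The default fit window spans the last two decades of available lag time and
excludes the first 10 lags (early-time transient); zero-MSD lags are dropped
with a warning. Noiseless power-law input is recovered to machine precision.
For calibrated CTRW ensembles the fitted prefactor approaches the step-level
asymptote K_α = 2d·D/τ_D^(α−1).

The α(ν) validation uses the 2-D scenario with D = 3.66 µm²/s and
τ_D = 0.05 s, 10⁴ steps × 10³ replicates per ν (one-tenth the replicate
count of the original study, chosen to keep the sweep under a minute per ν
on one core): fitted α lies within ±0.05 of ν for ν ∈ {0.25, 0.5, 0.82} and
within ±0.05 of 1 for ν ∈ {1.5, 2}.

## Encounter experiment

One bacterium starts at the center of a periodic cube (L = 100 µm,
V = 10⁶ µm³); n_phage non-interacting phage start uniformly distributed
outside the adsorption sphere of radius R_C = R_B + R_P = 1.1 µm (matching
the theory's initial condition P(r, 0) = 0 for r ≤ R_C). Distances use the
minimum-image convention. Per step of dt = 0.01 s, each species advances
under its own dynamics; an *active* phage whose minimum-image distance to the
bacterium falls below R_C is tallied as one encounter and flagged inactive —
it keeps moving but cannot tally again until it has been reactivated at
distance ≥ 50 µm (attainable, since the maximum minimum-image distance is
50√3 µm). Phage are recycled, never removed, so the far-field concentration
is maintained. The per-step kernel estimate is β = N_enc·V/(N_act·dt) with
N_act counted at the start of the step; steps with N_act = 0 record a missing
value rather than dividing by zero.

Encounter detection is end-of-step only. This is safe at the default
parameters: the bacterium moves v_B·dt = 0.3 µm < R_C per step (asserted at
configuration time, warning if violated) and the phage's 3σ Gaussian step is
0.67 µm < R_C at 1% mucin.

Because per-step encounter counts are small integers, reported kernels are a
windowed moving average, a running (cumulative) mean, and a post-transient
time average β̄ = V·ΣN_enc/(dt·ΣN_act) over steps after a 500-step transient,
with a Poisson standard error β̄/√(ΣN_enc). Reproducibility is per-seed: the
master seed spawns independent substreams for initialization, bacterium and
phage, so identical configurations give bit-identical series, and trajectory
ensembles derive one substream per replicate so that replicate i does not
depend on the ensemble size.

The validation experiments use 10⁴ phage for 10⁵ steps (1000 s) per
regime × phage combination — about two minutes each on one core — versus the
original study's 10⁸ phage; the phage are independent, so this costs only
statistical resolution (Poisson errors of ~3–15% on β̄ depending on regime).

## Encounter-kernel theory

In the bacterium's rest frame the relative MSD is the sum of the two MSDs,
giving the instantaneous diffusivity 𝔇(t) = v_B²⟨τ_R⟩/3 + α·D_α·t^(α−1) in
three dimensions. Feeding 𝔇(t) into the absorbing-sphere problem yields the
flux 𝒥(t) = 4π·P_∞·R_C·𝔇(t)·(1 + √(R_C²/(π·λ(t)))) with λ(t) = ∫₀ᵗ 𝔇 dt′
(the λ(0) = 0 convention makes the α = 1, v_B = 0 case reduce exactly to the
textbook Smoluchowski transient 4πR_C·D·(1 + R_C/√(πDt))). β(t) = 𝒥(t)/P_∞.
⟨τ_R⟩ enters as the mean run time 1/ω_T. Closed-form limits used throughout:

* ballistic (long runs): β_ball = π·R_C²·v_B = 4.1×10⁻⁷ mL/h at the default
  parameters;
* frequent tumbler: β_∞ = 4πR_C·(v_B²⟨τ_R⟩/3 + [D if α = 1]), giving
  1.49×10⁻⁷ mL/h (wild type, whose subdiffusive term decays away) and
  2.77×10⁻⁷ mL/h (mutant) at ω_T = 100 s⁻¹;
* static bacterium: 4πR_C·D = 1.26×10⁻⁷ mL/h for the mutant; for the
  subdiffusive wild type β(t) ∝ t^(α−1) decays with no nonzero steady state.

The ballistic-to-static uptake ratio is β_ball/(4πR_C·D) = R_C·v_B/4D = 3.25.
Kernels are reported in both µm³/s and mL/h through the single conversion
1 µm³/s = 3.6×10⁻⁹ mL/h. For α < 1 the small-t behavior of the transient
term is an extrapolation of the continuum theory below the step time τ_D;
the provided time grids are user-chosen and values at t ≲ τ_D should be
read with that caveat.

## Simulation versus theory: what agrees, and one honest discrepancy

With the calibrated 1%-mucin parameters and the desk-scale experiment above,
the time-averaged simulated kernels agree with the matching closed forms
within Monte-Carlo tolerances in five of six regime × phage combinations:
standard runner + wild type (+7% of β_ball), frequent tumbler (−4% wild
type, −19% mutant, the latter dominated by end-of-step detection loss at
ω_T·dt = 1), static + mutant (−15% of the Smoluchowski value), and static +
wild type (+12% of the window-averaged decaying kernel). The qualitative
orderings hold: a motile bacterium makes the kernel nearly independent of
phage transport, and around a static bacterium the Brownian mutant clearly
outperforms the subdiffusive wild type, whose kernel decays.

The one systematic deviation is the standard runner + Brownian mutant: the
simulation gives 5.2×10⁻⁷ mL/h, 27% above β_ball. This is physics, not
noise (the Monte-Carlo error is ~3%): a diffusing phage contributes its own
capture flux on top of the swept cylinder, and the simulated value matches
the additive estimate β_ball + 4πR_C·D = 5.4×10⁻⁷ mL/h well within the
Monte-Carlo tolerance (asserted as its own test). The
swept-cylinder kernel is only the leading term for a fast swimmer; for the
wild type the extra term decays with time, which is why that combination
agrees with β_ball alone. The corresponding acceptance assertion is left
failing rather than loosening the tolerance or altering the experiment.

## What the synthetic experiments do not show

The mucus is implicit and homogeneous: no mucin mesh geometry, no
viscoelasticity or shear-thinning, no hydrodynamic coupling between swimmer
and phage (the local flow field around a swimming bacterium is precisely the
mechanism this kind of model cannot probe). Phage are non-interacting and
never depleted; there is one bacterium, no chemotaxis, and v_B does not vary
with mucin concentration. Agreement of the simulated kernels with the
closed forms validates the stochastic machinery and the calibration chain,
not the biological completeness of the model.

## Defaults

| parameter | value | meaning |
| --- | --- | --- |
| kT | 4.28 pN·nm | thermal energy at 37 °C |
| η_W | 0.69 mPa·s | water viscosity at 37 °C |
| R_P | 0.09 µm | phage hydrodynamic radius (calibrated) |
| R_B | 1 µm | bacterium radius |
| R_C | 1.1 µm | adsorption radius R_B + R_P |
| v_B | 30 µm/s | run speed |
| ω_T | 1 s⁻¹ (or 100 s⁻¹) | tumble rate |
| dt (= τ_D) | 0.01 s | simulation step |
| L | 100 µm | periodic box edge |
| reactivation distance | 50 µm | inactive → active threshold |
| transient discard | 500 steps | for time-averaged kernels |
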