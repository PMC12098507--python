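# Methods

## Model

The package simulates a one-dimensional reaction coordinate x(t) governed
by the generalized Langevin equation (GLE) in the linear-friction
approximation,

    m ẍ(t) = − ∫₀ᵗ Γ(t−t′) ẋ(t′) dt′ − U′(x(t)) + F_R(t),

in the asymmetric piecewise-quartic double well

    U(x) = U_L[(x/L_L)² − 1]²                   for x ≤ 0,
    U(x) = U_R[(x/L_R)² − 1]² + (U_L − U_R)     for x > 0.

U and U′ are continuous at the barrier top (x = 0); U″ is discontinuous
there (one-sided values −4U_s/L_s²), which leaves the dynamics
unperturbed. The left-minimum energy is pinned to zero and the minima sit
at −L_L and +L_R, with well curvatures K_s = 8U_s/L_s².

The memory kernel is a sum of exponentials, Γ(t) = Σᵢ (γᵢ/τᵢ)e^(−|t|/τᵢ),
with total friction γ = Σγᵢ. At equilibrium the random force satisfies the
fluctuation–dissipation relation ⟨F_R(t)F_R(t′)⟩ = β⁻¹Γ(t−t′), realized
per component. The non-equilibrium variant keeps an exponential friction
kernel with decay τ_V but drives the system with an *independent*
exponential random force of decay τ_R (both integrating to γ); for
τ_R ≠ τ_V the stationary distribution is no longer Boltzmann.

Everything is expressed in the dimensionless frame k_BT = 1, L_L = 1,
γ = 1, so studies are specified by (βU_L, βU_R, L_R/L_L, τ_m/τ_D, τ/τ_D)
with inertial time τ_m = m/γ and diffusion time τ_D = βL_L²γ = 1.
Conversion to physical units is a matter of supplying β, L_L, γ explicitly
— every function takes them as arguments.

## Closed-form MFPT predictions

The well-to-well MFPT for a symmetric well (barrier U₀, curvature K)
interpolates the Kramers limits:

    τ_MFP = e^(βU₀) [ (1/βU₀)(3π/8√2)(m/γ + 2Kτ²/3γ)
            + (2√2πγ/K)/(1 + KβU₀τ/4γ) + 4√(2m/K) ].

The three addends are exposed on the returned `TheoryPrediction` as the
energy-diffusion (inertial), overdamped, and crossover terms. The
well-to-*barrier-top* MFPT uses the same expression with the overdamped
prefactor halved (√2πγ/K) and side-specific U_s, K_s; in the overdamped
Markovian limit it is exactly half the well-to-well time, and for long
memory the ratio tends to one because the τ²-term dominates both. For
multi-exponential kernels, per-component overdamped contributions add
while per-component energy-diffusion contributions combine harmonically;
the N = 1 case reproduces the single-exponential formula bit-exactly. The
non-equilibrium prediction is the well-to-top formula with
β → β_NEQ = βτ_R²/τ_V² and τ → τ_V.

An exact overdamped Markovian oracle is provided as the double quadrature
βγ∫ dy e^(βU(y)) ∫ dz e^(−βU(z)); the open lower limit is truncated where
the Boltzmann weight falls below 1e−12 of its maximum (a reflecting
boundary can be imposed instead). The interpolation formulas are
asymptotic in the barrier height: against this oracle the well-to-well
form deviates by 20% at βU₀ = 2, 10% at 5, and 5% at 8.

## Integrator

The GLE is integrated by Markovian embedding. Each kernel
component is one auxiliary force z_i (friction + thermal noise combined)
with the exact one-step update

    z_i ← e^(−dt/τᵢ) z_i − γᵢ(1 − e^(−dt/τᵢ)) v + σᵢ ξ,
    σᵢ² = (γᵢ/βτᵢ)(1 − e^(−2dt/τᵢ)),

inside a symmetric splitting (half kick with potential + auxiliary forces,
half drift, auxiliary update, half drift, half kick). The auxiliary
recursion is the exact discrete convolution of e^(−t/τ) with the velocity,
so stiffly short τᵢ do not constrain dt; with vanishing friction the
scheme reduces to velocity Verlet and conserves energy to O(dt²) per step
with no secular drift. The non-equilibrium engine splits the auxiliary
force into a noiseless friction convolution (decay τ_V) and an independent
stationary Ornstein–Uhlenbeck force of variance γ/(βτ_R).

Initial conditions are stationary: Maxwellian velocity, auxiliary forces
from N(0, γᵢ/βτᵢ); the non-equilibrium friction convolution starts at zero
and a burn-in of 10 τ_D (configurable) is discarded in all cases. Gaussian
increments are pre-generated with numpy's SFC64 generator from a
SeedSequence, so trajectories replay bit-exactly from their seed, in
chunks whose decimation phase is threaded through, making chunked and
monolithic runs identical.

Timestep policy: the stability contract requires
dt ≤ 0.1·min(τ_m, minᵢτᵢ, √(m/K_max)); the library default is a
conservative factor 0.01 of the fastest scale (including τ_D). The bundled
scaled-down studies run at the contract bound (factor 0.1), which a
dt-halving test shows shifts MFPT estimates by less than their standard
errors. Validation of the engine includes harmonic equipartition, the
free-diffusion Einstein relation, stationary histograms against
e^(−βU), realized noise autocovariance against β⁻¹Γ, agreement with an
independently coded white-noise BAOAB integrator in the memoryless limit,
and — for the non-equilibrium engine — the exact stationary variance
obtained from the spectral density of the linear (harmonic-well) GLE.

## First-passage extraction

MFPTs use the mean all-to-first-passage convention: every crossing of the
start coordinate (well minimum) opens a passage, and all open passages
close at the next crossing of the target (barrier top at 0, or the other
minimum). Crossings are located by linear interpolation between bracketing
samples (a sample exactly on a level counts as the negative side; the
choice is inconsequential for diffusive paths). Passages sharing a closing
arrival form a group; the estimator's standard error is a circular
moving-block bootstrap over ~50 blocks of consecutive groups (200
resamples, seeded), because at long memory times a single well sojourn
produces many serially correlated recrossing groups and a plain per-group
bootstrap would understate the error. Estimates with fewer than 100 groups
are flagged unreliable. Long runs stream through the crossing detector in
chunks, so memory use is independent of run length; the streaming path is
property-tested to agree exactly with the array path and with an O(n²)
brute-force scan.

## Study sizing and scaled-down reproductions

Per sweep point, the run length is sized from the closed-form predictions
themselves: total simulated time ≈ 1.3 × (events target) × (τ̂_L + τ̂_R)
(doubled for well-to-well observables), so the requested number of passage
groups accrues without hand-tuned step counts. The bundled parameter
studies use 300 events per point, reduced to 30–60 at τ/τ_D = 10 where a
single MFPT reaches 10⁴–10⁵ τ_D; all tables carry achieved SEMs so
comparisons are calibrated by the statistics actually collected. A desk
machine completes the full acceptance suite in minutes.

## Choices where the design was open

- **Fit protocol** (`fit_double_well`): trust-region least squares over
  six parameters (U_L, U_R, L_L, L_R plus horizontal/vertical shifts),
  initialized from smoothed-profile extrema; the shift is reported so the
  fitted frame (barrier at 0, left minimum at energy 0) is explicit.
  Profiles without a two-minima/one-maximum topology are rejected.
- **Crossing convention**: interpolated crossing times rather than
  grid-snapped ones; any sign change counts as a visit (no dwell
  criterion).
- **τ_V/τ_D for the non-equilibrium studies**: the effective-temperature
  replacement β → βτ_R²/τ_V² is the *long-memory harmonic limit*: the
  exact stationary variance of the harmonic-well non-equilibrium GLE
  (computed from the spectral density) approaches 1/(β_NEQ K) only when
  τ_V√(K/m) ≫ 1, and deviates by tens of percent when τ_V is comparable
  to the well oscillation period. The default study therefore uses
  τ_V/τ_D = 1.0 (where the harmonic effective temperature is accurate to
  ~1% for the masses and curvatures studied); τ_V remains a parameter.
- **α3D-like fixture**: built synthetically from the published double-well
  parameters of the α3D folding landscape (unfolded well left:
  βU = 1.7, L = 0.15; folded well right: βU = 3.2, L = 0.08), not from MD
  data; it exercises the fitting round trip only.

## Known limitations

- The closed-form MFPTs are asymptotic in βU and least accurate in the
  memory-induced speed-up regime (τ/τ_D ≈ 1) at low barriers: at
  βU = 3, τ_m/τ_D = 0.01 the well-to-top prediction exceeds simulation by
  ~25%, shrinking to ~10% at βU = 4–5. This mirrors the formulas'
  interpolating character; the ratio observables and high-barrier
  comparisons are much tighter.
- The non-equilibrium effective-temperature prediction is quantitative
  only for τ_R/τ_V near 1 even in its validity regime: at
  τ_R/τ_V = 1.25 the simulated MFPT falls ~15–20% below the prediction
  (the stationary state matches the β_NEQ equilibrium only in its
  harmonic second moment, not in its barrier tails). The trend and the
  equilibrium-recovery point are exact.
- The synthetic studies emulate dynamics *on* a prescribed 1-D free-energy
  profile with exponential memory. They do not model multidimensional
  effects, position-dependent friction or mass, non-exponential kernels,
  or extraction of profiles/kernels from real trajectories — so passing
  tests validate the simulator/theory pair, not the 1-D projection of any
  particular molecular system.
- Simulation requires m > 0; the massless limit exists only in the
  closed-form theory.
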