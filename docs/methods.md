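# Methods

## The model

A trajectory q(t) of a system obeying a stationary-action principle is
*scale-free* when the rescaling q → λq, t → λ^α t maps physical
trajectories onto physical trajectories; equivalently, the action of the
rescaled path equals the original up to a path-independent constant κ(λ).
It is *scale-symmetric* when κ ≡ 1. For a Lagrangian L(q, q̇, t) the
symmetric case holds iff

    L(λq, λ^{1-α} q̇, λ^α t) = λ^{-α} L(q, q̇, t),

i.e. L scales like inverse time. For a power series L = Σ C_{xyz} q^x q̇^y
t^z, matching powers of λ fixes the position exponent of every term,

    x = -α - (1-α) y - α z,

so the symmetric family is parameterised by the temporal exponent α and
the coefficients C_{yz} alone (`family.solve_position_exponent`).
Exponents are kept real (not restricted to integers), which restricts the
domain to q > 0; planar systems use the radius r > 0.

Multiplying the whole series by q^δ defines the deviation family

    L = q^{δ-α} Σ_y C_y q^{y(α-1)} q̇^y        (time-independent, 5 terms),

with δ = 0 symmetric and δ ≠ 0 merely scale-free. A key algebraic fact is
that the *trajectories* of this family are scale-covariant for **every**
δ (all terms of the equation of motion are homogeneous of matching degree
under the rescaling): what δ breaks is the invariance of the action,
κ = λ^δ. Tests therefore separate the two regimes by the action ratio and
by the Noether charge, never by trajectory covariance.

The y = 1 term is a total time derivative (gauge term): it changes L but
not the dynamics, so the inference parameter vector omits C1.

### Noether charge

An infinitesimal scale transformation of a symmetric action conserves

    N = (q - α t q̇) ∂L/∂q̇ + α t L = q ∂L/∂q̇ - α t H,

with H = q̇ ∂L/∂q̇ - L the energy. For the power-series family this has a
closed form with a q̇^{-1} factor; the implementation always evaluates the
general expression (finite at q̇ = 0) and keeps the closed form as an
independent cross-check. Along a trajectory of the δ-family,
dN/dt = δ q^δ L_sym: the charge drifts exactly when δ ≠ 0. The drift
statistic is max_i |N(t_i) - median N| / (|median N| + 10⁻¹²); the median
reference is robust to integrator transients and the floor keeps the
statistic defined for zero-centred series. Noiseless integrations are
reported as "conserved" below a default drift of 10⁻⁴.

### Equations of motion

1D: the Euler-Lagrange equation of the δ-family solves in closed form to

    q̈ = q^{-1} Σ_y C_y (1-y)((α-1)y + δ - α) q^{(α-1)y} q̇^y
         / Σ_{y≥2} y(y-1) C_y q^{(α-1)y} q̇^{y-2},

with the q^{δ-α} prefactor cancelling. A denominator below 10⁻¹² (absolute,
configurable) raises a singular-dynamics error; the choice is arbitrary in
the sense that the theory does not single out a tolerance, and is exposed
as a parameter.

2D (planar central reading, r = |u|, v = |u̇|): the Euler-Lagrange system
is (P I + Q u̇ u̇ᵀ) a = b with

    P = Σ y C_y r^{e_y} v^{y-2},   Q = Σ y(y-2) C_y r^{e_y} v^{y-4},
    b = Σ C_y e_y r^{e_y-2} v^y u - Σ y C_y e_y r^{e_y-2} (u·u̇) v^{y-2} u̇,

e_y = δ - α + y(α-1), solved by Sherman–Morrison. For α = 2, δ = 0 with
terms {C0, C2} this is exactly the attractive inverse-cube force
a = -(C0/C2) r^{-4} u; for α = 3/2, δ = 1/2 it is exactly the Kepler
system (L = C2 v² ... reduces to ½mv² + k/r with m = 2C2, k = C0). Both
identities are asserted in the test suite against the independent
force-law integrator.

Both equations of motion are verified against independent Euler-Lagrange
oracles: a fully symbolic derivation (sympy, 1D, 10⁻¹⁰ relative) and a
finite-difference derivation with its own Lagrangian arithmetic (2D,
~10⁻⁴, limited by second-order differencing).

## Simulators

Fixed-step classical RK4 throughout, with numba-compiled kernels (the
pure-Python closed forms are retained as the reference and the two are
asserted equal). Fixed stepping keeps grids aligned with the discrete-time
inference and makes seeded runs bit-reproducible; a step-doubling check
(`refinement_error`, `certified_prefix`) provides an a-posteriori accuracy
certificate. Attractive singular potentials can reach the origin in finite
time; a collision guard (default r_min = 10⁻³) checks every RK4 stage
point and aborts with the valid partial trajectory attached. For runs that
approach the singularity, `certified_prefix` bounds the usable span by
verified accuracy (relative position change ≤ 10⁻¹⁰ under step halving)
rather than an ad-hoc position cut-off. Energy and (in 2D) angular
momentum conservation serve as integration checks (≤ 10⁻⁸ relative at the
default steps).

### Stochastic observation model

The state-space generative model adds fluctuations to the two state
equations (position and velocity derivatives) and observation noise to the
output. Process noise is Gaussian-kernel-smoothed white noise with a
single temporal width — one interpretable parameter capturing the smooth,
non-Markovian character the theory assumes for state fluctuations — added
to the derivatives inside the integrator. Observation noise is white by
default (the non-Markovian qualifier belongs to the state noise; smoothing
the *observation* noise would put temporally correlated errors against a
white-noise likelihood and bias estimates far beyond their nominal
posterior spread). All draws come from one named generator per call with a
mandatory integer seed; identical seeds give bit-identical series. When
process noise is zero, the latent path is integrated on a 10× refined grid
and subsampled, so the returned "truth" is integrator-accurate well below
the observation noise.

### Fixture conditions

The packaged fixtures define the study conditions used by the test suite;
where the theory fixes no value, the choices below were made once and
documented here.

| fixture | system | samples | noise |
|---|---|---|---|
| `symmetric_1d` | α=2, δ=0, C0=1, C2=0.5; q0=1, v0=1.5 | 200 over 10 s | obs 1 % of signal sd; smoothness 0.1 s (process only) |
| `scalefree_1d` | same with δ=1 | 200 over 10 s | same |
| `noisy_symmetric` / `noisy_scalefree` | as above | 200 over 10 s | obs 5 %, process sd 0.01, smoothness 0.2 s |
| `spiral_2d` | inverse-cube, m=k=1; u0=(1,0), u̇0=(-1,1) | 200 over 0.4 s | obs 1 % (white) |
| `ellipse_2d` | inverse-square, m=k=1; u0=(1,0), u̇0=(0,1.1) | 200 over one radial period (≈8.95 s) | obs 1 % (white) |

The 1D initial state (q0 = 1, v0 = 1.5) gives H > 0 and outward motion, so
the whole 10 s window is collision-free. The spiral's initial velocity
puts it on the pure-exponential branch of the inverse-cube orbit
(radial velocity -ℓ/(m r0) with ℓ² < 2mk), so log r is exactly affine in
the polar angle; the orbit collapses at t = 0.5, and the window stops at
0.4. The ellipse is mildly eccentric (tangential speed 1.1 at r = 1) and
observed for exactly one radial period.

## Inversion

The observed series y is modelled as a deterministic trajectory of the
family, integrated from estimated initial conditions, plus white Gaussian
observation noise with unknown precision λ_g = exp(h). This is a
deliberate simplification of generalised-coordinate filtering schemes
(DEM): latent states are not filtered; process noise is absorbed into the
hyperparameter-weighted residual. The scheme is judged on parameter and
model recovery against the simulators, which provide exact ground truth.

Parameters: θ = (α, δ, C0, C2, C3, C4) plus (log q0, v0) in 1D or
(x0, y0, vx0, vy0) in 2D. Optimising log q0 enforces the q > 0 domain.
Priors: θ components N(0, 1); initial-state components get data-informed
means (first sample; slope of a linear fit to the first ten samples — a
raw first difference is far too noisy at small dt) with unit variance.
Hyperpriors on the three log-precisions are N(1/64, 16): the mean follows
the shrinkage-prior convention for this model class, and the wide variance
lets the data set the noise level — a tight hyperprior pins the assumed
noise near sd 1 and makes the scheme unable to fit its own synthetic data.
All priors are overridable in `ModelSpec`.

The variational free energy is

    F = -λ/2 ‖y - g(μ)‖² - λ/2 tr(Jᵀ J Σ) + (n/2) ln λ - (n/2) ln 2π
        - KL(q(θ) ‖ p(θ)) - KL(q(h) ‖ p(h)),

with g the integrated trajectory at the posterior mean, J its Jacobian
(forward differences), Σ the posterior covariance and λ = exp(posterior
mean log-precision). An uninvertible candidate (collision, singular
dynamics) scores -∞ and is treated as a rejected step. The two
process-noise log-precisions do not enter the deterministic likelihood;
they remain at their prior (zero KL) and are reported as such.

`invert` is staged:

1. **Basin scan.** The trajectory objective is multi-modal in (α, δ). On a
   coarse grid (α ∈ 0.5…3 step 0.5, δ ∈ -1.5…1.5 step 0.5) only C0 and
   the initial state are fitted, with C2 = 0.5 fixed — a pure gauge
   choice, since the equation of motion depends on the coefficients only
   through ratios — and C3 = C4 = 0. The best nodes (plus the best δ = 0
   node, the hypothesis under test) seed the refinement.
2. **Mode search.** Penalised least squares (trust-region reflective) on
   the λ-weighted residual stacked with the Cholesky-whitened prior
   deviation, alternating with the scalar Newton MAP update of h; the
   starting λ comes from the grid-phase residual.
3. **Variational-Laplace polish.** Damped Gauss-Newton ascent on F with
   Levenberg-style damping; parameter steps and hyperparameter updates are
   accepted only if F does not decrease, so the accepted-step F trace is
   monotone. The posterior covariance is the inverse curvature
   (λ JᵀJ + Π₀)⁻¹ at the final mean; convergence is ΔF below tol
   (default 10⁻³) within max_iter (default 32), otherwise the best iterate
   is returned flagged.

### Model reduction and the decision

Bayesian model reduction re-scores the fitted model under a reduced prior
that pins δ: prior mean 0, prior variance ε = 10⁻⁸ (a finite stand-in for
the exact-zero limit, keeping every precision matrix finite). With
precisions Π₀, Π_q, Π_r the reduced posterior has precision
Π_p = Π_q + Π_r - Π₀ and

    ΔF = ½ [ln|Π_q| + ln|Π_r| - ln|Π₀| - ln|Π_p|]
       + ½ [m₀ᵀΠ₀m₀ - m_qᵀΠ_q m_q - m_rᵀΠ_r m_r + m_pᵀΠ_p m_p],

verified against brute-force quadrature of both evidences on one- and
two-parameter problems to 10⁻⁶. Probabilities default to the stable
softmax of the two free energies; the alternative normalisation
F_r/(F_r + F_f) is provided verbatim for reproduction but rejects
mixed-sign inputs, since for negative log evidences it prefers the less
probable model. A tie at p = 0.5 is reported "undetermined".
`classify_symmetry` finally integrates the trajectories implied by both
posterior means and reports their Noether drifts: the symmetric fit should
conserve the charge, the scale-free one generally should not.

## Identifiability: why the decision fixtures are planar

A single monotone 1D series constrains the equation of motion only along a
one-dimensional curve in (q, q̇). With the quintic coefficients free, a
δ = 0 member can reproduce a δ = 1 trajectory to ~10⁻⁶ rms — measured,
not hypothetical — so δ is unidentifiable under those conditions no matter
the inference scheme; the posterior honestly reports sd(δ) ≈ prior sd.
Planar orbits are qualitatively richer: the spiral is exactly the
(α, δ) = (2, 0) member, the Kepler ellipse exactly (3/2, ½), and the best
δ = 0 fit to the ellipse leaves a residual of ~4 % of signal sd, three
hundred times the 1 % observation noise. The model-selection and recovery
studies therefore use the spiral/ellipse fixtures (20 seeded series, 200
samples, 1 % noise: selection ≥ 80 %, posterior coverage of (2, 0) on
spirals and exclusion of δ = 0 on ellipses in ≥ 8/10). The 1D fixtures
remain for the conservation contrast and fit-quality checks, with their
weak-δ limitation stated.

## Problem sizes and runtime

Test-suite inversions use the 200-sample fixtures; the 20-series selection
study runs in ~1.5 minutes on one core (numba-compiled trajectory kernels,
~0.1 ms per 200-step integration). Oracle comparisons use 100 random
family members; conservation checks integrate at dt = 10⁻³.

## Known limitations

- No latent-state filtering: strong process noise is misattributed to
  observation noise, flattening the evidence contrast (the `noisy_*`
  fixtures probe this regime).
- Single-series inversion only; trial averaging and subject-level model
  averaging are out of scope.
- The likelihood assumes white observation noise; temporally correlated
  observation noise biases estimates beyond their nominal uncertainty.
- Driven (z ≠ 0) terms are supported in evaluation and Noether
  computation, not in the closed-form equations of motion or inversion.
- The basin scan covers α ∈ [0.5, 3], δ ∈ [-1.5, 1.5]; systems far outside
  that range need user-supplied starts via `ModelSpec` priors.
- The Laplace posterior is a local Gaussian; on strongly ridged posteriors
  (1D data) its covariance describes the ridge only locally.
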