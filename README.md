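# scalesym

Detect **scale symmetry** — as opposed to mere **scale freeness** — in time
series from dynamical systems that obey a stationary-action principle.

Many systems, neural dynamics prominently among them, look the same at
different magnifications: rescaling space by λ and time by λ^α maps
trajectories onto trajectories. That is *scale freeness*. A strictly
stronger property is *scale symmetry*: the action itself is invariant,

S[q(t)] = S[λ q(λ^{-α} t)],

which holds iff the Lagrangian transforms like inverse time,

L(λq, λ^{1-α} q̇, λ^α t) = λ^{-α} L(q, q̇, t).

Writing L as a power series Σ C_{xyz} q^x q̇^y t^z, this condition fixes
every position exponent, x = -α - (1-α)y - αz, leaving a family
parameterised by (α, {C_yz}) alone. Multiplying the whole series by q^δ
yields a one-parameter deviation: δ = 0 is scale-symmetric, δ ≠ 0 is
scale-free only. By Noether's theorem, scale symmetry conserves the charge

N = (q - α t q̇) ∂L/∂q̇ + α t L = q ∂L/∂q̇ - α t H,

so the question "is this system scale-symmetric?" becomes a Bayesian model
comparison: fit the δ-free state-space model to an observed series, reduce
it to δ = 0 by Bayesian model reduction, and compare free energies. The
conserved (or drifting) charge N along the fitted trajectory is the
physical readout.

The classical benchmark: a particle under an attractive inverse-cube force
(V = -k/q², logarithmic-spiral orbits) is the unique scale-symmetric
kinetic-plus-power-potential system (α = 2, potential exponent -2), while
the inverse-square force (V = -k/q, Kepler ellipses) is scale-free but not
scale-symmetric.

The package provides, in `scalesym`:

- `family` — the power-series Lagrangian family, scale transforms, the
  symmetry-defect diagnostic, and closed-form equations of motion (1D and
  planar central-force);
- `noether` — the Noether charge (general and closed form, 1D and 2D) and
  a drift statistic quantifying its conservation along trajectories;
- `simulate` — RK4 integrators with collision guards and step-doubling
  certificates, spiral/ellipse particle ground truths, a stochastic
  observation model with smooth (non-Markovian) process noise, and seeded
  fixtures;
- `inference` — variational-Laplace inversion of the state-space model,
  Bayesian model reduction over δ, model probabilities, Noether parameter
  maps, and scikit-learn-style estimators (`VariationalLaplace`,
  `ScaleSymmetryClassifier`);
- a CLI: `scalesym simulate | noether | invert | compare | sweep`.

## Worked example

Classify the two classical ground truths (200 observed samples each, 1 %
observation noise):

```python
from scalesym import make_fixture, ScaleSymmetryClassifier

spiral = make_fixture("spiral_2d", seed=1)      # inverse-cube: symmetric
clf = ScaleSymmetryClassifier().fit(spiral.observed.times, spiral.observed.y)
post = clf.posterior_full_
print(clf.label_, clf.p_symmetric_)
print(post["alpha"], post.sd("alpha"), post["delta"], post.sd("delta"))
```

prints

```
label        : scale-symmetric
p(delta = 0) : 0.839
alpha        : 2.001 +/- 0.147
delta        : -0.042 +/- 0.187
N drift (reduced posterior) : 3.55e-08
```

— the posterior covers the generating values (α, δ) = (2, 0), the
reduced (symmetric) model wins the evidence comparison, and the Noether
charge along the fitted symmetric trajectory is constant to 4 parts in
10⁸. The same code on the Kepler ellipse (`"ellipse_2d"`) prints

```
label        : scale-free
p(delta = 0) : 0.000
delta        : 0.501 +/- 0.001
N drift (full posterior)    : 1.00
```

— δ is pinned sharply at ½ (the Kepler Lagrangian ½v² + k/r is exactly
the family member α = 3/2, δ = ½), zero is excluded, and the charge
drifts: scale-free, not scale-symmetric.

From the shell:

```
scalesym simulate --fixture spiral_2d --seed 1 --out runs/spiral
scalesym compare --data runs/spiral/data.csv
```

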