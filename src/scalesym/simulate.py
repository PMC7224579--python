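"""Ground-truth simulators: deterministic trajectories and noisy observations.

Two kinds of generator live here. Deterministic integrators produce the
classical-particle ground truths — the scale-symmetric case is a particle in
an attractive inverse-cube force field (V = -k/q**2, logarithmic-spiral
orbits in 2D), the merely scale-free contrast is the inverse-square force
(V = -k/q, elliptical orbits). A stochastic wrapper turns the equation of
motion into a state-space generative model,

    x    = qdot + w_f(x)
    xdot = qddot(q, qdot; alpha, delta, C) + w_f(xdot)
    y    = q + w_g,

whose state fluctuations are smooth (Gaussian-kernel-filtered white noise
with a single temporal smoothness width), emulating small non-Markovian
fluctuations; observation noise is white by default (``obs_smoothness``
widens it if desired).

Fixture conditions
------------------
The packaged fixtures define the study conditions used throughout the test
suite: 1D series are 200 samples over 10 s (dt = 0.05 s) from the family
alpha = 2, C0 = 1, C2 = 0.5 started at q0 = 1, v0 = 1.5 (an unbound outward
trajectory, H > 0, so the full window is collision-free), with delta = 0
(symmetric) or delta = 1 (scale-free) and observation noise at 1 % of the
signal standard deviation smoothed over 0.1 s. The ``noisy_*`` variants
raise observation noise to 5 % and add process noise. 2D fixtures use unit
mass and force constant; the spiral starts on the pure-exponential Cotes
branch (v_r = -l/(m r0) with l**2 < 2mk) so that log r is exactly affine in
the polar angle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._exceptions import (
    CollisionError,
    DomainError,
    SingularDynamicsError,
    UnsupportedModelError,
)
from .family import LagrangianFamily, acceleration

__all__ = [
    "Trajectory",
    "StateSpaceModel",
    "ObservedSeries",
    "FixtureBundle",
    "integrate_eom",
    "integrate_eom_2d",
    "refinement_error",
    "simulate_particle_2d",
    "simulate_observations",
    "delta_sweep",
    "DeltaSweepResult",
    "make_fixture",
    "FIXTURE_NAMES",
]

#: Default collision-guard radius for attractive singular potentials.
R_MIN = 1e-3


@dataclass(frozen=True)
class Trajectory:
    """A sampled deterministic path: times, positions, velocities.

    ``positions``/``velocities`` are (n,) arrays in 1D or (n, 2) in 2D.
    ``complete`` is False when integration stopped early at the collision
    guard and the trajectory is the valid prefix.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    complete: bool = True

    def __post_init__(self):
        n = len(self.times)
        if len(self.positions) != n or len(self.velocities) != n:
            raise ValueError("times, positions, velocities must have equal length")
        if n >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def ndim(self) -> int:
        return 1 if np.asarray(self.positions).ndim == 1 else 2


@dataclass(frozen=True)
class StateSpaceModel:
    """Generative model: family dynamics plus smooth Gaussian fluctuations.

    ``process_noise_sd`` holds the standard deviations of the fluctuations
    on the two state equations (position and velocity derivatives);
    ``obs_noise_sd`` that of the observation noise; ``noise_smoothness`` the
    temporal width (in time units) of the Gaussian kernel giving the noise
    its non-Markovian character. All-zero noise collapses the model onto the
    deterministic trajectory.
    """

    family: LagrangianFamily
    dt: float
    n_samples: int
    process_noise_sd: tuple[float, float] = (0.0, 0.0)
    obs_noise_sd: float = 0.0
    noise_smoothness: float = 0.0
    obs_smoothness: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if min(self.process_noise_sd) < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")

    @property
    def t_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class ObservedSeries:
    """Observable output y(t) of a state-space simulation, with its truth."""

    times: np.ndarray
    y: np.ndarray
    truth: Trajectory


# ---------------------------------------------------------------------------
# deterministic integration


def _rk4(deriv, state0, t_grid, guard=None):
    """Classical fixed-step RK4. ``guard(state)`` may raise to stop early."""
    t_grid = np.asarray(t_grid, dtype=float)
    states = np.empty((len(t_grid), len(state0)))
    states[0] = state0
    s = np.asarray(state0, dtype=float)
    if guard is not None:
        guard(s, t_grid[0])
    for i in range(len(t_grid) - 1):
        t, dt = t_grid[i], t_grid[i + 1] - t_grid[i]
        k1 = deriv(s, t)
        k2 = deriv(s + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = deriv(s + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = deriv(s + dt * k3, t + dt)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if guard is not None:
            guard(s, t_grid[i + 1])
        states[i + 1] = s
    return states


def _uniform_dt(t_grid) -> float:
    steps = np.diff(t_grid)
    if len(steps) == 0:
        raise ValueError("time grid needs at least 2 samples")
    dt = float(steps[0])
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-9, atol=1e-12):
        raise ValueError("integration requires a fixed-step time grid")
    return dt


def _family_arrays(family: LagrangianFamily):
    if not family.is_time_independent:
        raise UnsupportedModelError("integration requires a time-independent family")
    ys = np.array([t.y_order for t in family.terms], dtype=np.int64)
    cs = np.array([t.coeff for t in family.terms], dtype=np.float64)
    return ys, cs


def _handle_partial(t_grid, n_ok, build_partial, on_collision, r_min):
    partial = build_partial(n_ok) if n_ok >= 2 else None
    if on_collision == "truncate" and partial is not None:
        return partial
    t_fail = t_grid[min(n_ok, len(t_grid) - 1)]
    raise CollisionError(
        f"trajectory crossed the collision guard r_min={r_min} near t={t_fail:.6g}",
        time_reached=float(t_fail),
        partial=partial,
    )


def integrate_eom(
    family: LagrangianFamily,
    q0: float,
    v0: float,
    t_grid,
    r_min: float = R_MIN,
    on_collision: str = "raise",
) -> Trajectory:
    """Integrate the family's 1D equation of motion with fixed-step RK4.

    ``on_collision`` controls behaviour when the position crosses the guard
    radius ``r_min``: "raise" (default) raises :class:`CollisionError`
    carrying the partial trajectory; "truncate" returns the valid prefix
    with ``complete=False``.
    """
    from ._fast import rk4_1d

    t_grid = np.asarray(t_grid, dtype=float)
    if q0 <= r_min:
        raise DomainError(f"initial position {q0} at or below collision guard {r_min}")
    dt = _uniform_dt(t_grid)
    ys, cs = _family_arrays(family)
    # fail fast with a diagnostic if the dynamics are singular at the start
    acceleration(family, q0, v0)
    pos, vel, n_ok = rk4_1d(
        float(q0), float(v0), dt, len(t_grid), family.alpha, family.delta, ys, cs, r_min
    )
    if n_ok < len(t_grid):
        return _handle_partial(
            t_grid,
            n_ok,
            lambda n: Trajectory(t_grid[:n], pos[:n], vel[:n], complete=False),
            on_collision,
            r_min,
        )
    return Trajectory(times=t_grid, positions=pos, velocities=vel)


def integrate_eom_2d(
    family: LagrangianFamily,
    x0: float,
    y0: float,
    vx0: float,
    vy0: float,
    t_grid,
    r_min: float = R_MIN,
    on_collision: str = "raise",
) -> Trajectory:
    """Integrate the planar central-family equation of motion (RK4).

    Uses the Euler-Lagrange system of L = sum C_y r**e_y v**y (see
    :func:`scalesym.family.acceleration_2d`).
    """
    from ._fast import rk4_2d

    t_grid = np.asarray(t_grid, dtype=float)
    if np.hypot(x0, y0) <= r_min:
        raise DomainError("initial position inside the collision guard")
    dt = _uniform_dt(t_grid)
    ys, cs = _family_arrays(family)
    states, n_ok = rk4_2d(
        float(x0), float(y0), float(vx0), float(vy0), dt, len(t_grid),
        family.alpha, family.delta, ys, cs, r_min,
    )
    if n_ok < len(t_grid):
        return _handle_partial(
            t_grid,
            n_ok,
            lambda n: Trajectory(
                t_grid[:n], states[:n, :2].copy(), states[:n, 2:].copy(), complete=False
            ),
            on_collision,
            r_min,
        )
    return Trajectory(times=t_grid, positions=states[:, :2], velocities=states[:, 2:])


def refinement_error(family: LagrangianFamily, q0: float, v0: float, t_grid) -> float:
    """Step-doubling error estimate: relative terminal-state change on dt/2.

    Useful as an a-posteriori accuracy certificate for a fixed-step run.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    coarse = integrate_eom(family, q0, v0, t_grid)
    fine_grid = np.linspace(t_grid[0], t_grid[-1], 2 * (len(t_grid) - 1) + 1)
    fine = integrate_eom(family, q0, v0, fine_grid)
    end_c = np.array([coarse.positions[-1], coarse.velocities[-1]])
    end_f = np.array([fine.positions[-1], fine.velocities[-1]])
    return float(np.linalg.norm(end_c - end_f) / (np.linalg.norm(end_f) + 1e-300))


def certified_prefix(
    family: LagrangianFamily,
    q0: float,
    v0: float,
    t_grid,
    tol: float = 1e-10,
    r_min: float = R_MIN,
) -> Trajectory:
    """Longest trajectory prefix whose positions pass a step-doubling check.

    Integrates on ``t_grid`` and on the half-step grid, and returns the
    prefix on which the relative position difference stays within ``tol``.
    For trajectories approaching a collision this bounds the usable span by
    verified accuracy rather than by an ad-hoc position cut-off.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    coarse = integrate_eom(family, q0, v0, t_grid, r_min=r_min, on_collision="truncate")
    n = len(coarse.times)
    fine_grid = np.linspace(t_grid[0], coarse.times[-1], 2 * (n - 1) + 1)
    fine = integrate_eom(family, q0, v0, fine_grid, r_min=r_min, on_collision="truncate")
    n_f = (len(fine.times) + 1) // 2
    n_cmp = min(n, n_f)
    rel = np.abs(coarse.positions[:n_cmp] - fine.positions[::2][:n_cmp]) / (
        np.abs(fine.positions[::2][:n_cmp]) + 1e-12
    )
    bad = rel > tol
    idx = int(np.argmax(bad)) if bad.any() else n_cmp
    if idx < 2:
        raise CollisionError("no certified samples at the requested tolerance")
    complete = coarse.complete and idx == len(t_grid)
    return Trajectory(
        coarse.times[:idx], coarse.positions[:idx], coarse.velocities[:idx],
        complete=complete,
    )


_FORCE_LAWS = {
    # radial acceleration magnitude prefactor: accel = coeff(k, m) / r**p * rhat
    "inverse_cube": lambda k, m: (2.0 * k / m, 3),
    "inverse_square": lambda k, m: (k / m, 2),
}


def simulate_particle_2d(
    force_law: str,
    m: float,
    k: float,
    x0: float,
    y0: float,
    vx0: float,
    vy0: float,
    t_grid,
    r_min: float = R_MIN,
    on_collision: str = "raise",
) -> Trajectory:
    """Integrate a planar particle under an attractive central force.

    ``inverse_cube`` applies F = -2k/r**3 (from V = -k r**-2, the
    scale-symmetric case; logarithmic-spiral orbits for l**2 < 2mk);
    ``inverse_square`` applies F = -k/r**2 (V = -k/r, Kepler ellipses).
    Angular momentum l = m (x vy - y vx) is conserved by construction and
    serves as an integration check.
    """
    if force_law not in _FORCE_LAWS:
        raise ValueError(f"unknown force law {force_law!r}; options: {sorted(_FORCE_LAWS)}")
    coeff, p = _FORCE_LAWS[force_law](k, m)
    t_grid = np.asarray(t_grid, dtype=float)

    def deriv(s, t):
        x, y, vx, vy = s
        r = np.hypot(x, y)
        if not r > r_min:  # also guards RK4 stage points inside a step
            raise CollisionError(
                f"radius crossed collision guard r_min={r_min} at t={t:.6g}",
                time_reached=t,
            )
        a = -coeff / r ** (p + 1)  # includes the 1/r of the unit vector
        return np.array([vx, vy, a * x, a * y])

    def guard(s, t):
        if not np.hypot(s[0], s[1]) > r_min:
            raise CollisionError(
                f"radius crossed collision guard r_min={r_min} at t={t:.6g}",
                time_reached=t,
            )

    try:
        states = _rk4(deriv, [x0, y0, vx0, vy0], t_grid, guard=guard)
    except CollisionError as err:
        t_fail = err.time_reached
        n_ok = 0 if t_fail is None else int(np.searchsorted(t_grid, t_fail, side="left"))
        partial = None
        if n_ok >= 1:
            sub = simulate_particle_2d(
                force_law, m, k, x0, y0, vx0, vy0, t_grid[:n_ok], r_min=r_min
            )
            partial = Trajectory(sub.times, sub.positions, sub.velocities, complete=False)
        if on_collision == "truncate" and partial is not None:
            return partial
        err.partial = partial
        raise
    return Trajectory(times=t_grid, positions=states[:, :2], velocities=states[:, 2:])


# ---------------------------------------------------------------------------
# stochastic observations


def smoothed_noise(rng, n: int, sd: float, smoothness: float, dt: float) -> np.ndarray:
    """White Gaussian draws, optionally Gaussian-smoothed, rescaled to sd.

    ``smoothness`` is the kernel standard deviation in time units; zero
    returns plain white noise. The smoothed series is rescaled so its
    sample standard deviation equals ``sd`` exactly.
    """
    if sd == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    if smoothness > 0:
        w = gaussian_filter1d(w, sigma=smoothness / dt, mode="reflect")
    s = w.std()
    if s == 0.0:
        return np.zeros(n)
    return w * (sd / s)


def simulate_observations(
    ssm: StateSpaceModel, q0: float, v0: float, seed: int
) -> ObservedSeries:
    """Draw one realisation of the state-space model.

    The deterministic equation of motion is integrated by RK4 with the
    smooth process fluctuations added to the two state derivatives; smooth
    observation noise is added to the resulting positions. The same seed
    always reproduces the same series bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    t_grid = ssm.t_grid
    n = ssm.n_samples
    w_x = smoothed_noise(rng, n, ssm.process_noise_sd[0], ssm.noise_smoothness, ssm.dt)
    w_v = smoothed_noise(rng, n, ssm.process_noise_sd[1], ssm.noise_smoothness, ssm.dt)
    w_y = smoothed_noise(rng, n, ssm.obs_noise_sd, ssm.obs_smoothness, ssm.dt)

    if ssm.process_noise_sd == (0.0, 0.0):
        # integrate on a 10x refined grid and subsample: the returned truth
        # is then integrator-accurate well below the observation noise
        refine = 10
        fine = np.linspace(t_grid[0], t_grid[-1], refine * (n - 1) + 1)
        fine_traj = integrate_eom(ssm.family, q0, v0, fine)
        truth = Trajectory(
            times=t_grid,
            positions=fine_traj.positions[::refine].copy(),
            velocities=fine_traj.velocities[::refine].copy(),
        )
    else:
        t0 = t_grid[0]

        def deriv(s, t):
            # piecewise-linear interpolation of the smooth fluctuations
            u = np.clip((t - t0) / ssm.dt, 0, n - 1)
            i = int(u)
            j = min(i + 1, n - 1)
            frac = u - i
            wx = (1 - frac) * w_x[i] + frac * w_x[j]
            wv = (1 - frac) * w_v[i] + frac * w_v[j]
            return np.array([s[1] + wx, acceleration(ssm.family, s[0], s[1]) + wv])

        def guard(s, t):
            if not s[0] > R_MIN:
                raise CollisionError(
                    f"position crossed collision guard at t={t:.6g}", time_reached=t
                )

        states = _rk4(deriv, [q0, v0], t_grid, guard=guard)
        truth = Trajectory(times=t_grid, positions=states[:, 0], velocities=states[:, 1])

    y = truth.positions + w_y
    return ObservedSeries(times=t_grid, y=y, truth=truth)


# ---------------------------------------------------------------------------
# delta sweep


@dataclass(frozen=True)
class DeltaSweepResult:
    """Trajectories per delta; failures collected instead of aborting."""

    trajectories: dict[float, Trajectory]
    failures: dict[float, Exception] = field(default_factory=dict)


def delta_sweep(
    base_family: LagrangianFamily, delta_values, q0: float, v0: float, t_grid
) -> DeltaSweepResult:
    """Integrate the equation of motion for each delta on a shared grid."""
    trajectories: dict[float, Trajectory] = {}
    failures: dict[float, Exception] = {}
    for d in delta_values:
        fam = base_family.with_delta(float(d))
        try:
            trajectories[float(d)] = integrate_eom(fam, q0, v0, t_grid)
        except (CollisionError, DomainError, SingularDynamicsError) as err:
            failures[float(d)] = err
    return DeltaSweepResult(trajectories=trajectories, failures=failures)


# ---------------------------------------------------------------------------
# fixtures

_BASE_COEFFS = {0: 1.0, 2: 0.5}  # C0 = k = 1, C2 = m/2 = 0.5
_FIX_N, _FIX_DT = 200, 0.05  # 200 samples over 10 s
_FIX_Q0, _FIX_V0 = 1.0, 1.5  # unbound outward start (H > 0)
_FIX_SMOOTH = 0.1  # noise smoothness, seconds


def _family_1d(delta: float) -> LagrangianFamily:
    return LagrangianFamily.from_coefficients(alpha=2.0, coeffs=_BASE_COEFFS, delta=delta)


def _fixture_1d(delta: float, obs_frac: float, proc_sd: float, smooth: float, seed: int):
    family = _family_1d(delta)
    t_grid = np.arange(_FIX_N) * _FIX_DT
    clean = integrate_eom(family, _FIX_Q0, _FIX_V0, t_grid)
    signal_sd = float(np.std(clean.positions))
    ssm = StateSpaceModel(
        family=family,
        dt=_FIX_DT,
        n_samples=_FIX_N,
        process_noise_sd=(proc_sd, proc_sd),
        obs_noise_sd=obs_frac * signal_sd,
        noise_smoothness=smooth,
    )
    observed = simulate_observations(ssm, _FIX_Q0, _FIX_V0, seed)
    meta = {
        "family": family.to_dict(),
        "q0": _FIX_Q0,
        "v0": _FIX_V0,
        "dt": _FIX_DT,
        "n_samples": _FIX_N,
        "obs_noise_sd": ssm.obs_noise_sd,
        "process_noise_sd": list(ssm.process_noise_sd),
        "noise_smoothness": smooth,
        "signal_sd": signal_sd,
    }
    return family, observed, meta


FIXTURE_NAMES = (
    "spiral_2d",
    "ellipse_2d",
    "symmetric_1d",
    "scalefree_1d",
    "noisy_symmetric",
    "noisy_scalefree",
)


@dataclass(frozen=True)
class FixtureBundle:
    """Reproducible dataset: observed series, ground truth, provenance."""

    name: str
    seed: int
    family: LagrangianFamily | None
    observed: ObservedSeries
    metadata: dict

    @property
    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "name": self.name,
                "seed": self.seed,
                "times": np.asarray(self.observed.times).tolist(),
                "y": np.asarray(self.observed.y).tolist(),
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()


def make_fixture(name: str, seed: int) -> FixtureBundle:
    """Build one of the packaged ground-truth datasets (see module docstring)."""
    if name == "symmetric_1d":
        family, observed, meta = _fixture_1d(0.0, 0.01, 0.0, _FIX_SMOOTH, seed)
    elif name == "scalefree_1d":
        family, observed, meta = _fixture_1d(1.0, 0.01, 0.0, _FIX_SMOOTH, seed)
    elif name == "noisy_symmetric":
        family, observed, meta = _fixture_1d(0.0, 0.05, 0.01, 2 * _FIX_SMOOTH, seed)
    elif name == "noisy_scalefree":
        family, observed, meta = _fixture_1d(1.0, 0.05, 0.01, 2 * _FIX_SMOOTH, seed)
    elif name in ("spiral_2d", "ellipse_2d"):
        m, k = 1.0, 1.0
        if name == "spiral_2d":
            # pure-exponential Cotes branch: l = 1 < sqrt(2mk), v_r = -l/(m r0)
            ic = dict(x0=1.0, y0=0.0, vx0=-1.0, vy0=1.0)
            force, t_end, n = "inverse_cube", 0.4, 200
        else:
            # mildly eccentric Kepler orbit; one radial period
            ic = dict(x0=1.0, y0=0.0, vx0=0.0, vy0=1.1)
            energy = 0.5 * 1.1**2 - 1.0
            t_end = 2 * np.pi * (-k / (2 * energy)) ** 1.5
            force, n = "inverse_square", 200
        t_grid = np.linspace(0.0, t_end, n)
        traj = simulate_particle_2d(force, m, k, t_grid=t_grid, **ic)
        rng = np.random.default_rng(seed)
        obs_sd = 0.01 * float(np.std(np.linalg.norm(traj.positions, axis=1)))
        dt = t_grid[1] - t_grid[0]
        noise = np.column_stack(
            [smoothed_noise(rng, n, obs_sd, 0.0, dt) for _ in range(2)]
        )
        observed = ObservedSeries(times=t_grid, y=traj.positions + noise, truth=traj)
        family = _family_1d(0.0 if name == "spiral_2d" else 1.0)
        family = LagrangianFamily(
            alpha=family.alpha, terms=family.terms, delta=family.delta, dimensionality=2
        )
        meta = {
            "force_law": force,
            "m": m,
            "k": k,
            **ic,
            "t_end": float(t_end),
            "n_samples": n,
            "obs_noise_sd": obs_sd,
            "noise_smoothness": 0.0,
            "family": family.to_dict(),
        }
    else:
        raise ValueError(f"unknown fixture {name!r}; options: {FIXTURE_NAMES}")
    meta = {"name": name, "seed": seed, **meta}
    return FixtureBundle(name=name, seed=seed, family=family, observed=observed, metadata=meta)
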