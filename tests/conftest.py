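import numpy as np
import pytest
import sympy as sp
from hypothesis import HealthCheck, settings

from scalesym.family import LagrangianFamily

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def inverse_cube_family():
    """m = k = 1 scale-symmetric particle: L = 1/2 qdot^2 + q^-2."""
    return LagrangianFamily.from_coefficients(2.0, {0: 1.0, 2: 0.5})


@pytest.fixture(scope="session")
def free_particle_family():
    """L = 1/2 qdot^2 (unit mass)."""
    return LagrangianFamily.from_coefficients(2.0, {2: 0.5})


@pytest.fixture(scope="session")
def symbolic_acceleration_1d():
    """Independent Euler-Lagrange oracle for the delta-perturbed family.

    Derives qddot symbolically from L = q**(d-a) sum_y c_y q**(y(a-1))
    qdot**y via qddot = (L_q - L_{qdot q} qdot) / L_{qdot qdot}, with all
    parameters symbolic, then lambdifies once.
    """
    q, qd = sp.symbols("q qd", positive=True, real=True)
    a, d = sp.symbols("a d", real=True)
    cs = sp.symbols("c0 c1 c2 c3 c4", real=True)
    L = q ** (d - a) * sum(cs[y] * q ** (y * (a - 1)) * qd**y for y in range(5))
    Lq = sp.diff(L, q)
    Lqd = sp.diff(L, qd)
    expr = (Lq - sp.diff(Lqd, q) * qd) / sp.diff(Lqd, qd)
    fn = sp.lambdify((q, qd, a, d) + cs, expr)

    def oracle(family: LagrangianFamily, qv: float, qdv: float) -> float:
        c = {y: 0.0 for y in range(5)}
        c.update(family.coefficients)
        return float(
            fn(qv, qdv, family.alpha, family.delta, c[0], c[1], c[2], c[3], c[4])
        )

    return oracle


@pytest.fixture(scope="session")
def numeric_acceleration_2d():
    """Independent planar Euler-Lagrange oracle via finite differences.

    Evaluates L = sum c_y r**e_y v**y with its own arithmetic and solves
    M a = dL/du - (d2L/dw du) w, with M = d2L/dw dw, all second partials by
    central differences. Shares no code with the closed-form implementation.
    """

    def oracle(family, pos, vel, h=2e-4):
        c = family.coefficients
        a_, d_ = family.alpha, family.delta

        def L(u1, u2, w1, w2):
            r = np.hypot(u1, u2)
            v = np.hypot(w1, w2)
            out = 0.0
            for y, cy in c.items():
                out += cy * r ** (d_ - a_ + y * (a_ - 1.0)) * v**y
            return out

        x = np.array([pos[0], pos[1], vel[0], vel[1]], dtype=float)

        def partial2(i, j):
            e_i = np.eye(4)[i] * h
            e_j = np.eye(4)[j] * h
            return (
                L(*(x + e_i + e_j)) - L(*(x + e_i - e_j))
                - L(*(x - e_i + e_j)) + L(*(x - e_i - e_j))
            ) / (4 * h * h)

        def partial1(i):
            e_i = np.eye(4)[i] * h
            return (L(*(x + e_i)) - L(*(x - e_i))) / (2 * h)

        M = np.array([[partial2(2, 2), partial2(2, 3)], [partial2(3, 2), partial2(3, 3)]])
        rhs = np.array(
            [
                partial1(0) - (partial2(2, 0) * vel[0] + partial2(2, 1) * vel[1]),
                partial1(1) - (partial2(3, 0) * vel[0] + partial2(3, 1) * vel[1]),
            ]
        )
        return np.linalg.solve(M, rhs)

    return oracle


def random_family(rng, with_cubic=True):
    """A random well-posed family member for property tests."""
    coeffs = {0: rng.uniform(-2, 2), 2: rng.uniform(0.3, 2)}
    if with_cubic:
        coeffs[3] = rng.uniform(-1, 1)
        coeffs[4] = rng.uniform(-1, 1)
    return LagrangianFamily.from_coefficients(
        alpha=rng.uniform(0.5, 3.0),
        coeffs=coeffs,
        delta=rng.uniform(-1.5, 1.5),
    )
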