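"""Generalised scale-symmetric Lagrangian family.

A dynamical system with position q(t) is *scale-free* when the rescaling
q -> lambda*q, t -> lambda**alpha * t maps physical trajectories onto
physical trajectories, and *scale-symmetric* when the action itself is
invariant, which holds iff the Lagrangian obeys

    L(lambda*q, lambda**(1-alpha)*qdot, lambda**alpha*t)
        = lambda**(-alpha) * L(q, qdot, t).

Writing L as a power series sum C_xyz q**x qdot**y t**z, the symmetry
condition fixes the position exponent of every term,

    x = -alpha - (1 - alpha)*y - alpha*z,

so a scale-symmetric family is parameterised by (alpha, {C_yz}) alone.
Multiplying the whole series by q**delta produces a one-parameter deviation
from symmetry: delta = 0 is scale-symmetric, delta != 0 merely scale-free.
This module evaluates the family, its partial derivatives, the symmetry
defect under a finite rescaling, and the closed-form acceleration of the
Euler-Lagrange equation of motion.

Exponents are kept as reals; consequently the family is only defined on
q > 0 (and t > 0 where a term has a negative time exponent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import DomainError, SingularDynamicsError, UnsupportedModelError

__all__ = [
    "LagrangianTerm",
    "LagrangianFamily",
    "ScaleTransform",
    "solve_position_exponent",
    "lagrangian_value",
    "scaled_lagrangian_value",
    "symmetry_defect",
    "dL_dq",
    "dL_dqdot",
    "acceleration",
]

#: Default absolute tolerance below which the equation-of-motion denominator
#: is treated as singular.
DENOMINATOR_TOL = 1e-12

#: Absolute floor in the relative symmetry-defect measure, guarding points
#: where L is numerically zero.
DEFECT_ABS_FLOOR = 1e-12


def solve_position_exponent(alpha: float, y: int, z: int = 0) -> float:
    """Position exponent x making the term C q**x qdot**y t**z scale-symmetric.

    Solves x + (1 - alpha)*y + alpha*z = -alpha for x.
    """
    return -alpha - (1.0 - alpha) * y - alpha * z


@dataclass(frozen=True)
class LagrangianTerm:
    """One power-series term, C qdot**y t**z (position exponent implied).

    The position exponent is never stored: for a family with temporal
    exponent alpha it is determined by the symmetry condition (plus the
    family's delta offset), see :func:`solve_position_exponent`.
    """

    y_order: int
    coeff: float
    z_order: int = 0

    def __post_init__(self):
        if self.y_order < 0:
            raise ValueError(f"velocity power y_order must be >= 0, got {self.y_order}")
        if not np.isfinite(self.coeff):
            raise ValueError("term coefficient must be finite")


@dataclass(frozen=True)
class LagrangianFamily:
    """A member of the (possibly delta-perturbed) scale-symmetric family.

    L(q, qdot, t) = q**(delta - alpha)
                    * sum_terms C_yz q**(y*(alpha-1) - z*alpha) qdot**y t**z

    Parameters
    ----------
    alpha : temporal scale exponent pairing t -> lambda**alpha t with
        q -> lambda q.
    delta : deviation-from-symmetry exponent; the whole series is multiplied
        by q**delta, so delta = 0 is the scale-symmetric case.
    terms : ordered collection of :class:`LagrangianTerm`.
    dimensionality : 1 for a scalar coordinate; 2 marks the family as the
        radial part of a planar central-force system.
    """

    alpha: float
    terms: tuple[LagrangianTerm, ...]
    delta: float = 0.0
    dimensionality: int = 1

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_coefficients(
        cls,
        alpha: float,
        coeffs,
        delta: float = 0.0,
        dimensionality: int = 1,
    ) -> "LagrangianFamily":
        """Build a time-independent family from velocity-power coefficients.

        ``coeffs`` maps velocity power y -> C_y (dict) or is a sequence
        (C_0, C_1, ...). Zero coefficients are dropped.
        """
        if not isinstance(coeffs, dict):
            coeffs = dict(enumerate(coeffs))
        terms = tuple(
            LagrangianTerm(y_order=int(y), coeff=float(c))
            for y, c in sorted(coeffs.items())
            if c != 0.0
        )
        return cls(alpha=alpha, terms=terms, delta=delta, dimensionality=dimensionality)

    def with_delta(self, delta: float) -> "LagrangianFamily":
        return replace(self, delta=delta)

    # -- derived quantities ------------------------------------------------

    def q_exponent(self, term: LagrangianTerm) -> float:
        """Total position exponent of ``term`` inside this family."""
        return (
            self.delta
            - self.alpha
            + term.y_order * (self.alpha - 1.0)
            - term.z_order * self.alpha
        )

    @property
    def is_time_independent(self) -> bool:
        return all(t.z_order == 0 for t in self.terms)

    @property
    def coefficients(self) -> dict[int, float]:
        """Velocity-power -> coefficient map (time-independent families)."""
        if not self.is_time_independent:
            raise UnsupportedModelError("family has driven (z != 0) terms")
        out: dict[int, float] = {}
        for t in self.terms:
            out[t.y_order] = out.get(t.y_order, 0.0) + t.coeff
        return out

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "delta": self.delta,
            "dimensionality": self.dimensionality,
            "terms": [
                {"y": t.y_order, "z": t.z_order, "coeff": t.coeff} for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LagrangianFamily":
        terms = tuple(
            LagrangianTerm(y_order=int(t["y"]), z_order=int(t.get("z", 0)), coeff=float(t["coeff"]))
            for t in d["terms"]
        )
        return cls(
            alpha=float(d["alpha"]),
            delta=float(d.get("delta", 0.0)),
            dimensionality=int(d.get("dimensionality", 1)),
            terms=terms,
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "LagrangianFamily":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class ScaleTransform:
    """The rescaling (q, qdot, t) -> (lam*q, lam**(1-alpha)*qdot, lam**alpha*t)."""

    lam: float
    alpha: float

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError(f"scale factor lam must be positive, got {self.lam}")

    def apply(self, q: float, qdot: float, t: float) -> tuple[float, float, float]:
        return (
            self.lam * q,
            self.lam ** (1.0 - self.alpha) * qdot,
            self.lam**self.alpha * t,
        )

    def apply_trajectory(self, times, positions):
        """Map a sampled path q(t) to the scaled path lam*q(lam**-alpha ts).

        Returns (scaled_times, scaled_positions) on the image grid
        ts = lam**alpha * t.
        """
        times = np.asarray(times, dtype=float)
        positions = np.asarray(positions, dtype=float)
        return self.lam**self.alpha * times, self.lam * positions


# ---------------------------------------------------------------------------
# evaluation


def _check_domain(family: LagrangianFamily, q: float, t: float) -> None:
    if not q > 0:
        raise DomainError(f"position must be positive, got q={q}")
    if any(term.z_order < 0 for term in family.terms) and not t > 0:
        raise DomainError(
            f"t must be positive for a family with negative time exponents, got t={t}"
        )


def _pow(base: float, exponent: float) -> float:
    """base**exponent with the 0**0 = 1 and 0**positive = 0 conventions."""
    if base == 0.0:
        if exponent == 0:
            return 1.0
        if exponent > 0:
            return 0.0
        raise DomainError(f"0 raised to negative power {exponent}")
    return float(base) ** exponent


def lagrangian_value(family: LagrangianFamily, q: float, qdot: float, t: float = 0.0) -> float:
    """Evaluate L(q, qdot, t) for the family.

    L = q**(delta - alpha) * sum C_yz q**(y(alpha-1) - z alpha) qdot**y t**z.
    """
    _check_domain(family, q, t)
    total = 0.0
    for term in family.terms:
        total += (
            term.coeff
            * q ** family.q_exponent(term)
            * _pow(qdot, term.y_order)
            * _pow(t, term.z_order)
        )
    return total


def scaled_lagrangian_value(
    family: LagrangianFamily, transform: ScaleTransform, q: float, qdot: float, t: float = 0.0
) -> float:
    """L_s(q, qdot, t) = L(lam*q, lam**(1-alpha)*qdot, lam**alpha*t)."""
    return lagrangian_value(family, *transform.apply(q, qdot, t))


def symmetry_defect(family: LagrangianFamily, transform: ScaleTransform, points) -> float:
    """Worst relative violation of the scale-symmetry condition over ``points``.

    For each point the condition demands L_s = lam**(-alpha) L; the defect is
    max |L_s - lam**(-alpha) L| / (|lam**(-alpha) L| + floor). It vanishes
    (to round-off) iff the family is scale-symmetric at those points.
    """
    points = list(points)
    if not points:
        raise ValueError("symmetry_defect requires a non-empty point collection")
    target_scale = transform.lam ** (-transform.alpha)
    worst = 0.0
    for q, qdot, t in points:
        ref = target_scale * lagrangian_value(family, q, qdot, t)
        ls = scaled_lagrangian_value(family, transform, q, qdot, t)
        worst = max(worst, abs(ls - ref) / (abs(ref) + DEFECT_ABS_FLOOR))
    return worst


def dL_dqdot(family: LagrangianFamily, q: float, qdot: float, t: float = 0.0) -> float:
    """Closed-form partial derivative of L with respect to qdot."""
    _check_domain(family, q, t)
    total = 0.0
    for term in family.terms:
        y = term.y_order
        if y == 0:
            continue
        total += (
            term.coeff
            * y
            * q ** family.q_exponent(term)
            * _pow(qdot, y - 1)
            * _pow(t, term.z_order)
        )
    return total


def dL_dq(family: LagrangianFamily, q: float, qdot: float, t: float = 0.0) -> float:
    """Closed-form partial derivative of L with respect to q."""
    _check_domain(family, q, t)
    total = 0.0
    for term in family.terms:
        x = family.q_exponent(term)
        if x == 0.0:
            continue
        total += (
            term.coeff
            * x
            * q ** (x - 1.0)
            * _pow(qdot, term.y_order)
            * _pow(t, term.z_order)
        )
    return total


def acceleration(
    family: LagrangianFamily,
    q: float,
    qdot: float,
    denominator_tol: float = DENOMINATOR_TOL,
) -> float:
    """Closed-form acceleration of the family's Euler-Lagrange equation.

    For the time-independent family the equation of motion solves to

        qddot = q**-1 * sum_y C_y (1-y) ((alpha-1) y + delta - alpha)
                              q**((alpha-1) y) qdot**y
                /  sum_{y>=2} y (y-1) C_y q**((alpha-1) y) qdot**(y-2).

    Gauge terms (y = 1) drop out through the (1-y) factor; the q**(delta-alpha)
    prefactor cancels between numerator and denominator.
    """
    if not family.is_time_independent:
        raise UnsupportedModelError(
            "closed-form acceleration requires a time-independent (z = 0) family"
        )
    if not q > 0:
        raise DomainError(f"position must be positive, got q={q}")
    a, d = family.alpha, family.delta
    num = 0.0
    den = 0.0
    for term in family.terms:
        y = term.y_order
        qpow = q ** ((a - 1.0) * y)
        num += term.coeff * (1 - y) * ((a - 1.0) * y + d - a) * qpow * _pow(qdot, y)
        if y >= 2:
            den += y * (y - 1) * term.coeff * qpow * _pow(qdot, y - 2)
    if abs(den) < denominator_tol:
        raise SingularDynamicsError(
            f"equation-of-motion denominator {den!r} below tolerance {denominator_tol}"
        )
    return num / (q * den)


def acceleration_2d(
    family: LagrangianFamily,
    position,
    velocity,
    denominator_tol: float = DENOMINATOR_TOL,
) -> np.ndarray:
    """Acceleration of the planar central reading of the family.

    The 2D Lagrangian L = sum C_y r**e_y v**y (r = |u|, v = |udot|,
    e_y = delta - alpha + y(alpha - 1)) yields the Euler-Lagrange system

        (P I + Q udot udot') a = b,
        P = sum y C_y r**e_y v**(y-2),
        Q = sum y (y-2) C_y r**e_y v**(y-4),
        b = sum C_y e_y r**(e_y - 2) v**y u
            - sum y C_y e_y r**(e_y - 2) (u . udot) v**(y-2) udot,

    solved here directly. For the two-term symmetric family (alpha = 2,
    delta = 0) this reduces to the attractive inverse-cube force
    a = -(C0/C2) r**-4 u.
    """
    if not family.is_time_independent:
        raise UnsupportedModelError(
            "closed-form acceleration requires a time-independent (z = 0) family"
        )
    u = np.asarray(position, dtype=float)
    ud = np.asarray(velocity, dtype=float)
    r2 = float(u @ u)
    if r2 <= 0.0:
        raise DomainError("2D evaluation point at the origin")
    r = np.sqrt(r2)
    v = float(np.linalg.norm(ud))
    rv = float(u @ ud)
    P = 0.0
    Q = 0.0
    b = np.zeros(2)
    for term in family.terms:
        y, c = term.y_order, term.coeff
        e = family.delta - family.alpha + y * (family.alpha - 1.0)
        re = r**e
        if v > 0.0:
            vy, vym2, vym4 = v**y, v ** (y - 2), v ** (y - 4)
        else:  # odd-power terms vanish with their velocity factors at v = 0
            vy = 1.0 if y == 0 else 0.0
            vym2 = 1.0 if y == 2 else 0.0
            vym4 = 1.0 if y == 4 else 0.0
        if y >= 1:
            P += y * c * re * vym2
            Q += y * (y - 2) * c * re * vym4
            b -= y * c * e * re / r2 * rv * vym2 * ud
        b += c * e * re / r2 * vy * u
    denom = P + Q * v * v
    if abs(P) < denominator_tol or abs(denom) < denominator_tol:
        raise SingularDynamicsError("singular 2D equation-of-motion system")
    return b / P - Q * float(ud @ b) * ud / (P * denom)
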