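"""Numba-compiled equation-of-motion kernels.

These mirror the closed forms in :mod:`scalesym.family` (1D) and the planar
generalisation (2D) for use inside tight integration/optimisation loops.
The pure-Python implementations remain the reference; the test suite
asserts agreement between the two.

Conventions: a family is passed as arrays ``ys`` (velocity powers, int64)
and ``cs`` (coefficients, float64) plus scalars ``alpha`` and ``delta``.
Kernels signal failure (collision, singular denominator, non-finite state)
through the number of completed samples rather than exceptions.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def accel_1d(q, qd, alpha, delta, ys, cs):
    """Closed-form 1D acceleration; NaN when the denominator vanishes."""
    num = 0.0
    den = 0.0
    for i in range(ys.size):
        y = ys[i]
        c = cs[i]
        qp = q ** ((alpha - 1.0) * y)
        num += c * (1 - y) * ((alpha - 1.0) * y + delta - alpha) * qp * qd ** y
        if y >= 2:
            den += y * (y - 1) * c * qp * qd ** (y - 2)
    if abs(den) < 1e-12:
        return np.nan
    return num / (q * den)


@njit(cache=True)
def rk4_1d(q0, v0, dt, n, alpha, delta, ys, cs, r_min):
    """Fixed-step RK4 on (q, v). Returns (positions, velocities, n_ok)."""
    pos = np.empty(n)
    vel = np.empty(n)
    q, v = q0, v0
    pos[0] = q
    vel[0] = v
    if not q > r_min:
        return pos, vel, 0
    for i in range(n - 1):
        a1 = accel_1d(q, v, alpha, delta, ys, cs)
        q2, v2 = q + 0.5 * dt * v, v + 0.5 * dt * a1
        if not (q2 > r_min and np.isfinite(a1)):
            return pos, vel, i + 1
        a2 = accel_1d(q2, v2, alpha, delta, ys, cs)
        q3, v3 = q + 0.5 * dt * v2, v + 0.5 * dt * a2
        if not (q3 > r_min and np.isfinite(a2)):
            return pos, vel, i + 1
        a3 = accel_1d(q3, v3, alpha, delta, ys, cs)
        q4, v4 = q + dt * v3, v + dt * a3
        if not (q4 > r_min and np.isfinite(a3)):
            return pos, vel, i + 1
        a4 = accel_1d(q4, v4, alpha, delta, ys, cs)
        if not np.isfinite(a4):
            return pos, vel, i + 1
        q = q + dt / 6.0 * (v + 2.0 * v2 + 2.0 * v3 + v4)
        v = v + dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        if not (np.isfinite(q) and np.isfinite(v) and q > r_min):
            return pos, vel, i + 1
        pos[i + 1] = q
        vel[i + 1] = v
    return pos, vel, n


@njit(cache=True)
def accel_2d(ux, uy, vx, vy, alpha, delta, ys, cs, out):
    """Planar acceleration of the central family; False on singularity.

    The Euler-Lagrange system for L = sum C_y r**e_y v**y (e_y = delta -
    alpha + y(alpha-1)) is (P I + Q v v') a = b with

        P = sum y C_y r**e_y v**(y-2)
        Q = sum y (y-2) C_y r**e_y v**(y-4)
        b = sum C_y e_y r**(e_y-2) v**y u
            - sum y C_y e_y r**(e_y-2) (u.v) v**(y-2) udot,

    solved in closed form via Sherman-Morrison.
    """
    r2 = ux * ux + uy * uy
    if r2 <= 0.0:
        return False
    r = np.sqrt(r2)
    v2 = vx * vx + vy * vy
    v = np.sqrt(v2)
    rv = ux * vx + uy * vy
    P = 0.0
    Q = 0.0
    bx = 0.0
    by = 0.0
    for i in range(ys.size):
        y = ys[i]
        c = cs[i]
        e = delta - alpha + y * (alpha - 1.0)
        re = r ** e
        # v powers with the 0**0 = 1 convention
        if v > 0.0:
            vy_p = v ** y
            vym2 = v ** (y - 2)
            vym4 = v ** (y - 4)
        else:
            vy_p = 1.0 if y == 0 else 0.0
            vym2 = 1.0 if y == 2 else 0.0
            vym4 = 1.0 if y == 4 else 0.0
            if y == 1 or y == 3:
                vym2 = 0.0
                vym4 = 0.0
        if y >= 1:
            P += y * c * re * vym2
            Q += y * (y - 2) * c * re * vym4
            bx -= y * c * e * re / r2 * rv * vym2 * vx
            by -= y * c * e * re / r2 * rv * vym2 * vy
        bx += c * e * re / r2 * vy_p * ux
        by += c * e * re / r2 * vy_p * uy
    denom = P + Q * v2
    if abs(P) < 1e-12 or abs(denom) < 1e-12:
        return False
    wb = vx * bx + vy * by
    out[0] = bx / P - Q * wb * vx / (P * denom)
    out[1] = by / P - Q * wb * vy / (P * denom)
    return np.isfinite(out[0]) and np.isfinite(out[1])


@njit(cache=True)
def rk4_2d(x0, y0, vx0, vy0, dt, n, alpha, delta, ys, cs, r_min):
    """Fixed-step RK4 on (x, y, vx, vy). Returns (states (n,4), n_ok)."""
    out = np.empty((n, 4))
    s = np.empty(4)
    s[0], s[1], s[2], s[3] = x0, y0, vx0, vy0
    out[0] = s
    if not np.sqrt(s[0] ** 2 + s[1] ** 2) > r_min:
        return out, 0
    a = np.empty(2)
    k = np.empty((4, 4))
    tmp = np.empty(4)
    for i in range(n - 1):
        ok = True
        for stage in range(4):
            if stage == 0:
                for j in range(4):
                    tmp[j] = s[j]
            elif stage == 1 or stage == 2:
                for j in range(4):
                    tmp[j] = s[j] + 0.5 * dt * k[stage - 1, j]
            else:
                for j in range(4):
                    tmp[j] = s[j] + dt * k[2, j]
            if not np.sqrt(tmp[0] ** 2 + tmp[1] ** 2) > r_min:
                ok = False
                break
            if not accel_2d(tmp[0], tmp[1], tmp[2], tmp[3], alpha, delta, ys, cs, a):
                ok = False
                break
            k[stage, 0] = tmp[2]
            k[stage, 1] = tmp[3]
            k[stage, 2] = a[0]
            k[stage, 3] = a[1]
        if not ok:
            return out, i + 1
        for j in range(4):
            s[j] = s[j] + dt / 6.0 * (k[0, j] + 2.0 * k[1, j] + 2.0 * k[2, j] + k[3, j])
        if not (
            np.isfinite(s[0])
            and np.isfinite(s[1])
            and np.isfinite(s[2])
            and np.isfinite(s[3])
            and np.sqrt(s[0] ** 2 + s[1] ** 2) > r_min
        ):
            return out, i + 1
        out[i + 1] = s
    return out, n
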