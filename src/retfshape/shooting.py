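"""LDDMM geodesic shooting with a Gaussian reproducing kernel.

Deformations are parameterized by initial momenta attached to control
points (by default the template vertices).  The control points follow the
Hamiltonian point flow of H(q, p) = 1/2 sum_ij K(q_i, q_j) p_i . p_j with
K(x, y) = exp(-|x - y|^2 / s_V^2); additional "carried" points are
transported passively by the induced velocity field.  Integration is the
explicit midpoint rule; the reverse-mode adjoint is hand-coded so the
registration energy has exact analytic gradients with respect to the
initial momenta and the initial point positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass
class Deformation:
    """Initial-momentum parameterization of one diffeomorphic deformation."""

    control_points: np.ndarray  # (nc, 3), positions at t=0
    initial_momenta: np.ndarray  # (nc, 3)
    n_timesteps: int = 10

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float).reshape(-1, 3)
        self.initial_momenta = np.asarray(self.initial_momenta, dtype=float).reshape(-1, 3)
        if self.control_points.shape != self.initial_momenta.shape:
            raise ValueError("control points and momenta must have the same shape")
        if not np.all(np.isfinite(self.initial_momenta)):
            raise ValueError("momenta must be finite")


@njit(cache=True, fastmath=True)
def _hamiltonian_rhs(q, p, inv_s2):  # pragma: no cover
    n = q.shape[0]
    v = np.zeros_like(q)
    a = np.zeros_like(p)
    c = 2.0 * inv_s2
    for i in range(n):
        for j in range(n):
            dx = q[i, 0] - q[j, 0]
            dy = q[i, 1] - q[j, 1]
            dz = q[i, 2] - q[j, 2]
            kij = np.exp(-(dx * dx + dy * dy + dz * dz) * inv_s2)
            v[i, 0] += kij * p[j, 0]
            v[i, 1] += kij * p[j, 1]
            v[i, 2] += kij * p[j, 2]
            pp = p[i, 0] * p[j, 0] + p[i, 1] * p[j, 1] + p[i, 2] * p[j, 2]
            f = c * kij * pp
            a[i, 0] += f * dx
            a[i, 1] += f * dy
            a[i, 2] += f * dz
    return v, a


@njit(cache=True, fastmath=True)
def _hamiltonian_vjp(q, p, qb, pb, inv_s2):  # pragma: no cover
    """Pullback of cotangents (qb, pb) on (v, a) = rhs(q, p) to (q, p)."""
    n = q.shape[0]
    gq = np.zeros_like(q)
    gp = np.zeros_like(p)
    c = 2.0 * inv_s2
    for i in range(n):
        for j in range(n):
            dx = q[i, 0] - q[j, 0]
            dy = q[i, 1] - q[j, 1]
            dz = q[i, 2] - q[j, 2]
            kij = np.exp(-(dx * dx + dy * dy + dz * dz) * inv_s2)
            qbp = qb[i, 0] * p[j, 0] + qb[i, 1] * p[j, 1] + qb[i, 2] * p[j, 2]
            # v_i = sum_j K_ij p_j
            gp[j, 0] += kij * qb[i, 0]
            gp[j, 1] += kij * qb[i, 1]
            gp[j, 2] += kij * qb[i, 2]
            dk = -c * kij * qbp  # through K_ij in the velocity term
            gq[i, 0] += dk * dx
            gq[i, 1] += dk * dy
            gq[i, 2] += dk * dz
            gq[j, 0] -= dk * dx
            gq[j, 1] -= dk * dy
            gq[j, 2] -= dk * dz
            # a_i = c sum_j K_ij (p_i . p_j) d_ij
            pp = p[i, 0] * p[j, 0] + p[i, 1] * p[j, 1] + p[i, 2] * p[j, 2]
            pbd = pb[i, 0] * dx + pb[i, 1] * dy + pb[i, 2] * dz
            # w.r.t. p_m: j=m term c K (pb_i . d) p_i ; i=m term c K (pb_m . d) p_j
            gp[j, 0] += c * kij * pbd * p[i, 0]
            gp[j, 1] += c * kij * pbd * p[i, 1]
            gp[j, 2] += c * kij * pbd * p[i, 2]
            gp[i, 0] += c * kij * pbd * p[j, 0]
            gp[i, 1] += c * kij * pbd * p[j, 1]
            gp[i, 2] += c * kij * pbd * p[j, 2]
            # w.r.t. q: K_ij factor and the displacement d_ij
            f = c * pp * (-c * kij * pbd)
            gq[i, 0] += f * dx + c * pp * kij * pb[i, 0]
            gq[i, 1] += f * dy + c * pp * kij * pb[i, 1]
            gq[i, 2] += f * dz + c * pp * kij * pb[i, 2]
            gq[j, 0] -= f * dx + c * pp * kij * pb[i, 0]
            gq[j, 1] -= f * dy + c * pp * kij * pb[i, 1]
            gq[j, 2] -= f * dz + c * pp * kij * pb[i, 2]
    return gq, gp


@njit(cache=True, fastmath=True)
def _carry_rhs(x, q, p, inv_s2):  # pragma: no cover
    v = np.zeros_like(x)
    for i in range(x.shape[0]):
        for j in range(q.shape[0]):
            dx = x[i, 0] - q[j, 0]
            dy = x[i, 1] - q[j, 1]
            dz = x[i, 2] - q[j, 2]
            kij = np.exp(-(dx * dx + dy * dy + dz * dz) * inv_s2)
            v[i, 0] += kij * p[j, 0]
            v[i, 1] += kij * p[j, 1]
            v[i, 2] += kij * p[j, 2]
    return v


@njit(cache=True, fastmath=True)
def _carry_vjp(x, q, p, xb, inv_s2):  # pragma: no cover
    gx = np.zeros_like(x)
    gq = np.zeros_like(q)
    gp = np.zeros_like(p)
    c = 2.0 * inv_s2
    for i in range(x.shape[0]):
        for j in range(q.shape[0]):
            dx = x[i, 0] - q[j, 0]
            dy = x[i, 1] - q[j, 1]
            dz = x[i, 2] - q[j, 2]
            kij = np.exp(-(dx * dx + dy * dy + dz * dz) * inv_s2)
            xbp = xb[i, 0] * p[j, 0] + xb[i, 1] * p[j, 1] + xb[i, 2] * p[j, 2]
            gp[j, 0] += kij * xb[i, 0]
            gp[j, 1] += kij * xb[i, 1]
            gp[j, 2] += kij * xb[i, 2]
            dk = -c * kij * xbp
            gx[i, 0] += dk * dx
            gx[i, 1] += dk * dy
            gx[i, 2] += dk * dz
            gq[j, 0] -= dk * dx
            gq[j, 1] -= dk * dy
            gq[j, 2] -= dk * dz
    return gx, gq, gp


def kinetic_energy(q: np.ndarray, p: np.ndarray, sigma_v: float) -> float:
    """Deformation energy p^T K(q) p (twice the Hamiltonian)."""
    v, _ = _hamiltonian_rhs(q, p, 1.0 / sigma_v**2)
    return float(np.sum(p * v))


def kinetic_energy_grad(q: np.ndarray, p: np.ndarray, sigma_v: float):
    """(E_V, dE/dq, dE/dp)."""
    inv_s2 = 1.0 / sigma_v**2
    v, a = _hamiltonian_rhs(q, p, inv_s2)
    return float(np.sum(p * v)), -2.0 * a, 2.0 * v


class ShootResult:
    """Forward trajectory of one geodesic shoot (keeps states for the adjoint)."""

    def __init__(self, states, carried, h, inv_s2, has_carry):
        self.states = states  # list of (q, p, q_mid, p_mid) per step + final (q, p)
        self.carried = carried  # list of (x, x_mid) per step + final x, or None
        self.h = h
        self.inv_s2 = inv_s2
        self.has_carry = has_carry

    @property
    def q_final(self) -> np.ndarray:
        return self.states[-1][0]

    @property
    def p_final(self) -> np.ndarray:
        return self.states[-1][1]

    @property
    def x_final(self) -> np.ndarray:
        return self.carried[-1][0] if self.has_carry else self.q_final


def shoot_forward(
    q0: np.ndarray,
    p0: np.ndarray,
    sigma_v: float,
    n_timesteps: int = 10,
    carried0: np.ndarray | None = None,
) -> ShootResult:
    """Integrate the Hamiltonian flow by the explicit midpoint rule."""
    inv_s2 = 1.0 / sigma_v**2
    h = 1.0 / n_timesteps
    q = np.array(q0, dtype=float)
    p = np.array(p0, dtype=float)
    has_carry = carried0 is not None
    x = np.array(carried0, dtype=float) if has_carry else None
    states = []
    carried = []
    for _ in range(n_timesteps):
        v1, a1 = _hamiltonian_rhs(q, p, inv_s2)
        qm = q + 0.5 * h * v1
        pm = p + 0.5 * h * a1
        v2, a2 = _hamiltonian_rhs(qm, pm, inv_s2)
        if has_carry:
            u1 = _carry_rhs(x, q, p, inv_s2)
            xm = x + 0.5 * h * u1
            u2 = _carry_rhs(xm, qm, pm, inv_s2)
            carried.append((x, xm))
            x = x + h * u2
        states.append((q, p, qm, pm))
        q = q + h * v2
        p = p + h * a2
    states.append((q, p, None, None))
    if has_carry:
        carried.append((x, None))
    return ShootResult(states, carried if has_carry else None, h, inv_s2, has_carry)


def shoot_adjoint(
    result: ShootResult,
    qT_bar: np.ndarray,
    xT_bar: np.ndarray | None = None,
):
    """Pull a cotangent on the final positions back to (q0, p0, x0).

    Returns (q0_bar, p0_bar, x0_bar); x0_bar is None when nothing was carried.
    """
    h = result.h
    inv_s2 = result.inv_s2
    qb = np.array(qT_bar, dtype=float)
    pb = np.zeros_like(qb)
    xb = np.array(xT_bar, dtype=float) if (result.has_carry and xT_bar is not None) else None
    for step in range(len(result.states) - 2, -1, -1):
        q, p, qm, pm = result.states[step]
        if xb is not None:
            x, xm = result.carried[step]
            # x' = x + h * u(xm, qm, pm); xm = x + h/2 * u(x, q, p)
            gx_m, gq_m, gp_m = _carry_vjp(xm, qm, pm, h * xb, inv_s2)
            xm_bar = gx_m
            qmb_from_carry = gq_m
            pmb_from_carry = gp_m
            xb = xb + xm_bar
            gx0, gq0, gp0 = _carry_vjp(x, q, p, 0.5 * h * xm_bar, inv_s2)
            xb = xb + gx0
            qb_extra = gq0
            pb_extra = gp0
        else:
            qmb_from_carry = 0.0
            pmb_from_carry = 0.0
            qb_extra = 0.0
            pb_extra = 0.0
        # y' = y + h * rhs(y_mid); y_mid = y + h/2 * rhs(y)
        gq_m, gp_m = _hamiltonian_vjp(qm, pm, h * qb, h * pb, inv_s2)
        qm_bar = gq_m + qmb_from_carry
        pm_bar = gp_m + pmb_from_carry
        qb = qb + qm_bar + qb_extra
        pb = pb + pm_bar + pb_extra
        gq0, gp0 = _hamiltonian_vjp(q, p, 0.5 * h * qm_bar, 0.5 * h * pm_bar, inv_s2)
        qb = qb + gq0
        pb = pb + gp0
    return qb, pb, xb


def shoot(
    deformation: Deformation,
    sigma_v: float,
    points: np.ndarray | None = None,
) -> np.ndarray:
    """Displace ``points`` (default: the control points) under the flow."""
    carried = None
    if points is not None:
        carried = np.asarray(points, dtype=float).reshape(-1, 3)
    res = shoot_forward(
        deformation.control_points,
        deformation.initial_momenta,
        sigma_v,
        deformation.n_timesteps,
        carried,
    )
    return res.x_final if points is not None else res.q_final
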