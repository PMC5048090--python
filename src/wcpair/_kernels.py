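"""JIT-compiled inner loops: fixed-step RK4 and tangent-space propagation.

The Python-level API lives in :mod:`wcpair.simulate` and
:mod:`wcpair.lyapunov`; these kernels mirror the formulas of
:func:`wcpair.model.rhs` and :func:`wcpair.model.jacobian` in scalar form
(the tests assert the two routes agree).  Parameters arrive as a length-14
array in :data:`wcpair.model.PARAM_KEYS` order and the activation kind as
an integer code (0 nonlinear, 1 linear, 2 saturating).

Trajectories that leave |state| <= BLOWUP_LIMIT are truncated and flagged:
the linear activation is genuinely unstable in several regimes and silent
inf propagation is unacceptable.
"""

import math

import numpy as np
from numba import njit

KIND_NONLINEAR = 0
KIND_LINEAR = 1
KIND_SATURATING = 2

BLOWUP_LIMIT = 1e6


@njit(cache=True, inline="always")
def _S(z, kind):
    if kind == KIND_NONLINEAR:
        return z / math.sqrt(1.0 + z * z)
    elif kind == KIND_LINEAR:
        return z
    else:
        if z > 0.0:
            return 1.0
        elif z < 0.0:
            return -1.0
        return 0.0


@njit(cache=True, inline="always")
def _Sprime(z, kind):
    if kind == KIND_NONLINEAR:
        return (1.0 + z * z) ** -1.5
    return 1.0


@njit(cache=True)
def _deriv(s, p, kind, out):
    x1, y1, x2, y2 = s[0], s[1], s[2], s[3]
    z1 = p[5] * x1 - p[1] * y1 + p[6] * x2 + p[10]
    z2 = p[2] * x1 - p[4] * y1 + p[8] * x2 + p[12]
    z3 = p[5] * x2 - p[1] * y2 + p[7] * x1 + p[11]
    z4 = p[2] * x2 - p[4] * y2 + p[9] * x1 + p[13]
    out[0] = -p[0] * x1 + _S(z1, kind)
    out[1] = -p[3] * y1 + _S(z2, kind)
    out[2] = -p[0] * x2 + _S(z3, kind)
    out[3] = -p[3] * y2 + _S(z4, kind)


@njit(cache=True)
def _jac(s, p, kind, J):
    x1, y1, x2, y2 = s[0], s[1], s[2], s[3]
    a, b, c, d, e, w = p[0], p[1], p[2], p[3], p[4], p[5]
    a1, a2, b1, b2 = p[6], p[7], p[8], p[9]
    s1 = _Sprime(w * x1 - b * y1 + a1 * x2 + p[10], kind)
    s2 = _Sprime(c * x1 - e * y1 + b1 * x2 + p[12], kind)
    s3 = _Sprime(w * x2 - b * y2 + a2 * x1 + p[11], kind)
    s4 = _Sprime(c * x2 - e * y2 + b2 * x1 + p[13], kind)
    J[0, 0] = s1 * w - a
    J[0, 1] = -s1 * b
    J[0, 2] = s1 * a1
    J[0, 3] = 0.0
    J[1, 0] = s2 * c
    J[1, 1] = -s2 * e - d
    J[1, 2] = s2 * b1
    J[1, 3] = 0.0
    J[2, 0] = s3 * a2
    J[2, 1] = 0.0
    J[2, 2] = s3 * w - a
    J[2, 3] = -s3 * b
    J[3, 0] = s4 * b2
    J[3, 1] = 0.0
    J[3, 2] = s4 * c
    J[3, 3] = -s4 * e - d


@njit(cache=True)
def _rk4_step(s, p, kind, h, k1, k2, k3, k4, tmp):
    _deriv(s, p, kind, k1)
    for i in range(4):
        tmp[i] = s[i] + 0.5 * h * k1[i]
    _deriv(tmp, p, kind, k2)
    for i in range(4):
        tmp[i] = s[i] + 0.5 * h * k2[i]
    _deriv(tmp, p, kind, k3)
    for i in range(4):
        tmp[i] = s[i] + h * k3[i]
    _deriv(tmp, p, kind, k4)
    for i in range(4):
        s[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def integrate_rk4(p, kind, y0, h, n_steps):
    """Integrate n_steps of classical RK4; returns (states, blowup_index).

    states has shape (n_steps + 1, 4) including the initial state.
    blowup_index is the first row at which |state| exceeded BLOWUP_LIMIT
    (subsequent rows are unwritten), or -1 if the run completed.
    """
    out = np.empty((n_steps + 1, 4))
    s = y0.copy()
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    tmp = np.empty(4)
    out[0] = s
    for n in range(1, n_steps + 1):
        _rk4_step(s, p, kind, h, k1, k2, k3, k4, tmp)
        for i in range(4):
            if not math.isfinite(s[i]) or abs(s[i]) > BLOWUP_LIMIT:
                return out, n
        out[n] = s
    return out, -1


@njit(cache=True)
def lyapunov_benettin(p, kind, y0, h, n_transient, n_window, renorm_every):
    """Full 4-exponent spectrum by tangent-space propagation.

    Runs ``n_transient`` state-only RK4 steps, then ``n_window`` steps
    co-evolving an initially identity 4x4 tangent frame under the analytic
    Jacobian (same RK4 stages as the state), re-orthonormalizing by
    modified Gram-Schmidt every ``renorm_every`` steps and accumulating
    log stretch factors.  Also averages trace(J) along the window, which
    must match the exponent sum for a volume-consistency check.

    Returns (exponents desc-sorted, mean_trace, final_state, blowup_flag).
    """
    s = y0.copy()
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    tmp = np.empty(4)
    blowup = False
    for _ in range(n_transient):
        _rk4_step(s, p, kind, h, k1, k2, k3, k4, tmp)
        for i in range(4):
            if not math.isfinite(s[i]) or abs(s[i]) > BLOWUP_LIMIT:
                blowup = True
        if blowup:
            return np.zeros(4), 0.0, s, True

    V = np.eye(4)
    J = np.empty((4, 4))
    sums = np.zeros(4)
    trace_sum = 0.0
    K1 = np.empty((4, 4))
    K2 = np.empty((4, 4))
    K3 = np.empty((4, 4))
    K4 = np.empty((4, 4))
    Vt = np.empty((4, 4))
    s_mid = np.empty(4)
    s_end = np.empty(4)

    for n in range(n_window):
        # state stages (kept explicitly: the tangent stages need the
        # Jacobian at the same intermediate states)
        _deriv(s, p, kind, k1)
        for i in range(4):
            s_mid[i] = s[i] + 0.5 * h * k1[i]
        _jac(s, p, kind, J)
        trace_sum += J[0, 0] + J[1, 1] + J[2, 2] + J[3, 3]
        for i in range(4):
            for j in range(4):
                K1[i, j] = (J[i, 0] * V[0, j] + J[i, 1] * V[1, j]
                            + J[i, 2] * V[2, j] + J[i, 3] * V[3, j])

        _deriv(s_mid, p, kind, k2)
        _jac(s_mid, p, kind, J)
        for i in range(4):
            for j in range(4):
                Vt[i, j] = V[i, j] + 0.5 * h * K1[i, j]
        for i in range(4):
            for j in range(4):
                K2[i, j] = (J[i, 0] * Vt[0, j] + J[i, 1] * Vt[1, j]
                            + J[i, 2] * Vt[2, j] + J[i, 3] * Vt[3, j])

        for i in range(4):
            s_mid[i] = s[i] + 0.5 * h * k2[i]
        _deriv(s_mid, p, kind, k3)
        _jac(s_mid, p, kind, J)
        for i in range(4):
            for j in range(4):
                Vt[i, j] = V[i, j] + 0.5 * h * K2[i, j]
        for i in range(4):
            for j in range(4):
                K3[i, j] = (J[i, 0] * Vt[0, j] + J[i, 1] * Vt[1, j]
                            + J[i, 2] * Vt[2, j] + J[i, 3] * Vt[3, j])

        for i in range(4):
            s_end[i] = s[i] + h * k3[i]
        _deriv(s_end, p, kind, k4)
        _jac(s_end, p, kind, J)
        for i in range(4):
            for j in range(4):
                Vt[i, j] = V[i, j] + h * K3[i, j]
        for i in range(4):
            for j in range(4):
                K4[i, j] = (J[i, 0] * Vt[0, j] + J[i, 1] * Vt[1, j]
                            + J[i, 2] * Vt[2, j] + J[i, 3] * Vt[3, j])

        for i in range(4):
            s[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not math.isfinite(s[i]) or abs(s[i]) > BLOWUP_LIMIT:
                blowup = True
        if blowup:
            return np.zeros(4), 0.0, s, True
        for i in range(4):
            for j in range(4):
                V[i, j] += (h / 6.0) * (K1[i, j] + 2.0 * K2[i, j]
                                        + 2.0 * K3[i, j] + K4[i, j])

        if (n + 1) % renorm_every == 0 or n == n_window - 1:
            # modified Gram-Schmidt on columns of V
            for j in range(4):
                for jj in range(j):
                    dot = (V[0, jj] * V[0, j] + V[1, jj] * V[1, j]
                           + V[2, jj] * V[2, j] + V[3, jj] * V[3, j])
                    for i in range(4):
                        V[i, j] -= dot * V[i, jj]
                norm = math.sqrt(V[0, j] ** 2 + V[1, j] ** 2
                                 + V[2, j] ** 2 + V[3, j] ** 2)
                sums[j] += math.log(norm)
                for i in range(4):
                    V[i, j] /= norm

    t_window = n_window * h
    exps = sums / t_window
    exps = np.sort(exps)[::-1].copy()
    return exps, trace_sum / n_window, s, False


@njit(cache=True)
def _deriv2(s, pp, kind, out):
    # planar (single-population) subsystem: pp = (a, b, c, d, e, w, I, J)
    x, y = s[0], s[1]
    zx = pp[5] * x - pp[1] * y + pp[6]
    zy = pp[2] * x - pp[4] * y + pp[7]
    out[0] = -pp[0] * x + _S(zx, kind)
    out[1] = -pp[3] * y + _S(zy, kind)


@njit(cache=True)
def lyapunov_benettin_2d(pp, kind, y0, h, n_transient, n_window, renorm_every):
    """Two-exponent spectrum of one isolated population (planar flow).

    Same scheme as :func:`lyapunov_benettin` on the (x_i, y_i) subsystem;
    only meaningful when all inter-population couplings are zero.
    """
    s = y0.copy()
    k1 = np.empty(2)
    k2 = np.empty(2)
    k3 = np.empty(2)
    k4 = np.empty(2)
    tmp = np.empty(2)
    J = np.empty((2, 2))
    a, b, c, d, e, w = pp[0], pp[1], pp[2], pp[3], pp[4], pp[5]

    for _ in range(n_transient):
        _deriv2(s, pp, kind, k1)
        for i in range(2):
            tmp[i] = s[i] + 0.5 * h * k1[i]
        _deriv2(tmp, pp, kind, k2)
        for i in range(2):
            tmp[i] = s[i] + 0.5 * h * k2[i]
        _deriv2(tmp, pp, kind, k3)
        for i in range(2):
            tmp[i] = s[i] + h * k3[i]
        _deriv2(tmp, pp, kind, k4)
        for i in range(2):
            s[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not math.isfinite(s[i]) or abs(s[i]) > BLOWUP_LIMIT:
                return np.zeros(2), s, True

    V = np.eye(2)
    K1 = np.empty((2, 2))
    K2 = np.empty((2, 2))
    K3 = np.empty((2, 2))
    K4 = np.empty((2, 2))
    Vt = np.empty((2, 2))
    s_mid = np.empty(2)
    sums = np.zeros(2)

    for n in range(n_window):
        _deriv2(s, pp, kind, k1)
        sx = _Sprime(w * s[0] - b * s[1] + pp[6], kind)
        sy = _Sprime(c * s[0] - e * s[1] + pp[7], kind)
        J[0, 0] = sx * w - a
        J[0, 1] = -sx * b
        J[1, 0] = sy * c
        J[1, 1] = -sy * e - d
        for i in range(2):
            for j in range(2):
                K1[i, j] = J[i, 0] * V[0, j] + J[i, 1] * V[1, j]

        for stage in range(3):
            if stage == 0:
                kk, KK, fac = k1, K1, 0.5
            elif stage == 1:
                kk, KK, fac = k2, K2, 0.5
            else:
                kk, KK, fac = k3, K3, 1.0
            for i in range(2):
                s_mid[i] = s[i] + fac * h * kk[i]
            if stage == 0:
                kout, Kout = k2, K2
            elif stage == 1:
                kout, Kout = k3, K3
            else:
                kout, Kout = k4, K4
            _deriv2(s_mid, pp, kind, kout)
            sx = _Sprime(w * s_mid[0] - b * s_mid[1] + pp[6], kind)
            sy = _Sprime(c * s_mid[0] - e * s_mid[1] + pp[7], kind)
            J[0, 0] = sx * w - a
            J[0, 1] = -sx * b
            J[1, 0] = sy * c
            J[1, 1] = -sy * e - d
            for i in range(2):
                for j in range(2):
                    Vt[i, j] = V[i, j] + fac * h * KK[i, j]
            for i in range(2):
                for j in range(2):
                    Kout[i, j] = J[i, 0] * Vt[0, j] + J[i, 1] * Vt[1, j]

        for i in range(2):
            s[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not math.isfinite(s[i]) or abs(s[i]) > BLOWUP_LIMIT:
                return np.zeros(2), s, True
        for i in range(2):
            for j in range(2):
                V[i, j] += (h / 6.0) * (K1[i, j] + 2.0 * K2[i, j]
                                        + 2.0 * K3[i, j] + K4[i, j])

        if (n + 1) % renorm_every == 0 or n == n_window - 1:
            for j in range(2):
                for jj in range(j):
                    dot = V[0, jj] * V[0, j] + V[1, jj] * V[1, j]
                    for i in range(2):
                        V[i, j] -= dot * V[i, jj]
                norm = math.sqrt(V[0, j] ** 2 + V[1, j] ** 2)
                sums[j] += math.log(norm)
                for i in range(2):
                    V[i, j] /= norm

    exps = sums / (n_window * h)
    exps = np.sort(exps)[::-1].copy()
    return exps, s, False
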