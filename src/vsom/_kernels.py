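"""Compiled inner loops (numba) for the three models.

The state-space math lives here in scalar form so the per-step cost stays in
the microsecond range; the public modules wrap these kernels with the
documented containers.  Layouts must match the owning modules:

* SVM state: [z_c(3), g_hs(3), z_ci(3), f_hat(3), g_hat(3), v_hat(3), q(4)]
* MSOM state: [z_c(3), z_ci(3), g_hat(3), v_hat(3), q(4)]
"""

from __future__ import annotations

import numpy as np
from numba import njit

_G = 9.81


@njit(cache=True, inline="always")
def _cross(a, b, out):
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]


@njit(cache=True)
def _svm_deriv(x, f, w, tau_ssc, tau_lp, K_ac, K_gc, kw_ratio, dx):
    w_hs = np.empty(3)
    w_hat = np.empty(3)
    w_hs_hat = np.empty(3)
    for i in range(3):
        w_hs[i] = w[i] - x[i]
        w_hat[i] = w_hs[i] + kw_ratio * x[6 + i]
        w_hs_hat[i] = w_hat[i] - x[6 + i]

    cr = np.empty(3)
    # sensed gravity (Mayne)
    g_hs = x[3:6]
    _cross(w_hs, g_hs, cr)
    for i in range(3):
        dx[i] = w_hs[i] / tau_ssc
        dx[3 + i] = (f[i] - g_hs[i]) / tau_lp[i] - cr[i]
        dx[6 + i] = w_hs_hat[i] / tau_ssc

    # conflicts and internal model
    g_hat = x[12:15]
    _cross(w_hs_hat, g_hat, cr)
    for i in range(3):
        c_g = x[3 + i] - x[12 + i]
        c_a = (f[i] - x[3 + i]) - (x[9 + i] - x[12 + i])
        dx[9 + i] = K_gc[i] * c_g + K_ac[i] * c_a
        dx[12 + i] = (x[9 + i] - x[12 + i]) / tau_lp[i] - cr[i]
        dx[15 + i] = x[9 + i] - x[12 + i]  # a_hat -> v_hat

    # quaternion kinematics dq = 0.5 q * (0, w_hat)
    qw, qx, qy, qz = x[18], x[19], x[20], x[21]
    ox, oy, oz = w_hat[0], w_hat[1], w_hat[2]
    dx[18] = 0.5 * (-qx * ox - qy * oy - qz * oz)
    dx[19] = 0.5 * (qw * ox + qy * oz - qz * oy)
    dx[20] = 0.5 * (qw * oy - qx * oz + qz * ox)
    dx[21] = 0.5 * (qw * oz + qx * oy - qy * ox)


@njit(cache=True)
def svm_rk4(f, w, dt, tau_ssc, tau_lp, K_ac, K_gc, kw_ratio, x0):
    n = f.shape[0]
    xs = np.empty((n, x0.size))
    xs[0] = x0
    x = x0.copy()
    k1 = np.empty(x0.size)
    k2 = np.empty(x0.size)
    k3 = np.empty(x0.size)
    k4 = np.empty(x0.size)
    xt = np.empty(x0.size)
    fm = np.empty(3)
    wm = np.empty(3)
    for k in range(n - 1):
        for i in range(3):
            fm[i] = 0.5 * (f[k, i] + f[k + 1, i])
            wm[i] = 0.5 * (w[k, i] + w[k + 1, i])
        _svm_deriv(x, f[k], w[k], tau_ssc, tau_lp, K_ac, K_gc, kw_ratio, k1)
        for i in range(x.size):
            xt[i] = x[i] + 0.5 * dt * k1[i]
        _svm_deriv(xt, fm, wm, tau_ssc, tau_lp, K_ac, K_gc, kw_ratio, k2)
        for i in range(x.size):
            xt[i] = x[i] + 0.5 * dt * k2[i]
        _svm_deriv(xt, fm, wm, tau_ssc, tau_lp, K_ac, K_gc, kw_ratio, k3)
        for i in range(x.size):
            xt[i] = x[i] + dt * k3[i]
        _svm_deriv(xt, f[k + 1], w[k + 1], tau_ssc, tau_lp, K_ac, K_gc, kw_ratio, k4)
        for i in range(x.size):
            x[i] += (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        qn = np.sqrt(x[18] ** 2 + x[19] ** 2 + x[20] ** 2 + x[21] ** 2)
        for i in range(18, 22):
            x[i] /= qn
        ok = True
        for i in range(x.size):
            if not np.isfinite(x[i]):
                ok = False
        if not ok:
            return xs[: k + 1]
        xs[k + 1] = x
    return xs


@njit(cache=True)
def _msom_deriv(x, f, w, tau_ssc, K_a, K_f, K_fw, K_w, K_1, dx):
    g_hat = x[6:9]
    c_o = np.empty(3)
    f_hat = np.empty(3)
    for i in range(3):
        c_o[i] = (f[i] - g_hat[i]) / (1.0 - K_a)
        f_hat[i] = f[i] - c_o[i]
    fn = np.sqrt(f[0] ** 2 + f[1] ** 2 + f[2] ** 2)
    fhn = np.sqrt(f_hat[0] ** 2 + f_hat[1] ** 2 + f_hat[2] ** 2)
    if fn < 1e-6 or fhn < 1e-6:
        for i in range(dx.size):
            dx[i] = np.nan
        return
    c_oa = np.empty(3)
    _cross(f_hat, f, c_oa)
    for i in range(3):
        c_oa[i] /= fn * fhn

    w_hat = np.empty(3)
    for i in range(3):
        w_hs = w[i] - x[i]
        w_hat[i] = (K_w * (w_hs + x[3 + i]) + K_fw * c_oa[i]) / (1.0 + K_w)

    omega_g = np.empty(3)
    for i in range(3):
        omega_g[i] = K_f * c_oa[i] - K_1 * w_hat[i]
    cr = np.empty(3)
    _cross(omega_g, g_hat, cr)
    for i in range(3):
        dx[i] = (w[i] - x[i]) / tau_ssc          # sensor canal LP state
        dx[3 + i] = (w_hat[i] - x[3 + i]) / tau_ssc  # internal canal LP state
        dx[6 + i] = cr[i]
        dx[9 + i] = K_a * c_o[i]                 # a_hat -> v_hat

    qw, qx, qy, qz = x[12], x[13], x[14], x[15]
    ox, oy, oz = w_hat[0], w_hat[1], w_hat[2]
    dx[12] = 0.5 * (-qx * ox - qy * oy - qz * oz)
    dx[13] = 0.5 * (qw * ox + qy * oz - qz * oy)
    dx[14] = 0.5 * (qw * oy - qx * oz + qz * ox)
    dx[15] = 0.5 * (qw * oz + qx * oy - qy * ox)


@njit(cache=True)
def msom_rk4(f, w, dt, tau_ssc, K_a, K_f, K_fw, K_w, K_1, x0):
    n = f.shape[0]
    xs = np.empty((n, x0.size))
    xs[0] = x0
    x = x0.copy()
    k1 = np.empty(x0.size)
    k2 = np.empty(x0.size)
    k3 = np.empty(x0.size)
    k4 = np.empty(x0.size)
    xt = np.empty(x0.size)
    fm = np.empty(3)
    wm = np.empty(3)
    for k in range(n - 1):
        for i in range(3):
            fm[i] = 0.5 * (f[k, i] + f[k + 1, i])
            wm[i] = 0.5 * (w[k, i] + w[k + 1, i])
        _msom_deriv(x, f[k], w[k], tau_ssc, K_a, K_f, K_fw, K_w, K_1, k1)
        for i in range(x.size):
            xt[i] = x[i] + 0.5 * dt * k1[i]
        _msom_deriv(xt, fm, wm, tau_ssc, K_a, K_f, K_fw, K_w, K_1, k2)
        for i in range(x.size):
            xt[i] = x[i] + 0.5 * dt * k2[i]
        _msom_deriv(xt, fm, wm, tau_ssc, K_a, K_f, K_fw, K_w, K_1, k3)
        for i in range(x.size):
            xt[i] = x[i] + dt * k3[i]
        _msom_deriv(xt, f[k + 1], w[k + 1], tau_ssc, K_a, K_f, K_fw, K_w, K_1, k4)
        for i in range(x.size):
            x[i] += (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        # keep |g_hat| = G exactly and q unit-norm
        gn = np.sqrt(x[6] ** 2 + x[7] ** 2 + x[8] ** 2)
        for i in range(6, 9):
            x[i] *= _G / gn
        qn = np.sqrt(x[12] ** 2 + x[13] ** 2 + x[14] ** 2 + x[15] ** 2)
        for i in range(12, 16):
            x[i] /= qn
        ok = True
        for i in range(x.size):
            if not np.isfinite(x[i]):
                ok = False
        if not ok:
            return xs[: k + 1]
        xs[k + 1] = x
    return xs


@njit(cache=True, fastmath=True)
def pfm_loop(f, v_sensed, dt, tau_ssc, sigma_c, sigma_a, sigma_w, n_particles, seed, systematic):
    """Full particle-filter run; returns per-sample posterior means.

    f, v_sensed: (n, 3); sigmas in SI units (rad/s, m/s^2, rad/s).
    Outputs: w_hat (n,3), a_earth (n,3), g_head (n,3), theta (n,4).
    """
    np.random.seed(seed)
    n = f.shape[0]
    m = n_particles

    C = np.zeros((m, 3))
    Omega = np.zeros((m, 3))
    Theta = np.zeros((m, 4))
    Theta[:, 0] = 1.0

    w_hat = np.zeros((n, 3))
    a_earth = np.zeros((n, 3))
    g_head = np.zeros((n, 3))
    g_head[0, 2] = _G
    theta = np.zeros((n, 4))
    theta[0, 0] = 1.0

    C_new = np.empty((m, 3))
    Omega_new = np.empty((m, 3))
    Theta_new = np.empty((m, 4))
    A = np.empty((m, 3))
    logw = np.empty(m)
    wts = np.empty(m)
    cumw = np.empty(m)
    idx = np.empty(m, dtype=np.int64)

    inv_sa2 = 1.0 / (sigma_a * sigma_a)
    inv_sw2 = 1.0 / (sigma_w * sigma_w)

    for k in range(1, n):
        fx, fy, fz = f[k, 0], f[k, 1], f[k, 2]
        maxlog = -1e300
        for j in range(m):
            # perturb the sensed canal signal and invert the canal equation
            for i in range(3):
                c = v_sensed[k - 1, i] + sigma_c * np.random.standard_normal()
                Omega_new[j, i] = Omega[j, i] + (c - C[j, i]) + (dt / tau_ssc) * C[j, i]
                C_new[j, i] = c
            # advance the orientation quaternion by R(Omega dt)
            rx = Omega_new[j, 0] * dt
            ry = Omega_new[j, 1] * dt
            rz = Omega_new[j, 2] * dt
            ang = np.sqrt(rx * rx + ry * ry + rz * rz)
            if ang < 1e-12:
                dw, s = 1.0, 0.5
            else:
                dw = np.cos(0.5 * ang)
                s = np.sin(0.5 * ang) / ang
            dx_, dy, dz = s * rx, s * ry, s * rz
            qw, qx, qy, qz = Theta[j, 0], Theta[j, 1], Theta[j, 2], Theta[j, 3]
            nw = qw * dw - qx * dx_ - qy * dy - qz * dz
            nx = qw * dx_ + qx * dw + qy * dz - qz * dy
            ny = qw * dy - qx * dz + qy * dw + qz * dx_
            nz = qw * dz + qx * dy - qy * dx_ + qz * dw
            qn = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
            nw /= qn
            nx /= qn
            ny /= qn
            nz /= qn
            Theta_new[j, 0], Theta_new[j, 1], Theta_new[j, 2], Theta_new[j, 3] = nw, nx, ny, nz
            # earth-frame acceleration: A = R(Theta) f + (0,0,-G)
            tx = 2.0 * (ny * fz - nz * fy)
            ty = 2.0 * (nz * fx - nx * fz)
            tz = 2.0 * (nx * fy - ny * fx)
            ax = fx + nw * tx + (ny * tz - nz * ty)
            ay = fy + nw * ty + (nz * tx - nx * tz)
            az = fz + nw * tz + (nx * ty - ny * tx) - _G
            A[j, 0], A[j, 1], A[j, 2] = ax, ay, az
            lw = -0.5 * (
                (ax * ax + ay * ay + az * az) * inv_sa2
                + (
                    Omega_new[j, 0] ** 2
                    + Omega_new[j, 1] ** 2
                    + Omega_new[j, 2] ** 2
                )
                * inv_sw2
            )
            logw[j] = lw
            if lw > maxlog:
                maxlog = lw

        total = 0.0
        for j in range(m):
            wts[j] = np.exp(logw[j] - maxlog)
            total += wts[j]
        if total <= 0.0 or not np.isfinite(total):
            for j in range(m):
                wts[j] = 1.0 / m
            total = 1.0
        for j in range(m):
            wts[j] /= total

        # weighted posterior means (pre-resampling)
        for i in range(3):
            w_hat[k, i] = 0.0
            a_earth[k, i] = 0.0
            g_head[k, i] = 0.0
        for i in range(4):
            theta[k, i] = 0.0
        for j in range(m):
            wj = wts[j]
            nw, nx, ny, nz = Theta_new[j, 0], Theta_new[j, 1], Theta_new[j, 2], Theta_new[j, 3]
            # head-frame gravity implied by the particle: R^T (0,0,G)
            gx = 2.0 * _G * (nx * nz - nw * ny)
            gy = 2.0 * _G * (ny * nz + nw * nx)
            gz = _G * (nw * nw - nx * nx - ny * ny + nz * nz)
            for i in range(3):
                w_hat[k, i] += wj * Omega_new[j, i]
                a_earth[k, i] += wj * A[j, i]
            g_head[k, 0] += wj * gx
            g_head[k, 1] += wj * gy
            g_head[k, 2] += wj * gz
            theta[k, 0] += wj * nw
            theta[k, 1] += wj * nx
            theta[k, 2] += wj * ny
            theta[k, 3] += wj * nz
        qn = np.sqrt(theta[k, 0] ** 2 + theta[k, 1] ** 2 + theta[k, 2] ** 2 + theta[k, 3] ** 2)
        for i in range(4):
            theta[k, i] /= qn

        # resampling
        cum = 0.0
        for j in range(m):
            cum += wts[j]
            cumw[j] = cum
        cumw[m - 1] = 1.0
        if systematic:
            u0 = np.random.random() / m
            j = 0
            for i in range(m):
                u = u0 + i / m
                while cumw[j] < u:
                    j += 1
                idx[i] = j
        else:
            for i in range(m):
                u = np.random.random()
                j = np.searchsorted(cumw, u)
                idx[i] = j

        for i in range(m):
            j = idx[i]
            for a_ in range(3):
                C[i, a_] = C_new[j, a_]
                Omega[i, a_] = Omega_new[j, a_]
            for a_ in range(4):
                Theta[i, a_] = Theta_new[j, a_]

    return w_hat, a_earth, g_head, theta
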