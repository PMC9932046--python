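"""Coordinate-descent kernels for penalized weighted least squares.

The penalized logistic / Cox solvers reduce each outer iteration to a
quadratic (IRLS) subproblem solved here. Penalty codes: 0 = lasso,
1 = adaptive lasso, 2 = elastic net, 3 = MCP. The MCP coordinate subproblem
can be nonconvex when the curvature ``v`` falls below ``1/gamma``; the update
then compares the stationary candidates by objective value instead of using
the firm-threshold formula blindly.
"""

import numpy as np
from numba import njit

LASSO, ALASSO, ENET, MCP = 0, 1, 2, 3


@njit(cache=False)
def _soft(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=False)
def _mcp_pen(b, lam, gam):
    ab = abs(b)
    if ab <= gam * lam:
        return lam * ab - b * b / (2.0 * gam)
    return 0.5 * gam * lam * lam


@njit(cache=False)
def _coord_update(zj, vj, lam, pen, gam, alp, wj):
    """argmin_b  0.5*vj*b^2 - zj*b + penalty(b; lam)."""
    if vj <= 1e-12:
        return 0.0
    if pen == LASSO:
        return _soft(zj, lam) / vj
    if pen == ALASSO:
        return _soft(zj, lam * wj) / vj
    if pen == ENET:
        return _soft(zj, lam * alp) / (vj + lam * (1.0 - alp))
    # MCP: evaluate stationary candidates by objective value
    best_b = 0.0
    best_q = 0.0  # q(0) = 0
    denom = vj - 1.0 / gam
    if denom > 1e-12:
        b1 = _soft(zj, lam) / denom
        if abs(b1) <= gam * lam:
            q1 = 0.5 * vj * b1 * b1 - zj * b1 + _mcp_pen(b1, lam, gam)
            if q1 < best_q:
                best_q = q1
                best_b = b1
    b2 = zj / vj
    if abs(b2) >= gam * lam:
        q2 = 0.5 * vj * b2 * b2 - zj * b2 + _mcp_pen(b2, lam, gam)
        if q2 < best_q:
            best_q = q2
            best_b = b2
    b3 = gam * lam if zj > 0 else -gam * lam
    q3 = 0.5 * vj * b3 * b3 - zj * b3 + _mcp_pen(b3, lam, gam)
    if q3 < best_q:
        best_q = q3
        best_b = b3
    return best_b


@njit(cache=False)
def cd_wls(Xs, w, r, beta, b0, vj, lam, pen, gam, alp, adw, fit_icpt, tol, max_sweep):
    """In-place CD sweeps on the weighted quadratic subproblem.

    ``r`` is the working residual ``z - b0 - Xs @ beta`` and is kept in sync.
    Returns (b0, sweeps_used, last_max_step).
    """
    n, p = Xs.shape
    active = np.zeros(p, dtype=np.uint8)
    maxd = 0.0
    sweeps = 0
    full = True
    while sweeps < max_sweep:
        sweeps += 1
        maxd = 0.0
        if fit_icpt:
            num = 0.0
            den = 0.0
            for i in range(n):
                num += w[i] * r[i]
                den += w[i]
            if den > 0.0:
                d0 = num / den
                b0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > maxd:
                    maxd = abs(d0)
        for j in range(p):
            if not full and active[j] == 0:
                continue
            if vj[j] <= 1e-12:
                continue
            zj = 0.0
            for i in range(n):
                zj += w[i] * Xs[i, j] * r[i]
            zj = zj / n + vj[j] * beta[j]
            bn = _coord_update(zj, vj[j], lam, pen, gam, alp, adw[j])
            d = bn - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= Xs[i, j] * d
                beta[j] = bn
                if abs(d) > maxd:
                    maxd = abs(d)
            active[j] = 1 if beta[j] != 0.0 else 0
        if full:
            if maxd < tol:
                break  # converged on a full sweep
            full = False
        elif maxd < tol:
            full = True  # active set converged; verify with a full sweep
    return b0, sweeps, maxd


@njit(cache=False)
def cox_weights(eta, event_sorted):
    """Breslow working weights/response pieces for time-sorted rows.

    Returns (grad_eta, w, pll): per-subject score and curvature of the
    partial likelihood w.r.t. the linear predictor, and the log partial
    likelihood itself.
    """
    n = eta.shape[0]
    e = np.exp(eta)
    s0 = np.empty(n)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc += e[i]
        s0[i] = acc
    H = np.empty(n)
    G = np.empty(n)
    pll = 0.0
    h = 0.0
    g2 = 0.0
    for i in range(n):
        if event_sorted[i] == 1:
            h += 1.0 / s0[i]
            g2 += 1.0 / (s0[i] * s0[i])
            pll += eta[i] - np.log(s0[i])
        H[i] = h
        G[i] = g2
    grad = np.empty(n)
    w = np.empty(n)
    for i in range(n):
        grad[i] = event_sorted[i] - e[i] * H[i]
        wi = e[i] * H[i] - e[i] * e[i] * G[i]
        w[i] = wi if wi > 1e-9 else 1e-9
    return grad, w, pll
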