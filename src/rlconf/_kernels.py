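"""JIT-compiled sequential likelihood pass.

The per-trial recursion is inherently sequential, and model fitting
evaluates it tens of thousands of times, so the inner loop is compiled
with numba.  The readable per-trial reference lives in :mod:`rlconf.models`
(prediction_errors / apply_update); the two paths are asserted equal in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_P_CLIP = 1e-12

# family codes: 0=ABS, 1=REL, 2=ASYM, 3=RELASYM
# variant codes: -1=none, 0=zero, 1=Qu, 2=last_outcome, 3=weighted_imaginary


@njit(cache=True)
def learning_pass(family, variant, theta, ctx, chosen_good, complete, r_c, r_u):
    a1, a2, alpha_v, w, beta = theta[0], theta[1], theta[2], theta[3], theta[4]
    n = ctx.shape[0]
    Q = np.zeros((4, 2))
    V = np.zeros(4)
    last = np.zeros((4, 2))
    latents = np.empty((n, 7))
    relative = family == 1 or family == 3
    asym = family == 2 or family == 3
    loglik = 0.0
    for t in range(n):
        s = ctx[t]
        cg = chosen_good[t]
        ug = 1 - cg
        qc = Q[s, cg]
        qu = Q[s, ug]
        v = V[s]
        d = beta * (qc - qu)
        if d > 700.0:
            d = 700.0
        elif d < -700.0:
            d = -700.0
        p = 1.0 / (1.0 + np.exp(-d))
        if p < _P_CLIP:
            p = _P_CLIP
        elif p > 1.0 - _P_CLIP:
            p = 1.0 - _P_CLIP
        loglik += np.log(p)

        center = v if relative else 0.0
        dc = r_c[t] - center - qc
        du = r_u[t] - center - qu if complete[t] == 1 else np.nan
        if relative:
            if complete[t] == 1:
                other = r_u[t]
            elif variant == 0:
                other = 0.0
            elif variant == 1:
                other = qu
            elif variant == 2:
                other = last[s, ug]
            else:
                if v == 0.0:
                    img = 0.0
                else:
                    comp = 1.0 if np.abs(r_c[t]) < 0.5 else 0.1
                    img = comp if v > 0.0 else -comp
                other = w * img
            dv = (r_c[t] + other) / 2.0 - v
        else:
            dv = np.nan

        latents[t, 0] = qc
        latents[t, 1] = qu
        latents[t, 2] = v
        latents[t, 3] = dc
        latents[t, 4] = du
        latents[t, 5] = dv
        latents[t, 6] = p

        ac = (a1 if dc > 0.0 else a2) if asym else a1
        Q[s, cg] = qc + ac * dc
        if complete[t] == 1:
            au = (a1 if du < 0.0 else a2) if asym else a2
            Q[s, ug] = qu + au * du
        if relative:
            V[s] = v + alpha_v * dv
        last[s, cg] = r_c[t]
        if complete[t] == 1:
            last[s, ug] = r_u[t]
    return latents, Q, V, loglik


@njit(cache=True)
def transfer_loglik(beta, q_end, c_ctx, c_good, u_ctx, u_good):
    loglik = 0.0
    for t in range(c_ctx.shape[0]):
        d = beta * (q_end[c_ctx[t], c_good[t]] - q_end[u_ctx[t], u_good[t]])
        if d > 700.0:
            d = 700.0
        elif d < -700.0:
            d = -700.0
        p = 1.0 / (1.0 + np.exp(-d))
        if p < _P_CLIP:
            p = _P_CLIP
        elif p > 1.0 - _P_CLIP:
            p = 1.0 - _P_CLIP
        loglik += np.log(p)
    return loglik
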