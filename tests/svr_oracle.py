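"""Independent high-accuracy oracle for the asymmetric ε-insensitive QP.

Solves the full primal (weights, bias and explicit slack variables) with
scipy's SLSQP — a generic sequential-QP path entirely separate from the
package's reduced-primal solver — for cross-checking predictions.
"""

import numpy as np
from scipy.optimize import minimize


def solve_qp_primal(X, y, C_over, C_under, eps_over, eps_under):
    n, d = X.shape
    k = d + 1 + 2 * n

    def f(z):
        w = z[:d]
        return 0.5 * w @ w + C_over @ z[d + 1 : d + 1 + n] + C_under @ z[d + 1 + n :]

    def g(z):
        gr = np.zeros(k)
        gr[:d] = z[:d]
        gr[d + 1 : d + 1 + n] = C_over
        gr[d + 1 + n :] = C_under
        return gr

    jac_over = np.hstack([-X, -np.ones((n, 1)), np.eye(n), np.zeros((n, n))])
    jac_under = np.hstack([X, np.ones((n, 1)), np.zeros((n, n)), np.eye(n)])
    cons = [
        {  # (w.x + b) - y <= eps_over + xi_over
            "type": "ineq",
            "fun": lambda z: (y + eps_over) - (X @ z[:d] + z[d]) + z[d + 1 : d + 1 + n],
            "jac": lambda z: jac_over,
        },
        {  # y - (w.x + b) <= eps_under + xi_under
            "type": "ineq",
            "fun": lambda z: (X @ z[:d] + z[d]) - (y - eps_under) + z[d + 1 + n :],
            "jac": lambda z: jac_under,
        },
    ]
    bounds = [(None, None)] * (d + 1) + [(0, None)] * (2 * n)
    z0 = np.zeros(k)
    z0[d] = y.mean()
    r0 = z0[d] - y
    z0[d + 1 : d + 1 + n] = np.maximum(0, r0 - eps_over)
    z0[d + 1 + n :] = np.maximum(0, -r0 - eps_under)
    res = minimize(
        f, z0, jac=g, method="SLSQP", constraints=cons, bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-16},
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative
        raise RuntimeError(f"oracle QP failed: {res.message}")
    return res.x[:d], float(res.x[d])
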