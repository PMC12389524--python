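"""Independent reference solver for the epsilon-SVR dual.

Kept separate from the package so the acceptance script's cross-check never
shares code with the implementation it verifies.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def qp_oracle(gram, y, cost, epsilon):
    """Direct SLSQP solve of the epsilon-SVR dual.

    Variables (alpha, alpha*) stacked; minimize
      1/2 (a-a*)^T K (a-a*) + eps * sum(a+a*) - y^T (a-a*)
    s.t. 0 <= a, a* <= C and sum(a-a*) = 0.  Returns (net duals, maximized
    dual objective), best of several starts.
    """
    n = len(y)
    K = np.asarray(gram, dtype=float)

    def objective(z):
        d = z[:n] - z[n:]
        return 0.5 * d @ K @ d + epsilon * z.sum() - y @ d

    def grad(z):
        d = z[:n] - z[n:]
        Kd = K @ d
        return np.concatenate([Kd + epsilon - y, -Kd + epsilon + y])

    constraints = [{"type": "eq", "fun": lambda z: z[:n].sum() - z[n:].sum()}]
    bounds = [(0.0, cost)] * (2 * n)
    best = None
    for start_seed in range(3):
        z0 = np.random.default_rng(start_seed).uniform(0, min(cost, 1.0), 2 * n)
        res = minimize(
            objective, z0, jac=grad, bounds=bounds, constraints=constraints,
            method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    d = best.x[:n] - best.x[n:]
    return d, -best.fun
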