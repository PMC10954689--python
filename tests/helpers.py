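"""Shared test oracles, independent of the package's own solver path."""

import numpy as np
from scipy.optimize import minimize


def lbfgsb_oracle(X, y, alpha, alpha2):
    """Reference solve of the pixel decoding problem.

    Under w >= 0 the L1 term is linear, so the elastic-net objective is
    smooth on the feasible set: L-BFGS-B provides a starting point, and an
    active-set polish solves the KKT system exactly on the detected support
    (dropping negative coordinates, admitting violated ones) so the oracle
    is accurate to machine precision even along nearly-flat directions.
    This route shares no code with the package's iterative solver.
    """
    m, N = X.shape
    G = X.T @ X / m
    b = X.T @ y / m

    def fun(w):
        r = y - X @ w
        return 0.5 / m * r @ r + alpha * w.sum() + 0.5 * alpha2 * w @ w

    def grad(w):
        return -(X.T @ (y - X @ w)) / m + alpha + alpha2 * w

    res = minimize(fun, np.zeros(N), jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * N,
                   options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12})
    support = set(np.nonzero(res.x > 1e-10)[0])

    for _ in range(4 * N):
        S = sorted(support)
        w = np.zeros(N)
        if S:
            A = G[np.ix_(S, S)] + alpha2 * np.eye(len(S))
            sol = np.linalg.solve(A, b[S] - alpha)
            if sol.min() < -1e-12:
                support.discard(S[int(np.argmin(sol))])
                continue
            w[S] = np.maximum(sol, 0.0)
        # KKT: for inactive coords the gradient must be non-negative
        g = -(b - G @ w) + alpha + alpha2 * w
        inactive = np.ones(N, dtype=bool)
        inactive[S] = False
        viol = np.nonzero(inactive & (g < -1e-12))[0]
        if viol.size == 0:
            return w
        support.add(int(viol[np.argmin(g[viol])]))
    raise RuntimeError("active-set oracle failed to converge")
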