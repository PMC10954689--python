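"""Batched non-negative elastic-net solver for pixel decoding.

Each foreground pixel poses the same small problem with a shared design
(the codebook matrix ``X``, shape ``3n x N``):

    minimize_{w >= 0}  1/(2*3n) ||y - X w||^2  +  alpha ||w||_1
                       + alpha2/2 ||w||_2^2

The 1/(2m) data-term scaling (m = 3n) is what makes the detection bound for
a pure-barcode pixel come out as w_max = (3n/k) * alpha when alpha2 = 0.

Because a single field of view needs 1e5-1e6 of these solves, the solver is
written as FISTA vectorized across pixels: every iteration is a pair of
(3n x N) x (N x P) matrix products.  Under the non-negativity constraint the
L1 term is linear, so the proximal step is a plain shifted projection onto
the non-negative orthant and solutions carry exact zeros.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nonneg_elastic_net", "decode_pixel", "spd_objective"]


def spd_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                  alpha: float, alpha2: float) -> float:
    """Objective value for one pixel (used by tests and diagnostics)."""
    m = X.shape[0]
    r = y - X @ w
    return float(0.5 / m * r @ r + alpha * np.abs(w).sum()
                 + 0.5 * alpha2 * w @ w)


def nonneg_elastic_net(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: float,
    alpha2: float = 0.0,
    tol: float = 1e-7,
    max_iter: int = 2000,
    w_init: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Solve the non-negative elastic net for a batch of pixels.

    Parameters
    ----------
    X : (m, N) design (codebook) matrix.
    Y : (m, P) pixel intensity vectors, one column per pixel.
    alpha, alpha2 : L1 and ridge penalties (see module docstring for the
        objective scaling).
    tol : convergence threshold on the max coordinate change between
        consecutive iterates.
    max_iter : iteration cap; pixels still moving more than ``tol`` at the
        cap are zeroed and counted as non-converged.
    w_init : optional (N, P) warm start (e.g. the solution at a nearby
        alpha when sweeping a regularization grid).

    Returns
    -------
    W : (N, P) weight matrix, non-negative with exact zeros.
    n_nonconverged : number of zeroed, non-converged pixels.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    m, N = X.shape
    P = Y.shape[1]
    if Y.shape[0] != m:
        raise ValueError(f"X has {m} rows but Y has {Y.shape[0]}")
    if alpha < 0 or alpha2 < 0:
        raise ValueError("penalties must be non-negative")
    if P == 0:
        return np.zeros((N, 0)), 0

    G = X.T @ X / m
    lip = float(np.linalg.eigvalsh(G)[-1]) + alpha2
    step = 1.0 / lip
    shift = step * alpha
    check_every = 25  # freeze converged pixels periodically

    W_out = np.zeros((N, P))
    active = np.arange(P)  # columns still iterating
    converged = np.zeros(P, dtype=bool)
    B = X.T @ Y / m  # constant part of the gradient
    if w_init is not None:
        W = np.array(w_init, dtype=np.float64)
        if W.ndim == 1:
            W = W[:, None]
        if W.shape != (N, P):
            raise ValueError(f"w_init has shape {W.shape}, expected {(N, P)}")
    else:
        W = np.zeros((N, P))
    Z = W.copy()  # FISTA extrapolation point
    t = np.ones(P)  # per-pixel momentum (reset on restart)
    delta = np.full(P, np.inf)
    for it in range(1, max_iter + 1):
        grad = (X.T @ (X @ Z)) / m - B + alpha2 * Z
        W_new = Z - step * grad - shift
        np.maximum(W_new, 0.0, out=W_new)
        dW = W_new - W
        # gradient-scheme adaptive restart, per pixel
        restart = ((Z - W_new) * dW).sum(axis=0) > 0.0
        t[restart] = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Z = W_new + ((t - 1.0) / t_new) * dW
        np.abs(dW).max(axis=0, out=delta)
        W = W_new
        t = t_new
        if it % check_every == 0 or delta.max() < tol:
            done = delta < tol
            if done.all():
                W_out[:, active] = W
                converged[active] = True
                break
            if done.any():
                W_out[:, active[done]] = W[:, done]
                converged[active[done]] = True
                keep = ~done
                active = active[keep]
                W, Z, B = W[:, keep], Z[:, keep], B[:, keep]
                delta, t = delta[keep], t[keep]
    else:
        # pixels still moving at the cap: flag and zero them
        done = delta < tol
        W_out[:, active[done]] = W[:, done]
        converged[active[done]] = True
    n_bad = int(P - converged.sum())
    W = W_out
    if single:
        return W[:, 0], n_bad
    return W, n_bad


def decode_pixel(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
    alpha2: float = 0.0,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> np.ndarray:
    """Sparse deconvolution of a single pixel vector; returns w_lasso (N,)."""
    w, _ = nonneg_elastic_net(X, np.asarray(y, dtype=float), alpha, alpha2,
                              tol=tol, max_iter=max_iter)
    return w
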