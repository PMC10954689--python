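"""SparseDeconvolution (SpD): pixel-level barcode decoding.

Pipeline per field of view:

1. *Channel coefficients.*  Per-plane multiplicative gains ``c`` (length 3n)
   relating weights to intensities, ``y = c (*) X w``, are estimated
   iteratively from pixels that decode to a single unsaturated barcode.
2. *Adaptive regularization.*  An L1 penalty ``alpha`` is chosen per pixel
   from a lookup table over pixel norms; the table is trained by maximizing
   a Gaussian-weighted sum of refit L1 norms over an alpha grid.
3. *Decoding.*  Every foreground pixel (``||y/c||_2 > 0.25``) is deconvolved
   by a non-negative elastic net over the codebook columns, the top weights
   are accepted by an elbow rule (at most two barcodes per pixel), and the
   accepted support is refit by ordinary least squares for unbiased weights.

The elastic-net objective is ``1/(2*3n) ||y - Xw||^2 + alpha ||w||_1 +
alpha2/2 ||w||_2^2`` with ``w >= 0`` and ``alpha2 = alpha/100``; under this
scaling a pixel made purely of one barcode at intensity ``w`` stays
undetected exactly when ``w <= w_max = (3n/k) alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .codebook import Codebook
from .io import FOVStack
from .solver import nonneg_elastic_net, decode_pixel  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderConfig",
    "AlphaLookup",
    "WeightMaps",
    "decode_pixel",
    "max_undetected_weight",
    "elbow_filter",
    "ols_refit",
    "estimate_channel_coefficients",
    "build_alpha_lookup",
    "decode_fov",
]


def _default_alpha_grid() -> tuple:
    # 0.01 .. 0.1 inclusive, step 0.005
    return tuple(round(float(a), 4)
                 for a in np.arange(0.01, 0.1 + 1e-9, 0.005))


def _default_norm_grid() -> tuple:
    return tuple(float(u) for u in np.linspace(0.0, 2.8, 50))


@dataclass
class DecoderConfig:
    """Tunable parameters of the SpD decoder.

    The ratio ``alpha_ratio = alpha2/alpha`` keeps a small ridge term for
    numerical stability; ``foreground_norm_threshold`` separates background;
    the elbow ratios accept the top weight (second < 0.5 * first) or the top
    two (third < 0.3 * first); channel gains are refined for
    ``coeff_iterations`` passes using pixels whose single refit weight lies
    in ``coeff_weight_window`` (dominant but unsaturated).
    """

    alpha_ratio: float = 0.01
    foreground_norm_threshold: float = 0.25
    elbow_second_ratio: float = 0.5
    elbow_third_ratio: float = 0.3
    coeff_iterations: int = 2
    coeff_weight_window: tuple = (0.1, 0.5)
    coeff_alpha: float = 0.05
    alpha_grid: tuple = _default_alpha_grid()
    norm_grid: tuple = _default_norm_grid()
    kernel_bandwidth: float = 0.1
    train_sample_size: int = 20000
    lookup_sample_size: int = 10000
    solver_tol: float = 1e-6
    solver_max_iter: int = 2000
    chunk_size: int = 65536
    keep_lasso: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        ag = np.asarray(self.alpha_grid, dtype=float)
        if ag.size == 0 or np.any(np.diff(ag) <= 0):
            raise ValueError("alpha_grid must be non-empty and strictly increasing")
        for name in ("alpha_ratio", "foreground_norm_threshold",
                     "elbow_second_ratio", "elbow_third_ratio",
                     "kernel_bandwidth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def max_undetected_weight(n: int, k: int, alpha: float) -> float:
    """Largest pure-barcode intensity that the lasso leaves at zero.

    For a pixel composed of a single barcode (k on-rounds out of n) and no
    ridge term, weights at or below ``(3n/k) * alpha`` are absorbed entirely
    by the L1 penalty.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    return 3.0 * n * alpha / k


def elbow_filter(
    w: np.ndarray,
    second_ratio: float = 0.5,
    third_ratio: float = 0.3,
) -> tuple[int, ...]:
    """Accept the top one or two weights of a deconvolved pixel.

    Returns the indices of the accepted weights: ``(top1,)`` when the second
    largest weight is below ``second_ratio`` of the top, ``(top1, top2)``
    when instead the third largest is below ``third_ratio`` of the top, and
    ``()`` otherwise (ambiguous pixel).  Ties are broken by barcode index
    (stable sort on weight).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.max(initial=0.0) <= 0:
        return ()
    order = np.argsort(-w, kind="stable")
    w1 = w[order[0]]
    w2 = w[order[1]] if w.size > 1 else 0.0
    w3 = w[order[2]] if w.size > 2 else 0.0
    if w2 < second_ratio * w1:
        return (int(order[0]),)
    if w3 < third_ratio * w1:
        return (int(order[0]), int(order[1]))
    return ()


def ols_refit(y: np.ndarray, X: np.ndarray, support) -> np.ndarray:
    """Unbiased least-squares refit on 1 or 2 accepted barcodes.

    Negative refit weights are physically meaningless and are handled by
    dropping the offending barcode and refitting the remaining one.  Returns
    a full-length weight vector with zeros off the support.
    """
    support = tuple(support)
    if len(support) not in (1, 2):
        raise ValueError("support must contain 1 or 2 indices")
    y = np.asarray(y, dtype=float)
    w = np.zeros(X.shape[1])
    cols = X[:, support]
    if len(support) == 2 and np.array_equal(cols[:, 0], cols[:, 1]):
        support = support[:1]
        cols = cols[:, :1]
    coef, *_ = np.linalg.lstsq(cols, y, rcond=None)
    if len(support) == 2 and coef.min() < 0:
        keep = int(np.argmax(coef))
        support = (support[keep],)
        cols = cols[:, keep:keep + 1]
        coef, *_ = np.linalg.lstsq(cols, y, rcond=None)
    w[list(support)] = np.maximum(coef, 0.0)
    return w


# --------------------------------------------------------------------------
# vectorized elbow + OLS refit over pixel batches


def _elbow_ols_batch(
    W_lasso: np.ndarray,
    X: np.ndarray,
    Yn: np.ndarray,
    config: DecoderConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the elbow rule and OLS refit to a batch of lasso solutions.

    Returns ``(support, weights)`` of shape (2, P): barcode indices (-1 for
    absent) and their refit weights, clipped at zero with support reduction
    on negative refits.
    """
    N, P = W_lasso.shape
    sup = np.full((2, P), -1, dtype=np.int64)
    wout = np.zeros((2, P))
    if P == 0:
        return sup, wout
    # top-3 weights per pixel (N >= 3 for any real codebook)
    part = np.argpartition(-W_lasso, 2, axis=0)[:3]
    vals = np.take_along_axis(W_lasso, part, axis=0)
    # order the three, stable by (weight desc, index asc)
    ord3 = np.lexsort((part, -vals), axis=0)
    idx3 = np.take_along_axis(part, ord3, axis=0)
    w3v = np.take_along_axis(vals, ord3, axis=0)
    w1, w2, w3 = w3v
    i1, i2 = idx3[0], idx3[1]
    nonzero = w1 > 0
    top1 = nonzero & (w2 < config.elbow_second_ratio * w1)
    top2 = nonzero & ~top1 & (w3 < config.elbow_third_ratio * w1)

    k = int(X[:, 0].sum())
    Gram = X.T @ X  # (N, N) small
    # correlations b_i = x_i' y for the selected columns
    b1 = np.einsum("mp,mp->p", X[:, i1], Yn)
    b2 = np.einsum("mp,mp->p", X[:, i2], Yn)

    # single-barcode refit
    if top1.any():
        sup[0, top1] = i1[top1]
        wout[0, top1] = np.maximum(b1[top1] / k, 0.0)

    # two-barcode refit via the 2x2 normal equations
    if top2.any():
        o = Gram[i1, i2].astype(float)
        det = k * k - o * o
        safe = top2 & (det > 0)
        # identical columns cannot occur for distinct barcodes, but guard
        degenerate = top2 & ~safe
        wi = np.zeros(P)
        wj = np.zeros(P)
        wi[safe] = (k * b1[safe] - o[safe] * b2[safe]) / det[safe]
        wj[safe] = (k * b2[safe] - o[safe] * b1[safe]) / det[safe]
        neg_i = safe & (wi < 0)
        neg_j = safe & (wj < 0) & ~neg_i
        both = safe & ~neg_i & ~neg_j
        sup[0, both] = i1[both]
        sup[1, both] = i2[both]
        wout[0, both] = wi[both]
        wout[1, both] = wj[both]
        # drop the negative one, refit the survivor alone
        drop_to_j = neg_i
        drop_to_i = neg_j | degenerate
        sup[0, drop_to_j] = i2[drop_to_j]
        wout[0, drop_to_j] = np.maximum(b2[drop_to_j] / k, 0.0)
        sup[0, drop_to_i] = i1[drop_to_i]
        wout[0, drop_to_i] = np.maximum(b1[drop_to_i] / k, 0.0)
    return sup, wout


def _sample_pixels(n_total: int, n_sample: int, rng: np.random.Generator) -> np.ndarray:
    if n_total <= n_sample:
        return np.arange(n_total)
    return rng.choice(n_total, size=n_sample, replace=False)


def _solve_batch(X, Yn, alpha, config: DecoderConfig, w_init=None):
    return nonneg_elastic_net(
        X, Yn, alpha, alpha * config.alpha_ratio,
        tol=config.solver_tol, max_iter=config.solver_max_iter,
        w_init=w_init,
    )


def estimate_channel_coefficients(
    stack: FOVStack,
    codebook: Codebook,
    config: DecoderConfig | None = None,
) -> np.ndarray:
    """Estimate per-plane multiplicative gains from the stack itself.

    Starting from ``c = 1``, a fixed random sample of foreground pixels is
    repeatedly (a) normalized by the current ``c``, (b) decoded at
    ``coeff_alpha``, (c) filtered to pixels carrying exactly one barcode
    with refit weight inside ``coeff_weight_window``, and (d) used to update
    each ``c_j`` by a scalar least-squares fit of observed intensities on
    predicted ones.  Planes with no qualifying pixel keep their current
    coefficient (with a warning).
    """
    config = config or DecoderConfig()
    X = codebook.X
    m = X.shape[0]
    if stack.n_planes != m:
        raise ValueError(f"stack has {stack.n_planes} planes, codebook needs {m}")
    pixels = stack.pixels().astype(np.float64)
    norms = np.linalg.norm(pixels, axis=0)
    fg = np.nonzero(norms > config.foreground_norm_threshold)[0]
    if fg.size == 0:
        raise ValueError("stack has no foreground pixels")
    rng = np.random.default_rng(config.rng_seed)
    sample = fg[_sample_pixels(fg.size, config.train_sample_size, rng)]
    Y = pixels[:, sample]

    c = np.ones(m)
    lo, hi = config.coeff_weight_window
    for _ in range(config.coeff_iterations):
        Yn = Y / c[:, None]
        W, _ = _solve_batch(X, Yn, config.coeff_alpha, config)
        sup, wref = _elbow_ols_batch(W, X, Yn, config)
        keep = (sup[0] >= 0) & (sup[1] < 0) & (wref[0] >= lo) & (wref[0] <= hi)
        if not keep.any():
            logger.warning("channel coefficients: no qualifying pixels; "
                           "keeping current estimate")
            break
        M = X[:, sup[0, keep]] * wref[0, keep]  # predicted Xw, (m, n_kept)
        num = np.einsum("mp,mp->m", Y[:, keep], M)
        den = np.einsum("mp,mp->m", M, M)
        ok = den > 0
        if not ok.all():
            logger.warning("channel coefficients: %d plane(s) had no signal; "
                           "coefficient retained", int((~ok).sum()))
        c = np.where(ok, num / np.where(ok, den, 1.0), c)
    # The model y = c * Xw leaves the joint scale of (c, w) undetermined:
    # (s*c, w/s) fits identically, and the scale the iteration happens to
    # settle in depends on its first, gain-mismatched pass.  Report gains
    # in the unit-mean gauge, consistent with the c = 1 initialization.
    return c / c.mean()


@dataclass
class AlphaLookup:
    """Lookup table: pixel L2 norm -> L1 penalty alpha.

    Norm queries are clamped to the grid range and resolved to the nearest
    grid point.
    """

    norms: np.ndarray
    alphas: np.ndarray

    def __post_init__(self) -> None:
        self.norms = np.asarray(self.norms, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.norms.shape != self.alphas.shape:
            raise ValueError("norms and alphas must have the same length")

    def alpha_for(self, norm) -> np.ndarray:
        """Alpha for one norm or an array of norms (nearest grid point)."""
        q = np.clip(np.atleast_1d(np.asarray(norm, dtype=float)),
                    self.norms[0], self.norms[-1])
        mid = 0.5 * (self.norms[1:] + self.norms[:-1])
        idx = np.searchsorted(mid, q)
        out = self.alphas[idx]
        return out if np.ndim(norm) else float(out[0])


def build_alpha_lookup(
    stack: FOVStack,
    codebook: Codebook,
    c: np.ndarray,
    config: DecoderConfig | None = None,
) -> AlphaLookup:
    """Train the norm -> alpha lookup on a sample of foreground pixels.

    For every alpha on the grid, the full SpD chain (deconvolution, elbow,
    OLS refit) is run on the training pixels; for every norm ``u`` on the
    norm grid the alpha maximizing the Gaussian-weighted sum of refit L1
    norms (bandwidth ``kernel_bandwidth``) is recorded.  Ties go to the
    larger (sparser) alpha.
    """
    config = config or DecoderConfig()
    X = codebook.X
    pixels = stack.pixels().astype(np.float64)
    c = np.asarray(c, dtype=float)
    Yn_all = pixels / c[:, None]
    norms = np.linalg.norm(Yn_all, axis=0)
    fg = np.nonzero(norms > config.foreground_norm_threshold)[0]
    if fg.size == 0:
        raise ValueError("no foreground pixels to train the alpha lookup")
    rng = np.random.default_rng([config.rng_seed, 1])
    sample = fg[_sample_pixels(fg.size, config.lookup_sample_size, rng)]
    Yn = Yn_all[:, sample]
    u_i = norms[sample]

    alpha_grid = np.asarray(config.alpha_grid, dtype=float)
    l1 = np.zeros((alpha_grid.size, sample.size))
    W_prev = None
    # sweep alphas descending so each solve warm-starts from a denser one
    for a_idx in np.argsort(-alpha_grid):
        alpha = alpha_grid[a_idx]
        W, _ = _solve_batch(X, Yn, alpha, config, w_init=W_prev)
        W_prev = W
        _, wref = _elbow_ols_batch(W, X, Yn, config)
        l1[a_idx] = wref.sum(axis=0)

    norm_grid = np.asarray(config.norm_grid, dtype=float)
    sigma = config.kernel_bandwidth
    # Gaussian kernel weights between grid norms and training-pixel norms
    gk = np.exp(-0.5 * ((norm_grid[:, None] - u_i[None, :]) / sigma) ** 2)
    scores = gk @ l1.T  # (n_norms, n_alphas)
    # argmax with ties toward larger alpha
    rev = scores[:, ::-1]
    best = alpha_grid.size - 1 - np.argmax(rev, axis=1)
    return AlphaLookup(norms=norm_grid, alphas=alpha_grid[best])


class WeightMaps:
    """Per-barcode sparse images of decoded weights over one field of view.

    At most two barcodes are non-zero at any pixel (elbow rule).  Maps of
    the OLS-refit weights are always stored; lasso maps are kept when the
    decoder ran with ``keep_lasso``.
    """

    def __init__(self, shape: tuple[int, int], n_barcodes: int,
                 pixel_idx: np.ndarray, barcode_idx: np.ndarray,
                 weights: np.ndarray, lasso_weights: np.ndarray | None = None,
                 metadata: dict | None = None) -> None:
        self.shape = tuple(shape)
        self.n_barcodes = int(n_barcodes)
        self.pixel_idx = np.asarray(pixel_idx, dtype=np.int64)
        self.barcode_idx = np.asarray(barcode_idx, dtype=np.int64)
        self.weights = np.asarray(weights, dtype=np.float64)
        self.lasso_weights = (None if lasso_weights is None
                              else np.asarray(lasso_weights, dtype=np.float64))
        self.metadata = metadata or {}
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n_entries(self) -> int:
        return self.pixel_idx.size

    def barcodes_present(self) -> np.ndarray:
        return np.unique(self.barcode_idx)

    def dense(self, barcode: int, lasso: bool = False) -> np.ndarray:
        """(H, W) weight image of one barcode."""
        vals = self.lasso_weights if lasso else self.weights
        if vals is None:
            raise ValueError("lasso maps were not kept; decode with keep_lasso")
        img = np.zeros(self.shape[0] * self.shape[1])
        mask = self.barcode_idx == barcode
        img[self.pixel_idx[mask]] = vals[mask]
        return img.reshape(self.shape)

    def stack(self, lasso: bool = False) -> np.ndarray:
        """(N, H, W) dense stack of all maps (memory permitting)."""
        return np.stack([self.dense(b, lasso=lasso)
                         for b in range(self.n_barcodes)])


def decode_fov(
    stack: FOVStack,
    codebook: Codebook,
    c: np.ndarray,
    lookup: AlphaLookup,
    config: DecoderConfig | None = None,
) -> WeightMaps:
    """Decode every foreground pixel of a field of view into weight maps.

    Pixels are normalized by the channel coefficients; pixels whose
    normalized norm is at or below the foreground threshold get zero weight
    everywhere.  Each foreground pixel is deconvolved at the alpha assigned
    by the lookup (pixels sharing an alpha are solved in one batch), passed
    through the elbow filter and refit by OLS.
    """
    config = config or DecoderConfig()
    X = codebook.X
    if stack.n_planes != X.shape[0]:
        raise ValueError(f"stack has {stack.n_planes} planes but codebook "
                         f"expects {X.shape[0]}")
    c = np.asarray(c, dtype=float)
    if c.shape != (X.shape[0],):
        raise ValueError(f"channel coefficients have shape {c.shape}, "
                         f"expected ({X.shape[0]},)")
    pixels = stack.pixels().astype(np.float64)
    Yn_all = pixels / c[:, None]
    norms = np.linalg.norm(Yn_all, axis=0)
    fg = np.nonzero(norms > config.foreground_norm_threshold)[0]

    pix_out, bc_out, w_out, wl_out = [], [], [], []
    n_nonconv = 0
    alphas = lookup.alpha_for(norms[fg]) if fg.size else np.empty(0)
    for alpha in np.unique(alphas):
        group = fg[alphas == alpha]
        for start in range(0, group.size, config.chunk_size):
            chunk = group[start:start + config.chunk_size]
            Yn = Yn_all[:, chunk]
            W, nbad = _solve_batch(X, Yn, float(alpha), config)
            n_nonconv += nbad
            sup, wref = _elbow_ols_batch(W, X, Yn, config)
            for r in range(2):
                keep = (sup[r] >= 0) & (wref[r] > 0)
                pix_out.append(chunk[keep])
                bc_out.append(sup[r, keep])
                w_out.append(wref[r, keep])
                if config.keep_lasso:
                    wl_out.append(W[sup[r, keep], np.nonzero(keep)[0]])
    if n_nonconv:
        logger.warning("decode_fov: %d pixel(s) did not converge and were "
                       "zeroed", n_nonconv)
    empty = np.empty(0)
    return WeightMaps(
        shape=stack.shape,
        n_barcodes=codebook.n_barcodes,
        pixel_idx=np.concatenate(pix_out) if pix_out else empty,
        barcode_idx=np.concatenate(bc_out) if bc_out else empty,
        weights=np.concatenate(w_out) if w_out else empty,
        lasso_weights=(np.concatenate(wl_out) if config.keep_lasso and wl_out
                       else None),
        metadata={
            "n_foreground": int(fg.size),
            "n_nonconverged": int(n_nonconv),
            "alpha_counts": {float(a): int((alphas == a).sum())
                             for a in np.unique(alphas)},
        },
    )
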