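"""Decoder benchmarking against simulated ground truth.

Matching rule: a ground-truth spot and a decoded spot may pair only if they
carry the same barcode and their centroids are closer than a distance cutoff
(6 pixels by default); pairing is one-to-one, nearest pairs first.  From the
matching follow the three headline metrics:

* sensitivity — fraction of ground-truth spots matched;
* specificity — fraction of decoded spots matched;
* empty rate  — fraction of decoded spots carrying empty barcodes (the
  observable proxy for specificity on real tissue).

Also provides the naive per-pixel matching baseline (nearest barcode by
normalized Euclidean distance, threshold 0.7, connected-component grouping)
and a density sweep that scores decoders on shared simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label, regionprops

from .codebook import Codebook
from .decoder import DecoderConfig, build_alpha_lookup, decode_fov, \
    estimate_channel_coefficients
from .io import FOVStack
from .simulate import simulate_fov, truth_frame
from .spots import call_spots

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkResult", "match_spots", "compute_metrics",
           "naive_decode", "run_density_sweep"]


@dataclass
class BenchmarkResult:
    """Scores of one decoder on one simulated dataset."""

    decoder: str
    density: int
    n_truth: int
    n_decoded: int
    n_matched: int
    sensitivity: float | None
    specificity: float | None
    empty_rate: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def match_spots(
    truth: pd.DataFrame,
    decoded: pd.DataFrame,
    max_dist_px: float = 6.0,
    method: str = "greedy",
) -> np.ndarray:
    """One-to-one matching of truth to decoded spots.

    Candidate pairs share a barcode and lie strictly closer than
    ``max_dist_px``.  ``method="greedy"`` accepts pairs nearest-first;
    ``method="optimal"`` solves the assignment problem per barcode
    (minimum total distance, maximum cardinality).  Returns an (M, 2) array
    of positional row indices ``(truth_i, decoded_j)``.
    """
    if max_dist_px <= 0:
        raise ValueError("max_dist_px must be positive")
    if method not in ("greedy", "optimal"):
        raise ValueError(f"unknown matching method {method!r}")
    pairs = []
    if len(truth) and len(decoded):
        t_codes = truth["barcode"].to_numpy()
        d_codes = decoded["barcode"].to_numpy()
        t_xy = truth[["row", "col"]].to_numpy(dtype=float)
        d_xy = decoded[["row", "col"]].to_numpy(dtype=float)
        for code in np.intersect1d(np.unique(t_codes), np.unique(d_codes)):
            ti = np.nonzero(t_codes == code)[0]
            dj = np.nonzero(d_codes == code)[0]
            dist = cKDTree(t_xy[ti]).sparse_distance_matrix(
                cKDTree(d_xy[dj]), max_distance=max_dist_px, output_type="coo_matrix")
            ok = dist.data < max_dist_px  # strictly closer than the cutoff
            if not ok.any():
                continue
            rows, cols, dd = dist.row[ok], dist.col[ok], dist.data[ok]
            if method == "greedy":
                order = np.argsort(dd, kind="stable")
                used_t, used_d = set(), set()
                for r, c in zip(rows[order], cols[order]):
                    if r not in used_t and c not in used_d:
                        used_t.add(r)
                        used_d.add(c)
                        pairs.append((ti[r], dj[c]))
            else:
                big = 10 * max_dist_px
                cost = np.full((ti.size, dj.size), big)
                cost[rows, cols] = dd
                ri, ci = linear_sum_assignment(cost)
                for r, c in zip(ri, ci):
                    if cost[r, c] < max_dist_px:
                        pairs.append((ti[r], dj[c]))
    return np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)


def compute_metrics(
    truth: pd.DataFrame,
    decoded: pd.DataFrame,
    matches: np.ndarray,
    codebook: Codebook,
    decoder: str = "",
    density: int | None = None,
) -> BenchmarkResult:
    """Sensitivity, specificity and empty rate from a matching.

    Metrics with an empty denominator are reported as None (undefined), not
    as zero.
    """
    n_truth = len(truth)
    n_decoded = len(decoded)
    n_matched = int(matches.shape[0]) if matches.size else 0
    empty_set = {codebook.barcodes[i] for i in codebook.empty_indices}
    if n_decoded:
        n_empty = int(decoded["barcode"].isin(empty_set).sum())
    else:
        n_empty = 0
    return BenchmarkResult(
        decoder=decoder,
        density=density if density is not None else n_truth,
        n_truth=n_truth,
        n_decoded=n_decoded,
        n_matched=n_matched,
        sensitivity=(n_matched / n_truth) if n_truth else None,
        specificity=(n_matched / n_decoded) if n_decoded else None,
        empty_rate=(n_empty / n_decoded) if n_decoded else None,
    )


def naive_decode(
    stack: FOVStack,
    codebook: Codebook,
    distance_threshold: float = 0.7,
    foreground_norm_threshold: float = 0.25,
) -> pd.DataFrame:
    """Baseline decoder: direct per-pixel barcode matching.

    Each foreground pixel vector and each codebook column are L2-normalized;
    the pixel takes the nearest barcode if their Euclidean distance is at
    most the threshold, else it stays unlabeled.  Equidistant barcodes go to
    the smaller index.  Labeled pixels are grouped into spots per barcode by
    8-connected components with intensity-weighted centroids.  No post-hoc
    filtering is applied.
    """
    X = codebook.X
    Xn = X / np.linalg.norm(X, axis=0, keepdims=True)
    pixels = stack.pixels().astype(np.float64)
    norms = np.linalg.norm(pixels, axis=0)
    fg = np.nonzero(norms > foreground_norm_threshold)[0]
    records = []
    if fg.size:
        Yn = pixels[:, fg] / norms[fg]
        cos = Xn.T @ Yn  # (N, P); distance^2 = 2 - 2 cos
        best = np.argmax(cos, axis=0)  # first max -> smallest barcode index
        best_cos = cos[best, np.arange(fg.size)]
        dist = np.sqrt(np.maximum(2.0 - 2.0 * best_cos, 0.0))
        ok = dist <= distance_threshold
        n_ties = int((np.isclose(cos, best_cos[None, :]).sum(axis=0) > 1)[ok].sum())
        if n_ties:
            logger.info("naive_decode: %d pixel(s) equidistant between "
                        "barcodes; smaller index chosen", n_ties)
        h, w = stack.shape
        label_img = np.full(h * w, -1, dtype=np.int64)
        label_img[fg[ok]] = best[ok]
        label_img = label_img.reshape(h, w)
        weight_img = norms.reshape(h, w)
        for b in np.unique(label_img[label_img >= 0]):
            comp = cc_label(label_img == b, connectivity=2)
            for region in regionprops(comp, intensity_image=weight_img):
                wr, wc = region.centroid_weighted
                records.append({
                    "row": wr, "col": wc, "area": int(region.area),
                    "max_weight": float(region.intensity_max),
                    "mean_weight": float(region.intensity_mean),
                    "barcode_index": int(b),
                    "barcode": codebook.barcodes[int(b)],
                    "gene": codebook.genes[int(b)],
                    "is_empty": bool(codebook.is_empty[int(b)]),
                })
    df = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["row", "col", "area", "max_weight", "mean_weight",
                 "barcode_index", "barcode", "gene", "is_empty"])
    df.insert(0, "spot_id", np.arange(len(df)))
    df["empty_prob"] = np.nan
    df["cell_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


def _spd_decode(stack: FOVStack, codebook: Codebook,
                config: DecoderConfig, smoothing_sigma: float,
                min_peak_distance: int) -> pd.DataFrame:
    c = estimate_channel_coefficients(stack, codebook, config)
    lookup = build_alpha_lookup(stack, codebook, c, config)
    maps = decode_fov(stack, codebook, c, lookup, config)
    return call_spots(maps, codebook, smoothing_sigma=smoothing_sigma,
                      min_peak_distance=min_peak_distance)


def run_density_sweep(
    codebook: Codebook,
    densities: list[int],
    decoders: tuple[str, ...] = ("spd", "naive"),
    shape: tuple[int, int] = (1024, 1024),
    rng_seed: int = 0,
    config: DecoderConfig | None = None,
    smoothing_sigma: float = 1.0,
    min_peak_distance: int = 2,
    match_dist_px: float = 6.0,
) -> pd.DataFrame:
    """Simulate, decode and score across rolony densities.

    One stack is simulated per density (sub-seed ``rng_seed + index``) and
    shared by all decoders, so rows are directly comparable.  Returns a tidy
    table with one row per (density, decoder).
    """
    if not densities:
        raise ValueError("densities must be non-empty")
    for name in decoders:
        if name not in ("spd", "naive"):
            raise ValueError(f"unknown decoder {name!r}")
    config = config or DecoderConfig()
    rows = []
    for i, density in enumerate(densities):
        stack, truth, _ = simulate_fov(codebook, density, shape=shape,
                                       rng_seed=rng_seed + i)
        tdf = truth_frame(truth)
        for name in decoders:
            if name == "spd":
                decoded = _spd_decode(stack, codebook, config,
                                      smoothing_sigma, min_peak_distance)
            else:
                decoded = naive_decode(
                    stack, codebook,
                    foreground_norm_threshold=config.foreground_norm_threshold)
            matches = match_spots(tdf, decoded, max_dist_px=match_dist_px)
            res = compute_metrics(tdf, decoded, matches, codebook,
                                  decoder=name, density=density)
            rows.append(res.to_dict())
            logger.info("density %d, %s: sens=%s spec=%s empty=%s",
                        density, name, res.sensitivity, res.specificity,
                        res.empty_rate)
    return pd.DataFrame(rows)
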