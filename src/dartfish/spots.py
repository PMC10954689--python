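"""Spot calling and empty-barcode-driven false-positive filtering.

Decoded weight maps are turned into discrete spots per barcode: Gaussian
smoothing, local-maximum detection, and marker-based watershed segmentation
over the non-zero region.  Each segmented region becomes one spot with four
features (area, weight-weighted centroid, maximum and mean weight).

Specificity is controlled through the codebook's *empty* barcodes: spots
decoded to an empty barcode are known false positives, so a random-forest
classifier trained on (area, max weight, mean weight) with empty/non-empty
labels yields an emptiness probability for every spot, and thresholding that
probability removes the spots that look like decoding noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed
from sklearn.ensemble import RandomForestClassifier

from .codebook import Codebook
from .decoder import WeightMaps

logger = logging.getLogger(__name__)

__all__ = ["call_spots", "EmptyClassifier", "train_empty_classifier",
           "filter_spots", "empty_rate_of"]


def _spots_for_barcode(dense: np.ndarray, smoothing_sigma: float,
                       min_peak_distance: int) -> list[dict]:
    """Segment one barcode's weight map into spots."""
    rows_nz, cols_nz = np.nonzero(dense)
    if rows_nz.size == 0:
        return []
    # work on the bounding box only; pad so smoothing tails stay inside
    pad = int(np.ceil(3 * smoothing_sigma)) + 1
    r0 = max(rows_nz.min() - pad, 0)
    r1 = min(rows_nz.max() + pad + 1, dense.shape[0])
    c0 = max(cols_nz.min() - pad, 0)
    c1 = min(cols_nz.max() + pad + 1, dense.shape[1])
    crop = dense[r0:r1, c0:c1]
    smoothed = ndimage.gaussian_filter(crop, smoothing_sigma)
    # watershed only the true (unsmoothed) support so spot areas stay inside
    # the barcode's non-zero region; peaks are detected on the smoothed map
    mask = crop > 0
    peaks = peak_local_max(smoothed, min_distance=min_peak_distance,
                           labels=mask)
    if peaks.shape[0] == 0:
        return []
    markers = np.zeros(crop.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    labels = watershed(-smoothed, markers=markers, mask=mask)
    out = []
    for region in regionprops(labels, intensity_image=crop):
        if region.intensity_max <= 0:
            continue
        wr, wc = region.centroid_weighted
        if not np.isfinite(wr):  # all-zero region weights
            wr, wc = region.centroid
        out.append({
            "row": wr + r0,
            "col": wc + c0,
            "area": int(region.area),
            "max_weight": float(region.intensity_max),
            "mean_weight": float(region.intensity_mean),
        })
    return out


def call_spots(
    maps: WeightMaps,
    codebook: Codebook,
    smoothing_sigma: float = 1.0,
    min_peak_distance: int = 2,
) -> pd.DataFrame:
    """Convert weight maps into a spot table.

    Returns a DataFrame with one row per spot: ``spot_id, gene, barcode,
    barcode_index, is_empty, row, col, area, max_weight, mean_weight,
    empty_prob, cell_id`` (the last two filled by later stages).
    """
    records = []
    for b in maps.barcodes_present():
        b = int(b)
        for rec in _spots_for_barcode(maps.dense(b), smoothing_sigma,
                                      min_peak_distance):
            rec["barcode_index"] = b
            rec["barcode"] = codebook.barcodes[b]
            rec["gene"] = codebook.genes[b]
            rec["is_empty"] = bool(codebook.is_empty[b])
            records.append(rec)
    df = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["row", "col", "area", "max_weight", "mean_weight",
                 "barcode_index", "barcode", "gene", "is_empty"])
    df.insert(0, "spot_id", np.arange(len(df)))
    df["empty_prob"] = np.nan
    df["cell_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


FEATURES = ["area", "max_weight", "mean_weight"]


def ensure_is_empty(spots: pd.DataFrame,
                    codebook: Codebook | None = None) -> pd.DataFrame:
    """Recover the ``is_empty`` flag on a spot table that lacks it.

    Preferred route: join the barcode column against a codebook.  Fallback:
    the ``Empty_<i>`` gene-naming convention.
    """
    if "is_empty" in spots.columns:
        return spots
    df = spots.copy()
    if codebook is not None:
        lut = dict(zip(codebook.barcodes, codebook.is_empty))
        df["is_empty"] = df["barcode"].map(lut).fillna(False).astype(bool)
    else:
        df["is_empty"] = df["gene"].astype(str).str.startswith("Empty_")
    return df


@dataclass
class EmptyClassifier:
    """Random-forest emptiness scorer over spot features."""

    clf: RandomForestClassifier
    threshold: float = 0.325
    sample_fraction: float = 0.5
    rng_seed: int = 0
    training_meta: dict = None  # type: ignore[assignment]

    def predict_proba(self, spots: pd.DataFrame) -> np.ndarray:
        """Emptiness probability for each spot."""
        proba = self.clf.predict_proba(spots[FEATURES].to_numpy(dtype=float))
        empty_col = list(self.clf.classes_).index(1)
        return proba[:, empty_col]


def train_empty_classifier(
    spots: pd.DataFrame,
    sample_fraction: float = 0.5,
    rng_seed: int = 0,
    n_trees: int = 100,
    threshold: float = 0.325,
) -> EmptyClassifier:
    """Fit the emptiness classifier on a seeded subsample of spots.

    Requires both classes (at least one empty-barcode spot and one gene
    spot); otherwise raises with instructions to skip probability filtering.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    labels = spots["is_empty"].astype(int)
    if labels.nunique() < 2:
        raise ValueError(
            "training data contains a single class; skip the emptiness "
            "filter (threshold-free pass-through) for this dataset")
    rng = np.random.default_rng(rng_seed)
    n = len(spots)
    take = rng.random(n) < sample_fraction
    # guarantee both classes survive the subsample
    if labels[take].nunique() < 2:
        take = np.ones(n, dtype=bool)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=rng_seed)
    clf.fit(spots.loc[take, FEATURES].to_numpy(dtype=float),
            labels[take].to_numpy())
    meta = {"n_train": int(take.sum()), "n_total": n,
            "n_empty_train": int(labels[take].sum()),
            "rng_seed": rng_seed, "n_trees": n_trees}
    return EmptyClassifier(clf=clf, threshold=threshold,
                           sample_fraction=sample_fraction,
                           rng_seed=rng_seed, training_meta=meta)


def empty_rate_of(spots: pd.DataFrame) -> float:
    """Fraction of spots decoded to an empty barcode (0 if no spots)."""
    if len(spots) == 0:
        return 0.0
    return float(spots["is_empty"].mean())


def filter_spots(
    spots: pd.DataFrame,
    classifier: EmptyClassifier | None = None,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Drop spots whose emptiness probability reaches the threshold.

    Returns the kept spots and the empty rate *of the kept set* (the
    fraction still carrying empty barcodes — the observable proxy for
    specificity).  With no classifier, existing ``empty_prob`` values are
    used (all-NaN probabilities keep everything).
    """
    if threshold is None:
        threshold = classifier.threshold if classifier is not None else 0.325
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    df = spots.copy()
    if classifier is not None and len(df):
        df["empty_prob"] = classifier.predict_proba(df)
    probs = df["empty_prob"].fillna(0.0).to_numpy()
    # threshold 1.0 means "no filtering", even for probability exactly 1
    keep_mask = probs < threshold if threshold < 1.0 else np.ones(len(df), bool)
    kept = df[keep_mask].reset_index(drop=True)
    if len(kept) == 0:
        if len(df):
            logger.warning("all %d spots removed at threshold %.3f; "
                           "empty rate reported as 0", len(df), threshold)
        return kept, 0.0
    return kept, empty_rate_of(kept)
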