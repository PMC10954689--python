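"""Assignment of decoded spots to segmented cells.

Cells arrive as a labeled mask (0 = background).  A spot inside a cell is
assigned to it at distance 0; a spot outside is assigned to the cell with
the nearest boundary pixel, provided the distance (in micrometers) stays
within a global threshold or a per-gene override.  Myelin-associated
transcripts, for example, can be excluded from somatic assignment by giving
that gene a 0 um override.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

logger = logging.getLogger(__name__)

__all__ = ["mask_boundaries", "assign_spots_to_cells", "cell_gene_counts"]


def mask_boundaries(mask: np.ndarray) -> dict[int, np.ndarray]:
    """Per-cell boundary pixels of a labeled segmentation mask.

    A boundary pixel of a cell is one of its own pixels whose 8-neighborhood
    touches a different label or the background.  Returns
    ``{label: (n_pixels, 2) array of (row, col)}``; empty mask gives ``{}``.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D label image")
    labels = np.unique(mask)
    labels = labels[labels != 0]
    if labels.size == 0:
        return {}
    boundary = find_boundaries(mask, mode="inner", connectivity=2)
    out = {}
    rr, cc = np.nonzero(boundary)
    lab = mask[rr, cc]
    for lb in labels:
        sel = lab == lb
        out[int(lb)] = np.column_stack([rr[sel], cc[sel]])
    return out


def assign_spots_to_cells(
    spots: pd.DataFrame,
    mask: np.ndarray,
    max_dist_um: float,
    per_gene_max_dist: dict[str, float] | None = None,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Assign each spot to a cell or flag it as unassigned.

    Interior spots take their enclosing label with distance 0 (always
    assigned).  Exterior spots take the label of the nearest boundary pixel
    when the Euclidean distance, converted by ``pixel_size_um``, is at most
    the applicable threshold (a per-gene override wins over the global
    ``max_dist_um``).  Ties between equidistant cells go to the smaller
    label.  Returns a copy with ``cell_id`` (nullable Int64) and
    ``boundary_dist_um`` columns.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    per_gene_max_dist = per_gene_max_dist or {}
    mask = np.asarray(mask)
    df = spots.copy()
    n = len(df)
    cell_id = np.full(n, -1, dtype=np.int64)
    dist_um = np.zeros(n)
    if n:
        rows = np.clip(np.round(df["row"].to_numpy()).astype(int), 0,
                       mask.shape[0] - 1)
        cols = np.clip(np.round(df["col"].to_numpy()).astype(int), 0,
                       mask.shape[1] - 1)
        inside = mask[rows, cols]
        interior = inside > 0
        cell_id[interior] = inside[interior]

        exterior = ~interior
        if exterior.any():
            bnd = mask_boundaries(mask)
            if bnd:
                pts = np.concatenate(list(bnd.values()))
                pt_labels = np.concatenate(
                    [np.full(len(v), lb) for lb, v in bnd.items()])
                tree = cKDTree(pts)
                query = np.column_stack([df["row"].to_numpy()[exterior],
                                         df["col"].to_numpy()[exterior]])
                k = min(2, len(pts))
                d, idx = tree.query(query, k=k)
                d = np.atleast_2d(d.T).T
                idx = np.atleast_2d(idx.T).T
                near_label = pt_labels[idx[:, 0]]
                if k == 2:
                    tie = np.isclose(d[:, 0], d[:, 1])
                    other = pt_labels[idx[:, 1]]
                    n_ties = int((tie & (other != near_label)).sum())
                    if n_ties:
                        logger.info("%d spot(s) equidistant between cells; "
                                    "assigned to the smaller label", n_ties)
                    near_label = np.where(tie, np.minimum(near_label, other),
                                          near_label)
                d_um = d[:, 0] * pixel_size_um
                thresholds = np.array([
                    per_gene_max_dist.get(g, max_dist_um)
                    for g in df["gene"].to_numpy()[exterior]
                ])
                ok = d_um <= thresholds
                ext_ids = np.where(ok, near_label, -1)
                cell_id[exterior] = ext_ids
                dist_um[exterior] = d_um
    df["cell_id"] = pd.array([v if v >= 0 else pd.NA for v in cell_id],
                             dtype="Int64")
    df["boundary_dist_um"] = dist_um
    n_un = int((cell_id < 0).sum())
    if n_un:
        logger.info("%d of %d spots left unassigned", n_un, n)
    return df


def cell_gene_counts(spots: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Genes x cells count matrix from assigned spots (empties excluded).

    Write it with ``scipy.io.mmwrite`` for downstream tools if a sparse MTX
    export is wanted.
    """
    assigned = spots.dropna(subset=["cell_id"])
    assigned = assigned[~assigned["is_empty"]] if "is_empty" in assigned else assigned
    cells = sorted(assigned["cell_id"].astype(int).unique())
    counts = pd.DataFrame(0, index=genes, columns=cells, dtype=int)
    grouped = assigned.groupby(["gene", assigned["cell_id"].astype(int)]).size()
    for (gene, cell), cnt in grouped.items():
        if gene in counts.index:
            counts.loc[gene, cell] = cnt
    return counts
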