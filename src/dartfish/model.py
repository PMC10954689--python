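"""Model-style front end: fit SpD to a field of view, inspect the results.

`SparseDeconvolution` bundles the data (image stack + codebook) with a
decoder configuration; `fit()` runs channel-coefficient estimation, alpha
lookup training and per-pixel decoding, and returns an `SpDResults` object
carrying the weight maps, the fitted nuisance parameters and diagnostics,
with spot calling, filtering and plotting hanging off it.

    >>> model = SparseDeconvolution(stack, codebook)
    >>> res = model.fit()
    >>> spots = res.call_spots()
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codebook import Codebook
from .decoder import (AlphaLookup, DecoderConfig, WeightMaps,
                      build_alpha_lookup, decode_fov,
                      estimate_channel_coefficients)
from .io import FOVStack
from .spots import call_spots, filter_spots, train_empty_classifier

__all__ = ["SparseDeconvolution", "SpDResults"]


class SparseDeconvolution:
    """Sparse deconvolution decoder bound to one field of view.

    Parameters
    ----------
    stack : FOVStack
        Registered multi-round stack, intensities in [0, 1].
    codebook : Codebook
        Barcode design incl. empty entries.
    config : DecoderConfig, optional
        Decoder settings; defaults follow the standard protocol.
    """

    def __init__(self, stack: FOVStack, codebook: Codebook,
                 config: DecoderConfig | None = None) -> None:
        if stack.n_planes != 3 * codebook.n:
            raise ValueError(
                f"stack has {stack.n_planes} planes; codebook with n="
                f"{codebook.n} rounds needs {3 * codebook.n}")
        self.stack = stack
        self.codebook = codebook
        self.config = config or DecoderConfig()

    @classmethod
    def from_files(cls, stack_path, codebook_path,
                   config: DecoderConfig | None = None) -> "SparseDeconvolution":
        from .io import read_codebook, read_stack
        return cls(read_stack(stack_path), read_codebook(codebook_path), config)

    def fit(self, channel_coefficients: np.ndarray | None = None,
            lookup: AlphaLookup | None = None) -> "SpDResults":
        """Run the full decoding chain; pass precomputed pieces to skip them."""
        c = (np.asarray(channel_coefficients, dtype=float)
             if channel_coefficients is not None
             else estimate_channel_coefficients(self.stack, self.codebook,
                                                self.config))
        lk = lookup or build_alpha_lookup(self.stack, self.codebook, c,
                                          self.config)
        maps = decode_fov(self.stack, self.codebook, c, lk, self.config)
        return SpDResults(model=self, channel_coefficients=c, lookup=lk,
                          maps=maps)


class SpDResults:
    """Fitted decoding of one field of view."""

    def __init__(self, model: SparseDeconvolution,
                 channel_coefficients: np.ndarray, lookup: AlphaLookup,
                 maps: WeightMaps) -> None:
        self.model = model
        self.codebook = model.codebook
        self.channel_coefficients = channel_coefficients
        self.lookup = lookup
        self.maps = maps

    # ------------------------------------------------------------- spots
    def call_spots(self, smoothing_sigma: float = 1.0,
                   min_peak_distance: int = 2) -> pd.DataFrame:
        return call_spots(self.maps, self.codebook,
                          smoothing_sigma=smoothing_sigma,
                          min_peak_distance=min_peak_distance)

    def filter_spots(self, spots: pd.DataFrame, threshold: float = 0.325,
                     sample_fraction: float = 0.5, rng_seed: int = 0):
        """Train the emptiness classifier on these spots and filter them."""
        clf = train_empty_classifier(spots, sample_fraction=sample_fraction,
                                     rng_seed=rng_seed, threshold=threshold)
        return filter_spots(spots, clf, threshold)

    # -------------------------------------------------------- diagnostics
    def summary(self) -> str:
        cb = self.codebook
        md = self.maps.metadata
        c = self.channel_coefficients
        lines = [
            "Sparse deconvolution results",
            "=" * 60,
            f"codebook: n={cb.n} rounds, k={cb.k} on-rounds, "
            f"{cb.n_barcodes} barcodes ({int(cb.is_empty.sum())} empty)",
            f"field of view: {self.maps.shape[0]} x {self.maps.shape[1]} px, "
            f"{self.model.stack.n_planes} planes",
            f"foreground pixels: {md.get('n_foreground', 'n/a')}",
            f"non-converged pixels: {md.get('n_nonconverged', 0)}",
            f"decoded weight entries: {self.maps.n_entries}",
            f"channel coefficients: min={c.min():.3f} "
            f"median={np.median(c):.3f} max={c.max():.3f}",
            "alpha usage:",
        ]
        for a, cnt in sorted(md.get("alpha_counts", {}).items()):
            lines.append(f"  alpha={a:5.3f}: {cnt} pixels")
        return "\n".join(lines)

    # ------------------------------------------------------------ plotting
    def plot_weight_map(self, gene: str, ax=None, lasso: bool = False):
        """Show one gene's decoded weight image."""
        import matplotlib.pyplot as plt
        b = self.codebook.genes.index(gene)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.maps.dense(b, lasso=lasso), cmap="magma")
        ax.set_title(f"{gene} ({self.codebook.barcodes[b]})")
        plt.colorbar(im, ax=ax, label="weight")
        return ax

    def plot_coefficients(self, truth: np.ndarray | None = None, ax=None):
        """Bar plot of fitted channel gains (optionally vs known truth)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        j = np.arange(self.channel_coefficients.size)
        ax.bar(j, self.channel_coefficients, label="estimated")
        if truth is not None:
            ax.plot(j, truth, "k_", markersize=12, label="true")
            ax.legend()
        ax.set_xlabel("round-channel plane")
        ax.set_ylabel("gain")
        return ax
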