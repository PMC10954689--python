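"""File formats and configuration for the decoding pipeline.

Conventions used across the package:

* image stacks are multi-page TIFF, one page per round-channel plane in the
  shared flattening order ``3*(round-1) + (channel-1)`` (rounds outermost);
* coordinates are 0-based ``(row, col)``, pixel-centered, stored as floats;
* codebooks are CSV with columns ``gene,barcode,is_empty``; spot tables are
  CSV with the columns of :data:`SPOT_COLUMNS`;
* every CLI run writes a provenance JSON (config + seeds) that suffices to
  re-run the deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .codebook import Codebook

__all__ = [
    "FOVStack",
    "read_stack",
    "write_stack",
    "read_codebook",
    "write_codebook",
    "read_spots",
    "write_spots",
    "read_truth",
    "write_truth",
    "PipelineConfig",
    "load_config",
    "write_provenance",
]

SPOT_COLUMNS = [
    "spot_id", "gene", "barcode", "row", "col", "area",
    "max_weight", "mean_weight", "empty_prob", "cell_id",
]


@dataclass
class FOVStack:
    """A registered multi-round image stack, shape (3n, H, W), values in [0,1].

    Planes follow the shared flattening convention (see module docstring).
    """

    data: np.ndarray
    n: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (planes, H, W), got shape "
                             f"{self.data.shape}")
        if self.data.shape[0] != 3 * self.n:
            raise ValueError(f"stack has {self.data.shape[0]} planes, expected "
                             f"3*n = {3 * self.n}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def pixels(self) -> np.ndarray:
        """View of the stack as a (3n, H*W) pixel matrix."""
        return self.data.reshape(self.n_planes, -1)


def percentile_scale(data: np.ndarray, percentile: float = 99.9) -> np.ndarray:
    """Scale each plane by its upper percentile and clip to [0, 1].

    Convenience for raw integer TIFF input; simulated stacks are already
    in [0, 1].
    """
    out = np.empty_like(data, dtype=np.float32)
    for j, plane in enumerate(data):
        hi = np.percentile(plane, percentile)
        out[j] = np.clip(plane / hi if hi > 0 else plane, 0.0, 1.0)
    return out


def write_stack(stack: FOVStack, path, sidecar: bool = True) -> None:
    """Write a stack as multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     photometric="minisblack")
    if sidecar:
        meta = {"n": stack.n, "shape": list(stack.shape), **stack.metadata}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_stack(path, scale_percentile: float | None = None) -> FOVStack:
    """Read a multi-page TIFF stack; page count must be divisible by 3.

    If the data exceed [0, 1] (raw camera counts), pass ``scale_percentile``
    to apply per-plane percentile scaling.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] % 3 != 0:
        raise ValueError(
            f"{path}: {data.shape[0]} pages, not divisible by 3 channels")
    data = data.astype(np.float32)
    if scale_percentile is not None:
        data = percentile_scale(data, scale_percentile)
    elif data.max() > 1.0 + 1e-6:
        raise ValueError(
            f"{path}: intensities exceed 1; pass scale_percentile to rescale "
            "raw data")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return FOVStack(data=data, n=data.shape[0] // 3, metadata=meta)


def read_codebook(path) -> Codebook:
    path = Path(path)
    if path.suffix == ".json":
        return Codebook.from_json(path)
    return Codebook.from_csv(path)


def write_codebook(codebook: Codebook, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        codebook.to_json(path)
    else:
        codebook.to_csv(path)


def write_spots(spots: pd.DataFrame, path) -> None:
    """Write a spot table CSV with the canonical column set and order."""
    df = spots.copy()
    for col in SPOT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[SPOT_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_spots(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spot table lacks columns {sorted(missing)}")
    return df


def write_truth(truth, path) -> None:
    from .simulate import truth_frame
    df = truth if isinstance(truth, pd.DataFrame) else truth_frame(truth)
    df.to_csv(path, index=False, float_format="%.6g")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"barcode": str})


def write_weight_maps(maps, path) -> None:
    """Write decoded weight maps as a multi-page float32 TIFF.

    One page per barcode, in codebook order (dense; intended for inspection
    and interoperability, not as the primary storage of sparse maps).
    """
    tifffile.imwrite(Path(path), maps.stack().astype(np.float32),
                     photometric="minisblack")


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """Write a genes x cells count table as MatrixMarket MTX plus row/column
    name sidecars (``<prefix>.mtx``, ``<prefix>.genes.txt``,
    ``<prefix>.cells.txt``)."""
    from scipy import io as spio
    from scipy.sparse import csr_matrix
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")),
                 csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text(
        "\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".cells.txt").write_text(
        "\n".join(map(str, counts.columns)) + "\n")


# --------------------------------------------------------------------------
# configuration


def _strict_from_dict(cls, payload: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**payload)


@dataclass
class SpotConfig:
    smoothing_sigma: float = 1.0
    min_peak_distance: int = 2
    empty_threshold: float = 0.325
    classifier_trees: int = 100
    sample_fraction: float = 0.5


@dataclass
class AssignConfig:
    max_dist_um: float = 3.0
    pixel_size_um: float = 1.0
    per_gene_max_dist: dict = field(default_factory=dict)


@dataclass
class SimulateConfig:
    n_spots: int = 5000
    shape: tuple = (1024, 1024)
    intensity_range: tuple = (0.25, 0.7)
    sigma_range: tuple = (2.0, 2.5)
    coeff_range: tuple = (0.75, 1.25)


@dataclass
class PipelineConfig:
    """Umbrella configuration; sections mirror the pipeline stages."""

    decoder: "DecoderConfig" = None  # type: ignore[assignment]
    spots: SpotConfig = field(default_factory=SpotConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        from .decoder import DecoderConfig
        if self.decoder is None:
            self.decoder = DecoderConfig()

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        from .decoder import DecoderConfig
        payload = dict(payload)
        unknown = set(payload) - {"decoder", "spots", "assign", "simulate", "seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        if "decoder" in payload:
            kwargs["decoder"] = _strict_from_dict(DecoderConfig, payload["decoder"])
        if "spots" in payload:
            kwargs["spots"] = _strict_from_dict(SpotConfig, payload["spots"])
        if "assign" in payload:
            kwargs["assign"] = _strict_from_dict(AssignConfig, payload["assign"])
        if "simulate" in payload:
            kwargs["simulate"] = _strict_from_dict(SimulateConfig, payload["simulate"])
        if "seed" in payload:
            kwargs["seed"] = int(payload["seed"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def plain(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in d.items()}
        return {
            "decoder": plain(self.decoder),
            "spots": plain(self.spots),
            "assign": plain(self.assign),
            "simulate": plain(self.simulate),
            "seed": self.seed,
        }


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(payload or {})


def write_provenance(path, config: PipelineConfig, extra: dict | None = None) -> None:
    payload = {"config": config.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
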