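"""Combinatorial codebook design for multi-round, three-channel FISH barcoding.

A *compact barcode* is an ``n``-digit string over ``{0,1,2,3}``: digit
position = decoding round, ``0`` = the round is dark, ``1``/``2``/``3`` = the
fluorescent channel lighting up in that round.  A valid barcode is "on" in
exactly ``k`` rounds, so ``C(n,k) * 3**k`` barcodes exist in total.

The codebook matrix ``X`` (shape ``3n x N``) holds one column per barcode,
with a 1 at flat index ``3*(round-1) + (channel-1)`` for every on-round.
All modules in this package share that flattening convention (rounds
outermost, channels innermost).

Crosstalk between barcodes is controlled through a *conflict graph* whose
nodes are barcodes and whose edges join pairs at Hamming distance exactly 1.
Codebooks are selected as large independent sets of that graph (pairwise
Hamming distance >= 2), seeded by a smaller set at pairwise distance > 2.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

ALPHABET = "0123"
N_CHANNELS = 3

__all__ = [
    "Codebook",
    "enumerate_barcodes",
    "hamming_distance",
    "conflict_graph",
    "find_seed_set",
    "select_mis",
    "augment_barcodes",
    "assign_genes",
    "barcode_to_onehot",
]


def _validate_barcode(code: str, n: int | None = None) -> None:
    if n is not None and len(code) != n:
        raise ValueError(f"barcode {code!r} has length {len(code)}, expected {n}")
    bad = set(code) - set(ALPHABET)
    if bad:
        raise ValueError(f"barcode {code!r} contains invalid digits {sorted(bad)}")


def enumerate_barcodes(n: int, k: int, multicolor_only: bool = False) -> list[str]:
    """Enumerate all compact barcodes with exactly ``k`` on-rounds.

    Parameters
    ----------
    n : int
        Number of decoding rounds (barcode length), ``1 <= n <= 12``.
    k : int
        Number of on-rounds, ``1 <= k <= n``.
    multicolor_only : bool
        If True, exclude barcodes whose on-rounds all use the same channel.
        This leaves ``C(n,k) * (3**k - 3)`` barcodes (for ``k >= 2``); such
        single-color barcodes are the most vulnerable to channel-wide
        artifacts.

    Returns
    -------
    list of str, sorted lexicographically.
    """
    if not (isinstance(n, int) and isinstance(k, int)):
        raise ValueError("n and k must be integers")
    if not (1 <= k <= n):
        raise ValueError(f"require 1 <= k <= n, got n={n}, k={k}")
    if n > 12:
        raise ValueError("n > 12 is not supported (enumeration would be huge)")
    out = []
    for positions in itertools.combinations(range(n), k):
        for channels in itertools.product("123", repeat=k):
            if multicolor_only and len(set(channels)) == 1:
                continue
            digits = ["0"] * n
            for p, ch in zip(positions, channels):
                digits[p] = ch
            out.append("".join(digits))
    out.sort()
    return out


def hamming_distance(a: str, b: str) -> int:
    """Number of rounds in which two equal-length barcodes differ."""
    if len(a) != len(b):
        raise ValueError(f"barcodes must have equal length, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _digit_array(barcodes: list[str]) -> np.ndarray:
    """(m, n) uint8 array of barcode digits."""
    return np.array([[int(c) for c in bc] for bc in barcodes], dtype=np.uint8)


def _distance_matrix(barcodes: list[str]) -> np.ndarray:
    d = _digit_array(barcodes)
    return (d[:, None, :] != d[None, :, :]).sum(axis=2).astype(np.int16)


def conflict_graph(barcodes: list[str]) -> nx.Graph:
    """Graph with barcodes as nodes and edges at Hamming distance exactly 1."""
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes must be distinct")
    g = nx.Graph()
    g.add_nodes_from(barcodes)
    dist = _distance_matrix(barcodes)
    ii, jj = np.nonzero(np.triu(dist == 1, k=1))
    g.add_edges_from((barcodes[i], barcodes[j]) for i, j in zip(ii, jj))
    return g


def find_seed_set(
    barcodes: list[str], n_restarts: int = 1000, rng_seed: int = 0
) -> list[str]:
    """Search for a large barcode subset with pairwise Hamming distance > 2.

    Randomized greedy construction with restarts: each restart scans the
    barcodes in a random order, keeping every barcode compatible with the
    ones already kept.  The largest subset across restarts is returned; it is
    maximal (no remaining barcode can be added).
    """
    if not barcodes:
        raise ValueError("barcode list is empty")
    n = len(barcodes[0])
    for bc in barcodes:
        _validate_barcode(bc, n)
    dist = _distance_matrix(barcodes)
    m = len(barcodes)
    rng = np.random.default_rng(rng_seed)
    best: np.ndarray | None = None
    for _ in range(max(1, n_restarts)):
        order = rng.permutation(m)
        ok = np.ones(m, dtype=bool)
        chosen = []
        for v in order:
            if ok[v]:
                chosen.append(v)
                ok &= dist[v] > 2
        if best is None or len(chosen) > len(best):
            best = np.array(chosen)
    return [barcodes[i] for i in sorted(best)]


def select_mis(
    graph: nx.Graph,
    seed: list[str],
    n_runs: int = 20000,
    rng_seed: int = 0,
) -> list[str]:
    """Best-of-``n_runs`` randomized maximal independent set containing ``seed``.

    Each run seeds the independent set with ``seed`` and then repeatedly picks
    a uniformly random still-eligible node (implemented as a random-permutation
    greedy sweep, which draws from the same distribution).  The largest set
    across runs is returned, sorted.  Every pair in the result is at Hamming
    distance >= 2 since distance-1 pairs are edges of the conflict graph.
    """
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = len(nodes)
    seed_idx = [index[v] for v in seed]
    for a, b in itertools.combinations(seed, 2):
        if graph.has_edge(a, b):
            raise ValueError(f"seed is not independent: edge {a!r} - {b!r}")
    adj = [np.fromiter((index[u] for u in graph.neighbors(v)), dtype=np.int64)
           for v in nodes]
    rng = np.random.default_rng(rng_seed)
    best: list[int] = []
    for _ in range(max(1, n_runs)):
        # state: 0 free, 1 chosen, 2 blocked
        state = np.zeros(m, dtype=np.uint8)
        chosen: list[int] = []
        for v in seed_idx:
            state[v] = 1
            state[adj[v]] = 2
            chosen.append(v)
        for v in rng.permutation(m):
            if state[v] == 0:
                state[v] = 1
                state[adj[v]] = 2
                chosen.append(v)
        if len(chosen) > len(best):
            best = chosen
    return sorted(nodes[i] for i in best)


def augment_barcodes(
    mis: list[str],
    pool: list[str],
    n_extra: int,
    n_trials: int = 20000,
    rng_seed: int = 0,
) -> list[str]:
    """Extend an independent set with ``n_extra`` barcodes from ``pool``.

    Random draws are scored by the number of Hamming-distance-1 edges induced
    among the selected barcodes (extras vs. the set and among extras); the
    draw with the lowest edge count over ``n_trials`` trials wins.
    """
    pool = [b for b in pool if b not in set(mis)]
    if n_extra > len(pool):
        raise ValueError(f"pool has only {len(pool)} barcodes outside the set, "
                         f"need {n_extra}")
    if n_extra == 0:
        return list(mis)
    all_bcs = list(mis) + pool
    dist = _distance_matrix(all_bcs)
    adj = dist == 1
    n_mis = len(mis)
    pool_idx = np.arange(n_mis, len(all_bcs))
    rng = np.random.default_rng(rng_seed)
    best_extra: np.ndarray | None = None
    best_edges = None
    for _ in range(max(1, n_trials)):
        extra = rng.choice(pool_idx, size=n_extra, replace=False)
        sub = adj[np.ix_(extra, extra)].sum() // 2
        cross = adj[np.ix_(extra, np.arange(n_mis))].sum()
        edges = int(sub + cross)
        if best_edges is None or edges < best_edges:
            best_edges = edges
            best_extra = extra
    return list(mis) + sorted(all_bcs[i] for i in best_extra)


def barcode_to_onehot(code: str) -> np.ndarray:
    """One-hot vector of length 3n: flat index 3*(round-1) + (channel-1)."""
    _validate_barcode(code)
    x = np.zeros(3 * len(code))
    for rnd, ch in enumerate(code):
        if ch != "0":
            x[3 * rnd + int(ch) - 1] = 1.0
    return x


@dataclass
class Codebook:
    """Gene-to-barcode mapping plus its one-hot matrix form.

    Attributes
    ----------
    n, k : int
        Rounds and on-rounds of the barcode design.
    genes : list of str
        One name per entry; unassigned (empty) barcodes are named
        ``Empty_<i>``.
    barcodes : list of str
        Compact barcodes, same order as ``genes``.
    is_empty : numpy bool array
        Flags barcodes carried only for false-positive control.
    metadata : dict
        Provenance (RNG seeds, selection parameters).
    """

    n: int
    k: int
    genes: list[str]
    barcodes: list[str]
    is_empty: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.genes) == len(self.barcodes) == len(self.is_empty)):
            raise ValueError("genes, barcodes and is_empty must have equal length")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes in codebook")
        non_empty = [g for g, e in zip(self.genes, self.is_empty) if not e]
        if len(set(non_empty)) != len(non_empty):
            raise ValueError("duplicate gene names in codebook")
        for bc in self.barcodes:
            _validate_barcode(bc, self.n)
            if sum(c != "0" for c in bc) != self.k:
                raise ValueError(f"barcode {bc!r} does not have exactly "
                                 f"k={self.k} on-rounds")
        self.is_empty = np.asarray(self.is_empty, dtype=bool)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    @property
    def X(self) -> np.ndarray:
        """One-hot codebook matrix, shape (3n, N); every column sums to k."""
        return np.stack([barcode_to_onehot(bc) for bc in self.barcodes], axis=1)

    @property
    def empty_indices(self) -> np.ndarray:
        return np.nonzero(self.is_empty)[0]

    def gene_of(self, barcode_index: int) -> str:
        return self.genes[barcode_index]

    # ---------------------------------------------------------------- IO
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "barcode": self.barcodes,
             "is_empty": self.is_empty.astype(int)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "n": self.n, "k": self.k, "metadata": self.metadata,
            "entries": [
                {"gene": g, "barcode": b, "is_empty": bool(e)}
                for g, b, e in zip(self.genes, self.barcodes, self.is_empty)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Codebook":
        with open(path) as fh:
            payload = json.load(fh)
        entries = payload["entries"]
        return cls(
            n=payload["n"], k=payload["k"],
            genes=[e["gene"] for e in entries],
            barcodes=[e["barcode"] for e in entries],
            is_empty=np.array([e["is_empty"] for e in entries], dtype=bool),
            metadata=payload.get("metadata", {}),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "Codebook":
        required = {"gene", "barcode", "is_empty"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"codebook table lacks columns {sorted(missing)}")
        barcodes = [str(b) for b in df["barcode"]]
        for line, bc in enumerate(barcodes, start=2):  # header is line 1
            try:
                _validate_barcode(bc, len(barcodes[0]))
            except ValueError as err:
                raise ValueError(f"line {line}: {err}") from None
        n = len(barcodes[0])
        ks = {sum(c != "0" for c in bc) for bc in barcodes}
        if len(ks) != 1:
            raise ValueError(f"barcodes have inconsistent on-round counts {sorted(ks)}")
        return cls(
            n=n, k=ks.pop(), genes=[str(g) for g in df["gene"]],
            barcodes=barcodes,
            is_empty=df["is_empty"].astype(bool).to_numpy(),
            metadata=metadata or {},
        )

    @classmethod
    def from_csv(cls, path) -> "Codebook":
        # barcodes are digit strings; keep leading zeros
        return cls.from_frame(pd.read_csv(path, dtype={"barcode": str}))


def assign_genes(
    barcodes: list[str],
    genes: list[str],
    n_empty: int,
    rng_seed: int = 0,
) -> Codebook:
    """Randomly assign genes to barcodes and flag ``n_empty`` extra as empty.

    A random one-to-one draw maps each gene to a barcode; ``n_empty`` further
    barcodes are kept unassigned (named ``Empty_<i>``) as decoy entries for
    false-discovery control.  Barcodes beyond ``len(genes) + n_empty`` are
    dropped from the codebook.
    """
    if len(barcodes) < len(genes) + n_empty:
        raise ValueError(
            f"{len(barcodes)} barcodes cannot host {len(genes)} genes "
            f"plus {n_empty} empties")
    if len(set(genes)) != len(genes):
        raise ValueError("gene names must be unique")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(barcodes))
    used = [barcodes[i] for i in order[: len(genes) + n_empty]]
    names = list(genes) + [f"Empty_{i + 1}" for i in range(n_empty)]
    is_empty = np.array([False] * len(genes) + [True] * n_empty)
    n = len(barcodes[0])
    k = sum(c != "0" for c in barcodes[0])
    return Codebook(
        n=n, k=k, genes=names, barcodes=used, is_empty=is_empty,
        metadata={"rng_seed": int(rng_seed), "n_pool": len(barcodes)},
    )
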