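"""Undirected enzyme-enzyme interaction graphs and balanced pair datasets.

The interaction network is the supervision signal for link prediction:
positive examples are known edges, negative examples are sampled uniformly
from the non-edges.  The balanced split reproduces the convention of an
(almost) equal class split, with the odd unit going to the positive class
(a budget of 5149 yields 2575 positives and 2574 negatives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pairwise import GenePair, gene_pair


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected graph of enzymes; edges in canonical pair order, no loops."""

    vertices: tuple[str, ...]
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        verts = tuple(sorted({str(v) for v in self.vertices}))
        edges = set()
        for e in self.edges:
            p = gene_pair(*e)
            if p.first == p.second:
                raise NetworkError(f"self-loop on {p.first!r}")
            edges.add(p)
        vset = set(verts)
        for p in edges:
            if p.first not in vset or p.second not in vset:
                raise NetworkError(f"edge {p} has endpoint outside vertex set")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "edges", frozenset(edges))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   extra_vertices: Iterable[str] = ()) -> "InteractionNetwork":
        pairs = [gene_pair(a, b) for a, b in edges]
        verts = {v for p in pairs for v in p} | {str(v) for v in extra_vertices}
        return cls(tuple(verts), frozenset(pairs))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_non_edges(self) -> int:
        n = self.n_vertices
        return n * (n - 1) // 2 - self.n_edges

    def has_edge(self, a: str, b: str) -> bool:
        return gene_pair(a, b) in self.edges

    def non_edges(self) -> list[GenePair]:
        """All canonical non-adjacent distinct-gene pairs, sorted."""
        out = []
        verts = self.vertices
        for i, a in enumerate(verts):
            for b in verts[i + 1:]:
                p = GenePair(a, b)
                if p not in self.edges:
                    out.append(p)
        return out

    def sorted_edges(self) -> list[GenePair]:
        return sorted(self.edges)


@dataclass(frozen=True)
class PairDataset:
    """Labeled unordered gene pairs: +1 for edges, -1 for sampled non-edges."""

    pairs: tuple[GenePair, ...]
    labels: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if labels.shape != (len(self.pairs),):
            raise NetworkError("labels length does not match pairs")
        if labels.size and not np.isin(labels, (-1, 1)).all():
            raise NetworkError("labels must be +1/-1")
        if len(set(self.pairs)) != len(self.pairs):
            raise NetworkError("duplicate pairs in dataset")
        for p in self.pairs:
            if p.first == p.second:
                raise NetworkError(f"self-pair {p} in dataset")
        object.__setattr__(self, "pairs", tuple(self.pairs))
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == -1).sum())

    def subset(self, idx: Sequence[int]) -> "PairDataset":
        idx = np.asarray(idx, dtype=int)
        return PairDataset(tuple(self.pairs[i] for i in idx),
                           self.labels[idx], self.seed)


def sample_negative_pairs(net: InteractionNetwork, count: int,
                          seed: int) -> list[GenePair]:
    """Uniform sample without replacement from the non-edges of ``net``.

    Deterministic given the seed; raises if fewer non-edges exist than
    requested.
    """
    if count < 0:
        raise NetworkError("negative sample count")
    available = net.non_edges()
    if count > len(available):
        raise NetworkError(
            f"requested {count} negative pairs but only {len(available)} "
            f"non-edges are available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(available), size=count, replace=False)
    return [available[i] for i in sorted(idx)]


def balanced_split(net: InteractionNetwork, total_budget: int,
                   seed: int) -> PairDataset:
    """Balanced labeled dataset of ceil(b/2) positives and floor(b/2) negatives.

    Positives are subsampled uniformly when the network has more edges than
    the positive quota; the odd unit of an odd budget goes to the positives.
    """
    if total_budget < 0:
        raise NetworkError("budget must be nonnegative")
    n_pos = math.ceil(total_budget / 2)
    n_neg = total_budget // 2
    if n_pos > net.n_edges:
        raise NetworkError(
            f"budget requires {n_pos} positives but network has {net.n_edges} edges"
        )
    rng = np.random.default_rng(seed)
    edges = net.sorted_edges()
    if n_pos < len(edges):
        keep = rng.choice(len(edges), size=n_pos, replace=False)
        pos = [edges[i] for i in sorted(keep)]
    else:
        pos = edges
    neg = sample_negative_pairs(net, n_neg, seed + 1)
    pairs = tuple(pos) + tuple(neg)
    labels = np.concatenate([np.ones(len(pos), int), -np.ones(len(neg), int)])
    return PairDataset(pairs, labels, seed)
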