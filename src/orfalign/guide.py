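"""k-mer distances and UPGMA guide trees.

The guide tree orders progressive merges; it is a clustering device, not a
phylogeny.  Pairwise similarity is the fraction of shared nucleotide k-mer
types normalised by the smaller repertoire (k = 6 by default), and the
dichotomic rooted tree comes from UPGMA (arithmetic-average linkage) with
a deterministic tie rule: among equally close cluster pairs, merge the one
with the lexicographically smallest (label, label) pair, a cluster being
labelled by its smallest member id.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import InputError
from .model import NucSeq

__all__ = [
    "DistanceTable",
    "GuideTree",
    "TreeNode",
    "kmer_distance_matrix",
    "build_guide_tree",
]


@dataclass(frozen=True)
class DistanceTable:
    """Symmetric nonnegative distances over sequence ids, zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise InputError("distance table shape does not match ids")
        if not np.allclose(v, v.T) or not np.all(np.isfinite(v)):
            raise InputError("distance table must be symmetric and finite")
        if np.any(np.diag(v) != 0) or np.any(v < 0):
            raise InputError("distances must be nonnegative with zero diagonal")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class TreeNode:
    """A node of the rooted, strictly binary guide tree."""

    name: str | None = None  # leaf label
    children: tuple["TreeNode", "TreeNode"] | None = None
    height: float = 0.0
    label: str = field(default="", repr=False)  # smallest member id

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaf_ids(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return self.children[0].leaf_ids() + self.children[1].leaf_ids()

    def postorder(self) -> Iterator["TreeNode"]:
        if not self.is_leaf:
            yield from self.children[0].postorder()
            yield from self.children[1].postorder()
        yield self

    def newick(self, parent_height: float | None = None) -> str:
        bl = "" if parent_height is None else f":{parent_height - self.height:.6g}"
        if self.is_leaf:
            return f"{self.name}{bl}"
        inner = ",".join(c.newick(self.height) for c in self.children)
        return f"({inner}){bl}"


@dataclass(frozen=True)
class GuideTree:
    """Rooted binary tree over sequence ids driving progressive alignment."""

    root: TreeNode

    def leaf_ids(self) -> list[str]:
        return self.root.leaf_ids()

    def clades(self) -> list[TreeNode]:
        """All non-root nodes in postorder (the 2-cut split candidates)."""
        return [n for n in self.root.postorder() if n is not self.root]

    def newick(self) -> str:
        return self.root.newick() + ";"

    def topology(self) -> frozenset:
        """Unordered clade sets; equal topologies compare equal."""
        return frozenset(
            frozenset(n.leaf_ids()) for n in self.root.postorder()
        )


def _kmer_set(residues: str, k: int) -> set[str]:
    return {residues[i : i + k] for i in range(len(residues) - k + 1)}


def kmer_distance_matrix(seqs: Sequence[NucSeq], k: int = 6) -> DistanceTable:
    """1 - (shared k-mer types / smaller repertoire), clamped to [0, 1].

    A sequence shorter than ``k`` has an empty repertoire; its pairs get
    distance 1 with a warning.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    ids = tuple(s.id for s in seqs)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sequence ids")
    sets = [_kmer_set(s.residues, k) for s in seqs]
    for s, ks in zip(seqs, sets):
        if not ks:
            warnings.warn(
                f"sequence {s.id!r} is shorter than k={k}; distances set to 1"
            )
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        denom = min(len(sets[i]), len(sets[j]))
        sim = len(sets[i] & sets[j]) / denom if denom else 0.0
        d[i, j] = d[j, i] = min(1.0, max(0.0, 1.0 - sim))
    return DistanceTable(ids, d)


def build_guide_tree(d: DistanceTable) -> GuideTree:
    """Standard UPGMA agglomeration with the deterministic tie rule."""
    if len(d.ids) < 2:
        raise InputError("need at least 2 sequences to build a guide tree")
    nodes: dict[str, TreeNode] = {
        i: TreeNode(name=i, label=i) for i in d.ids
    }
    sizes = {i: 1 for i in d.ids}
    dist = {
        frozenset((a, b)): d.values[i, j]
        for i, a in enumerate(d.ids)
        for j, b in enumerate(d.ids)
        if i < j
    }
    while len(nodes) > 1:
        # smallest distance; ties -> lexicographically smallest label pair
        best = min(
            dist.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0])))
        )
        pair, dmin = best
        a, b = sorted(pair)
        na, nb = nodes.pop(a), nodes.pop(b)
        sa, sb = sizes.pop(a), sizes.pop(b)
        merged = TreeNode(
            children=(na, nb) if na.label <= nb.label else (nb, na),
            height=dmin / 2.0,
            label=min(na.label, nb.label),
        )
        del dist[pair]
        for other in list(nodes):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged.label, other))] = (sa * da + sb * db) / (sa + sb)
        nodes[merged.label] = merged
        sizes[merged.label] = sa + sb
    return GuideTree(root=next(iter(nodes.values())))
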