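"""Timed local genealogies and lineage counting.

A :class:`LocalTree` is the rooted, binary, timed gene tree of the sample
at one non-recombining genomic interval.  Node times are in generations
before present; sampled leaves sit at time 0 by default.  The two core
queries are :func:`count_lineages` — how many branches cross a given time
— and :func:`classify_lineages`, which splits that count into lineages
carrying the derived vs. the ancestral allele at a focal site, under the
infinite-sites assumption that the site's single mutation occurred on the
unique branch whose descendant leaves are exactly the derived carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "LocalTree",
    "SiteLabel",
    "IncompatibleSiteError",
    "MonomorphicSiteError",
    "count_lineages",
    "map_mutation_branch",
    "classify_lineages",
]


class IncompatibleSiteError(ValueError):
    """No branch of the tree subtends exactly the carrier set."""


class MonomorphicSiteError(ValueError):
    """Carrier set is empty or comprises every leaf."""


@dataclass(frozen=True)
class SiteLabel:
    """A polymorphic, biallelic site: position and derived-allele carriers.

    ``carriers`` holds leaf ids (0-based sample indices) bearing the
    derived allele.
    """

    position: float
    carriers: frozenset

    def __post_init__(self):
        object.__setattr__(self, "carriers", frozenset(self.carriers))

    def daf(self, n: int) -> float:
        return len(self.carriers) / n


class LocalTree:
    """Rooted binary timed tree over ``n`` labeled leaves.

    Nodes are integers ``0 .. m-1``; leaves are ``0 .. n-1``.  ``parent``
    maps each node to its parent (root maps to -1); ``time`` gives node
    times in generations, strictly increasing from child to parent.

    Parameters
    ----------
    parent : sequence of int
    time : sequence of float
    interval : (start, end)
        Genomic span in bp, half-open, ``start < end``.
    n_leaves : int, optional
        Number of leaves; inferred as the number of childless nodes.
    branch_map : dict, optional
        Explicit position -> node mapping for known mutations; takes
        precedence over carrier-set matching.
    """

    __slots__ = ("parent", "time", "interval", "n_leaves", "root", "branch_map",
                 "_leafsets", "_children")

    def __init__(
        self,
        parent: Sequence[int],
        time: Sequence[float],
        interval: tuple = (0.0, 1.0),
        n_leaves: Optional[int] = None,
        branch_map: Optional[dict] = None,
        validate: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.time = np.asarray(time, dtype=float)
        if self.parent.shape != self.time.shape:
            raise ValueError("parent and time must have equal length")
        m = len(self.parent)
        has_child = np.zeros(m, dtype=bool)
        valid = self.parent >= 0
        has_child[self.parent[valid]] = True
        if n_leaves is None:
            n_leaves = int(np.sum(~has_child))
        self.n_leaves = n_leaves
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if interval[0] >= interval[1]:
            raise ValueError("interval start must be < end")
        self.interval = (float(interval[0]), float(interval[1]))
        self.branch_map = dict(branch_map) if branch_map else {}
        self._leafsets = None
        self._children = None
        if validate:
            self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self):
        m = len(self.parent)
        n = self.n_leaves
        if m != 2 * n - 1:
            raise ValueError(
                f"binary tree over {n} leaves needs {2 * n - 1} nodes, got {m}"
            )
        valid = self.parent >= 0
        if np.any(self.time[valid] >= self.time[self.parent[valid]]):
            raise ValueError("every parent must be strictly older than its children")
        counts = np.bincount(self.parent[valid], minlength=m)
        internal = counts > 0
        if np.any(counts[internal] != 2):
            raise ValueError("internal nodes must have exactly two children")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root_time(self) -> float:
        return float(self.time[self.root])

    def children(self):
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for v, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(v)
            self._children = ch
        return self._children

    def leafsets(self) -> np.ndarray:
        """Per-node descendant-leaf sets as Python-int bitsets."""
        if self._leafsets is None:
            order = np.argsort(self.time, kind="stable")
            sets = [0] * self.n_nodes
            for v in range(self.n_leaves):
                sets[v] = 1 << v
            for v in order:  # children precede parents in time order
                p = self.parent[v]
                if p >= 0:
                    sets[p] |= sets[v]
            self._leafsets = sets
        return self._leafsets

    def descendant_leaves(self, node: int) -> frozenset:
        bits = self.leafsets()[node]
        return frozenset(i for i in range(self.n_leaves) if (bits >> i) & 1)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_tskit(cls, tree, interval=None) -> "LocalTree":
        """Build from a ``tskit.Tree`` (samples must be 0..n-1, binary)."""
        ts_nodes = [u for u in tree.nodes()]
        n = len([u for u in ts_nodes if tree.is_leaf(u)])
        remap = {}
        nxt = n
        for u in ts_nodes:
            if tree.is_leaf(u):
                if u >= n:
                    raise ValueError("tskit samples must be labeled 0..n-1")
                remap[u] = u
            else:
                remap[u] = nxt
                nxt += 1
        m = len(ts_nodes)
        parent = np.full(m, -1, dtype=np.int64)
        time = np.zeros(m)
        for u in ts_nodes:
            v = remap[u]
            time[v] = tree.time(u)
            pu = tree.parent(u)
            parent[v] = remap[pu] if pu != -1 else -1
        if interval is None:
            interval = (tree.interval.left, tree.interval.right)
        return cls(parent, time, interval=interval, n_leaves=n)

    def relabel(self, perm: Sequence[int]) -> "LocalTree":
        """Return a copy with leaf ``i`` renamed ``perm[i]`` (tests use this)."""
        perm = list(perm)
        m = self.n_nodes
        n = self.n_leaves
        mapping = {i: perm[i] for i in range(n)}
        mapping.update({v: v for v in range(n, m)})
        parent = np.full(m, -1, dtype=np.int64)
        time = np.zeros(m)
        for v in range(m):
            nv = mapping[v]
            time[nv] = self.time[v]
            p = self.parent[v]
            parent[nv] = mapping[p] if p >= 0 else -1
        return LocalTree(parent, time, interval=self.interval, n_leaves=n)


def count_lineages(tree: LocalTree, t: float) -> int:
    """Number of branches active at time ``t``.

    A branch from node ``v`` to its parent is active iff
    ``time[v] <= t < time[parent]`` (half-open: each coalescence reduces
    the count exactly once).  For ``t >= root_time`` the count clamps to 1
    — the persisting ancestral lineage.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    mask = tree.parent >= 0
    child_t = tree.time[mask]
    parent_t = tree.time[tree.parent[mask]]
    c = int(np.sum((child_t <= t) & (t < parent_t)))
    return max(c, 1)


def map_mutation_branch(
    tree: LocalTree, site: SiteLabel, allow_jaccard_fallback: bool = False
) -> int:
    """Node whose branch (to its parent) carries the site's mutation.

    The mutation branch is the unique branch whose subtended leaf set
    equals ``site.carriers``.  An explicit ``tree.branch_map`` entry for
    the position takes precedence.  With ``allow_jaccard_fallback`` the
    branch maximizing Jaccard similarity of leaf sets is returned when no
    exact match exists (useful for inferred trees that conflict with the
    observed carriers); ties break toward the smaller node id.
    """
    n = tree.n_leaves
    carriers = site.carriers
    if len(carriers) == 0 or len(carriers) >= n:
        raise MonomorphicSiteError(
            f"site at {site.position} is monomorphic in the sample "
            f"({len(carriers)}/{n} carriers)"
        )
    if site.position in tree.branch_map:
        return tree.branch_map[site.position]
    target = 0
    for i in carriers:
        target |= 1 << i
    sets = tree.leafsets()
    for v in range(tree.n_nodes):
        if v != tree.root and sets[v] == target:
            return v
    if allow_jaccard_fallback:
        best, best_j = None, -1.0
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            inter = bin(sets[v] & target).count("1")
            union = bin(sets[v] | target).count("1")
            j = inter / union
            if j > best_j:
                best, best_j = v, j
        return best
    raise IncompatibleSiteError(
        f"no branch subtends exactly the {len(carriers)} carriers of the "
        f"site at position {site.position}"
    )


def classify_lineages(
    tree: LocalTree,
    site: SiteLabel,
    t: float,
    mutation_node: Optional[int] = None,
    allow_jaccard_fallback: bool = False,
) -> tuple:
    """(ancestral, derived) lineage counts at time ``t``.

    An active branch is *derived* iff it is the mutation branch or a
    descendant of it; ancestral + derived = :func:`count_lineages`.
    Above the mutation branch's parent node the derived count is 0.
    """
    if mutation_node is None:
        mutation_node = map_mutation_branch(
            tree, site, allow_jaccard_fallback=allow_jaccard_fallback
        )
    total = count_lineages(tree, t)
    # descendants of the mutation node (inclusive)
    in_sub = np.zeros(tree.n_nodes, dtype=bool)
    in_sub[mutation_node] = True
    order = np.argsort(-tree.time, kind="stable")
    for v in order:  # parents before children
        p = tree.parent[v]
        if p >= 0 and in_sub[p]:
            in_sub[v] = True
    mask = (tree.parent >= 0) & in_sub
    child_t = tree.time[mask]
    parent_t = tree.time[tree.parent[mask]]
    der = int(np.sum((child_t <= t) & (t < parent_t)))
    return total - der, der
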