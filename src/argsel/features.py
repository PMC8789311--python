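"""Lineage-count feature encoding of a focal site and its flanking trees.

The feature for one locus is a ``K x (2 + 2*F)`` channel matrix on a
shared :class:`~argsel.grid.TimeGrid`: the focal tree contributes
ancestral- and derived-lineage counts split at the focal mutation, and
the ``F`` nearest distinct trees on each side contribute total lineage
counts, capturing linkage disequilibrium around the site.  With the
defaults (K = 100, F = 2) the flattened vector has 600 entries.

Channel order (fixed): left-2 total, left-1 total, focal ancestral,
focal derived, right-1 total, right-2 total — generalized to
``left-F .. left-1, anc, der, right-1 .. right-F``.  Time runs from the
present (index 0) into the past (index K-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from argsel.grid import TimeGrid
from argsel.trees import LocalTree, SiteLabel, map_mutation_branch

__all__ = [
    "FocalEncoding",
    "FlankEncoding",
    "FeatureVector",
    "encode_focal",
    "encode_flank",
    "extract_features",
    "channel_names",
]


@dataclass(frozen=True)
class FocalEncoding:
    """Ancestral/derived lineage counts of the focal tree on the grid."""

    anc_counts: np.ndarray
    der_counts: np.ndarray


@dataclass(frozen=True)
class FlankEncoding:
    """Total lineage counts of one flanking tree on the grid."""

    total_counts: np.ndarray


@dataclass(frozen=True)
class FeatureVector:
    """K x C channel matrix plus its provenance flags.

    ``matrix[j, c]`` is the (optionally n-normalized) lineage count of
    channel ``c`` at grid time ``j``.  ``values`` flattens time-major, so
    ``values.reshape(K, C)`` recovers the matrix.
    """

    matrix: np.ndarray
    channel_order: tuple
    normalized: bool

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.matrix.reshape(-1)

    def __len__(self) -> int:
        return self.matrix.size


def channel_names(n_flank_per_side: int = 2) -> tuple:
    left = tuple(f"left-{i}_total" for i in range(n_flank_per_side, 0, -1))
    right = tuple(f"right-{i}_total" for i in range(1, n_flank_per_side + 1))
    return left + ("focal_ancestral", "focal_derived") + right


def _active_matrix(tree: LocalTree, points: np.ndarray, node_mask=None):
    """Counts of active branches at each grid point (vectorized)."""
    mask = tree.parent >= 0
    if node_mask is not None:
        mask &= node_mask
    child_t = tree.time[mask]
    parent_t = tree.time[tree.parent[mask]]
    t = points[:, None]
    return np.sum((child_t[None, :] <= t) & (t < parent_t[None, :]), axis=1)


def encode_focal(
    tree: LocalTree,
    site: SiteLabel,
    grid: TimeGrid,
    allow_jaccard_fallback: bool = False,
) -> FocalEncoding:
    """Ancestral/derived lineage-count curves of the focal tree.

    Element ``j`` equals ``classify_lineages(tree, site, grid.points[j])``;
    totals clamp to 1 above the root.
    """
    mut = map_mutation_branch(tree, site, allow_jaccard_fallback=allow_jaccard_fallback)
    in_sub = np.zeros(tree.n_nodes, dtype=bool)
    in_sub[mut] = True
    for v in np.argsort(-tree.time, kind="stable"):
        p = tree.parent[v]
        if p >= 0 and in_sub[p]:
            in_sub[v] = True
    total = np.maximum(_active_matrix(tree, grid.points), 1)
    der = _active_matrix(tree, grid.points, node_mask=in_sub)
    return FocalEncoding(anc_counts=total - der, der_counts=der)


def encode_flank(tree: LocalTree, grid: TimeGrid) -> FlankEncoding:
    """Total lineage-count curve of a flanking tree (root-clamped to 1)."""
    return FlankEncoding(
        total_counts=np.maximum(_active_matrix(tree, grid.points), 1)
    )


def extract_features(
    trees: Sequence[LocalTree],
    focal_tree_index: int,
    site: SiteLabel,
    grid: TimeGrid,
    n_flank_per_side: int = 2,
    normalize: bool = True,
    allow_jaccard_fallback: bool = False,
) -> FeatureVector:
    """Build the full feature matrix for one focal site.

    ``trees`` must be ordered by genomic interval; the focal tree's
    interval must contain ``site.position``.  Missing flanks at contig
    edges are filled by repeating the outermost available tree.
    """
    focal = trees[focal_tree_index]
    lo, hi = focal.interval
    if not (lo <= site.position < hi):
        raise ValueError(
            f"focal site {site.position} outside focal tree interval [{lo}, {hi})"
        )
    K = grid.K
    cols = []
    for off in range(n_flank_per_side, 0, -1):
        idx = max(focal_tree_index - off, 0)
        cols.append(encode_flank(trees[idx], grid).total_counts)
    fe = encode_focal(focal, site, grid, allow_jaccard_fallback=allow_jaccard_fallback)
    cols.append(fe.anc_counts)
    cols.append(fe.der_counts)
    for off in range(1, n_flank_per_side + 1):
        idx = min(focal_tree_index + off, len(trees) - 1)
        cols.append(encode_flank(trees[idx], grid).total_counts)
    matrix = np.stack(cols, axis=1).astype(float)
    if normalize:
        matrix = matrix / focal.n_leaves
    return FeatureVector(
        matrix=matrix,
        channel_order=channel_names(n_flank_per_side),
        normalized=normalize,
    )
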