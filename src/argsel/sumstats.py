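"""Haplotype summary statistics and genotype encodings (baseline methods).

These are the classical sweep-scan statistics the LSTM is benchmarked
against: diversity measures (segregating sites, pi, Watterson's and
Fay-Wu's theta, Tajima's D, distinct haplotype count), haplotype
homozygosities (H1, H12, H2/H1), linkage statistics (ZnS, the omega
maximum), the integrated haplotype score (iHS), windowed feature tables,
and the sorted genotype-image encoding used by alignment-based CNNs.

Conventions: haplotype blocks are binary n x S matrices, 0 = ancestral,
1 = derived, with bp positions ascending.  Statistics that are undefined
on an input (e.g. Tajima's D with no segregating site) return NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeBlock",
    "basic_stats",
    "garud_h",
    "zns",
    "omega_max",
    "ehh_integral",
    "ihs_unstandardized",
    "ihs_region",
    "window_features",
    "haplotype_sort",
    "genotype_image",
    "STAT_ORDER",
]

STAT_ORDER = (
    "ss", "pi", "theta_w", "theta_h", "tajimas_d", "n_haplotypes",
    "h1", "h12", "h2_h1", "zns", "omega_max",
)


@dataclass(frozen=True)
class HaplotypeBlock:
    """Binary haplotypes over a genomic span."""

    matrix: np.ndarray  # n x S, int
    positions: np.ndarray  # S, ascending bp
    span: Tuple[float, float] = None

    def __post_init__(self):
        m = np.asarray(self.matrix)
        p = np.asarray(self.positions, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(p):
            raise ValueError("matrix must be n x S with S == len(positions)")
        if np.any(np.diff(p) < 0):
            raise ValueError("positions must be ascending")
        object.__setattr__(self, "matrix", m.astype(np.int8))
        object.__setattr__(self, "positions", p)
        if self.span is None:
            lo = p[0] if len(p) else 0.0
            hi = p[-1] + 1 if len(p) else 1.0
            object.__setattr__(self, "span", (float(lo), float(hi)))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]

    def restrict(self, lo: float, hi: float) -> "HaplotypeBlock":
        keep = (self.positions >= lo) & (self.positions < hi)
        return HaplotypeBlock(self.matrix[:, keep], self.positions[keep], (lo, hi))


def _segregating(matrix) -> np.ndarray:
    d = matrix.sum(axis=0)
    return (d > 0) & (d < matrix.shape[0])


def basic_stats(block: HaplotypeBlock) -> dict:
    """ss, pi, theta_w, theta_h, Tajima's D and distinct-haplotype count.

    pi is the mean number of pairwise differences across the block,
    theta_w = S / a1, theta_h = sum_i 2 d_i^2 / (n (n-1)) (Fay-Wu,
    derived-count weighted), and Tajima's D uses its standard variance
    normalization.  ``tajimas_d`` is NaN when S = 0.
    """
    m = block.matrix
    n = block.n
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    seg = _segregating(m)
    d = m.sum(axis=0)[seg].astype(float)
    S = int(seg.sum())
    denom = n * (n - 1)
    pi = float(np.sum(2.0 * d * (n - d)) / denom)
    theta_h = float(np.sum(2.0 * d * d) / denom)
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    theta_w = S / a1
    if S == 0:
        D = np.nan
    else:
        a2 = np.sum(1.0 / i**2)
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        var = e1 * S + e2 * S * (S - 1)
        D = float((pi - theta_w) / np.sqrt(var)) if var > 0 else np.nan
    uniq = np.unique(m, axis=0)
    return {
        "ss": S,
        "pi": pi,
        "theta_w": float(theta_w),
        "theta_h": theta_h,
        "tajimas_d": D,
        "n_haplotypes": int(len(uniq)),
    }


def _hap_freqs(matrix) -> np.ndarray:
    _, counts = np.unique(matrix, axis=0, return_counts=True)
    p = np.sort(counts / matrix.shape[0])[::-1]
    return p


def garud_h(block: HaplotypeBlock) -> dict:
    """Haplotype-homozygosity statistics H1, H12 and H2/H1."""
    p = _hap_freqs(block.matrix)
    h1 = float(np.sum(p**2))
    p1 = p[0]
    p2 = p[1] if len(p) > 1 else 0.0
    h12 = float((p1 + p2) ** 2 + np.sum(p[2:] ** 2))
    h2_h1 = float((h1 - p1**2) / h1)
    return {"h1": h1, "h12": h12, "h2_h1": h2_h1}


def _r2_matrix(m) -> np.ndarray:
    """Pairwise r^2 between columns of a binary matrix."""
    p = m.mean(axis=0)
    pq = p * (1 - p)
    cov = (m.T @ m) / m.shape[0] - np.outer(p, p)
    denom = np.sqrt(np.outer(pq, pq))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (cov / denom) ** 2
    return r2


def zns(block: HaplotypeBlock) -> float:
    """Mean pairwise r^2 across segregating sites (NaN if < 2 sites)."""
    m = block.matrix[:, _segregating(block.matrix)]
    S = m.shape[1]
    if S < 2:
        return np.nan
    r2 = _r2_matrix(m)
    iu = np.triu_indices(S, k=1)
    return float(np.mean(r2[iu]))


def omega_max(block: HaplotypeBlock) -> float:
    """Maximum of the omega LD-ratio statistic over all split points.

    For a split after the l-th segregating site, omega is the average
    within-flank r^2 divided by the average between-flank r^2; a sweep
    between the flanks elevates within-flank LD relative to cross-flank
    LD.  All splits with at least one site per side are evaluated;
    NaN if fewer than 3 segregating sites.
    """
    m = block.matrix[:, _segregating(block.matrix)]
    S = m.shape[1]
    if S < 3:
        return np.nan
    r2 = _r2_matrix(m)
    iu = np.triu_indices(S, k=1)
    best = -np.inf
    for l in range(1, S):
        left = r2[:l, :l][np.triu_indices(l, k=1)]
        right = r2[l:, l:][np.triu_indices(S - l, k=1)]
        between = r2[:l, l:]
        n_within = len(left) + len(right)
        if n_within == 0:
            continue
        num = (left.sum() + right.sum()) / n_within
        den = between.mean()
        w = np.inf if den == 0 else num / den
        best = max(best, w)
    return float(best)


def ehh_integral(
    matrix: np.ndarray,
    positions: np.ndarray,
    core: int,
    group: np.ndarray,
    truncate: float = 0.05,
) -> float:
    """Integrated EHH for one haplotype group around a core site.

    EHH at marker ``j`` is the probability that two random haplotypes of
    the group are identical over all markers between the core and ``j``
    (inclusive).  The integral is trapezoidal over bp distance, extended
    outward on each side until EHH drops below ``truncate`` or the block
    edge is reached.
    """
    g = np.flatnonzero(group)
    ng = len(g)
    if ng < 2:
        return np.nan
    pairs = ng * (ng - 1) / 2.0
    total = 0.0
    for step in (1, -1):
        idx = core
        ehh_prev = 1.0
        # group haplotypes as tuples extended marker by marker
        keys = np.zeros(ng, dtype=np.int64)
        key_map = {}
        while True:
            nxt = idx + step
            if nxt < 0 or nxt >= matrix.shape[1]:
                break
            col = matrix[g, nxt]
            new_keys = []
            key_map.clear()
            for k, a in zip(keys, col):
                kk = key_map.setdefault((k, a), len(key_map))
                new_keys.append(kk)
            keys = np.asarray(new_keys)
            _, counts = np.unique(keys, return_counts=True)
            ehh = float(np.sum(counts * (counts - 1) / 2.0) / pairs)
            dist = abs(positions[nxt] - positions[idx])
            total += 0.5 * (ehh_prev + ehh) * dist
            ehh_prev = ehh
            idx = nxt
            if ehh < truncate:
                break
    return total


def ihs_unstandardized(
    block: HaplotypeBlock, core: int, truncate: float = 0.05
) -> float:
    """ln(iHH_ancestral / iHH_derived) at one core site."""
    der = block.matrix[:, core] == 1
    ihh_d = ehh_integral(block.matrix, block.positions, core, der, truncate)
    ihh_a = ehh_integral(block.matrix, block.positions, core, ~der, truncate)
    if not np.isfinite(ihh_d) or not np.isfinite(ihh_a) or ihh_d <= 0 or ihh_a <= 0:
        return np.nan
    return float(np.log(ihh_a / ihh_d))


def ihs_region(
    block: HaplotypeBlock,
    maf_min: float = 0.05,
    n_bins: int = 50,
    truncate: float = 0.05,
    return_sites: bool = False,
):
    """Mean standardized iHS over all scored sites of a region.

    Unstandardized iHS is computed at every site with minor allele
    frequency above ``maf_min``, standardized to zero mean and unit
    variance within ``n_bins`` equal-width derived-frequency bins (bins
    with fewer than 2 scored sites fall back to the global moments), and
    averaged.  NaN when no site can be scored.
    """
    daf = block.matrix.mean(axis=0)
    maf = np.minimum(daf, 1 - daf)
    cores = np.flatnonzero(maf > maf_min)
    if len(cores) == 0:
        return (np.nan, {}) if return_sites else np.nan
    raw = np.array([ihs_unstandardized(block, c, truncate) for c in cores])
    ok = np.isfinite(raw)
    if not np.any(ok):
        return (np.nan, {}) if return_sites else np.nan
    scores = np.full(len(cores), np.nan)
    g_mean = np.mean(raw[ok])
    g_std = np.std(raw[ok])
    bins = np.clip((daf[cores] * n_bins).astype(int), 0, n_bins - 1)
    for b in np.unique(bins):
        sel = (bins == b) & ok
        if sel.sum() >= 2 and np.std(raw[sel]) > 0:
            scores[sel] = (raw[sel] - np.mean(raw[sel])) / np.std(raw[sel])
        elif g_std > 0:
            scores[sel] = (raw[sel] - g_mean) / g_std
        else:
            scores[sel] = 0.0
    region = float(np.nanmean(scores))
    if return_sites:
        return region, dict(zip(cores.tolist(), scores.tolist()))
    return region


def window_features(block: HaplotypeBlock, n_windows: int = 5) -> pd.DataFrame:
    """The 11-statistic x 5-window normalized feature table.

    Each statistic is computed per window (equal bp fifths of the span),
    then normalized across windows by dividing by the row sum.  Rows
    whose (nan-aware) sum is zero, and windows where a statistic is
    undefined, are NaN.
    """
    lo, hi = block.span
    edges = np.linspace(lo, hi, n_windows + 1)
    cols = {}
    for w in range(n_windows):
        sub = block.restrict(edges[w], edges[w + 1])
        row = {}
        if sub.n >= 2 and sub.S >= 0:
            row.update(basic_stats(sub))
            row.update(garud_h(sub))
            row["zns"] = zns(sub)
            row["omega_max"] = omega_max(sub)
        else:
            row = {k: np.nan for k in STAT_ORDER}
        cols[f"window_{w}"] = [row[k] for k in STAT_ORDER]
    df = pd.DataFrame(cols, index=list(STAT_ORDER))
    sums = df.sum(axis=1, skipna=True)
    out = df.div(sums, axis=0)
    out[sums == 0] = np.nan
    inf_rows = ~np.isfinite(sums)
    out[inf_rows] = np.nan
    return out


def haplotype_sort(matrix: np.ndarray) -> np.ndarray:
    """Sort haplotype rows by Manhattan-distance centrality.

    The row with the smallest total Manhattan distance to all others
    comes first; the rest follow in increasing distance to that row.
    Ties preserve the original row order.
    """
    m = np.asarray(matrix)
    diff = np.abs(m[:, None, :].astype(int) - m[None, :, :].astype(int)).sum(axis=2)
    totals = diff.sum(axis=1)
    first = int(np.argmin(totals))  # argmin is stable: first minimal index
    rest = [i for i in range(m.shape[0]) if i != first]
    rest.sort(key=lambda i: (diff[first, i], i))
    return m[[first] + rest]


def genotype_image(
    block: HaplotypeBlock, focal_index: int, half_width: int = 180,
    sort: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fixed-width genotype matrix centered on a focal variant.

    Haplotypes are first Manhattan-sorted (``sort=True``), then up to
    ``half_width`` variants left of the focal variant and
    ``half_width - 1`` to its right are retained, zero-padding deficits
    outward, so the focal variant sits at column ``half_width`` of an
    ``n x 2*half_width`` matrix.  Returns the matrix and the matching
    position vector (padded entries 0).
    """
    m = haplotype_sort(block.matrix) if sort else np.asarray(block.matrix)
    n, S = m.shape
    if not (0 <= focal_index < S):
        raise IndexError("focal_index out of range")
    width = 2 * half_width
    img = np.zeros((n, width), dtype=m.dtype)
    pos = np.zeros(width)
    lo = max(0, focal_index - half_width)
    n_left = focal_index - lo
    hi = min(S, focal_index + half_width)  # right side: focal + up to hw-1
    img[:, half_width - n_left : half_width + (hi - focal_index)] = m[:, lo:hi]
    pos[half_width - n_left : half_width + (hi - focal_index)] = block.positions[lo:hi]
    return img, pos
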