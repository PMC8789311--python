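"""Structured coalescent with recombination, conditioned on a sweep.

Backward-in-time ancestry sampler for a single locus of length ``L``.
Lineages carry ancestral genomic material (lists of half-open segments,
each mapped to a tskit node) and, while the selected allele segregates,
an allelic class: *derived* or *ancestral* with respect to the focal
site.  Coalescence is only allowed within a class, at per-generation
rate ``C(k,2) / (2 N(t) x(t))`` inside the derived background and
``C(k,2) / (2 N(t) (1 - x(t)))`` inside the ancestral background, where
``x(t)`` is the (pre-simulated) allele-frequency trajectory.
Recombination detaches material at rate ``r`` per bp per generation; the
piece on the focal side of the breakpoint keeps its class, the other
piece rejoins the derived background with probability ``x(t)``.  The
derived-class lineage count is capped by the number of derived copies in
the population, forcing the class to collapse to a single lineage by the
allele's origin, where the focal mutation is recorded and the lineage
rejoins the ancestral background; older history follows the ordinary
(piecewise-exponential) coalescent with recombination.

The sampler emits a :class:`tskit.TreeSequence` whose local trees are
binary with fully coalesced roots, plus the focal site carried as a real
site/mutation pair, so downstream feature extraction and mutation
placement use standard tskit machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import tskit

from argsel.demography import DemographyModel, constant_size
from argsel.trajectory import Trajectory

__all__ = ["simulate_ancestry_with_sweep", "SweepSimulationError"]

_BLOCK = 4096
_TIME_EPS = 1e-6


class SweepSimulationError(RuntimeError):
    pass


class _Lineage:
    __slots__ = ("segs", "cls")

    def __init__(self, segs: List[Tuple[float, float, int]], cls: int = 0):
        self.segs = segs  # sorted, non-overlapping (left, right, node)
        self.cls = cls

    @property
    def span(self) -> float:
        return self.segs[-1][1] - self.segs[0][0]

    @property
    def left(self) -> float:
        return self.segs[0][0]

    @property
    def right(self) -> float:
        return self.segs[-1][1]


def _subtract(segs, cuts):
    """Remove the (sorted, disjoint) intervals ``cuts`` from ``segs``."""
    if not cuts:
        return segs
    out = []
    ci = 0
    for l, r, node in segs:
        cur = l
        while ci < len(cuts) and cuts[ci][1] <= cur:
            ci += 1
        j = ci
        while j < len(cuts) and cuts[j][0] < r:
            cl, cr = cuts[j]
            if cl > cur:
                out.append((cur, cl, node))
            cur = max(cur, min(cr, r))
            j += 1
        if cur < r:
            out.append((cur, r, node))
    return out


def _merge_lineages(la, lb, w_time, tables):
    """Merge two lineages; create a parent node over overlapping material.

    Returns the merged segment list.  Non-overlapping material keeps its
    original node; a new node is created only if the lineages overlap.
    """
    bounds = sorted(
        {s[0] for s in la.segs} | {s[1] for s in la.segs}
        | {s[0] for s in lb.segs} | {s[1] for s in lb.segs}
    )

    def node_at(segs, l):
        for sl, sr, node in segs:
            if sl <= l < sr:
                return node
        return None

    w = None
    pieces = []
    for l, r in zip(bounds[:-1], bounds[1:]):
        na = node_at(la.segs, l)
        nb = node_at(lb.segs, l)
        if na is not None and nb is not None:
            if w is None:
                w = tables.nodes.add_row(flags=0, time=w_time)
            tables.edges.add_row(left=l, right=r, parent=w, child=na)
            tables.edges.add_row(left=l, right=r, parent=w, child=nb)
            pieces.append((l, r, w))
        elif na is not None:
            pieces.append((l, r, na))
        elif nb is not None:
            pieces.append((l, r, nb))
    # squash adjacent pieces with the same node
    squashed = [pieces[0]]
    for l, r, node in pieces[1:]:
        pl, pr, pn = squashed[-1]
        if pn == node and pl <= l <= pr:
            squashed[-1] = (pl, max(pr, r), pn)
        else:
            squashed.append((l, r, node))
    return squashed


def _retire_solo_material(lineages):
    """Drop material carried by exactly one lineage (local MRCA reached)."""
    events = []
    for lin in lineages:
        for l, r, _ in lin.segs:
            events.append((l, 1))
            events.append((r, -1))
    events.sort()
    solo = []
    depth = 0
    prev = None
    for pos, d in events:
        if prev is not None and pos > prev and depth == 1:
            if solo and solo[-1][1] == prev:
                solo[-1] = (solo[-1][0], pos)
            else:
                solo.append((prev, pos))
        depth += d
        prev = pos
    if solo:
        for lin in lineages:
            lin.segs = _subtract(lin.segs, solo)
    return [lin for lin in lineages if lin.segs]


def simulate_ancestry_with_sweep(
    n: int,
    L: float,
    recomb_rate: float,
    demography: Optional[DemographyModel] = None,
    trajectory: Optional[Trajectory] = None,
    n_derived: int = 0,
    focal_position: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    max_time: float = 1e9,
) -> tskit.TreeSequence:
    """Sample an ancestry for ``n`` haplotypes over ``[0, L)``.

    With ``trajectory`` (and ``1 <= n_derived < n``), the focal site at
    ``focal_position`` experiences the sweep encoded by the trajectory
    and the returned tree sequence carries it as site 0 (ancestral state
    "0", derived state "1").  Without a trajectory the model is the
    ordinary neutral coalescent with recombination.
    """
    if rng is None:
        rng = np.random.default_rng()
    if demography is None:
        demography = constant_size(10_000)
    if n < 2:
        raise ValueError("n must be >= 2")
    sweep = trajectory is not None
    if sweep:
        if not (1 <= n_derived < n):
            raise ValueError("sweep mode requires 1 <= n_derived < n")
        if focal_position is None:
            focal_position = L / 2.0

    tables = tskit.TableCollection(sequence_length=L)
    tables.nodes.metadata_schema = tskit.MetadataSchema.null()
    for _ in range(n):
        tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0)

    lineages = [
        _Lineage([(0.0, L, i)], cls=(1 if sweep and i < n_derived else 0))
        for i in range(n)
    ]

    t = 0.0
    origin = trajectory.origin_generation if sweep else -1
    in_sweep = sweep
    mutation_recorded = not sweep
    E = rng.exponential()  # standing Exp(1) hazard target

    def class_counts():
        kd = sum(1 for lin in lineages if lin.cls == 1)
        return len(lineages) - kd, kd

    def do_coalescence(cls, when):
        nonlocal lineages, t
        group = [i for i, lin in enumerate(lineages) if lin.cls == cls]
        ia, ib = rng.choice(len(group), size=2, replace=False)
        la, lb = lineages[group[ia]], lineages[group[ib]]
        t = max(t + _TIME_EPS, when)
        merged = _merge_lineages(la, lb, t, tables)
        keep = [lin for lin in lineages if lin is not la and lin is not lb]
        keep.append(_Lineage(merged, cls=cls))
        lineages = _retire_solo_material(keep)

    def do_recombination(x_now, when):
        nonlocal lineages, t
        spans = np.array([lin.span for lin in lineages])
        i = rng.choice(len(lineages), p=spans / spans.sum())
        lin = lineages[i]
        u = rng.uniform(lin.left, lin.right)
        left_segs, right_segs = [], []
        for l, r, node in lin.segs:
            if r <= u:
                left_segs.append((l, r, node))
            elif l >= u:
                right_segs.append((l, r, node))
            else:
                left_segs.append((l, u, node))
                right_segs.append((u, r, node))
        if not left_segs or not right_segs:
            return  # breakpoint outside carried material; no-op
        t = max(t + _TIME_EPS, when)
        if in_sweep:
            focal_left = focal_position < u
            keep_cls = lin.cls
            new_cls = 1 if rng.uniform() < x_now else 0
            cl = keep_cls if focal_left else new_cls
            cr = new_cls if focal_left else keep_cls
        else:
            cl = cr = lin.cls
        lineages = (
            [x for j, x in enumerate(lineages) if j != i]
            + [_Lineage(left_segs, cls=cl), _Lineage(right_segs, cls=cr)]
        )

    def record_focal_mutation():
        nonlocal mutation_recorded, t
        derived = [lin for lin in lineages if lin.cls == 1]
        if len(derived) != 1:
            raise SweepSimulationError(
                f"{len(derived)} derived lineages at allele origin (expected 1)"
            )
        lin = derived[0]
        node = None
        for l, r, nd in lin.segs:
            if l <= focal_position < r:
                node = nd
                break
        if node is None:
            raise SweepSimulationError(
                "derived lineage lost focal material before origin"
            )
        t = max(t, float(tables.nodes.time[node])) + _TIME_EPS
        site = tables.sites.add_row(position=focal_position, ancestral_state="0")
        tables.mutations.add_row(site=site, node=node, derived_state="1", time=t)
        lin.cls = 0
        mutation_recorded = True

    while lineages:
        if t > max_time:
            raise SweepSimulationError(f"ancestry not coalesced by t={max_time:g}")
        k_a, k_d = class_counts()
        G = sum(lin.span for lin in lineages)
        lam_r = recomb_rate * G
        g0 = int(math.ceil(t + _TIME_EPS))

        if in_sweep and g0 > origin:
            record_focal_mutation()
            in_sweep = False
            continue

        if in_sweep:
            g1 = min(origin + 1, g0 + _BLOCK)
            gens = np.arange(g0, g1)
            x = trajectory.freqs[gens]
            N = demography.size_at(gens)
            copies = np.maximum(np.round(2.0 * N * x), 1.0)
            lam_d = np.where(
                copies >= 2, (k_d * (k_d - 1) / 2.0) / (2.0 * N * x), 0.0
            ) if k_d >= 2 else np.zeros_like(x)
            lam_a = ((k_a * (k_a - 1) / 2.0) / (2.0 * N * (1.0 - x))
                     if k_a >= 2 else np.zeros_like(x))
            # forced class collapse where population copies < lineage count
            forced = np.flatnonzero(copies < k_d)
            f_idx = forced[0] if len(forced) else len(gens)
            lam_tot = lam_d + lam_a + lam_r
            cum = np.cumsum(lam_tot)
            j = int(np.searchsorted(cum, E))
            if j < f_idx and j < len(gens):
                g_ev = gens[j]
                E = rng.exponential()
                w = np.array([lam_d[j], lam_a[j], lam_r])
                kind = rng.choice(3, p=w / w.sum())
                when = g_ev + rng.uniform()
                if kind == 0:
                    do_coalescence(1, when)
                elif kind == 1:
                    do_coalescence(0, when)
                else:
                    do_recombination(float(x[j]), when)
            elif f_idx < len(gens):
                # forced mergers inside the derived class at generation g_f
                E = max(E - (cum[f_idx - 1] if f_idx > 0 else 0.0), 0.0) or rng.exponential()
                g_f = gens[f_idx]
                target = int(copies[f_idx])
                while sum(1 for lin in lineages if lin.cls == 1) > max(target, 1):
                    do_coalescence(1, g_f + rng.uniform())
                t = max(t, float(g_f) + 1.0 - _TIME_EPS)
            else:
                E -= float(cum[-1]) if len(cum) else 0.0
                t = float(g1) - _TIME_EPS
            continue

        # neutral phase: single class, piecewise-exponential demography
        k = len(lineages)
        epoch_idx = np.searchsorted(
            [e.start_time for e in demography.epochs], t, side="right"
        ) - 1
        epoch = demography.epochs[epoch_idx]
        epoch_end = (
            demography.epochs[epoch_idx + 1].start_time
            if epoch_idx + 1 < len(demography.epochs)
            else math.inf
        )
        if epoch.growth_rate == 0.0:
            N = epoch.size
            lam_c = (k * (k - 1) / 2.0) / (2.0 * N) if k >= 2 else 0.0
            lam = lam_c + lam_r
            if lam <= 0:
                t = epoch_end
                continue
            dt = E / lam
            if t + dt >= epoch_end:
                E -= lam * (epoch_end - t)
                t = epoch_end
                continue
            when = t + dt
            E = rng.exponential()
            if rng.uniform() < lam_c / lam:
                do_coalescence(0, when)
            else:
                do_recombination(0.0, when)
        else:
            # growing epoch: per-generation hazard accumulation
            g1 = int(min(epoch_end, g0 + _BLOCK))
            gens = np.arange(g0, max(g1, g0 + 1))
            N = demography.size_at(gens)
            lam_c = (k * (k - 1) / 2.0) / (2.0 * N) if k >= 2 else np.zeros_like(N)
            lam_tot = lam_c + lam_r
            cum = np.cumsum(lam_tot)
            j = int(np.searchsorted(cum, E))
            if j < len(gens):
                when = gens[j] + rng.uniform()
                E = rng.exponential()
                w = np.array([float(lam_c[j]), lam_r])
                if rng.uniform() < w[0] / w.sum():
                    do_coalescence(0, when)
                else:
                    do_recombination(0.0, when)
            else:
                E -= float(cum[-1])
                t = float(gens[-1]) + 1.0 - _TIME_EPS

    if not mutation_recorded:
        raise SweepSimulationError("focal mutation was never recorded")

    tables.sort()
    tables.edges.squash()
    tables.sort()
    tables.build_index()
    return tables.tree_sequence()
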