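"""Format adapters: Newick + interval sidecar, tree sequences, VCF, HDF5.

Coordinates are 0-based half-open internally; VCF positions are 1-based
and converted at this boundary.  Times are always generations.
"""

from __future__ import annotations

import json
from typing import List, Optional, Sequence, Tuple

import numpy as np

from argsel.trees import LocalTree, SiteLabel

__all__ = [
    "read_trees",
    "read_tree_sequence",
    "write_trees",
    "read_carriers",
    "write_vcf",
    "save_feature_dataset",
    "load_feature_dataset",
]


class TreeValidationError(ValueError):
    pass


def _local_tree_from_dendropy(tree, interval, leaf_order=None, ultrametric_tol=1e-3):
    """Convert a dendropy tree (branch lengths in generations) to LocalTree."""
    tree.seed_node.edge.length = None
    nodes = list(tree.preorder_node_iter())
    depth = {id(tree.seed_node): 0.0}
    for nd in nodes[1:]:
        bl = nd.edge.length
        if bl is None or bl < 0:
            raise TreeValidationError("every branch needs a non-negative length")
        depth[id(nd)] = depth[id(nd.parent_node)] + bl
    leaves = [nd for nd in nodes if nd.is_leaf()]
    height = max(depth[id(nd)] for nd in leaves)
    tol = max(ultrametric_tol, 1e-9 * height)
    for nd in leaves:
        if height - depth[id(nd)] > tol:
            raise TreeValidationError(
                f"leaf {nd.taxon.label!r} is not contemporaneous "
                f"(deviates {height - depth[id(nd)]:g} generations)"
            )
    names = [nd.taxon.label for nd in leaves]
    if leaf_order is None:
        try:
            order = {nm: int(nm) for nm in names}
            if sorted(order.values()) != list(range(len(names))):
                raise ValueError
        except ValueError:
            order = {nm: i for i, nm in enumerate(sorted(names))}
    else:
        order = {nm: i for i, nm in enumerate(leaf_order)}
    n = len(leaves)
    ids = {}
    nxt = n
    for nd in nodes:
        if nd.is_leaf():
            ids[id(nd)] = order[nd.taxon.label]
        else:
            ids[id(nd)] = nxt
            nxt += 1
    m = len(nodes)
    parent = np.full(m, -1, dtype=np.int64)
    time = np.zeros(m)
    for nd in nodes:
        v = ids[id(nd)]
        time[v] = 0.0 if nd.is_leaf() else height - depth[id(nd)]
        if nd.parent_node is not None:
            parent[v] = ids[id(nd.parent_node)]
    return LocalTree(parent, time, interval=interval, n_leaves=n)


def read_trees(
    newick_path,
    intervals_path,
    leaf_order: Optional[Sequence[str]] = None,
    ultrametric_tol: float = 1e-3,
) -> List[LocalTree]:
    """Read per-interval Newick trees with a BED-like interval sidecar.

    The Newick file holds one tree per line (branch lengths in
    generations); the sidecar holds tab-separated ``chrom  start  end
    tree_index`` lines, one per tree, in genomic order.  Intervals must
    tile the region: gaps or overlaps are rejected.
    """
    import dendropy

    intervals = []
    with open(intervals_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, *_ = line.split("\t")
            intervals.append((float(start), float(end)))
    trees = dendropy.TreeList.get(path=str(newick_path), schema="newick")
    if len(trees) != len(intervals):
        raise TreeValidationError(
            f"{len(trees)} trees but {len(intervals)} intervals"
        )
    prev_end = None
    out = []
    for tr, (start, end) in zip(trees, intervals):
        if start >= end:
            raise TreeValidationError(f"empty interval [{start}, {end})")
        if prev_end is not None:
            if start < prev_end:
                raise TreeValidationError(
                    f"overlapping intervals at {start} (previous end {prev_end})"
                )
            if start > prev_end:
                raise TreeValidationError(
                    f"gap between {prev_end} and {start}; intervals must tile"
                )
        prev_end = end
        try:
            out.append(
                _local_tree_from_dendropy(
                    tr, (start, end), leaf_order, ultrametric_tol
                )
            )
        except (TreeValidationError, ValueError) as exc:
            raise TreeValidationError(f"tree over [{start}, {end}): {exc}") from exc
    return out


def read_tree_sequence(path) -> List[LocalTree]:
    """Local trees of a succinct tree-sequence (.trees) file."""
    import tskit

    ts = tskit.load(str(path))
    return [LocalTree.from_tskit(t) for t in ts.trees()]


def _newick(tree: LocalTree, node: int, parent_time: Optional[float]) -> str:
    kids = tree.children()[node]
    if kids:
        inner = ",".join(_newick(tree, k, tree.time[node]) for k in kids)
        label = f"({inner})"
    else:
        label = str(node)
    if parent_time is None:
        return label
    return f"{label}:{parent_time - tree.time[node]:.17g}"


def write_trees(trees: Sequence[LocalTree], newick_path, intervals_path,
                chrom: str = "1"):
    """Inverse of :func:`read_trees`."""
    with open(newick_path, "w") as nf, open(intervals_path, "w") as bf:
        for i, tr in enumerate(trees):
            nf.write(_newick(tr, tr.root, None) + ";\n")
            bf.write(f"{chrom}\t{tr.interval[0]:.17g}\t{tr.interval[1]:.17g}\t{i}\n")


def read_carriers(vcf_path, position: float, ancestral_field: str = "AA") -> SiteLabel:
    """Derived-allele carriers at one site of a phased VCF.

    ``position`` is 0-based; the VCF's 1-based POS is converted here.
    The ancestral allele comes from the INFO field (default ``AA``) and
    must match REF or ALT; sites with a missing or invalid ancestral
    allele, multiallelic sites, and unphased genotypes are rejected.
    Haplotype ``p * i + k`` is the k-th allele of sample ``i`` for
    ploidy ``p``.
    """
    from cyvcf2 import VCF

    pos1 = int(round(position)) + 1
    vcf = VCF(str(vcf_path))
    record = None
    for rec in vcf:
        if rec.POS == pos1:
            record = rec
            break
    if record is None:
        raise ValueError(f"no VCF record at 1-based position {pos1}")
    if len(record.ALT) != 1:
        raise ValueError(f"site at {pos1} is not biallelic")
    aa = record.INFO.get(ancestral_field)
    if aa is None:
        raise ValueError(f"site at {pos1} lacks the {ancestral_field} INFO field")
    aa = str(aa).split("|")[0].strip().upper()
    ref, alt = record.REF.upper(), record.ALT[0].upper()
    if aa == ref:
        derived_code = 1
    elif aa == alt:
        derived_code = 0  # polarization flip: REF is derived
    else:
        raise ValueError(
            f"ancestral allele {aa!r} at {pos1} matches neither REF nor ALT"
        )
    carriers = []
    hap = 0
    for g in record.genotypes:
        alleles, phased = g[:-1], g[-1]
        if len(alleles) > 1 and not phased:
            raise ValueError(f"unphased genotype at {pos1}")
        for a in alleles:
            if a < 0:
                raise ValueError(f"missing genotype at {pos1}")
            if a == derived_code:
                carriers.append(hap)
            hap += 1
    return SiteLabel(position=float(position), carriers=frozenset(carriers))


def write_vcf(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    path,
    chrom: str = "1",
    ploidy: int = 2,
    ancestral_field: str = "AA",
):
    """Write 0/1 haplotypes as a phased VCF with ancestral-allele INFO.

    Alleles are written as A (ancestral, REF) / T (derived, ALT) with
    ``AA=A``; haplotypes are grouped into samples of the given ploidy
    (n must be divisible by it).  Positions are rounded to unique
    1-based integers.
    """
    n, S = haplotypes.shape
    if n % ploidy:
        raise ValueError("haplotype count not divisible by ploidy")
    pos1 = np.round(np.asarray(positions)).astype(int) + 1
    for i in range(1, S):  # enforce strictly increasing integer positions
        if pos1[i] <= pos1[i - 1]:
            pos1[i] = pos1[i - 1] + 1
    samples = [f"s{i}" for i in range(n // ploidy)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            f'##INFO=<ID={ancestral_field},Number=1,Type=String,'
            'Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(S):
            gts = [
                "|".join(str(int(haplotypes[ploidy * i + k, j]))
                         for k in range(ploidy))
                for i in range(n // ploidy)
            ]
            fh.write(
                f"{chrom}\t{pos1[j]}\t.\tA\tT\t.\tPASS\t{ancestral_field}=A\tGT\t"
                + "\t".join(gts) + "\n"
            )


def save_feature_dataset(path, data: dict):
    """Write a feature dataset container to HDF5.

    Layout: datasets ``features`` (N x K x C, chunked), ``grid`` (K),
    one dataset per label under ``labels/``, and the full provenance
    dict JSON-encoded in the root attribute ``metadata``.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        feats = np.asarray(data["features"], dtype=np.float32)
        fh.create_dataset(
            "features", data=feats,
            chunks=(min(64, max(len(feats), 1)),) + feats.shape[1:],
        )
        fh.create_dataset("grid", data=np.asarray(data["grid"], dtype=float))
        lab = fh.create_group("labels")
        for k, v in data["labels"].items():
            lab.create_dataset(k, data=np.asarray(v))
        fh.attrs["metadata"] = json.dumps(data.get("metadata", {}))


def load_feature_dataset(path) -> dict:
    import h5py

    with h5py.File(path, "r") as fh:
        return {
            "features": fh["features"][...],
            "grid": fh["grid"][...],
            "labels": {k: fh["labels"][k][...] for k in fh["labels"]},
            "metadata": json.loads(fh.attrs["metadata"]),
        }
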