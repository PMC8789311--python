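"""Hand-checkable fixtures used by the test suite and the CLI.

The canonical toy genealogy is a 4-leaf binary tree: leaves A,B,C,D (ids
0..3) at time 0, (A,B) coalescing at 1, (C,D) at 2, and the root at 3
generations.  Its lineage counts at any time can be enumerated on paper.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from argsel.trees import LocalTree

__all__ = ["toy_tree", "toy_block", "make_fixtures"]


def toy_tree(interval=(0.0, 100.0)) -> LocalTree:
    """((A,B):1, (C,D):2) with root at t=3; leaves 0..3 at t=0."""
    #        nodes: 0=A 1=B 2=C 3=D 4=AB 5=CD 6=root
    parent = [4, 4, 5, 5, 6, 6, -1]
    time = [0.0, 0.0, 0.0, 0.0, 1.0, 2.0, 3.0]
    return LocalTree(parent, time, interval=interval)


def toy_block():
    """8 haplotypes x 5 sites with mixed frequencies, for statistics."""
    matrix = np.array(
        [
            [1, 1, 0, 0, 1],
            [1, 1, 0, 0, 0],
            [1, 0, 1, 0, 0],
            [0, 0, 1, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    positions = np.array([10.0, 25.0, 40.0, 60.0, 85.0])
    return matrix, positions


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the toy fixture set and return the paths.

    Contents: the 4-leaf tree as Newick + interval sidecar (three copies
    tiling [0, 300) so flanking extraction works), a phased toy VCF of
    the statistic block, the 8x5 statistic block as CSV, and a 20-region
    mini feature dataset (10 neutral / 10 sweep) in HDF5.
    """
    from argsel.grid import build_time_grid
    from argsel.io import write_trees, write_vcf
    from argsel.regions import make_dataset
    from argsel.sumstats import HaplotypeBlock, basic_stats, garud_h, zns

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trees = [toy_tree((0.0, 100.0)), toy_tree((100.0, 200.0)), toy_tree((200.0, 300.0))]
    write_trees(trees, out / "toy.nwk", out / "toy.intervals.bed")

    matrix, positions = toy_block()
    write_vcf(matrix, positions, out / "toy.vcf", ploidy=2)
    np.savetxt(out / "toy_block.csv", matrix, fmt="%d", delimiter=",")

    # 4-haplotype VCF whose carrier sets are clades of the toy tree
    tree_matrix = np.array(
        [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 1]], dtype=np.int8
    )
    write_vcf(tree_matrix, np.array([10.0, 40.0, 70.0]),
              out / "toy_tree.vcf", ploidy=2)

    grid = build_time_grid(K=32, t_max=4e4)
    data = make_dataset(
        out / "mini_dataset.h5",
        n_neutral=10,
        n_sweep=10,
        L=2e4,
        n=16,
        grid=grid,
        seed=seed,
    )
    block = HaplotypeBlock(matrix, positions)
    expected = {"basic_stats": basic_stats(block), "garud_h": garud_h(block),
                "zns": zns(block)}
    with open(out / "expected_stats.json", "w") as fh:
        json.dump(expected, fh, indent=2, default=float)
    return {
        "newick": out / "toy.nwk",
        "intervals": out / "toy.intervals.bed",
        "vcf": out / "toy.vcf",
        "tree_vcf": out / "toy_tree.vcf",
        "block_csv": out / "toy_block.csv",
        "dataset": out / "mini_dataset.h5",
        "expected": out / "expected_stats.json",
        "n_records": len(data["features"]),
    }
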