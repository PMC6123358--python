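"""Phylogenetic-cohesion permutation test.

Cultivation is expected to select for heritable traits, so the cultured
subset of a community should be phylogenetically clustered: its mean
pairwise distance (MPD) should fall low in the distribution of MPDs of
size-matched random subsets of the source community.  This module provides
that permutation null, globally and per taxonomic family, over any
distance matrix.  Two distance backends are shipped: uncorrected
p-distances from an aligned FASTA and patristic distances from a tree with
branch lengths.

Empirical P-values use the add-one (pseudocount) estimator, so the
smallest attainable P at B permutations is 1/(B+1); ties between the
observed and null means count toward both tails.  A percentile rank is
reported alongside to support "below the 10th / 1st percentile"
annotations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix

from .core import Taxonomy


@dataclass
class PermutationResult:
    group_label: str
    observed_mean: float
    null_means: np.ndarray
    p_lesser: float
    p_greater: float
    percentile_rank: float        # 100 * (#null < observed) / B
    subset_size: int
    B: int
    seed: int

    def to_dict(self, include_null: bool = True) -> dict:
        out = {
            "group_label": self.group_label,
            "observed_mean": self.observed_mean,
            "p_lesser": self.p_lesser,
            "p_greater": self.p_greater,
            "percentile_rank": self.percentile_rank,
            "subset_size": self.subset_size,
            "B": self.B,
            "seed": self.seed,
        }
        if include_null:
            out["null_means"] = self.null_means.tolist()
        return out


# ---------------------------------------------------------------------------
# distance backends

_VALID = np.frombuffer(b"ACGT", dtype="S1")


def pdistance_from_alignment(aligned_fasta: str | Path) -> DistanceMatrix:
    """Uncorrected p-distances from an aligned FASTA.

    d[i, j] = mismatches / comparable columns, where a column is
    comparable when both sequences carry a non-gap, non-N base.  Sequences
    must be equal length (aligned); a pair with zero comparable columns is
    an error.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for record in SeqIO.parse(str(aligned_fasta), "fasta"):
        if record.id in ids:
            raise ValueError(f"duplicate sequence id {record.id!r}")
        ids.append(record.id)
        rows.append(
            np.frombuffer(str(record.seq).upper().encode("ascii"), dtype="S1")
        )
    if not ids:
        raise ValueError(f"no sequences in {aligned_fasta}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences are not aligned (lengths {sorted(lengths)}) in {aligned_fasta}"
        )
    seqs = np.vstack(rows)
    valid = np.isin(seqs, _VALID)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = valid[i] & valid[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            mism = int((seqs[i][comparable] != seqs[j][comparable]).sum())
            d[i, j] = d[j, i] = mism / n_comp
    return DistanceMatrix(d, ids=ids)


def patristic_distances(tree: dendropy.Tree | str | Path) -> DistanceMatrix:
    """Tip-to-tip path-length distances from a tree with branch lengths.

    Accepts a dendropy tree, a Newick string, or a path to a Newick file.
    Computed by merging child tip sets bottom-up with vectorized outer
    sums, which keeps the cost at O(n^2) for n tips.
    """
    if not isinstance(tree, dendropy.Tree):
        text = str(tree)
        if os.path.exists(text):
            tree = dendropy.Tree.get(path=text, schema="newick")
        else:
            tree = dendropy.Tree.get(data=text, schema="newick")
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    ids = [leaf.taxon.label for leaf in leaves]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tip labels")
    index = {id(leaf): i for leaf, i in zip(leaves, range(len(leaves)))}
    n = len(ids)
    d = np.zeros((n, n))
    # per-node state: (tip indices, distance of each tip to this node)
    state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = (
                np.array([index[id(node)]], dtype=np.intp),
                np.zeros(1),
            )
        else:
            parts = []
            for child in node.child_nodes():
                tips, dist = state.pop(id(child))
                length = child.edge.length
                if length is None:
                    raise ValueError(
                        f"missing branch length on edge above {child!r}"
                    )
                parts.append((tips, dist + length))
            for a in range(len(parts)):
                for b in range(a + 1, len(parts)):
                    ti, di = parts[a]
                    tj, dj = parts[b]
                    block = di[:, None] + dj[None, :]
                    d[np.ix_(ti, tj)] = block
                    d[np.ix_(tj, ti)] = block.T
            state[id(node)] = (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
    return DistanceMatrix(d, ids=ids)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Square distance matrix from a TSV with ids in header and first column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column ids differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))


# ---------------------------------------------------------------------------
# statistics


def _indices(D: DistanceMatrix, ids: Iterable[str]) -> np.ndarray:
    lookup = {x: i for i, x in enumerate(D.ids)}
    try:
        return np.array([lookup[x] for x in ids], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"id {exc.args[0]!r} not in distance matrix") from None


def mean_pairwise_distance(ids: Iterable[str], D: DistanceMatrix) -> float:
    """Mean distance over all unordered pairs in ``ids`` (each pair once)."""
    idx = _indices(D, sorted(set(ids)))
    n = len(idx)
    if n < 2:
        raise ValueError("mean pairwise distance requires at least 2 ids")
    sub = D.data[np.ix_(idx, idx)]
    return float(sub.sum() / (n * (n - 1)))


def _mpd_from_indices(data: np.ndarray, idx: np.ndarray) -> float:
    sub = data[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))


def phylo_permutation_test(
    focal_ids: Iterable[str],
    pool_ids: Iterable[str],
    D: DistanceMatrix,
    B: int = 100,
    subset_size: int | None = None,
    seed: int = 0,
    group_label: str = "all",
) -> PermutationResult:
    """MPD of the focal set versus size-matched random subsets of the pool.

    Draws B subsets of ``subset_size`` ids (default: the focal set's size)
    uniformly without replacement from the pool; ``p_lesser`` is the
    add-one tail probability that a random subset is at least as tight as
    the focal set.
    """
    focal = sorted(set(focal_ids))
    pool = sorted(set(pool_ids))
    if subset_size is None:
        subset_size = len(focal)
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    if subset_size > len(pool):
        raise ValueError(
            f"subset_size {subset_size} exceeds pool size {len(pool)}"
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    focal_idx = _indices(D, focal)
    if len(focal_idx) < 2:
        raise ValueError("focal set must contain at least 2 ids")
    pool_idx = _indices(D, pool)
    data = D.data
    observed = _mpd_from_indices(data, focal_idx)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        draw = rng.choice(pool_idx, size=subset_size, replace=False)
        null[b] = _mpd_from_indices(data, draw)
    p_lesser = (1 + int((null <= observed).sum())) / (B + 1)
    p_greater = (1 + int((null >= observed).sum())) / (B + 1)
    percentile = 100.0 * int((null < observed).sum()) / B
    return PermutationResult(
        group_label=group_label,
        observed_mean=observed,
        null_means=null,
        p_lesser=p_lesser,
        p_greater=p_greater,
        percentile_rank=percentile,
        subset_size=subset_size,
        B=B,
        seed=seed,
    )


def family_cohesion_tests(
    focal_ids: Iterable[str],
    pool_ids: Iterable[str],
    taxonomy: Taxonomy,
    D: DistanceMatrix,
    B: int = 100,
    min_otus: int = 10,
    seed: int = 0,
) -> tuple[list[PermutationResult], list[dict]]:
    """Cohesion test within each family populous enough on both sides.

    A family qualifies when it has at least ``min_otus`` members in the
    focal (cultured) set and at least ``min_otus`` members in the pool;
    for each qualifying family the permutation test runs restricted to
    that family's pool with subset size equal to the family's focal
    count.  Families failing the threshold are skipped, never an error;
    they are returned in a skip list with their counts.
    """
    focal = set(focal_ids)
    pool = set(pool_ids)
    focal_fams = taxonomy.families(focal)
    pool_fams = taxonomy.families(pool)
    results: list[PermutationResult] = []
    skipped: list[dict] = []
    rng = np.random.default_rng(seed)
    for fam in sorted(set(focal_fams) | set(pool_fams)):
        n_focal = len(focal_fams.get(fam, ()))
        n_pool = len(pool_fams.get(fam, ()))
        fam_seed = int(rng.integers(2**31))
        if n_focal < min_otus or n_pool < min_otus:
            skipped.append({"family": fam, "n_focal": n_focal, "n_pool": n_pool})
            continue
        results.append(
            phylo_permutation_test(
                focal_fams[fam],
                pool_fams[fam],
                D,
                B=B,
                subset_size=min(n_focal, n_pool),
                seed=fam_seed,
                group_label=fam,
            )
        )
    return results, skipped
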