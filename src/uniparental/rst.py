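"""R_ST population distances and neighbor-joining trees.

R_ST is the microsatellite analog of F_ST: a two-group AMOVA on squared
allele-size differences (Slatkin 1995).  With repeat counts x_{il} for
individual i at locus l, the squared distance between two individuals is
d_ij = sum_l (x_il - x_jl)^2, and the statistic is
sigma2_among / (sigma2_among + sigma2_within) from the standard one-level
AMOVA decomposition with unequal sample sizes.  Only complete haplotypes on
the chosen locus subset enter the computation; negative values are clipped
to 0 in matrix output.

Trees are built with the Saitou-Nei neighbor-joining algorithm (consistent
on additive distances); negative branch lengths, which NJ can produce on
non-additive inputs, are set to 0 after construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .errors import UniparentalError
from .io import STRHaplotypeTable
from .ystr import _eligible_populations

logger = logging.getLogger("uniparental")


def _complete_rows(X: np.ndarray) -> np.ndarray:
    return X[~np.isnan(X).any(axis=1)]


def rst_pair(pop_a: np.ndarray, pop_b: np.ndarray) -> float:
    """Raw (unclipped) R_ST between two populations of complete haplotypes.

    ``pop_a``/``pop_b`` are (n x L) arrays of repeat counts; rows with any
    missing locus are dropped first.  Returns NaN with a warning when either
    population retains fewer than 2 complete haplotypes.

    The computation decomposes per-locus sums of squared deviations around
    population and grand means (summed over loci) into among/within mean
    squares; variance components follow the unequal-n AMOVA coefficient
    n' = (N - sum(n_p^2)/N) / (P - 1).
    """
    A = _complete_rows(np.asarray(pop_a, dtype=float))
    B = _complete_rows(np.asarray(pop_b, dtype=float))
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise UniparentalError("populations must be 2-D arrays on a common panel")
    na, nb = len(A), len(B)
    if na < 2 or nb < 2:
        logger.warning("R_ST undefined: population with < 2 complete haplotypes "
                       "(n_a=%d, n_b=%d)", na, nb)
        return float("nan")
    N = na + nb
    ss_within = float(((A - A.mean(axis=0)) ** 2).sum()
                      + ((B - B.mean(axis=0)) ** 2).sum())
    grand = np.vstack([A, B]).mean(axis=0)
    ss_total = float(((np.vstack([A, B]) - grand) ** 2).sum())
    ss_among = ss_total - ss_within
    ms_within = ss_within / (N - 2)
    ms_among = ss_among / 1.0  # P - 1 = 1
    n_prime = (N - (na ** 2 + nb ** 2) / N) / 1.0
    sigma_among = (ms_among - ms_within) / n_prime
    denom = sigma_among + ms_within
    if denom == 0.0:
        return 0.0  # both populations monomorphic and identical
    return float(sigma_among / denom)


@dataclass
class PopulationDistanceMatrix:
    """Symmetric population-level R_ST matrix, clipped to [0, 1]."""

    matrix: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return list(self.matrix.index)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def rst_matrix(table: STRHaplotypeTable, loci: list[str] | None = None,
               min_pop: int = 4) -> PopulationDistanceMatrix:
    """All pairwise R_ST values with negatives clipped to 0.

    Only complete haplotypes on the locus subset are used; modern
    populations with fewer than ``min_pop`` complete haplotypes are
    excluded (ancient populations exempt).
    """
    sub = table if loci is None else table.subset_loci(loci)
    era = sub.population_era()
    groups: dict[str, np.ndarray] = {}
    for pop in _eligible_populations(sub, min_pop_size=0):
        X = _complete_rows(sub.subset_population(pop).repeats().to_numpy())
        if era[pop] == "modern" and len(X) < min_pop:
            logger.warning("excluding population %s from R_ST (complete n=%d < %d)",
                           pop, len(X), min_pop)
            continue
        groups[pop] = X
    pops = sorted(groups)
    k = len(pops)
    M = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            raw = rst_pair(groups[pops[i]], groups[pops[j]])
            if not math.isnan(raw) and raw < 0:
                logger.info("clipping negative R_ST %g to 0 for (%s, %s)",
                            raw, pops[i], pops[j])
                raw = 0.0
            M[i, j] = M[j, i] = raw
    return PopulationDistanceMatrix(pd.DataFrame(M, index=pops, columns=pops))


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: PopulationDistanceMatrix | pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clipped to 0."""
    df = dist.matrix if isinstance(dist, PopulationDistanceMatrix) else dist
    if df.shape[0] < 3:
        raise UniparentalError("NJ requires at least 3 populations")
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise UniparentalError(
            f"NJ input has NaN distance for pair ({df.index[i]}, {df.columns[j]})")
    tree = nj(DistanceMatrix(arr, ids=list(df.index)), neg_as_zero=False)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            logger.warning("clipping negative branch length %g at %s",
                           node.length, node.name or "<internal>")
            node.length = 0.0
    return tree


def _newick_label(name: str | None) -> str:
    if not name:
        return ""
    if all(c.isalnum() or c in "_.-" for c in name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _to_newick(node: TreeNode) -> str:
    parts = ""
    if node.children:
        parts = "(" + ",".join(_to_newick(c) for c in node.children) + ")"
    label = parts + _newick_label(node.name)
    if node.length is not None:
        label += f":{node.length:g}"
    return label


def write_newick(tree: TreeNode, path) -> None:
    """Write standard newick with branch lengths; labels with spaces or
    other special characters are single-quoted."""
    with open(path, "w") as fh:
        fh.write(_to_newick(tree) + ";\n")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)
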