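"""Y-STR haplotype statistics.

Implements the individual-level and population-level summaries used for
uniparental population history:

* pairwise repeat distances under a stepwise mutation model (L1 distance on
  repeat counts, pairwise deletion of missing loci);
* pairwise tMRCA under the Average Squared Difference (ASD) model: with a
  single-step symmetric SMM, E[(x1 - x2)^2] = 2*mu*T for a pair diverged T
  generations ago, so the two-sample variance per locus, (x1-x2)^2/2,
  divided by the locus rate is an unbiased estimate of T; the estimator
  averages this ratio over loci and converts to years;
* haplotype diversity with the small-sample correction n/(n-1);
* mean per-locus unbiased repeat-count variance;
* population-pair haplotype-sharing matrices under an identity or
  tMRCA-bin criterion, with a continent-wide median filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import UniparentalError
from .io import MutationRateTable, STRHaplotypeTable

logger = logging.getLogger("uniparental")


def _as_vector(h, loci: list[str] | None) -> np.ndarray:
    if isinstance(h, pd.Series):
        h = h[loci] if loci is not None else h
        return h.to_numpy(dtype=float)
    return np.asarray(h, dtype=float)


def pairwise_repeat_distance(h1, h2, loci: list[str] | None = None) -> float:
    """Sum over loci non-missing in both haplotypes of |r1 - r2|.

    Returns NaN (with a warning) when the two haplotypes share no
    non-missing locus.
    """
    a, b = _as_vector(h1, loci), _as_vector(h2, loci)
    if a.shape != b.shape:
        raise UniparentalError("haplotypes are on different panels")
    shared = ~np.isnan(a) & ~np.isnan(b)
    if not shared.any():
        logger.warning("no shared non-missing loci between haplotype pair")
        return float("nan")
    return float(np.abs(a[shared] - b[shared]).sum())


def pairwise_tmrca(h1, h2, rates: MutationRateTable, generation_time: float = 30.0,
                   loci: list[str] | None = None) -> float:
    """ASD tMRCA in years for one haplotype pair.

    Per locus the two-sample variance (r1-r2)^2/2 is divided by the locus
    mutation rate; the mean of these ratios over loci non-missing in both
    haplotypes, times the generation time, is the tMRCA estimate.  Missing
    loci are excluded from the mean (pairwise deletion).
    """
    if generation_time <= 0:
        raise UniparentalError("generation_time must be positive")
    if loci is None:
        if not (isinstance(h1, pd.Series) and isinstance(h2, pd.Series)):
            raise UniparentalError("loci required for bare vectors")
        loci = list(h1.index)
    a, b = _as_vector(h1, loci), _as_vector(h2, loci)
    mu = rates.vector(list(loci))
    shared = ~np.isnan(a) & ~np.isnan(b)
    if not shared.any():
        logger.warning("tMRCA undefined: no shared non-missing loci")
        return float("nan")
    var_m = (a[shared] - b[shared]) ** 2 / 2.0
    return float(np.mean(var_m / mu[shared]) * generation_time)


def _pair_stats(X: np.ndarray, i: int, j: int, mu: np.ndarray) -> tuple[float, float]:
    """(repeat distance, tMRCA in generations) for rows i, j of X."""
    a, b = X[i], X[j]
    shared = ~np.isnan(a) & ~np.isnan(b)
    if not shared.any():
        return float("nan"), float("nan")
    d = a[shared] - b[shared]
    return float(np.abs(d).sum()), float(np.mean(d ** 2 / 2.0 / mu[shared]))


@dataclass
class PairwiseMatrix:
    """Square symmetric individual-level matrix (distance or tMRCA years)."""

    matrix: pd.DataFrame
    kind: str  # repeat_distance | tmrca_years

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def individual_distance_matrix(table: STRHaplotypeTable,
                               loci: list[str] | None = None) -> PairwiseMatrix:
    """All-pairs repeat distance, pairwise deletion of missing loci."""
    sub = table if loci is None else table.subset_loci(loci)
    X = sub.repeats().to_numpy()
    ids = sub.sample_ids
    n = len(ids)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = X[i], X[j]
            shared = ~np.isnan(a) & ~np.isnan(b)
            if not shared.any():
                logger.warning("no shared loci for pair (%s, %s)", ids[i], ids[j])
                M[i, j] = M[j, i] = float("nan")
            else:
                M[i, j] = M[j, i] = np.abs(a[shared] - b[shared]).sum()
    return PairwiseMatrix(pd.DataFrame(M, index=ids, columns=ids), "repeat_distance")


def tmrca_matrix(table: STRHaplotypeTable, rates: MutationRateTable,
                 generation_time: float = 30.0) -> PairwiseMatrix:
    """All-pairs ASD tMRCA in years."""
    X = table.repeats().to_numpy()
    mu = rates.vector(table.loci)
    ids = table.sample_ids
    n = len(ids)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, t = _pair_stats(X, i, j, mu)
            M[i, j] = M[j, i] = t * generation_time if not math.isnan(t) else float("nan")
    return PairwiseMatrix(pd.DataFrame(M, index=ids, columns=ids), "tmrca_years")


# ---------------------------------------------------------------------------
# Population diversity


def _haplotype_classes(repeats: pd.DataFrame) -> pd.Series:
    """Counts of distinct haplotype vectors; missing is its own symbol."""
    keys = [tuple("?" if pd.isna(v) else float(v) for v in row)
            for row in repeats.to_numpy()]
    return pd.Series(keys).value_counts()


def haplotype_diversity(repeats: pd.DataFrame) -> float:
    """(1 - sum_k p_k^2) * n/(n-1) over distinct haplotype classes.

    Equals 1 when every individual carries a different haplotype and 0 when
    the population is monomorphic.  NaN (with warning) for n < 2.
    """
    n = len(repeats)
    if n < 2:
        logger.warning("haplotype diversity undefined for n=%d", n)
        return float("nan")
    counts = _haplotype_classes(repeats)
    p = counts.to_numpy(dtype=float) / n
    return float((1.0 - np.sum(p ** 2)) * n / (n - 1))


def mean_locus_variance(repeats: pd.DataFrame) -> float:
    """Mean across loci of the unbiased (n-1) variance of repeat counts.

    Loci with fewer than two non-missing observations are excluded from
    the mean.
    """
    if len(repeats) < 2:
        logger.warning("variance undefined for n=%d", len(repeats))
        return float("nan")
    variances = repeats.var(axis=0, ddof=1, skipna=True)
    counts = repeats.notna().sum(axis=0)
    variances = variances[counts >= 2]
    if variances.empty:
        return float("nan")
    return float(variances.mean())


def diversity_report(table: STRHaplotypeTable) -> pd.DataFrame:
    """Per-population sample size, haplotype count, diversity and variance."""
    rows = []
    for pop in table.populations:
        rep = table.subset_population(pop).repeats()
        rows.append({
            "population": pop,
            "sample_size": len(rep),
            "n_haplotypes": len(_haplotype_classes(rep)),
            "haplotype_diversity": haplotype_diversity(rep),
            "mean_locus_variance": mean_locus_variance(rep),
        })
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Haplotype sharing between populations


@dataclass
class SharingMatrix:
    """Population x population haplotype-sharing frequencies in [0, 1].

    Off-diagonal entries are the fraction of cross-population individual
    pairs satisfying the criterion; diagonal entries the fraction of
    within-population pairs.  ``criterion`` is ``identical`` or
    ``tmrca_lt``; in the latter case ``threshold`` is the year bound
    (half-open: pairs at exactly the threshold do not qualify).
    """

    matrix: pd.DataFrame
    criterion: str
    threshold: float | None = None
    median_threshold: float | None = None

    @property
    def populations(self) -> list[str]:
        return list(self.matrix.index)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")

    def edge_list(self) -> pd.DataFrame:
        """Off-diagonal upper-triangle entries as (pop_a, pop_b, frequency)."""
        pops = self.populations
        rows = []
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                rows.append({"pop_a": a, "pop_b": b,
                             "frequency": self.matrix.loc[a, b],
                             "criterion": self._criterion_label()})
        return pd.DataFrame(rows, columns=["pop_a", "pop_b", "frequency", "criterion"])

    def _criterion_label(self) -> str:
        if self.criterion == "identical":
            return "identical"
        return f"tmrca_lt_{self.threshold:g}"


def _eligible_populations(table: STRHaplotypeTable, min_pop_size: int) -> list[str]:
    """Populations entering sharing/R_ST summaries.

    Modern populations below ``min_pop_size`` are excluded with a warning;
    ancient populations are exempt from the size rule.  Empty populations
    cannot occur (no rows -> not listed).
    """
    era = table.population_era()
    out = []
    for pop in table.populations:
        n = (table.data["population"] == pop).sum()
        if era[pop] == "modern" and n < min_pop_size:
            logger.warning("excluding population %s (n=%d < %d)", pop, n, min_pop_size)
            continue
        out.append(pop)
    return out


def sharing_matrix(table: STRHaplotypeTable, criterion: str = "identical",
                   threshold: float | None = None,
                   rates: MutationRateTable | None = None,
                   config: RunConfig | None = None) -> SharingMatrix:
    """Population-pair sharing frequencies under an identity or tMRCA bin.

    ``identical`` counts pairs at repeat distance 0 over their shared loci;
    ``tmrca_lt`` counts pairs with ASD tMRCA strictly below ``threshold``
    years.  Cross-population entries are normalized by n_A*n_B, diagonal
    entries by C(n, 2); populations with a single member get a NaN diagonal.
    """
    config = config or RunConfig()
    if criterion not in ("identical", "tmrca_lt"):
        raise UniparentalError(f"unknown sharing criterion {criterion!r}")
    if criterion == "tmrca_lt":
        if threshold is None:
            raise UniparentalError("tmrca_lt criterion requires a threshold")
        if rates is None:
            raise UniparentalError("tmrca_lt criterion requires mutation rates")
    pops = _eligible_populations(table, config.min_pop_size)
    X = table.repeats().to_numpy()
    mu = rates.vector(table.loci) if rates is not None else None
    pop_rows = {p: np.flatnonzero((table.data["population"] == p).to_numpy()) for p in pops}

    def satisfied(i: int, j: int) -> bool:
        d, t = _pair_stats(X, i, j, mu if mu is not None else np.ones(X.shape[1]))
        if math.isnan(d):
            return False
        if criterion == "identical":
            return d == 0.0
        return t * config.generation_time < threshold

    k = len(pops)
    M = np.zeros((k, k))
    for ai in range(k):
        rows_a = pop_rows[pops[ai]]
        # within-population pairs
        na = len(rows_a)
        if na < 2:
            M[ai, ai] = float("nan")
        else:
            hits = sum(satisfied(i, j) for x, i in enumerate(rows_a) for j in rows_a[x + 1:])
            M[ai, ai] = hits / (na * (na - 1) / 2)
        for bi in range(ai + 1, k):
            rows_b = pop_rows[pops[bi]]
            hits = sum(satisfied(i, j) for i in rows_a for j in rows_b)
            M[ai, bi] = M[bi, ai] = hits / (len(rows_a) * len(rows_b))
    return SharingMatrix(pd.DataFrame(M, index=pops, columns=pops),
                         criterion, threshold)


def median_filter(sharing: SharingMatrix) -> SharingMatrix:
    """Zero out off-diagonal frequencies at or below the continent-wide median.

    The median is taken over the non-zero off-diagonal entries of the full
    matrix; entries <= median become 0 (strictly-above-median survive).
    The threshold used is recorded on the returned matrix.
    """
    M = sharing.matrix.to_numpy(copy=True)
    off = ~np.eye(M.shape[0], dtype=bool)
    vals = M[off]
    nonzero = vals[~np.isnan(vals) & (vals > 0)]
    if nonzero.size == 0:
        logger.warning("median filter: no non-zero off-diagonal frequencies")
        return SharingMatrix(sharing.matrix.copy(), sharing.criterion,
                             sharing.threshold, median_threshold=None)
    med = float(np.median(nonzero))
    filtered = M.copy()
    filtered[off & ~np.isnan(M) & (M <= med)] = 0.0
    out = pd.DataFrame(filtered, index=sharing.populations, columns=sharing.populations)
    logger.info("median filter threshold: %g", med)
    return SharingMatrix(out, sharing.criterion, sharing.threshold, median_threshold=med)
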