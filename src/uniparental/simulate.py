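"""Coalescent genealogies with stepwise-mutation STR and clock-like
sequence evolution, plus fixture bundles with recorded ground truth.

The coalescent uses the haploid-size parameterization natural for
uniparental loci: with k lineages the waiting time to the next merger is
exponential with rate C(k,2)/N_e, so a pair of lineages has E[TMRCA] = N_e
generations.  Users comparing with diploid-N_e literature should halve.

STR loci evolve under a strictly single-step symmetric stepwise mutation
model: per branch and locus the mutation count is Poisson(rate x branch
length in generations) and each mutation moves the repeat count by +-1 with
probability 1/2, reflecting at the lower bound of 1 repeat.  Sequences
evolve under a Jukes-Cantor clock: Poisson(rate/site/year x branch years x
length) substitutions at uniform sites, each to a uniformly chosen
different base.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UniparentalError
from .io import (MtAlignment, MutationRateTable, STRHaplotypeTable,
                 write_fasta_alignment, write_rate_table, write_str_table)
from .panels import DEFAULT_MUTATION_RATES, PANEL_17

logger = logging.getLogger("uniparental")


# ---------------------------------------------------------------------------
# Genealogies


@dataclass
class Genealogy:
    """Binary coalescent tree; node times in generations before present.

    Nodes 0..n-1 are tips; internal nodes are appended in merge order so
    the root is the last node.  ``parent[root]`` is -1.
    """

    n_tips: int
    parent: np.ndarray          # int, len 2n-1
    time: np.ndarray            # float generations, len 2n-1
    tip_labels: list[str]
    tip_population: list[str]
    split_time: float | None = None

    def __post_init__(self) -> None:
        n = self.n_tips
        if len(self.parent) != 2 * n - 1 or len(self.time) != 2 * n - 1:
            raise UniparentalError("genealogy arrays must have length 2n-1")
        for child, par in enumerate(self.parent):
            # zero-length branches allowed for degenerate fixtures
            if par >= 0 and not self.time[child] <= self.time[par]:
                raise UniparentalError("child time must be <= parent time")

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for child, par in enumerate(self.parent):
            if par >= 0:
                kids[par].append(child)
        return kids

    def branch_lengths(self) -> np.ndarray:
        """Generations from each non-root node up to its parent."""
        out = np.zeros(self.n_nodes)
        for child, par in enumerate(self.parent):
            if par >= 0:
                out[child] = self.time[par] - self.time[child]
        return out

    def tmrca_matrix(self) -> np.ndarray:
        """True pairwise TMRCA in generations between tips (zero diagonal)."""
        n = self.n_tips
        kids = self.children()
        tips_below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):  # tips first, then merge order = post-order
            tips_below[v] = [v] if v < n else sum((tips_below[c] for c in kids[v]), [])
        M = np.zeros((n, n))
        for v in range(n, self.n_nodes):
            c1, c2 = kids[v]
            for a in tips_below[c1]:
                for b in tips_below[c2]:
                    M[a, b] = M[b, a] = self.time[v]
        return M


def _finish_genealogy(n: int, parent, time, labels, pops, split_time=None) -> Genealogy:
    return Genealogy(n, np.asarray(parent), np.asarray(time, dtype=float),
                     labels, pops, split_time)


def simulate_coalescent(n: int, ne: float, seed_or_rng,
                        tip_labels: list[str] | None = None,
                        populations: list[str] | None = None) -> Genealogy:
    """Panmictic Kingman coalescent for ``n`` tips with haploid size ``ne``."""
    if n < 2 or ne <= 0:
        raise UniparentalError("need n >= 2 and N_e > 0")
    rng = np.random.default_rng(seed_or_rng)
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(ne / (k * (k - 1) / 2))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    labels = tip_labels or [f"S{i + 1:03d}" for i in range(n)]
    pops = populations or ["pop1"] * n
    return _finish_genealogy(n, parent, time, labels, pops)


def simulate_split(n_a: int, n_b: int, ne: float, split_time: float, seed_or_rng,
                   max_time: float = 1e8,
                   pop_names: tuple[str, str] = ("popA", "popB")) -> Genealogy:
    """Two-population clean split: panmixia before ``split_time`` generations.

    Backwards in time, lineages coalesce only within their population until
    ``split_time``, when the surviving lineages are pooled into the
    ancestral population.  Raises if no common ancestor is reached before
    ``max_time`` generations.
    """
    if split_time <= 0:
        raise UniparentalError("split_time must be > 0")
    g = _simulate_structured([n_a, n_b], ne, split_time, seed_or_rng,
                             max_time=max_time, pop_names=list(pop_names))
    return g


def _simulate_structured(ns: list[int], ne: float, split_time: float, seed_or_rng,
                         max_time: float = 1e8,
                         pop_names: list[str] | None = None) -> Genealogy:
    """Star-shaped population split: all demes separate until ``split_time``."""
    rng = np.random.default_rng(seed_or_rng)
    n = sum(ns)
    if n < 2 or ne <= 0:
        raise UniparentalError("need >= 2 tips and N_e > 0")
    pop_names = pop_names or [f"pop{i + 1}" for i in range(len(ns))]
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    pools: list[list[int]] = []
    tip_pops: list[str] = []
    start = 0
    for name, k in zip(pop_names, ns):
        pools.append(list(range(start, start + k)))
        tip_pops.extend([name] * k)
        start += k
    t = 0.0
    nxt = n
    pooled = False
    while sum(len(p) for p in pools) > 1:
        rates = [len(p) * (len(p) - 1) / 2 / ne for p in pools]
        total = sum(rates)
        if total == 0.0:
            wait = math.inf
        else:
            wait = rng.exponential(1.0 / total)
        if not pooled and t + wait >= split_time:
            t = split_time
            pools = [sum(pools, [])]
            pooled = True
            continue
        t += wait
        if t > max_time:
            raise UniparentalError(
                f"no common ancestor reached before max_time={max_time:g} generations")
        which = rng.choice(len(pools), p=np.array(rates) / total)
        pool = pools[which]
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        pools[which] = [x for x in pool if x not in (a, b)] + [nxt]
        nxt += 1
    labels = [f"{p}{i + 1:02d}" for p, i in
              zip(tip_pops, _within_pop_index(tip_pops))]
    return _finish_genealogy(n, parent, time, labels, tip_pops, split_time)


def _within_pop_index(pops: list[str]) -> list[int]:
    seen: dict[str, int] = {}
    out = []
    for p in pops:
        out.append(seen.get(p, 0))
        seen[p] = out[-1] + 1
    return out


# ---------------------------------------------------------------------------
# Mutation processes


def mutate_str(g: Genealogy, rates: MutationRateTable | dict, seed_or_rng,
               ancestral: float | dict[str, float] = 15.0,
               loci: list[str] | None = None,
               era: list[str] | None = None) -> STRHaplotypeTable:
    """Evolve STR haplotypes down the genealogy under the single-step SMM.

    Repeat counts reflect at the lower bound of 1 (a contraction at 1
    becomes an expansion; logged).  Returns a haplotype table for the tips.
    """
    rng = np.random.default_rng(seed_or_rng)
    rate_map = rates.rates if isinstance(rates, MutationRateTable) else dict(rates)
    loci = loci or list(rate_map)
    mu = np.array([rate_map[l] for l in loci])
    if (mu < 0).any():
        raise UniparentalError("mutation rates must be >= 0")
    if isinstance(ancestral, dict):
        root_h = np.array([float(ancestral[l]) for l in loci])
    else:
        root_h = np.full(len(loci), float(ancestral))
    if (root_h < 1).any():
        raise UniparentalError("ancestral repeat counts must be >= 1")
    kids = g.children()
    blen = g.branch_lengths()
    haplos = np.zeros((g.n_nodes, len(loci)))
    haplos[g.root] = root_h
    n_reflected = 0
    order = sorted(range(g.n_nodes), key=lambda v: -g.time[v])  # root first
    for v in order:
        for c in kids[v]:
            h = haplos[v].copy()
            counts = rng.poisson(mu * blen[c])
            for l_idx in np.flatnonzero(counts):
                for _ in range(counts[l_idx]):
                    step = 1 if rng.random() < 0.5 else -1
                    if h[l_idx] <= 1 and step == -1:
                        step = 1  # reflecting boundary at one repeat
                        n_reflected += 1
                    h[l_idx] += step
            haplos[c] = h
    if n_reflected:
        logger.info("%d SMM contractions reflected at the 1-repeat boundary",
                    n_reflected)
    era = era or ["modern"] * g.n_tips
    df = pd.DataFrame({
        "sample_id": g.tip_labels,
        "population": g.tip_population,
        "era": era,
    })
    for i, locus in enumerate(loci):
        df[locus] = haplos[:g.n_tips, i]
    return STRHaplotypeTable(df, list(loci))


def simulate_str_pairs(tmrca_generations: float, rates: np.ndarray, n_pairs: int,
                       seed_or_rng, ancestral: float = 15.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized SMM evolution of ``n_pairs`` haplotype pairs at a fixed TMRCA.

    Each lineage accumulates Poisson(mu*T) single-step mutations from a
    common ancestor; the net displacement of k steps is 2*Binomial(k,1/2)-k.
    Returns two (n_pairs x n_loci) repeat-count arrays.  The reflecting
    boundary is approximated by a final clip at 1 repeat, adequate whenever
    mu*T << ancestral (the regime of every bundled default).
    """
    rng = np.random.default_rng(seed_or_rng)
    mu = np.asarray(rates, dtype=float)
    out = []
    for _ in range(2):
        k = rng.poisson(mu * tmrca_generations, size=(n_pairs, len(mu)))
        net = 2 * rng.binomial(k, 0.5) - k
        out.append(np.maximum(ancestral + net, 1.0))
    return out[0], out[1]


_BASES = np.array(list("ACGT"))


def mutate_sequence(g: Genealogy, seq_rate: float, seq_length: int,
                    generation_time: float, seed_or_rng,
                    era: list[str] | None = None) -> MtAlignment:
    """Evolve sequences down the genealogy under a Jukes-Cantor strict clock.

    ``seq_rate`` is substitutions per site per year; branch lengths in
    generations are converted with ``generation_time``.  Multiple hits at a
    site are allowed (each substitution picks a uniformly different base).
    """
    if seq_length < 1:
        raise UniparentalError("seq_length must be >= 1")
    if seq_rate < 0:
        raise UniparentalError("seq_rate must be >= 0")
    rng = np.random.default_rng(seed_or_rng)
    kids = g.children()
    blen = g.branch_lengths()
    seqs = np.zeros((g.n_nodes, seq_length), dtype=np.int8)
    seqs[g.root] = rng.integers(0, 4, size=seq_length, dtype=np.int8)
    order = sorted(range(g.n_nodes), key=lambda v: -g.time[v])
    for v in order:
        for c in kids[v]:
            s = seqs[v].copy()
            n_sub = rng.poisson(seq_rate * blen[c] * generation_time * seq_length)
            if n_sub:
                sites = rng.integers(0, seq_length, size=n_sub)
                shifts = rng.integers(1, 4, size=n_sub, dtype=np.int8)
                for site, shift in zip(sites, shifts):
                    s[site] = (s[site] + shift) % 4
            seqs[c] = s
    era = era or ["modern"] * g.n_tips
    meta = pd.DataFrame({
        "sample_id": g.tip_labels,
        "population": g.tip_population,
        "era": era,
        "haplogroup_label": "",
    })
    chars = _BASES[seqs[:g.n_tips]].astype("<U1")
    return MtAlignment(meta, chars, mask_ranges=[])


# ---------------------------------------------------------------------------
# Fixture bundles


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic fixture.

    Defaults: four demes of 20 samples splitting 100 generations (~3 kyr)
    ago from a haploid-N_e = 5000 ancestral pool; the 17-locus panel with
    its bundled per-locus rates; full-length (16569 bp) mitogenomes under
    the coding-region-like strict clock of 1.708e-8 substitutions/site/year;
    a 30-year generation.
    """

    n_per_pop: list[int] = field(default_factory=lambda: [20, 20, 20, 20])
    pop_names: list[str] | None = None
    ne: float = 5000.0
    split_time: float = 100.0
    str_rates: dict[str, float] = field(
        default_factory=lambda: {l: DEFAULT_MUTATION_RATES[l] for l in PANEL_17})
    ancestral_repeat: float = 15.0
    seq_length: int = 16569
    seq_rate: float = 1.708e-8
    generation_time: float = 30.0
    n_ancient: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (self.ne, self.split_time, self.seq_length,
                                self.generation_time)):
            raise UniparentalError("ne, split_time, seq_length, generation_time "
                                   "must be positive")
        if self.seq_rate < 0:
            raise UniparentalError("seq_rate must be >= 0")
        if self.pop_names is None:
            self.pop_names = [f"pop{i + 1}" for i in range(len(self.n_per_pop))]
        if len(self.pop_names) != len(self.n_per_pop):
            raise UniparentalError("pop_names and n_per_pop lengths differ")


def generate_fixture(config: SimulationConfig, outdir: str | Path,
                     force: bool = False) -> dict[str, Path]:
    """Simulate a full input bundle and write it in the pipeline's formats.

    Writes ``str_table.tsv``, ``rates.tsv``, ``alignment.fasta``,
    ``metadata.tsv``, ``truth_tmrca.tsv`` (sample_i, sample_j, tmrca_years
    for both marker systems) and ``config.json``.  Two independent
    genealogies are drawn (Y and mtDNA are separate non-recombining
    systems).  With ``n_ancient`` > 0, that many tips of the first deme are
    labelled era=ancient in the metadata (they are simulated as
    contemporary tips; the label exercises the ancient-sample code paths).
    Deterministic: the same config (including seed) reproduces the bundle
    byte for byte.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise UniparentalError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    if config.n_ancient > config.n_per_pop[0]:
        raise UniparentalError("n_ancient exceeds the first deme's size")
    root_rng = np.random.default_rng(config.seed)
    seeds = root_rng.integers(0, 2 ** 31 - 1, size=4)

    g_y = _simulate_structured(list(config.n_per_pop), config.ne, config.split_time,
                               seeds[0], pop_names=list(config.pop_names))
    era = ["ancient" if (p == config.pop_names[0] and i < config.n_ancient) else "modern"
           for p, i in zip(g_y.tip_population, _within_pop_index(g_y.tip_population))]
    str_table = mutate_str(g_y, config.str_rates, seeds[1],
                           ancestral=config.ancestral_repeat, era=era)

    g_mt = _simulate_structured(list(config.n_per_pop), config.ne, config.split_time,
                                seeds[2], pop_names=list(config.pop_names))
    aln = mutate_sequence(g_mt, config.seq_rate, config.seq_length,
                          config.generation_time, seeds[3], era=era)

    paths = {
        "str_table": outdir / "str_table.tsv",
        "rates": outdir / "rates.tsv",
        "fasta": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth_tmrca.tsv",
        "config": outdir / "config.json",
    }
    write_str_table(str_table, paths["str_table"])
    write_rate_table(MutationRateTable(dict(config.str_rates)), paths["rates"])
    write_fasta_alignment(aln, paths["fasta"], paths["metadata"])

    rows = []
    for system, g in (("ystr", g_y), ("mtdna", g_mt)):
        T = g.tmrca_matrix() * config.generation_time
        for i in range(g.n_tips):
            for j in range(i + 1, g.n_tips):
                rows.append({"system": system,
                             "sample_i": g.tip_labels[i],
                             "sample_j": g.tip_labels[j],
                             "tmrca_years": T[i, j]})
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False,
                              float_format="%.6f")
    with open(paths["config"], "w") as fh:
        json.dump({**dataclasses.asdict(config),
                   "split_time_years": config.split_time * config.generation_time},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
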