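"""Mitogenome distances, haplotype sharing and haplotype networks.

Distances are plain nucleotide differences with pairwise deletion: a column
contributes only when both sequences carry an unambiguous base (A/C/G/T).
Haplotype classes are groups of letter-identical sequences — a conservative
rule under which an N never matches a base, so partially missing sequences
form their own classes.  Networks are minimum-spanning networks: a minimum
spanning tree over haplotype classes plus every alternative connection not
longer than the tree edge that first joined the two components (plus an
epsilon relaxation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UniparentalError
from .io import MtAlignment

logger = logging.getLogger("uniparental")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seqs: np.ndarray) -> np.ndarray:
    """Characters -> int8 codes; anything outside ACGT becomes -1."""
    out = np.full(seqs.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[seqs == base] = code
    return out


@dataclass
class MtDistanceMatrix:
    """Symmetric matrix of nucleotide differences (float to allow NaN)."""

    matrix: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.matrix.index)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def mt_pairwise_distance(aln: MtAlignment, ids: list[str] | None = None) -> MtDistanceMatrix:
    """Pairwise nucleotide differences with pairwise deletion of N/gaps.

    The mask should have been applied first (`io.apply_mask`); a pair with
    zero mutually unambiguous columns gets NaN with a warning.
    """
    if aln.mask_ranges:
        logger.warning("computing mtDNA distances on an unmasked alignment")
    E = _encode(aln.seqs)
    sample_ids = aln.sample_ids
    n = len(sample_ids)
    M = np.zeros((n, n))
    valid = E >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if not both.any():
                logger.warning("no comparable columns for pair (%s, %s)",
                               sample_ids[i], sample_ids[j])
                M[i, j] = M[j, i] = float("nan")
            else:
                M[i, j] = M[j, i] = int(((E[i] != E[j]) & both).sum())
    df = pd.DataFrame(M, index=sample_ids, columns=sample_ids)
    if ids is not None:
        df = df.loc[ids, ids]
    return MtDistanceMatrix(df)


# ---------------------------------------------------------------------------
# Haplotype classes


@dataclass
class HaplotypeClass:
    """A group of letter-identical sequences."""

    class_id: str
    members: list[str]
    representative: str  # sample_id of first member

    @property
    def size(self) -> int:
        return len(self.members)


def collapse_haplotypes(aln: MtAlignment) -> list[HaplotypeClass]:
    """Group sequences by exact letter identity (Ns do not match bases).

    Class ids are ``H001``, ``H002``, ... in order of first appearance.
    """
    seen: dict[str, HaplotypeClass] = {}
    classes: list[HaplotypeClass] = []
    for sid, row in zip(aln.sample_ids, aln.seqs):
        key = "".join(row)
        if key in seen:
            seen[key].members.append(sid)
        else:
            hc = HaplotypeClass(f"H{len(classes) + 1:03d}", [sid], sid)
            seen[key] = hc
            classes.append(hc)
    return classes


def class_membership(classes: list[HaplotypeClass]) -> pd.Series:
    """sample_id -> class_id."""
    pairs = [(sid, hc.class_id) for hc in classes for sid in hc.members]
    return pd.Series(dict(pairs), name="class_id")


def class_distance_matrix(aln: MtAlignment, classes: list[HaplotypeClass]) -> MtDistanceMatrix:
    """Distances between class representatives (one sequence per class)."""
    reps = [hc.representative for hc in classes]
    dm = mt_pairwise_distance(aln, ids=reps).matrix
    ids = [hc.class_id for hc in classes]
    dm.index = ids
    dm.columns = ids
    return MtDistanceMatrix(dm)


def mt_sharing_table(classes: list[HaplotypeClass], meta: pd.DataFrame) -> pd.DataFrame:
    """Shared-haplotype counts and relative frequencies per population pair.

    For each unordered population pair (A != B): number of haplotype classes
    with at least one member in each, the number of individuals those
    classes contribute in A and in B, and those counts divided by the
    population sizes.  Rows with pop_a == pop_b report within-population
    sharing: classes with >= 2 members in the population.
    """
    pop_of = meta.set_index("sample_id")["population"]
    pops = sorted(pop_of.unique())
    sizes = pop_of.value_counts()
    per_class = []
    for hc in classes:
        per_class.append(pop_of.loc[hc.members].value_counts())
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i:]:
            if a == b:
                shared = [c for c in per_class if c.get(a, 0) >= 2]
                n_ind_a = n_ind_b = sum(int(c[a]) for c in shared)
            else:
                shared = [c for c in per_class if c.get(a, 0) >= 1 and c.get(b, 0) >= 1]
                n_ind_a = sum(int(c[a]) for c in shared)
                n_ind_b = sum(int(c[b]) for c in shared)
            rows.append({
                "pop_a": a, "pop_b": b,
                "shared_classes": len(shared),
                "shared_individuals_a": n_ind_a,
                "shared_individuals_b": n_ind_b,
                "freq_a": n_ind_a / sizes[a],
                "freq_b": n_ind_b / sizes[b],
            })
    return pd.DataFrame(rows)


def haplogroup_frequencies(meta: pd.DataFrame, pool_ancient: bool = False
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Major-haplogroup frequencies and sub-haplogroup counts per population.

    The major haplogroup is the first letter of the supplied label (A/B/C/D
    for Native American mitogenomes).  Unlabeled samples are tallied in an
    ``unassigned`` count column and excluded from the frequencies, which
    therefore sum to 1 over assigned haplogroups.  With ``pool_ancient``,
    all era=ancient samples are pooled into a single ``ancient`` row.
    """
    meta = meta.copy()
    labels = meta["haplogroup_label"].fillna("").astype(str).str.strip()
    n_unassigned = int((labels == "").sum())
    if n_unassigned:
        logger.warning("%d samples without haplogroup label counted as unassigned",
                       n_unassigned)
    meta["_major"] = labels.str[:1]
    group = meta["population"].copy()
    if pool_ancient:
        group[meta["era"] == "ancient"] = "ancient"
    meta["_group"] = group

    majors = sorted(m for m in meta["_major"].unique() if m)
    freq_rows, sub_rows = [], []
    for g, grp in meta.groupby("_group", sort=True):
        assigned = grp[grp["_major"] != ""]
        row = {"population": g, "n": len(grp),
               "unassigned": int((grp["_major"] == "").sum())}
        for m in majors:
            row[m] = (len(assigned[assigned["_major"] == m]) / len(assigned)
                      if len(assigned) else float("nan"))
        freq_rows.append(row)
        for label, cnt in grp.loc[grp["_major"] != "", "haplogroup_label"].value_counts().items():
            sub_rows.append({"population": g, "haplogroup": label, "count": int(cnt)})
    freq = pd.DataFrame(freq_rows).set_index("population")
    sub = pd.DataFrame(sub_rows, columns=["population", "haplogroup", "count"])
    return freq, sub.sort_values(["population", "haplogroup"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Minimum-spanning haplotype networks


def msn_network(dist: MtDistanceMatrix, classes: list[HaplotypeClass],
                meta: pd.DataFrame, epsilon: int = 0) -> nx.Graph:
    """Minimum-spanning network over haplotype classes.

    Contains a minimum spanning tree of the complete class-distance graph
    plus every edge (u, v) whose length is at most the minimax path length
    between u and v on the MST (the length of the edge that merged their
    components in Kruskal's algorithm) plus ``epsilon``.  With epsilon=0
    this adds exactly the alternative equally-short connections; large
    epsilon tends to the complete graph.

    Node attributes: ``size``, ``members`` (comma-joined sample ids),
    ``populations`` and ``eras`` (composition strings "pop:count").
    Edge attribute ``steps`` is the mutation-step distance.
    """
    ids = dist.ids
    D = dist.matrix.to_numpy()
    if np.isnan(D).any():
        raise UniparentalError("class distance matrix contains NaN")
    n = len(ids)
    complete = nx.Graph()
    complete.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            complete.add_edge(ids[i], ids[j], weight=float(D[i, j]))
    mst = nx.minimum_spanning_tree(complete, weight="weight") if n > 1 else complete

    # minimax path length between every pair on the MST
    minimax: dict[tuple[str, str], float] = {}
    for src in ids:
        best = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, attrs in mst[u].items():
                if v not in best:
                    best[v] = max(best[u], attrs["weight"])
                    stack.append(v)
        for v, w in best.items():
            minimax[(src, v)] = w

    g = nx.Graph()
    by_id = {hc.class_id: hc for hc in classes}
    pop_of = meta.set_index("sample_id")["population"]
    era_of = meta.set_index("sample_id")["era"]
    for cid in ids:
        hc = by_id[cid]
        pcounts = pop_of.loc[hc.members].value_counts()
        ecounts = era_of.loc[hc.members].value_counts()
        g.add_node(cid, size=hc.size,
                   members=",".join(hc.members),
                   populations=";".join(f"{p}:{c}" for p, c in sorted(pcounts.items())),
                   eras=";".join(f"{e}:{c}" for e, c in sorted(ecounts.items())))
    for i in range(n):
        for j in range(i + 1, n):
            u, v = ids[i], ids[j]
            if D[i, j] <= minimax[(u, v)] + epsilon:
                g.add_edge(u, v, steps=float(D[i, j]))
    return g


def network_edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [{"class_a": u, "class_b": v, "steps": d["steps"]}
            for u, v, d in g.edges(data=True)]
    return (pd.DataFrame(rows, columns=["class_a", "class_b", "steps"])
            .sort_values(["class_a", "class_b"]).reset_index(drop=True))


def write_network(g: nx.Graph, graphml_path, edges_path) -> None:
    nx.write_graphml(g, str(graphml_path))
    network_edge_list(g).to_csv(edges_path, sep="\t", index=False)


def closest_to_ancient(dist: MtDistanceMatrix, classes: list[HaplotypeClass],
                       meta: pd.DataFrame, max_steps: int) -> pd.DataFrame:
    """Modern haplotype classes within ``max_steps`` of each ancient sample.

    ``dist`` is the class-level distance matrix.  Each ancient sample yields
    one row per modern class within the threshold (columns: ancient_id,
    class_id, steps, class_size); ancient samples with no hit keep a single
    row with empty class_id so they remain visible in the report.
    """
    era_of = meta.set_index("sample_id")["era"]
    membership = class_membership(classes)
    by_id = {hc.class_id: hc for hc in classes}
    ancient_ids = [s for s in membership.index if era_of.get(s) == "ancient"]
    if not ancient_ids:
        raise UniparentalError("no ancient samples in metadata")
    modern_classes = [hc.class_id for hc in classes
                      if any(era_of.get(m) == "modern" for m in hc.members)]
    rows = []
    for aid in ancient_ids:
        acls = membership[aid]
        hits = []
        for cid in modern_classes:
            d = dist.matrix.loc[acls, cid]
            if not np.isnan(d) and d <= max_steps:
                hits.append((cid, float(d)))
        if not hits:
            rows.append({"ancient_id": aid, "class_id": "", "steps": float("nan"),
                         "class_size": 0})
        for cid, d in sorted(hits, key=lambda t: (t[1], t[0])):
            rows.append({"ancient_id": aid, "class_id": cid, "steps": d,
                         "class_size": by_id[cid].size})
    return pd.DataFrame(rows, columns=["ancient_id", "class_id", "steps", "class_size"])
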