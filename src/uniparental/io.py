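"""Input/output and data curation.

Reads tab-separated Y-STR haplotype tables, per-locus mutation-rate tables,
multi-FASTA mitogenome alignments with sample metadata, and applies the
curation filters used throughout: a missing-locus cap for modern STR
haplotypes, a missing-base cap for mitogenomes, and removal of the
hypervariable poly-C alignment columns.

Missing STR alleles are encoded as empty cells or ``NA`` on disk and as NaN
in memory; alleles may be non-integral (intermediate alleles such as 15.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .config import DEFAULT_MT_MASK
from .errors import UniparentalError
from .panels import DEFAULT_MUTATION_RATES

logger = logging.getLogger("uniparental")

ERAS = ("modern", "ancient")
_META_COLS = ["sample_id", "population", "era"]


# ---------------------------------------------------------------------------
# Y-STR haplotype tables


@dataclass
class STRHaplotypeTable:
    """Individuals x loci repeat counts with population and era labels.

    ``data`` holds one row per individual with columns ``sample_id``,
    ``population``, ``era`` followed by one float column per locus
    (NaN = missing allele).
    """

    data: pd.DataFrame
    loci: list[str]

    def __post_init__(self) -> None:
        if len(self.loci) != len(set(self.loci)):
            raise UniparentalError("locus names must be unique")
        missing = [c for c in _META_COLS + self.loci if c not in self.data.columns]
        if missing:
            raise UniparentalError(f"table lacks columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            dupes = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise UniparentalError(f"duplicate sample_id: {sorted(set(dupes))}")
        bad_era = set(self.data["era"]) - set(ERAS)
        if bad_era:
            raise UniparentalError(f"unknown era labels: {sorted(bad_era)}")
        vals = self.data[self.loci].to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise UniparentalError("repeat counts must be >= 0")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    def repeats(self) -> pd.DataFrame:
        """Repeat counts only, indexed by sample_id."""
        return self.data.set_index("sample_id")[self.loci].astype(float)

    def population_era(self) -> dict[str, str]:
        """Population -> ``ancient`` if every member is ancient, else ``modern``."""
        out = {}
        for pop, grp in self.data.groupby("population"):
            out[pop] = "ancient" if (grp["era"] == "ancient").all() else "modern"
        return out

    def subset_population(self, population: str) -> "STRHaplotypeTable":
        sub = self.data[self.data["population"] == population].reset_index(drop=True)
        return STRHaplotypeTable(sub, list(self.loci))

    def subset_loci(self, loci: list[str]) -> "STRHaplotypeTable":
        unknown = [l for l in loci if l not in self.loci]
        if unknown:
            raise UniparentalError(f"loci not in table: {unknown}")
        return STRHaplotypeTable(self.data[_META_COLS + list(loci)].copy(), list(loci))


def read_str_table(path: str | Path, panel: list[str] | None = None) -> STRHaplotypeTable:
    """Read a tab-separated haplotype table.

    Header must contain ``sample_id`` and ``population``; ``era`` is optional
    (default ``modern``); every other column is a locus.  Unparseable allele
    cells become missing with a logged warning.  If ``panel`` is given, the
    table is restricted to those loci and every panel locus must be present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise UniparentalError(f"{path}: missing required column {col!r}")
    if "era" not in df.columns:
        df["era"] = "modern"
    loci = [c for c in df.columns if c not in _META_COLS]
    if panel is not None:
        absent = [l for l in panel if l not in loci]
        if absent:
            raise UniparentalError(f"{path}: panel loci absent from file: {absent}")
        loci = list(panel)
    out = df[_META_COLS].copy()
    for locus in loci:
        raw = df[locus].str.strip()
        vals = pd.to_numeric(raw.replace({"": None, "NA": None}), errors="coerce")
        bad = vals.isna() & ~raw.isin(["", "NA"])
        if bad.any():
            for sid, cell in zip(df.loc[bad, "sample_id"], raw[bad]):
                logger.warning("unparseable allele %r at %s/%s treated as missing",
                               cell, sid, locus)
        out[locus] = vals.astype(float)
    return STRHaplotypeTable(out, loci)


def write_str_table(table: STRHaplotypeTable, path: str | Path) -> None:
    """Write in the same TSV dialect; missing alleles as empty cells."""
    df = table.data.copy()
    for locus in table.loci:
        df[locus] = df[locus].map(
            lambda v: "" if pd.isna(v) else (f"{v:g}")
        )
    df.to_csv(path, sep="\t", index=False)


def filter_str_missing(table: STRHaplotypeTable, max_missing_loci: int = 2) -> STRHaplotypeTable:
    """Drop modern haplotypes with more than ``max_missing_loci`` missing loci.

    Ancient samples are retained regardless; downstream comparisons use
    per-pair locus intersection.
    """
    n_missing = table.data[table.loci].isna().sum(axis=1)
    drop = (table.data["era"] == "modern") & (n_missing > max_missing_loci)
    for sid in table.data.loc[drop, "sample_id"]:
        logger.warning("dropping modern sample %s: %d missing loci",
                       sid, int(n_missing[table.data["sample_id"] == sid].iloc[0]))
    kept = table.data[~drop].reset_index(drop=True)
    return STRHaplotypeTable(kept, list(table.loci))


# ---------------------------------------------------------------------------
# Mutation rates


@dataclass
class MutationRateTable:
    """Per-locus mutation rates, mutations per generation."""

    rates: dict[str, float]

    def __post_init__(self) -> None:
        for locus, rate in self.rates.items():
            if not rate > 0:
                raise UniparentalError(f"mutation rate for {locus} must be > 0, got {rate}")

    def __getitem__(self, locus: str) -> float:
        try:
            return self.rates[locus]
        except KeyError:
            raise UniparentalError(f"no mutation rate for locus {locus!r}") from None

    def __contains__(self, locus: str) -> bool:
        return locus in self.rates

    def vector(self, loci: list[str]) -> np.ndarray:
        return np.array([self[l] for l in loci], dtype=float)

    @classmethod
    def default(cls) -> "MutationRateTable":
        return cls(dict(DEFAULT_MUTATION_RATES))


def read_rate_table(path: str | Path) -> MutationRateTable:
    df = pd.read_csv(path, sep="\t")
    if not {"locus", "rate"} <= set(df.columns):
        raise UniparentalError(f"{path}: rate table needs columns 'locus' and 'rate'")
    return MutationRateTable(dict(zip(df["locus"], df["rate"].astype(float))))


def write_rate_table(rates: MutationRateTable, path: str | Path) -> None:
    pd.DataFrame(
        {"locus": list(rates.rates), "rate": list(rates.rates.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mitogenome alignments


@dataclass
class MtAlignment:
    """Aligned mitogenomes with per-sample metadata and a column mask.

    ``seqs`` is an (n_samples, n_columns) array of single uppercase
    characters over {A,C,G,T,N,-}; ``meta`` has one row per sequence with
    ``sample_id``, ``population``, ``era`` and optional ``haplogroup_label``.
    ``mask_ranges`` are 1-based inclusive position intervals still to be
    removed; ``column_positions`` maps current columns to original 1-based
    positions (kept across apply_mask so coordinates remain interpretable).
    """

    meta: pd.DataFrame
    seqs: np.ndarray
    mask_ranges: list[tuple[int, int]] = field(default_factory=lambda: list(DEFAULT_MT_MASK))
    column_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.seqs.ndim != 2:
            raise UniparentalError("seqs must be a 2-D character array")
        if len(self.meta) != self.seqs.shape[0]:
            raise UniparentalError("metadata rows != number of sequences")
        for col in ("sample_id", "population", "era"):
            if col not in self.meta.columns:
                raise UniparentalError(f"alignment metadata lacks column {col!r}")
        if "haplogroup_label" not in self.meta.columns:
            self.meta = self.meta.copy()
            self.meta["haplogroup_label"] = ""
        if self.meta["sample_id"].duplicated().any():
            raise UniparentalError("duplicate sample_id in alignment metadata")
        L = self.seqs.shape[1]
        for lo, hi in self.mask_ranges:
            if not (1 <= lo <= hi <= max(L, 1)):
                raise UniparentalError(f"mask range ({lo},{hi}) outside [1,{L}]")
        if self.column_positions is None:
            self.column_positions = np.arange(1, L + 1)
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_columns(self) -> int:
        return self.seqs.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta["sample_id"])

    def sequence(self, sample_id: str) -> str:
        idx = self.meta.index[self.meta["sample_id"] == sample_id]
        if len(idx) == 0:
            raise UniparentalError(f"no such sample {sample_id!r}")
        return "".join(self.seqs[idx[0]])

    def masked_columns(self) -> np.ndarray:
        """Boolean vector: True where the column falls in a mask range."""
        pos = self.column_positions
        out = np.zeros(self.n_columns, dtype=bool)
        for lo, hi in self.mask_ranges:
            out |= (pos >= lo) & (pos <= hi)
        return out

    def subset(self, keep: np.ndarray) -> "MtAlignment":
        return MtAlignment(
            self.meta.loc[keep].reset_index(drop=True),
            self.seqs[keep],
            list(self.mask_ranges),
            self.column_positions.copy(),
        )


def read_fasta_alignment(path: str | Path, metadata_path: str | Path,
                         mask_ranges: list[tuple[int, int]] | None = None) -> MtAlignment:
    """Read a multi-FASTA alignment and join per-sample metadata.

    All records must have equal length and every record ID must appear in
    the metadata table (TSV with ``sample_id``, ``population``, optional
    ``era`` and ``haplogroup_label``).  Sequences are upper-cased.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise UniparentalError(f"{path}: no FASTA records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise UniparentalError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in meta.columns or "population" not in meta.columns:
        raise UniparentalError(f"{metadata_path}: needs sample_id and population columns")
    if "era" not in meta.columns:
        meta["era"] = "modern"
    meta = meta.set_index("sample_id", drop=False)
    rows = []
    for rec in records:
        if rec.id not in meta.index:
            raise UniparentalError(f"record {rec.id!r} absent from metadata")
        rows.append(meta.loc[rec.id])
    joined = pd.DataFrame(rows).reset_index(drop=True)
    seqs = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
    if mask_ranges is None:
        # default poly-C mask lives on reference coordinates; alignments
        # shorter than the reference simply do not contain those positions
        L = seqs.shape[1]
        mask_ranges = [(lo, min(hi, L)) for lo, hi in DEFAULT_MT_MASK if lo <= L]
    return MtAlignment(joined, seqs, mask_ranges)


def write_fasta_alignment(aln: MtAlignment, fasta_path: str | Path,
                          metadata_path: str | Path | None = None) -> None:
    with open(fasta_path, "w") as fh:
        for sid, row in zip(aln.sample_ids, aln.seqs):
            fh.write(f">{sid}\n")
            seq = "".join(row)
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    if metadata_path is not None:
        cols = ["sample_id", "population", "era", "haplogroup_label"]
        aln.meta[cols].to_csv(metadata_path, sep="\t", index=False)


def _missing_per_sample(aln: MtAlignment) -> np.ndarray:
    unmasked = ~aln.masked_columns()
    is_missing = (aln.seqs == "N") | (aln.seqs == "-")
    return is_missing[:, unmasked].sum(axis=1)


def filter_mt_missing(aln: MtAlignment, max_missing_bases: int = 5) -> MtAlignment:
    """Drop samples with more than ``max_missing_bases`` N/gap characters.

    Masked poly-C columns are excluded before counting, so missingness
    confined to the hypervariable stretches never disqualifies a sample.
    """
    n_missing = _missing_per_sample(aln)
    keep = n_missing <= max_missing_bases
    for sid, nm in zip(np.array(aln.sample_ids)[~keep], n_missing[~keep]):
        logger.warning("dropping sample %s: %d missing bases outside mask", sid, int(nm))
    return aln.subset(keep)


def _merge_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ranges:
        return []
    ranges = sorted(ranges)
    merged = [list(ranges[0])]
    for lo, hi in ranges[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(r) for r in merged]


def apply_mask(aln: MtAlignment, ref_id: str | None = None) -> MtAlignment:
    """Delete masked columns; overlapping ranges are merged first.

    Mask positions are 1-based reference coordinates.  If ``ref_id`` names a
    row of the alignment, positions are mapped through that row's non-gap
    columns (insertions relative to the reference are untouched); otherwise
    positions index alignment columns directly.
    """
    ranges = _merge_ranges(aln.mask_ranges)
    if not ranges:
        return replace(aln, mask_ranges=[])
    if ref_id is not None:
        ridx = aln.meta.index[aln.meta["sample_id"] == ref_id]
        if len(ridx) == 0:
            raise UniparentalError(f"reference row {ref_id!r} not in alignment")
        ref = aln.seqs[ridx[0]]
        ref_cols = np.flatnonzero(ref != "-")  # reference position p -> column
        drop = np.zeros(aln.n_columns, dtype=bool)
        for lo, hi in ranges:
            if hi > len(ref_cols):
                raise UniparentalError(f"mask range ({lo},{hi}) beyond reference length")
            drop[ref_cols[lo - 1:hi]] = True
    else:
        pos = aln.column_positions
        drop = np.zeros(aln.n_columns, dtype=bool)
        for lo, hi in ranges:
            drop |= (pos >= lo) & (pos <= hi)
    if drop.all():
        raise UniparentalError("mask covers the whole alignment: no columns remain")
    keep = ~drop
    return MtAlignment(
        aln.meta.copy(),
        aln.seqs[:, keep],
        [],
        aln.column_positions[keep],
    )
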