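"""End-to-end runs: curation, Y-STR arm, mtDNA arm, with a run manifest.

Every run writes a ``manifest.json`` recording the configuration snapshot,
SHA-256 hashes of the inputs, the list of outputs, the median-filter
thresholds applied, and all warnings emitted — so each output is traceable
to inputs and configuration.  Tabular outputs are sorted by population then
sample id for byte-stable diffs; reruns with identical inputs and seed are
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io, mtdna, rst, ystr
from .config import RunConfig
from .errors import UniparentalError
from .panels import PANEL_17

logger = logging.getLogger("uniparental")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _write_manifest(outdir: Path, config: RunConfig, inputs: dict[str, Path],
                    outputs: list[Path], medians: dict[str, float | None],
                    warnings: list[str]) -> Path:
    manifest = {
        "config": config.to_dict(),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "outputs": sorted(str(p.relative_to(outdir)) for p in outputs),
        "median_thresholds": medians,
        "warnings": warnings,
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_ystr(config: RunConfig, str_path: str | Path, rates_path: str | Path | None,
             outdir: str | Path, panel: list[str] | None = None,
             rst_loci: list[str] | None = None) -> dict[str, Path]:
    """Full Y-STR arm: curation, diversity, sharing per bin, R_ST + NJ,
    and the all-individual distance matrix on the full panel.

    ``rst_loci`` defaults to the 17-locus subset (when present in the
    table), mirroring the practice of computing R_ST on the common
    17-locus denominator of heterogeneous published datasets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logger.addHandler(collector)
    try:
        table = io.read_str_table(str_path, panel=panel)
        rates = (io.read_rate_table(rates_path) if rates_path is not None
                 else io.MutationRateTable.default())
        table = io.filter_str_missing(table, config.max_missing_loci)
        table.data = table.data.sort_values(
            ["population", "sample_id"]).reset_index(drop=True)

        outputs: list[Path] = []
        medians: dict[str, float | None] = {}

        div = ystr.diversity_report(table)
        p = outdir / "diversity_report.tsv"
        div.to_csv(p, sep="\t", float_format="%.6f")
        outputs.append(p)

        sm_id = ystr.sharing_matrix(table, "identical", config=config)
        p = outdir / "sharing_identical.tsv"
        sm_id.to_tsv(p)
        outputs.append(p)
        p = outdir / "sharing_identical_edges.tsv"
        sm_id.edge_list().to_csv(p, sep="\t", index=False, float_format="%.6f")
        outputs.append(p)

        for bound in config.tmrca_bins:
            sm = ystr.sharing_matrix(table, "tmrca_lt", threshold=bound,
                                     rates=rates, config=config)
            filt = ystr.median_filter(sm)
            medians[f"tmrca_lt_{bound:g}"] = filt.median_threshold
            p = outdir / f"sharing_tmrca_lt_{bound:g}.tsv"
            sm.to_tsv(p)
            outputs.append(p)
            p = outdir / f"sharing_tmrca_lt_{bound:g}_edges_above_median.tsv"
            edges = filt.edge_list()
            edges[edges["frequency"] > 0].to_csv(p, sep="\t", index=False,
                                                 float_format="%.6f")
            outputs.append(p)

        use_rst_loci = rst_loci
        if use_rst_loci is None and set(PANEL_17) <= set(table.loci):
            use_rst_loci = PANEL_17
        dist = rst.rst_matrix(table, loci=use_rst_loci, min_pop=config.min_pop_size_rst)
        p = outdir / "rst_matrix.tsv"
        dist.to_tsv(p)
        outputs.append(p)
        if len(dist.populations) >= 3:
            tree = rst.nj_tree(dist)
            p = outdir / "rst_nj.nwk"
            rst.write_newick(tree, p)
            outputs.append(p)
        else:
            logger.warning("fewer than 3 populations after R_ST exclusions: no NJ tree")

        idm = ystr.individual_distance_matrix(table)
        p = outdir / "individual_distances.tsv"
        idm.to_tsv(p)
        outputs.append(p)
    except UniparentalError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise UniparentalError(f"Y-STR arm failed: {exc}") from exc
    finally:
        logger.removeHandler(collector)

    inputs = {"str_table": Path(str_path)}
    if rates_path is not None:
        inputs["rates"] = Path(rates_path)
    manifest = _write_manifest(outdir, config, inputs, outputs, medians,
                               collector.messages)
    return {"outdir": outdir, "manifest": manifest}


def run_mtdna(config: RunConfig, fasta_path: str | Path, metadata_path: str | Path,
              outdir: str | Path) -> dict[str, Path]:
    """Full mtDNA arm: masking, curation, distances, haplotype sharing,
    haplogroup frequencies, and minimum-spanning networks with an
    ancient-proximity report when ancient samples are present."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logger.addHandler(collector)
    try:
        aln = io.read_fasta_alignment(fasta_path, metadata_path)
        aln = io.filter_mt_missing(aln, config.max_missing_bases)
        n_before = aln.n_columns
        aln = io.apply_mask(aln)
        order = aln.meta.sort_values(["population", "sample_id"]).index.to_numpy()
        aln = aln.subset(order)

        outputs: list[Path] = []
        stats = {
            "n_samples": len(aln),
            "columns_before_mask": n_before,
            "columns_after_mask": aln.n_columns,
        }
        p = outdir / "alignment_stats.json"
        with open(p, "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs.append(p)

        dist = mtdna.mt_pairwise_distance(aln)
        p = outdir / "mt_distances.tsv"
        dist.to_tsv(p)
        outputs.append(p)

        classes = mtdna.collapse_haplotypes(aln)
        membership = mtdna.class_membership(classes)
        p = outdir / "haplotype_classes.tsv"
        membership.rename_axis("sample_id").to_frame().to_csv(p, sep="\t")
        outputs.append(p)

        share = mtdna.mt_sharing_table(classes, aln.meta)
        p = outdir / "mt_sharing.tsv"
        share.to_csv(p, sep="\t", index=False, float_format="%.6f")
        outputs.append(p)

        freq, sub = mtdna.haplogroup_frequencies(aln.meta, pool_ancient=True)
        p = outdir / "haplogroup_frequencies.tsv"
        freq.to_csv(p, sep="\t", float_format="%.6f")
        outputs.append(p)
        p = outdir / "subhaplogroup_counts.tsv"
        sub.to_csv(p, sep="\t", index=False)
        outputs.append(p)

        cdist = mtdna.class_distance_matrix(aln, classes)
        net = mtdna.msn_network(cdist, classes, aln.meta, epsilon=config.msn_epsilon)
        mtdna.write_network(net, outdir / "network.graphml", outdir / "network_edges.tsv")
        outputs += [outdir / "network.graphml", outdir / "network_edges.tsv"]

        if (aln.meta["era"] == "ancient").any():
            close = mtdna.closest_to_ancient(cdist, classes, aln.meta,
                                             max_steps=config.ancient_max_steps)
            p = outdir / "closest_to_ancient.tsv"
            close.to_csv(p, sep="\t", index=False, float_format="%.6f")
            outputs.append(p)
    except UniparentalError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise UniparentalError(f"mtDNA arm failed: {exc}") from exc
    finally:
        logger.removeHandler(collector)

    manifest = _write_manifest(
        outdir, config,
        {"fasta": Path(fasta_path), "metadata": Path(metadata_path)},
        outputs, {}, collector.messages)
    return {"outdir": outdir, "manifest": manifest}
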