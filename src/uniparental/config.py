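"""Run configuration shared by the Y-STR and mtDNA analysis arms."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import UniparentalError

#: poly-C stretches excluded from all mitogenome comparisons, 1-based
#: inclusive nucleotide positions on the reference-aligned coordinate system
DEFAULT_MT_MASK = [(302, 315), (16183, 16194)]


@dataclass
class RunConfig:
    """Parameters governing curation filters and the tMRCA time bins.

    Attributes
    ----------
    generation_time
        Years per generation used to convert coalescent generations to
        calendar years.
    tmrca_bins
        Strictly increasing year thresholds; each defines a half-open
        sharing criterion ``tMRCA < T``.
    max_missing_loci
        Modern Y-STR haplotypes with more missing loci than this are
        dropped (ancient samples are exempt and handled by per-comparison
        locus intersection).
    max_missing_bases
        Mitogenomes with more N/gap characters than this outside the
        masked poly-C regions are dropped.
    min_pop_size
        Modern populations below this size are excluded from
        population-level summaries (``min_pop_size_rst`` applies to the
        R_ST arm); ancient populations are exempt.
    """

    generation_time: float = 30.0
    tmrca_bins: list[float] = field(default_factory=lambda: [500.0, 1000.0, 2000.0])
    max_missing_loci: int = 2
    max_missing_bases: int = 5
    min_pop_size: int = 5
    min_pop_size_rst: int = 4
    msn_epsilon: int = 0
    ancient_max_steps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        bins = [float(b) for b in self.tmrca_bins]
        if any(b < 0 for b in bins):
            raise UniparentalError("tmrca_bins thresholds must be >= 0")
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise UniparentalError("tmrca_bins must be strictly increasing")
        self.tmrca_bins = bins
        if self.generation_time <= 0:
            raise UniparentalError("generation_time must be positive")
        for name in ("max_missing_loci", "max_missing_bases",
                     "min_pop_size", "min_pop_size_rst", "msn_epsilon",
                     "ancient_max_steps"):
            if getattr(self, name) < 0:
                raise UniparentalError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise UniparentalError(f"config file {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise UniparentalError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
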