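"""Standard forensic Y-STR locus panels and default per-locus mutation rates.

The 17-locus panel corresponds to the Yfiler marker set; the 23-locus panel
to PowerPlex Y23, which adds six rapidly mutating loci.  The multi-copy locus
DYS385 is represented as two pseudo-loci ``DYS385a``/``DYS385b`` with the
smaller allele stored first, so every haplotype is a flat vector of repeat
counts.

Default mutation rates are locus-wise father–son estimates of the kind
curated by the YHRD registry, in mutations per locus per generation.  They
are configuration, not constants: any analysis accepts an explicit rate
table that overrides these values.
"""

PANEL_17 = [
    "DYS19", "DYS385a", "DYS385b", "DYS389I", "DYS389II", "DYS390",
    "DYS391", "DYS392", "DYS393", "DYS437", "DYS438", "DYS439",
    "DYS448", "DYS456", "DYS458", "DYS635", "YGATAH4",
]

PANEL_23 = PANEL_17 + [
    "DYS481", "DYS533", "DYS549", "DYS570", "DYS576", "DYS643",
]

# mutations / locus / generation
DEFAULT_MUTATION_RATES = {
    "DYS19": 2.3e-3,
    "DYS385a": 2.1e-3,
    "DYS385b": 2.1e-3,
    "DYS389I": 2.5e-3,
    "DYS389II": 3.6e-3,
    "DYS390": 2.1e-3,
    "DYS391": 2.6e-3,
    "DYS392": 6.0e-4,
    "DYS393": 1.1e-3,
    "DYS437": 1.3e-3,
    "DYS438": 4.0e-4,
    "DYS439": 5.1e-3,
    "DYS448": 1.7e-3,
    "DYS456": 4.4e-3,
    "DYS458": 6.9e-3,
    "DYS635": 3.8e-3,
    "YGATAH4": 2.8e-3,
    "DYS481": 5.0e-3,
    "DYS533": 4.1e-3,
    "DYS549": 4.2e-3,
    "DYS570": 1.24e-2,
    "DYS576": 1.43e-2,
    "DYS643": 1.2e-3,
}
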