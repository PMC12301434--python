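import numpy as np
import pandas as pd
import pytest

from uniparental.io import MutationRateTable, STRHaplotypeTable


def make_str_table(haplotypes, populations, loci=None, eras=None, ids=None):
    """Build an STRHaplotypeTable from a list of repeat-count vectors."""
    haplotypes = [list(h) for h in haplotypes]
    n_loci = len(haplotypes[0])
    loci = loci or [f"L{i + 1}" for i in range(n_loci)]
    df = pd.DataFrame({
        "sample_id": ids or [f"S{i + 1:03d}" for i in range(len(haplotypes))],
        "population": populations,
        "era": eras or ["modern"] * len(haplotypes),
    })
    for i, locus in enumerate(loci):
        df[locus] = pd.Series([h[i] for h in haplotypes], dtype=float)
    return STRHaplotypeTable(df, loci)


def make_alignment(seqs, populations=None, eras=None, haplogroups=None,
                   mask_ranges=()):
    """Build an MtAlignment from equal-length sequence strings."""
    from uniparental.io import MtAlignment

    n = len(seqs)
    meta = pd.DataFrame({
        "sample_id": [f"M{i + 1:03d}" for i in range(n)],
        "population": populations or ["P"] * n,
        "era": eras or ["modern"] * n,
        "haplogroup_label": haplogroups or [""] * n,
    })
    arr = np.array([list(s) for s in seqs], dtype="<U1")
    return MtAlignment(meta, arr, list(mask_ranges))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def flat_rates():
    return MutationRateTable({f"L{i + 1}": 0.002 for i in range(17)})
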