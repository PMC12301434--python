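# uniparental

Population-history analysis of uniparental markers: Y-chromosomal STR
haplotypes and complete mitogenomes. The package is aimed at population
geneticists who work with forensic-style Y-STR panels and aligned mtDNA
sequences and want reproducible, scriptable versions of the standard
descriptive analyses: individual-level coalescent-time estimates, haplotype
sharing between populations, AMOVA-based population distances with
neighbor-joining trees, and haplotype networks linking modern and ancient
samples. A built-in coalescent simulator with recorded ground truth
validates every estimator.

## The statistics

**ASD tMRCA.** Under a single-step symmetric stepwise mutation model (SMM),
the repeat counts of two Y-STR haplotypes that diverged *T* generations ago
satisfy E[(x₁ₗ − x₂ₗ)²] = 2μₗ*T* at each locus *l*. The two-sample variance
per locus, (x₁ₗ − x₂ₗ)²/2, divided by the locus mutation rate μₗ is
therefore an unbiased estimate of *T*; the estimator averages this ratio
over loci (missing loci excluded pairwise) and multiplies by the generation
time (default 30 years):

```
tMRCA = mean_l [ (x₁ₗ − x₂ₗ)² / (2 μₗ) ] × g
```

**Haplotype diversity.** With haplotype class frequencies p_k in a sample
of size *n*: `H = (1 − Σ p_k²) · n/(n−1)` — 1 when every individual is
unique, 0 for a monomorphic sample. Population "variance" is the mean
across loci of the unbiased (n−1) variance of repeat counts.

**Haplotype sharing.** For populations A, B, the sharing frequency is the
fraction of cross-population individual pairs that are identical (repeat
distance 0) or have an estimated tMRCA below a year threshold (default bins
500 / 1000 / 2000 years, strict upper bound), normalized by n_A·n_B
(within-population: C(n,2)). A continent-wide median filter keeps only
connections strictly above the median non-zero frequency.

**R_ST.** The microsatellite analog of F_ST: a two-group AMOVA on squared
allele-size differences d_ij = Σₗ (x_il − x_jl)², returning
σ²_among / (σ²_among + σ²_within) with the unequal-sample-size coefficient;
negative values are clipped to 0 and population trees are built by
neighbor joining (negative branches clipped to 0).

**Mitogenomes.** Distances are nucleotide differences with pairwise
deletion of N/gaps after removing the two hypervariable poly-C stretches
(positions 302–315 and 16183–16194; 26 columns). Haplotype classes are
letter-identical sequences; networks are minimum spanning networks (MST
plus equally short alternative connections, ε-relaxed), and an
ancient-proximity report lists every modern haplotype class within a given
number of mutation steps of each ancient sample.

**Simulator.** Kingman coalescent in the haploid parameterization (rate
C(k,2)/N_e, so E[TMRCA] = N_e for a pair), with an optional clean
population split; STR evolution under the single-step SMM with per-locus
rates and sequence evolution under a Jukes–Cantor strict clock. True
pairwise TMRCAs are written alongside the simulated inputs.

## Worked example

Estimate the tMRCA of two 5-locus haplotypes that differ by one repeat at
one locus (rate 2×10⁻³/generation):

```python
import pandas as pd
from uniparental import MutationRateTable, pairwise_tmrca

loci = [f"DYS{i}" for i in (19, 390, 391, 392, 393)]
rates = MutationRateTable({l: 2e-3 for l in loci})
h1 = pd.Series({l: 15.0 for l in loci})
h2 = h1.copy(); h2["DYS19"] = 16.0
t = pairwise_tmrca(h1, h2, rates, generation_time=30.0)
print(f"estimated tMRCA: {t:.1f} years")
```

```
estimated tMRCA: 1500.0 years
```

(one step contributes (1²/2)/0.002 = 250 generations; averaged over 5 loci
that is 50 generations = 1500 years.)

End to end from the shell — simulate four demes of 20 samples that split
100 generations ago, then run both analysis arms:

```sh
uniparental simulate --out demo/fix --pops 4 --n 20 \
    --seq-length 2000 --n-ancient 2 --seed 1
uniparental all --str-table demo/fix/str_table.tsv \
    --rates demo/fix/rates.tsv --fasta demo/fix/alignment.fasta \
    --metadata demo/fix/metadata.tsv --out demo/run
```

`demo/run/ystr/diversity_report.tsv` then contains

```
population	sample_size	n_haplotypes	haplotype_diversity	mean_locus_variance
pop1	20	20	1.000000	11.737461
pop2	20	18	0.989474	11.131889
pop3	20	20	1.000000	11.578793
pop4	20	19	0.994737	11.827090
```

— nearly every sampled man carries a unique 17-locus haplotype (diversity
≈ 1), as expected for rapidly mutating STRs in a large population, while
the repeat-count variance reflects the deep coalescent history
(N_e = 5000). The mtDNA arm writes the haplotype-sharing table, e.g.

```
pop_a	pop_b	shared_classes	shared_individuals_a	shared_individuals_b	freq_a	freq_b
pop1	pop1	4	12	12	0.600000	0.600000
pop1	pop2	6	11	8	0.550000	0.400000
```

(six mitogenome haplotypes occur in both pop1 and pop2 — the demes split
only ~3000 years ago), plus the R_ST neighbor-joining tree
(`rst_nj.nwk`), per-bin sharing edge lists, haplotype networks
(GraphML + edge list) and `closest_to_ancient.tsv`, which here places the
first ancient sample 0 steps from a 4-member modern haplotype class. Every
run directory includes a `manifest.json` with input hashes, configuration
and warnings.

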