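# Methods

This note documents the models implemented in `uniparental`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions applied at edge cases.

## Data model and curation

Y-STR haplotypes are vectors of repeat counts over a named locus panel
(bundled 17- and 23-locus forensic panels; the multi-copy locus DYS385 is
stored as two pseudo-loci `DYS385a`/`DYS385b`, smaller allele first, so
haplotypes stay flat vectors). Repeat counts may be non-integral
(intermediate alleles) and missing values are first-class: empty or `NA`
cells on disk, NaN in memory. Curation drops **modern** haplotypes with
more than `max_missing_loci` (default 2) missing loci; ancient samples are
kept regardless, because comparative ancient datasets are typically
incomplete, and every downstream pairwise statistic uses the locus
intersection of the pair (pairwise deletion). The filter is idempotent.

Mitogenome alignments must be rectangular; metadata (population, era,
optional externally assigned haplogroup label) is joined by record id.
The two homopolymeric cytosine stretches at positions 302–315 and
16183–16194 (1-based, inclusive; 14 + 12 = 26 columns) are removed from
every alignment before any comparison — their length variation is an
alignment artifact, not phylogenetic signal. Mask coordinates are
reference positions: they are applied through a designated reference row
when the alignment contains insertions, else positionally; overlapping
ranges are merged. Samples with more than `max_missing_bases` (default 5)
N/gap characters *outside* the mask are dropped — missingness confined to
the masked stretches never disqualifies a sample.

## ASD tMRCA estimator

For two haplotypes diverged *T* generations, the single-step symmetric SMM
gives E[(x₁ₗ−x₂ₗ)²] = 2μₗT per locus. The estimator is
`mean_l[(x₁ₗ−x₂ₗ)²/(2μₗ)] × g` with g = 30 years/generation, averaging
over loci non-missing in both haplotypes. It is unbiased at fixed *T*
(validated by simulation: mean over 2000 replicate pairs within 5% of
truth at 500–10000 years) but individual-pair estimates are extremely
noisy — the per-locus statistic is roughly exponential — which is why the
pipeline reports binned sharing frequencies rather than point estimates.
Assumptions worth keeping in mind: strictly single-step mutations, no
mutation-rate heterogeneity within locus, and linearity of ASD in *T*
(range constraints on repeat counts would saturate it at large *T*).

Per-locus mutation rates are configuration, not constants: a bundled table
of father–son–style estimates (0.4×10⁻³–14×10⁻³/generation; rapidly
mutating loci such as DYS570/DYS576 above 10⁻²) is used when no rate table
is supplied. Zero or negative rates are rejected wherever a division by μ
occurs.

## Sharing matrices

The sharing frequency between populations A and B is the number of
cross-population pairs satisfying the criterion divided by n_A·n_B; the
diagonal uses C(n,2) (NaN for singleton populations, where no pair
exists). Criteria: `identical` (repeat distance 0 on the pair's shared
loci) and `tmrca_lt(T)` (estimated tMRCA strictly below *T*; the bins are
half-open, so a pair at exactly *T* does not qualify). Pair normalization
was chosen so populations of different sizes are comparable. Modern
populations below `min_pop_size` (default 5) are excluded; ancient
populations are exempt. The median filter zeroes every off-diagonal entry
at or below the median of the non-zero off-diagonal frequencies of the
full matrix (the diagonal is left untouched — within-population sharing is
not a map edge); the threshold used is recorded in the run manifest.

## R_ST and neighbor joining

R_ST is computed as a two-group AMOVA on squared allele-size differences
(the Slatkin convention): per-locus sums of squared deviations around
population and grand means are summed over loci, mean squares use degrees
of freedom P−1 and N−P, the among-group variance component uses the
unequal-n coefficient n′ = (N − Σn_p²/N)/(P−1), and the statistic is
σ²_among/(σ²_among+σ²_within). Only complete haplotypes on the chosen
locus subset enter (applied per analysis, not globally); populations with
fewer than 4 complete modern haplotypes are excluded. Finite-sample values
can be negative (identically distributed populations give a negative
among-group component); matrix output clips them to 0. The test suite
checks the implementation against an independent oracle that derives the
same components from pairwise d_ij sums, to 10⁻¹⁰.

Trees use Saitou–Nei neighbor joining (via scikit-bio), which is exact on
additive matrices; on real (non-additive) R_ST matrices NJ can produce
negative branch lengths, which are set to 0 after construction without
redistributing length — the simplest topology-preserving correction.
Newick output quotes labels containing spaces.

## Mitogenome statistics

Distances are raw nucleotide differences with pairwise deletion (a column
counts only when both sequences have an unambiguous A/C/G/T); no multiple-
hit correction is applied, appropriate for the very low divergence of
within-species mitogenomes (≲0.3%). Haplotype classes use exact letter
identity: an N never matches a base, so a partially missing sequence forms
its own class. This conservative rule slightly inflates class counts for
low-quality samples but never merges distinct haplotypes. The sharing
table reports, per population pair, both the number of shared classes and
the number of individuals carrying them (with relative frequencies), so
either convention of "shared haplotypes" can be read off.

Networks are minimum spanning networks over classes: all MST edges plus
any edge no longer than the minimax MST path between its endpoints + ε
(default ε = 0 keeps exactly the equally short alternative connections).
Node sizes equal class sizes and sum to the sample count; edges carry
mutation-step lengths. Classes that differ only by missing data can sit at
distance 0, producing zero-length edges; with complete sequences all edges
are ≥ 1 step. The ancient-proximity report lists, for each ancient sample,
every modern class within `max_steps` (a user parameter — there is no
principled universal threshold); ancient samples with no hit keep an empty
row so they remain visible.

Haplogroup labels are consumed as input (classification is out of scope);
major haplogroups are the label's first letter, frequencies are computed
over assigned samples (rows sum to 1) with unassigned counts reported
separately, and all ancient samples can be pooled into a single row for
modern-vs-ancient comparisons.

## Synthetic-data generator

The generator exists to validate the estimators, with recorded truth. It
draws Kingman coalescent genealogies in the haploid parameterization
(merger rate C(k,2)/N_e; E[TMRCA] = N_e for a pair) — natural for
uniparental loci; halve N_e when comparing with diploid conventions. The
structured model is a clean star split: demes evolve in isolation until
`split_time` generations back, then pool into one ancestral population; no
migration, growth, or unequal deme sizes. STRs evolve by per-branch
Poisson mutation counts with ±½ step direction, reflecting at 1 repeat
(events logged; negligible at the defaults). Sequences evolve under a
Jukes–Cantor strict clock in substitutions/site/year. Defaults — the
conditions every stochastic test runs under — are four demes of 20
samples, haploid N_e = 5000, split 100 generations (~3 kyr) ago, the
17-locus panel with bundled rates, ancestral repeat 15, and 16569-bp
sequences at 1.708×10⁻⁸ substitutions/site/year (a coding-region-like
mitogenome clock) with a 30-year generation.

What the generator does **not** emulate: mutation-model violations
(multi-step STR mutations, rate heterogeneity across sites or lineages),
transition/transversion bias (Jukes–Cantor, not TN93/HKY — the generator
tests distance and sharing code, not clock inference), ancient-DNA damage
or genuine time-stratified sampling (tips labelled `ancient` are
contemporary tips exercising the ancient code paths), population growth,
migration after the split, and ascertainment of real panels. Passing tests
therefore demonstrate correctness of the statistics under their stated
models, not robustness to these real-data complications.

Determinism: every simulation takes a seed; a fixture regenerated with the
same configuration is byte-identical. Sub-seeds for the two genealogies
and two mutation processes are drawn from a root generator, so the Y and
mtDNA systems are independent, as they are in reality.

## Numerical conventions and degenerate inputs

- Pairs with no shared non-missing loci (or no comparable alignment
  columns) yield NaN with a warning; NaN never silently propagates into a
  tree (NJ rejects NaN naming the offending pair).
- Haplotype diversity and variance are NaN for n < 2; loci with fewer than
  2 observations are excluded from the variance mean.
- A mask covering the whole alignment is an error ("no columns remain").
- σ²_among + σ²_within = 0 (two identical monomorphic populations) returns
  R_ST 0 by convention.
- tMRCA bins and the median filter use strict inequalities as stated
  above; ties are therefore excluded/filtered deterministically.
- All tabular outputs are sorted (population, then sample id) and floats
  printed with fixed precision, so reruns diff byte-identically.

## Test and validation scale

Stochastic checks run at sizes chosen to keep the whole suite fast while
leaving comfortable Monte-Carlo margins: 2000–5000 replicate pairs for
unbiasedness identities (standard error ≲1.5% against 5% tolerances),
200 replicates per split depth for R_ST monotonicity, and fixtures of
4×6–4×20 samples with 1–2 kb sequences for end-to-end runs. The
acceptance script (`scripts/acceptance.py`) recomputes the headline
quantities at these sizes from a single command-line seed.

## Known limitations

- The ASD estimator's per-pair variance is large; binned sharing
  frequencies are the intended use, and bin boundaries at 500/1000/2000
  years are interpretable only up to that noise.
- R_ST variance-component conventions differ subtly between tools
  (treatment of the within-individual level, haploid vs diploid coding);
  values here follow the two-group Slatkin/AMOVA form documented above and
  are validated against the in-repo oracle, not against any external web
  service.
- The minimum spanning network is one of several network flavors;
  median-joining networks (which infer unsampled median vectors) are
  deliberately not implemented.
- No significance testing (permutation p-values for R_ST, diversity CIs)
  is provided; the upstream analyses report none.
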