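# slocus

Population-genomic tools for the intraspecific loss of distyly in
*Primula vulgaris*.

Distylous primroses come in two self-incompatible floral morphs — pins
(S-locus genotype 0/0; the supergene is absent) and thrums (hemizygous
S/0) — whose reciprocal anther/stigma heights enforce outcrossing.
Disruption of *CYP^T*, the S-locus cytochrome P450 that controls style
length and female self-incompatibility, converts thrums into
self-compatible homostyles carrying one (S\*/0) or two (S\*/S\*) copies of
the disrupted haplotype.  This package implements the computational chain
used to study that transition:

- **`slocus.crosby`** — a deterministic recursion for the four genotype
  frequencies (p, q, r, s) = (0/0, S/0, S\*/0, S\*/S\*) under pin selfing
  (σ_pin = 0.10), obligate homostyle selfing, and viability selection
  multiplying the S\*/S\* offspring class by v ∈ (0, 1] before
  renormalisation.  With v = 1 the recursion fixes S\*/S\*; with v = 0.65
  (a 35% viability deficit) thrums vanish while pins persist at low
  frequency and the two homostyle genotypes equilibrate at roughly equal
  frequencies.
- **`slocus.ploidy`** — S-locus copy number from relative read depth:
  rel_depth = mean depth over S-locus coding regions / mean depth over
  genome-wide coding regions, banded as 0.5 ± 0.25 → haploid,
  1 ± 0.25 → diploid, < 0.05 → absent; copy number + phenotype + *CYP^T*
  status yield the six-way S-locus genotype.
- **`slocus.filters` / `slocus.cypt`** — GATK-style hard filters
  (QD > 2, MQ > 40, FS < 60, MQRankSum > −12.5, ReadPosRankSum > −8,
  ½·mean < DP < 3·mean, InbreedingCoeff ≥ −0.99) and the three *CYP^T*
  disruption screens: codon-level consequence annotation (stop gains,
  frameshifts), homostyle-specific SNPs in introns/promoter, and
  structural signals (zero-depth deletion runs, discordant read-pair
  orientations), matched to the allele catalogue CYP^T-1/-2/-6/-8.
- **`slocus.diversity`** — 0-fold/4-fold degeneracy annotation and
  missing-data-aware π (summed pairwise differences over summed pairwise
  comparisons, invariant sites included), with π_N/π_S per gene and group.
- **`slocus.fit`** — observed genotype tables from survey counts plus
  sequenced-subsample proportions, tested against the recursion's
  expected-frequency grid (v ∈ {1, 0.9, 0.8, 0.7, 0.65, 0.6, 0.5},
  generations {10, 20, 30, 40}) with Pearson chi-squared tests and
  Bonferroni correction.
- **`slocus.synth`** — ground-truthed synthetic data for every stage:
  a miniature reference with *CYP^T* (exon 1 = 286 bp, exon 2 = 227 bp,
  3-kb promoter with motif intervals), cohort presets, Poisson depth
  tracks, read-pair tables and group-structured genotype matrices.

## Worked example

```python
from slocus.crosby import ModelParams, PopulationState, find_equilibrium

start = PopulationState(p=0.45, q=0.45, r=0.05, s=0.05)
for v in (1.0, 0.65):
    eq, _ = find_equilibrium(start, ModelParams(v=v))
    print(v, round(eq.p, 4), round(eq.q, 4), round(eq.r, 4), round(eq.s, 4))
```

prints

```
1.0  0.0    0.0  0.0    1.0
0.65 0.2114 0.0  0.4186 0.3699
```

i.e. equal viability fixes the double homostyle, while a 35% S\*/S\*
viability deficit maintains a pin/homostyle polymorphism without thrums.
Building the observed table for a trimorphic population from its survey
counts (3 thrums : 4 pins : 10 homostyles, homostyles split 40% haploid):

```python
from slocus.fit import observed_genotype_table
t = observed_genotype_table("EN4-T", (3, 4, 10), (0.40, 0.60))
print(t.counts, round(t.frequencies["S*/S*"], 2))
# {'0/0': 4, 'S*/0': 4, 'S*/S*': 6, 'S/0': 3} 0.35
```

The scripts in `examples/` walk through each capability end to end
(equilibria and grids, ploidy classification, the *CYP^T* screens, the
diversity table, and the observed-vs-expected fit).

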