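# Methods

## The genotype-frequency recursion

The model tracks the frequencies (p, q, r, s) of the four S-locus
genotypes — pin 0/0, thrum S/0, homostyle S\*/0 and homostyle S\*/S\* — in
an infinite population with discrete generations.  The S-locus is
hemizygous, so the null haplotype "0" segregates like an allele: S/0 and
S\*/0 transmit the S-bearing chromosome to half their gametes.

Crosses are resolved by anther height, with pollen non-limiting:

- **Pin mothers** self at rate σ_pin (default 0.10; offspring 0/0).  The
  outcrossed remainder is fertilised by the high-anther pollen pool, to
  which thrums and homostyles contribute in proportion to their genotype
  frequencies (pool alleles from Mendelian gamete tables).  Pin ovules
  always carry 0, so the offspring genotype is set by the pollen allele.
- **Thrum mothers** are self-incompatible and receive only pin pollen
  (allele 0), producing ½ S/0 : ½ 0/0.  When pins are absent thrums leave
  no offspring.
- **Homostyle mothers** self at rate σ_hom (default 1.0, since anthers and
  stigma touch).  S\*/0 selfing segregates ¼ 0/0 : ½ S\*/0 : ¼ S\*/S\*;
  S\*/S\* breeds true.  With σ_hom < 1 the outcrossed remainder takes
  high-anther pool pollen; S pollen on S\* ovules would produce S/S\*
  thrums, which fall outside the tracked state space and are dropped
  before renormalisation — this is why σ_hom = 1 is the default, and why
  the recursion omits the rare S/S and S/S\* genotypes altogether (they
  are handled descriptively by the classifier, not dynamically).

Viability selection multiplies the S\*/S\* offspring class by v before the
weight vector is renormalised; v is the probability that a germinated seed
becomes a seed-producing plant, relative to the other genotypes.  No
fecundity differences are modelled.

Equilibrium search iterates until the L∞ change between consecutive
states falls below `tol` (default 1e-10) or `max_gens` (default 100 000)
is reached; non-convergence is reported as a flag, not an exception.  Two
regimes emerge: v = 1 drives S\*/S\* to fixation, while v ≲ 0.8 maintains
a polymorphic equilibrium in which thrums are lost, pins persist at low
frequency (pins can still export pollen-free ovules fertilised by
homostyle pollen) and S\*/0 ≈ S\*/S\*.  The expected-frequency grid spans
v ∈ {1, 0.9, 0.8, 0.7, 0.65, 0.6, 0.5} and generations {10, 20, 30, 40}.
Because no generation-0 state is canonical, the default initial state
(p, q, r, s) = (0.495, 0.495, 0.01, 0) — a distylous population into which
the homostyle haplotype has just been introduced at 1% — is an explicit
convention, and equilibrium-based assertions are used wherever
initialisation independence matters.

## Ploidy from relative depth

rel_depth = (mean per-site depth over S-locus coding intervals) /
(mean over genome-wide coding intervals).  Positions inside a target
interval with no depth record count as depth 0, so the denominator is the
interval length; this makes deletions and absent loci visible rather than
silently ignored.  Bands: rel_depth < 0.05 → absent (pins yield no
S-locus reads at all); [0.25, 0.75] → haploid; (0.75, 1.25] → diploid;
anything else → unclassifiable.  The two published bands share the point
0.75; the tie goes to haploid so the rule is deterministic.  The
classification is scale-invariant because the ratio normalises away
per-individual sequencing effort.

## Variant filtering and the CYP^T screens

Hard thresholds follow standard GATK practice (QD > 2, MQ > 40, FS < 60,
MQRankSum > −12.5, ReadPosRankSum > −8, InbreedingCoeff ≥ −0.99).  The
depth band is implemented as the conjunction ½·mean < DP < 3·mean of the
cohort mean site depth — a disjunction would retain every record.
Missing annotations pass their sub-filter: rank-sum statistics are
undefined at sites without heterozygous calls and their absence is not
evidence against a site.

Consequence annotation maps a variant through the exon structure onto the
CDS and translates the affected codon under the standard nuclear code:
same amino acid → synonymous, stop → stop_gain, otherwise missense;
indels are frameshift when the length change inside the CDS is not a
multiple of 3.  Structural deletions are maximal runs of zero depth of at
least `min_length` (default 50 bp — short indels such as the 8-bp
frameshift belong to the indel path, not the depth path).  Read-pair
orientation is tallied as convergent (normal), same-orientation
(inversion signal) or cross-contig (translocation signal); the screen
flags these signals and does not attempt to resolve insertion sites.

The allele catalogue is operational for the alleles whose defining
mutations are known here: CYP^T-1 (functional), CYP^T-2 (exon-2 stop
gain), CYP^T-6 (8-bp exon-1 frameshift deletion), CYP^T-8 (~2150-bp
deletion spanning exon 1 and the proximal promoter motifs); CYP^T-3/-4/
-5/-7 are placeholders defined in prior work.  Conflicting signatures are
labelled "novel", never coerced.

## Nucleotide diversity

Degeneracy is assigned per CDS position by substituting all three
alternative bases: 4-fold if none changes the amino acid, 0-fold if all
do, otherwise "other" (2-/3-fold positions are excluded from both π_S and
π_N).  π follows the ratio-of-sums estimator: per site,
diffs = c_ref·c_alt and comparisons = n(n−1)/2 over the n non-missing
alleles; the aggregate is Σdiffs/Σcomparisons, so invariant sites add
comparisons and missing genotypes shrink a site's weight without biasing
the estimate.  Sites with fewer than two called alleles are excluded;
Σcomparisons = 0 yields NA with a warning, as does π_N/π_S when π_S = 0.
Hemizygous S-locus genotypes arrive as diploid homozygous VCF calls and
are consumed as such by default; a haploid mode counting one allele per
individual is provided, which leaves π unbiased but roughly halves each
site's comparison count.  Report tables round π to 4 decimals and ratios
to 2.

## Goodness of fit

Observed genotype counts multiply survey phenotype counts by
classified-subsample proportions, rounded to the nearest integer with the
residual assigned to the larger class.  The Pearson statistic is computed
over cells with positive expectation (expected-0/observed-0 cells are
dropped with a df reduction; expected-0/observed-positive is incompatible,
p = 0), with df = included cells − 1 and the p-value from the χ² upper
tail.  The Bonferroni family defaults to all (v, generation) cells tested
per population (28 for the full grid); both raw and adjusted p are
reported, compatibility is adjusted p ≥ α (default 0.05), and raw
p < 0.01 carries a "**" annotation to mirror the conventional table
typography.

## Synthetic data

The generator emulates the study's inputs, not its raw reads.  The
reference has two contigs: `S_locus` with CYP^T (exons
286/227/180/120/210 bp, introns 400/350/300/250 bp, a 3-kb promoter with
eight motif intervals placed 15–1361 bp upstream of exon 1) plus four
further 900-bp S-genes, and `Chr1` with four 900-bp paralogs.  Only the
exon-1/exon-2 lengths and the promoter window are constrained by the real
gene; all other lengths are documented free choices.  Codon 125 of CYP^T
is forced to TCA so a single C→G substitution at CDS position 374 creates
the catalogued premature stop.

Cohort presets mirror the published sampling: 37 pins, 37 thrums (34 S/0,
2 S/S, 1 S/S\* heterozygote in EN4-T) and 31 homostyles (10 S\*/0, 21
S\*/S\*; EN4-T split 40/60, EN5-T 60/40, EN6-M all S\*/S\* carrying the
structural deletion).  Depth is Poisson (optionally negative binomial,
since real resequencing is overdispersed) with genome mean 18.9 — the
study's average sequencing depth — and S-locus mean λ·copies/2, zero for
pins and inside deleted spans.  Genotype matrices make each site
independently polymorphic with probability 2θ at allele frequency ½,
which gives E[π] = θ exactly; the selfing group has excess homozygosity
(F = 0.9) and lower θ (0.0005 vs 0.003).  Sites are unlinked, which is
adequate because every downstream statistic is a per-site sum — but it
means the generator cannot exercise linkage-sensitive analyses, and
passing tests say nothing about LD structure, GC/mappability bias or
mapping artifacts in real data.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale: equilibria converge in
a few hundred generations; the depth-recovery checks use 500 hemizygotes
(plus 150 per class for accuracy) with 50 kb of Poisson sites per
compartment, at which the Monte-Carlo standard error of the mean relative
depth is ~3×10⁻⁵; θ-recovery uses 10 kb of callable sites and a
3-standard-error band.  All generators are deterministic under a fixed
seed.  Known limitations: the recursion drops S/S\* outcross products when
σ_hom < 1; the classifier has no GC or mappability correction and no
mixture-model thresholding; structural detection is single-region
run-length logic, not a general SV caller.
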