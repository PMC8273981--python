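# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `slrscape`. The package analyses a young XY sex
chromosome system and its pericentromeric context; because the analyses are
exercised on a synthetic genome with planted truth, this note also states
precisely what the generator does and does not emulate.

## Synthetic genome generator

The generator (`synthetic_data`) builds a diploid genome whose structure
mirrors a small teleost with a young sex chromosome. The `zigzag` preset
fixes the study conditions:

| parameter | default | meaning |
|---|---|---|
| chromosomes | 24 (5 metacentric, 3 submetacentric, 16 telocentric) | karyotype; ~615 Mb total |
| sex chromosome | chr7, 27.9 Mb, submetacentric | XY pair; centromere at ~19.4 Mb |
| SLR | 17–24 Mb | fully sex-linked region spanning the centromere; chromosome ends are PARs |
| strata divergence | R1 1.2% (17–20 Mb), R2 0.8% (20–24 Mb) | per-base X→Y substitution probability; both ≈1% |
| satellites | 524-bp centromeric monomer (96 copies ≈ 50 kb per centromere), 190-bp telomere-associated monomer (100 copies per end), (TTAGGG)×50 termini | monomer sequences are random at a fixed stream keyed by the seed; only lengths and placement are planted truth |
| PCH | length ~ Normal(4.2 Mb, 0.5 Mb) truncated > 1 Mb, one block containing each centromere | repeat fraction 0.55 inside vs 0.15 outside |
| population | 10 males + 10 females, SNP density 1/kb | full sex linkage inside the SLR, Hardy–Weinberg outside |
| reads | HiFi-like, i.i.d. substitution errors at 0.00086/bp | no indels, no quality strings |
| gonads | 5 testis + 5 ovary + 5 intersex (stages I1–I5) + 2 somatic samples | negative-binomial counts, dispersion 0.1 |

Design points worth noting:

* **PCH placement.** The block is an interval of the drawn length that
  *contains* the centromere, shifted to fit inside the chromosome. On
  telocentric chromosomes the domain therefore extends inward from the
  terminal centromere rather than being truncated; centring-and-clipping
  would halve PCH on two-thirds of the karyotype and contradict the
  planted ~4.2-Mb scale.
* **Repeat track.** Interspersed repeats are alternating
  exponential-length repeat/gap segments (mean repeat 1 kb) tuned to the
  regional coverage fraction; 50-kb windows then fluctuate by roughly ±4
  percentage points around 0.55 (PCH) and ±3 around 0.15 (background), so
  the 40% calling threshold separates the classes cleanly.
* **Sex-linked sites.** In sequence mode, the planted X–Y substitutions
  *are* the male-specific sites (≈12/kb in R1, 8/kb in R2). In track-only
  mode (no bases generated; used for whole-genome runs) they are drawn at
  `snp_density`. The count of planted differences always equals the count
  of fully sex-linked sites in the genotype table.
* **Genes** are placed on a regular grid (one per 40 kb, 6 exons × 250 bp,
  2-kb introns). This gives every 100-kb window ~20 kb of intronic sequence
  for the X–Y divergence scan; real gene deserts (windows with too little
  intron) are handled by the scan's missing-window rule but are not planted.
* **Candidates.** Two SLR genes are planted: one expressed exclusively in
  testis (baseline exactly zero elsewhere — "exclusive" is read literally),
  and one expressed in testis and early intersex (I1–I3) with ovary
  depletion.
* **Determinism.** Every stage draws from an independent RNG stream keyed
  by `(seed, stage, chromosome)`, so outputs are byte-identical across runs
  and insensitive to evaluation order.

What the generator does **not** emulate: indels and structural variants,
read-level Hi-C pairs, sequencing quality, population structure or kinship,
linkage disequilibrium beyond the planted sex linkage, heterozygosity
outside the SLR (autosomal haplotypes are identical), satellite higher-order
structure, and transposable-element families. Passing tests therefore show
that the inference chain recovers planted structure under clean assumptions,
not that it is robust to alignment artefacts or demographic confounding in
real data.

## k-mer spectrum model

Canonical k-mers (lexicographic minimum of the 2-bit packed k-mer and its
reverse complement; k ≤ 31) are counted into a multiplicity histogram h(m).
The fit targets a haploid/homozygous spectrum: heterozygosity is *not*
modeled, so on a diploid input the heterozygous peak would bias the
estimate. With T = Σ m·h(m), E = Σ_{m<v} m·h(m):

* the coverage peak is located as argmax of m·h̃(m) for m ≥ 2, where h̃ is
  h smoothed by a 3-point moving average (reflected at m = 1 so the empty
  m = 0 bin cannot fake a rise);
* the valley v is the minimum of h̃ between 1 and that peak (first index on
  ties); a spectrum with no separation raises an error advising the
  `error_free` flag, which pins v = 1;
* homozygous coverage c = argmax_{m≥v} m·h(m) (unsmoothed, so a noise-free
  single-peak spectrum is fit exactly);
* genome size = (T − E)/c; error rate = 1 − (1 − E/T)^(1/k), the inversion
  of the probability that a k-mer is error-free under i.i.d. errors.

Tests use k = 21 on a 1-Mb genome at 40× (the estimator is k-parametric;
memory at desk scale dictates the problem size). Known bias: c is discrete
and sits near λ+1 for Poisson-like coverage λ, giving a ~2% downward bias
in genome size at 40×.

## Tandem arrays and karyotype

Arrays are detected per candidate period p (default 10–2000) from the lag-p
self-mismatch profile: positions where every covering p-window has mismatch
fraction ≤ 0.2 are merged into runs; a run spanning fewer than two periods
is suppressed. Candidates across periods are reconciled longest-first; a
smaller-period candidate covering ≥ 90% of a kept interval replaces it, so
an array is reported at its fundamental period rather than a multiple (a
period-p detection can overhang the true array edge by up to ~p/0.2, which
otherwise makes the 2p/3p candidates marginally longer). The consensus
monomer is the per-column majority over aligned copies (ties → lowest base).

Monomer families merge arrays whose canonical monomers (minimal rotation
over both strands) match at ≥ 80% identity with lengths within 10%;
identity is computed by infix edit-distance alignment of the shorter
monomer against the doubled longer one (rotation-tolerant). Classification
uses chromosomal distribution only: centromeric = exactly one cluster on
≥ 70% of carrying chromosomes and interior on ≥ 1 bi-armed chromosome;
telomere-associated = ≥ 90% of clusters within 200 kb of an end (cluster
gap 500 kb). These thresholds are this package's own; the morphology cut
points (1.7, 3.0, short-arm floor 1 bp; boundaries inclusive) follow the
Levan arm-ratio convention collapsed to three classes.

## Sex-linkage scan

* Male-specific sites require *every* non-missing male heterozygous and
  every non-missing female homozygous; sites > 20% missing are excluded. A
  symmetric female-specific mode covers ZW-like systems.
* F_ST is the Hudson-type ratio of averages per 50-kb window with
  sample-size-corrected within-sex heterozygosity; windows with < 40
  variants are missing.
* The association scan is a two-sided exact hypergeometric (Fisher) test on
  the 2×2 allele-count table. A mixed model is deliberately not used: the
  synthetic population has no structure, and the scan's role is to localize
  a fully penetrant region.
* SLR demarcation marks 50-kb windows with ≥ 3 male-specific SNPs and
  merges runs across ≤ 5 unmarked windows; these two constants are not
  derived from data but chosen so a 1-SNP/kb planted region is recovered
  with sub-window boundary error while isolated false positives (whose
  per-site probability at 10+10 samples is < 10⁻⁶) never seed a region.
* X–Y divergence is computed on coordinate-matched haplotypes (no aligner;
  collinearity is assumed — for real data a whole-genome alignment must be
  applied first), restricted to intronic positions, in 100-kb windows with
  ≥ 1 kb compared bases.
* Strata segmentation does an exhaustive single-changepoint search
  minimizing within-segment sum of squares of divergence (≥ 3 windows per
  side). Because the changepoint maximizes separation, the naive post-hoc
  Wilcoxon is anti-conservative (it splits about half of constant-divergence
  datasets); the split decision therefore uses a Bonferroni correction by
  the number of candidate changepoints, while the reported `wilcoxon_p`
  stays uncorrected for comparability with single-test usage. The rank-sum
  test is exact for ≤ 20 untied values per side, otherwise a normal
  approximation with tie correction.

## PCH and Hi-C

* PCH calling: 50-kb repeat-content windows > 40% merged across ≤ 5-window
  gaps. Subtelomeric satellite arrays also exceed the threshold, so blocks
  are annotated with centromere containment and pericentromeric statistics
  use the flagged blocks.
* Peak enrichment keeps peaks with −log10 p > 8 (strict) and measures
  membership by midpoint, in peak counts.
* Balancing is symmetric iterative proportional scaling to uniform row
  sums (relative tolerance 1e-6, cap 1000 iterations, zero-sum bins
  masked, overall scale preserved); for positive matrices this has the same
  fixed point as Knight–Ruiz.
* Compartments: counts aggregated to 250-kb bins, O/E by per-diagonal mean
  (no smoothing), Pearson correlation of columns, PC1 of the
  column-centered correlation matrix by power iteration (tolerance 1e-8 on
  the eigenvector, deterministic start), sign oriented to correlate
  positively with gene density (A = positive).
* Distance-stratified contacts: pairs with value ≤ 10 are excluded; the
  per-log2-distance-stratum class means are reported on the raw scale, but
  the pooled Wilcoxon compares per-exact-distance normalized values
  (observed/expected) over strata containing both classes — raw pooling
  confounds class with distance because PCH pairs sit at the short end of
  each stratum.

## Expression

TPM is the standard length-normalized within-sample unit; tau is computed
on log2(TPM+1) group means (log damping keeps tau stable for
high-dynamic-range genes). The candidate screen's fold constants (≥ 4×
ovary depletion, testis/early-intersex concordance within 2×, expressed =
mean TPM > 1) are configurable; the expression threshold of 1 TPM is the
only one of the three anchored to a printed rule. Early intersex = stages
I1–I3, late = I4–I5 when stages are labeled, else one intersex group.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the planted effects are recovered
with comfortable margins: the full-length 27.9-Mb sex chromosome for the
SLR/strata analyses, a 1-Mb genome at 40× for the k-mer model, the
whole 24-chromosome karyotype in track-only mode for PCH, and an
8-chromosome × 500-kb sequence genome for satellite classification.

## Known limitations

* The k-mer model ignores heterozygosity and repeat structure of the
  spectrum; it is a two-component (error/homozygous) estimator.
* Tandem detection is O(periods × length) and intended for chromosome-arm
  scale scans or targeted regions, not for thousands of whole chromosomes
  at the full 2-kb period cap.
* The X–Y similarity scan requires pre-aligned, indel-free coordinates.
* Compartment calls on short chromosomes (< ~20 output bins) are fragile,
  as for any PC1-based method.
* The PCH/expression comparison treats genes as exchangeable; no
  gene-length or GC covariates are modeled.
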