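# Methods

`poolhaf` estimates population allele frequencies from low-coverage pooled
sequencing of a biparental (donor × recurrent) population and sharpens the
estimates by aggregating SNPs into haplotype windows. This note documents
the models, the defaults and why they are set where they are, the numerical
conventions, and what the synthetic-data generator does and does not
emulate.

## Haplotype windows

Anchors are genes (GFF3 intervals), chip markers (1 bp anchors), or a fixed
contig grid (default 100 kb tiles). Gene and marker anchors are extended
into their flanking intergenic space: for a gap of `g = next.start −
prev.end` bp between consecutive anchors, 10% of `g` is left unannotated
and the remainder is split evenly, so each facing flank grows by
`floor(0.45·g)` bp. Example: genes at 200–560 and 800–850 leave `g = 240`;
each side gains 108 bp, the new boundaries are 668 and 692, and 24 bp stay
unannotated. A SNP at 590 is thereby captured by the first window instead
of being lost.

Conventions and edge cases:

- All coordinates are 1-based inclusive; only BED export is 0-based
  half-open. Window membership is a closed interval (a SNP exactly on a
  boundary belongs to the window).
- Extensions are floored to integer bp. With the default fractions the two
  extensions can never meet; in the degenerate `extension_fraction = 0.5`
  case the downstream flank backs off one base so windows never overlap.
- Touching or overlapping anchors receive no extension toward each other.
  Overlap already present in the anchors (overlapping gene models) is kept
  as-is; SNP assignment refuses overlapping windows.
- Chromosome termini are treated as neighbour edges: the outward flank is
  the distance to position 1 (or to the chromosome length), extended with
  the same rule and clamped to the chromosome.
- Strand is ignored; both termini extend symmetrically.
- Marker windows are size-filtered to [500 bp, 1 Mb] before use (the upper
  bound also caps the damage of assuming no recombination within a
  window).

## Frequency estimation

Pool VCF records are kept if they are biallelic SNPs with quality strictly
greater than 30 (the "exceeds" convention), at least one read in the pool
sample, and — optionally — membership in a known-variant whitelist that
stands in for an external variant database. Sites are polarised at
parental-difference positions only (both parents homozygous, different
alleles): the donor-allele read count over total reads gives the SNP donor
frequency.

Within a window the haplotype allele frequency is the depth-weighted mean

    HAF = Σ_k rd_k·freq_k / Σ_k rd_k = total donor reads / total reads,

computed in integer read counts, so aggregation conserves donor reads
exactly and the HAF always lies between the member SNP frequency extremes.
The recurrent parent's HAF is `1 − HAF`. The genome-wide summary frequency
is read-weighted for the same reason (robust to depth heterogeneity;
unweighted means differ only in the third decimal on realistic tracks).

## Validation statistics

- **Pool-size design.** Cochran's `n₀ = ceil(Z²·p·(1−p)/e²)` with the
  two-sided normal quantile; ceiling because a sample size is an integer
  at least as large as the formula value (p=0.125, e=0.05, 99% → 291).
- **Agreement.** RMSE and Pearson r between paired frequency tracks;
  Pearson is reported as NaN (flagged missing) under zero variance. The
  "residual width" of a comparison is the mean absolute deviation.
- **ZINB group test.** Donor read counts are compared between two tracks
  with a zero-inflated NB2 regression (statsmodels): group indicator in
  both components, `log(total reads)` offset in the count component, logit
  zero-inflation, Wald p-values for the group coefficient in each
  component. Zero inflation absorbs loci where a low-frequency allele
  produced no donor read; the NB component carries overdispersed positive
  counts. A frequency-only reference track (e.g. individual genotyping) is
  converted to pseudo-counts at the paired pool window's depth so both
  groups share the offset scale. Start values come from a plain NB fit
  plus the empirical zero share; optimiser failures fall through
  bfgs → lbfgs → Nelder–Mead and end in NaN, never a fabricated p-value.
  No multiple-testing correction is applied (raw probabilities are
  reported).
- **Bias regression.** OLS of (estimated − true) on window extension size
  and chromosomal position. An identically-zero response degenerates the
  standard errors; by convention coefficients 0 with p = 1 are returned.
- **Neighbour QC.** Per chromosome, the absolute HAF distance between
  consecutive windows is computed; a window is flagged when its distance
  to *both* neighbours exceeds 5× the chromosome median (terminal windows
  use their single neighbour). The both-neighbours rule reflects that in a
  large-linkage-block selfing population an isolated jump would require a
  double crossover and is more plausibly a calling error.

## The synthetic-data generator

The generator emulates the study system: a BC₂F₃ spring-barley population
(donor × recurrent, two backcrosses, two selfings), pooled at 300
genotypes and sequenced at ~10× per SNP, i.e. ~0.03× per genotype.

- **Genome.** 7 chromosomes × 50 Mb × 150 cM with 700 markers each
  (~4,900 markers, the size of the uniquely mapped chip marker set), on a
  quasi-regular grid with ±40% spacing jitter; the genetic map is linear
  in bp. Physical scale is reduced from the 4.2 Gb barley genome so that a
  marker linkage window holds a median of ~43 pseudo-SNPs at the 1500 bp
  grid — the saturation the method was characterised at (~400–500 reads
  per window). All of this is overridable.
- **Meiosis.** Haldane's no-interference model: crossover count
  Poisson(map length in Morgans), breakpoints uniform in cM, no crossover
  interference. Loci between markers inherit the flanking segment.
- **Pedigree.** `CrossingScheme` defaults to independent descent per
  individual, which makes the Mendelian expectations exact with iid
  Monte-Carlo errors: donor frequency `(1/2)^(backcrosses+1)` (12.5% at
  BC₂), heterozygosity 25% at BC₂F₁ halving per selfing.
  `field_population_scheme()` instead routes descent through 6 BC₁ and 24
  BC₂ plants. A bulk-propagated backcross population really does descend
  from a handful of founder plants, and this is what creates between-locus
  drift of the *true* donor frequency: with 24 founders (siblings
  correlated 1/3 through shared BC₁ parents) the cross-locus variance of
  the true frequency is `0.25·(3/16)/24·(1 + 3·(1/3)) ≈ 3.9×10⁻³`
  (SD ≈ 0.06), which reproduces the observed accuracy ceiling of pooled
  experiments on such populations — a 300-of-24,000 subsample correlates
  ≈ 0.96 with the full population. With fully independent descent the
  truth would be nearly flat across loci and any correlation-based
  validation would be meaningless.
- **Population size.** 24,000 individuals (the scale of the ~25,000-plant
  field population the design mirrors). Truth variance is set by the
  founder structure, not by this number.
- **Reads.** Depth per SNP ~ Poisson(10) (fixed-depth option available);
  donor reads ~ Binomial(depth, pool frequency); no base-call errors and
  no alignment step — the pipeline consumes allelic-depth counts, and the
  binomial-at-depth structure is the statistically relevant part. The
  synthetic variant quality is `20 + 10·min(depth, 30)`, a deterministic
  monotone function of depth, so quality filters are exercisable; the
  default `>30` filter corresponds to depth ≥ 2.
- **Pseudo-SNPs.** Placed on the global 1500 bp grid; those inside a
  marker linkage window inherit the anchor marker's truth frequency
  (no intra-window recombination in the truth), mimicking the alternative
  reference-base trick used to densify simulated pools.

## The recovery experiment

`recovery_experiment` chains population → 300-genotype pool → reads →
MLW construction → SNP assignment → HAF, then scores SNP-level estimates
(all SNPs with ≥1 read) and HAF estimates at minimum-total-read thresholds
0/200/500 against the *full population's* true donor frequencies. Reads
are drawn from the subsample, so the reported accuracy includes the
subsampling error a real pooled experiment carries; this is why HAF
accuracy saturates near r ≈ 0.95 rather than 1. At the defaults the
single-SNP RMSE is ≈ 0.11, HAF correlation beyond 200 reads ≈ 0.93, and
HAF RMSE beyond 500 reads ≈ 0.021–0.026 — aggregation recovers roughly a
five-fold accuracy gain over single SNPs at identical sequencing effort.
One integer seed drives every random draw; identical seeds give
bit-identical outputs end to end.

Test problem sizes: the Mendelian-expectation checks use 10,000
individuals; the recovery expectations are checked on means over four
replicate seeds (single realisations of drift and read noise wiggle a few
percent, and monotonicity of RMSE in the coverage threshold is an
expectation statement); smaller genomes are used wherever a property does
not depend on scale.

## Limitations

- Equal DNA contribution per pooled individual is assumed; contribution
  variance (a real error source in pool construction) is not modelled.
- No sequencing error, PCR duplicates, alignment artefacts or
  variant-calling noise: passing the simulation says the *estimator* is
  accurate under binomial read sampling, not that a noisy wet-lab pipeline
  will reach the same numbers. Method-specific pathologies (duplicate
  inflation of GBS-style data, expression bias of transcript counts) are
  out of scope.
- Pseudo-SNP truth copying means simulated windows have internally
  homogeneous truth; real windows can straddle recombination breakpoints,
  which inflates real-data RMSE slightly relative to the simulation.
- Individual haplotypes and heterozygosity are not recoverable from a
  pool, and indels are excluded throughout.
- Windows never adapt to local recombination rate; the fixed 45%/10%
  extension rule is tuned to a selfing crop with large linkage blocks and
  would need smaller windows for outcrossers.
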