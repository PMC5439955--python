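# Methods

This note records the statistical models implemented in `sptumor`, the
default parameters and why they were chosen, the scope of the synthetic-data
generator, and the numerical decisions that affect results.

## 1. Recurrent whole-chromosome aneuploidy

Input: a tumors × 22 integer matrix of whole-chromosome autosome copy
numbers (sub-chromosomal/arm amplifications are stored separately and never
enter the matrix, so each chromosome contributes its lowest full-length copy
number). Sex chromosomes are excluded.

**Null model.** Each tumor is heavily aneuploid overall, so the interesting
question is not "is chromosome k aneuploid" but "is chromosome k gained (or
lost) more often than that tumor's own ploidy distribution predicts". The
null therefore shuffles each tumor's 22 values independently, preserving the
per-tumor multiset, and recomputes each chromosome's cross-tumor sum.

**Empirical p-values.** For chromosome k with observed sum S_k,

- gain: p = #{permutations with null sum > S_k} / N
- loss: p = #{permutations with null sum < S_k} / N

Strict inequalities; ties count toward neither tail; no pseudo-count is
added, so p = 0 is representable and is reported as "< 1/N". The 22 gain
p-values and the 22 loss p-values are each adjusted with
Benjamini–Hochberg (`statsmodels` `fdr_bh`).

**Exact reference values.** Because the null marginal of a uniformly random
permutation at any fixed position is uniform over the tumor's multiset, the
null distribution of each chromosome's sum is the convolution of the five
per-tumor uniform distributions and can be computed exactly. On the packaged
karyotype the exact adjusted values are: chr9 gain 0.01040, chr20 gain 0,
chr15/chr22 loss 0.00581, chr7/chr13 loss 0.04364. Monte-Carlo runs at
N = 100,000 land within ±3 SE of these (the SE of the raw p propagated
through each chromosome's BH multiplier, ≈ 0.004 / 0.003 / 0.006). A full
enumeration oracle (`exhaustive_recurrence`) is provided for instances with
≤ 10⁷ arrangements and is used in the tests.

**Implementation.** Vectorized with `numpy.random.Generator.permuted` in
chunks of 50,000 permutations; 100,000 permutations on the 5 × 22 table run
in well under a second. A `pooled` strategy (permute the flattened matrix,
destroying per-tumor structure) is kept only for comparison.

## 2. Copy number, zygosity and purity

At a SNP marker on a chromosome present in `c` copies with minor-allele
count `m`, in a tumor of purity ρ diluted by 2-copy normal tissue:

- expected tumor/normal depth ratio: μ_c = h · (ρc + 2(1−ρ))
- expected folded B-allele fraction: β_{c,m} = (ρm + (1−ρ)) / (ρc + 2(1−ρ))

where h converts one tumor copy into depth-ratio units (h × median normal
depth is the haploid coverage). Depth ratios are smoothed per chromosome
with a centered 500-marker moving average that never crosses chromosome
boundaries (shrunken windows at the edges).

**Grid search.** Purity runs over 0.30–1.00 in steps of 0.0125; candidate h
values anchor the median chromosome ratio at each integer copy 1–8. Each
(ρ, h) is scored by the marker-count-weighted squared residuals of the
per-chromosome median smoothed ratio and median folded BAF against their
nearest integer-copy expectations, with both residuals expressed in
copy-number units so they are commensurate.

**Aliasing.** Marker means cannot always separate a contaminated genome from
a purer genome with uniformly shifted copies: ρ = 0.5 with copies c is
mean-identical to ρ = 1 with copies c + 2. Three mechanisms break the
degeneracy: (i) a flat penalty (25 copy-units²) whenever a whole chromosome
would be assigned zero copies, since whole-genome nullisomy is not a
plausible explanation; (ii) BAF residuals, which are not alias-invariant
when the true minor count would become non-integer or negative; (iii) among
candidates whose scores are within `0.005·(1 + best)` of the best, the final
pick minimizes (mean ploidy rounded to 0.1, score, −purity) — parsimony
first, then fit, then the purest model. On a genuinely uninformative profile
(every chromosome at the same copy number) the estimate is flagged
`low_confidence`.

**Calling.** Chromosome copy is the nearest integer to the purity-corrected
median smoothed ratio (exact half-integer ties resolve toward the modal
genome ploidy); the minor count minimizes |median BAF − β_{c,m}| over
m = 0…⌊c/2⌋; `minor == 0` sets the LOH flag. Chromosomes supported by ≤ 1500
markers are suppressed rather than called. Runs of ≥ 1500 consecutive
markers at a different integer copy than the chromosome call are reported as
arm events. A singleton mode (no matched normal) takes ratios against a
constant diploid baseline (supplied or modal tumor coverage). An exon screen
flags targeted-capture intervals whose implied copy deviates from the
chromosome call by strictly more than one copy.

Verified recovery: exact copy numbers and zygosity on noise-free profiles;
at 52×/26× coverage with 60,000 markers, purity 0.825 is recovered within
±0.03 and ≥ 95% of autosome calls are correct; a 50% admixture is not
mistaken for a pure tumor.

## 3. Mutation timing from VAF

A somatic SNV on `m` of `c` copies has expected VAF ρm / (ρc + 2(1−ρ)); for
a pure trisomy this gives the anchors 1/3 (mutation after the gain, m = 1)
and 2/3 (before the gain, on the duplicated homolog, m = 2). The classifier
picks the m ∈ {1…c} whose expectation is nearest the observed VAF and labels
the variant `pre_gain` when m ≥ 2, `post_gain` when m = 1, and
`indeterminate` when the two nearest expectations both lie within
±2·√(v(1−v)/depth) of the observation — at typical 52× depth the 1/3 vs 2/3
decision is crisp, while shallow sites abstain rather than guess. On
synthetic cohorts the determinate calls are > 90% correct at study depth and
exact in the noise-free limit. Supporting statistics: Spearman correlation
of VAF with chromosome copy number (negative in a late-mutation cohort,
where VAF ≈ 1/c), per-chromosome VAF percentiles (a 2:0 uniparental-disomy
chromosome keeps its 99th percentile well below 0.9 because late mutations
still sit at VAF ≈ 0.5), and the Pearson correlation of per-tumor SNV burden
with total autosome count.

## 4. Trinucleotide spectrum

Each SNV is mapped to one of 96 types: 6 pyrimidine-frame substitution
classes × 16 flanking-base pairs. Purine-reference mutations are
reverse-complemented together with their context; variants within one base
of a contig edge are skipped and counted. Summary fractions: transitions
(C>T + T>C), C>T share, and the CpG share of C>T (3' base = G). Spectra are
compared by Pearson correlation of their 96 bin frequencies. A paired
one-sided t-test on per-tumor bin *frequencies* (tumors differ in burden, so
raw counts would weight them unevenly) tests whether one context exceeds
another, defaulting to ACG→ATG vs CCG→CTG.

The packaged comparator spectrum (`load_dnm_reference`) is a synthetic
stand-in for published germline de novo mutation compilations. It is built
from a parametric signature matching their headline fractions — 75.3%
transitions, 51.4% C>T, 56.6% of C>T at CpG, with ACG the modal context —
not from any measured 96-bin table; conclusions that depend on fine 96-bin
structure should not lean on it.

## 5. Methylation-conditioned mutability

A CpG site is methylated when **both** replicates report strictly more than
50% methylated reads; sites present in only one replicate are dropped (and
counted). File I/O accepts bedMethyl-like 0-based half-open rows with
percent-scale values and converts to internal 1-based fractions. A variant
overlaps a site if it hits the plus-strand C directly or hits the G one base
downstream (purine reference, mapped back to the C). Enrichment of the q
methylated among n overlapping variants against the site set's background
methylated fraction p is the upper-tail binomial probability
P(X ≥ q) = `scipy.stats.binom.sf(q − 1, n, p)`, with q = 0 defined as 1.
Worked example: q = 10, n = 11, p = 0.232 → 3.92 × 10⁻⁶. The test is
conservative under its own null (discreteness), which the suite verifies by
simulation.

## 6. Synthetic-data generator

Everything is deterministic given (config, seed); each stage draws from its
own `default_rng([seed, stream])` stream (1 reference, 2 karyotype,
3 markers, 4 variants, 5 methylation), so regenerating one artifact never
perturbs another.

- **Reference**: i.i.d. bases at 42% GC; 22 autosomes (200 kb down to
  ~99 kb), X (150 kb), Y (60 kb), all scalable by `genome_scale`.
- **Karyotypes**: either an explicit table passed through unchanged, or
  sampled (base ploidy in {2, 3, 4}, per-chromosome jitter, 8% whole-
  chromosome LOH) with optional planted recurrent gains/losses recorded as
  ground truth.
- **Markers**: Poisson tumor depth with mean ∝ (ρc + 2(1−ρ)) normalized by
  the length-weighted mean ploidy; Poisson normal depth; binomial alt counts
  at heterozygous markers with success probability β_{c,m}. With
  `depth_noise=False` every draw is replaced by its expectation, giving
  noise-free profiles for exact parameter-recovery tests.
- **Variants**: per-chromosome counts ∝ copy × length (Poisson at
  0.2 SNVs/Mb per diploid-equivalent by default, or an exact `n_variants`
  multinomial); contexts drawn from the germline-like signature and placed
  on matching reference trinucleotides on either strand; timing pre/post
  gain via `timing_fraction_pre_gain` (default 0: purely late mutations);
  read counts binomial at Poisson depth around the expected VAF. Two call
  sets share all true variants and each adds 10% private false positives, so
  the two-caller consensus equals the truth table by construction.
- **Methylation**: every reference CpG (optionally subsampled); a
  `methylated_fraction` (default 0.232) share is methylated with both
  replicates drawn in (0.55, 1.0) and the rest in (0.0, 0.45), leaving a
  guard band so the >50%-in-both rule recovers the truth exactly. Methylated
  CpGs attract C>T mutations with relative weight
  `methylation_mutation_multiplier` (default 30).

Defaults mirror the study conditions: 5 tumors, 52× tumor / 26× normal
coverage, 60,000 markers, purity 1.0 (set e.g. 0.825 to emulate a 15–20%
contaminated tumor).

**Scope.** The generator covers whole-chromosome events, SNVs and CpG
methylation only: no structural variants, indels, subclonal populations,
GC-dependent coverage bias, mapping artifacts, or linked reads. Chromosome
lengths are miniature (≈ 3.4 Mb genome) to keep tests fast; rates are
per-Mb, so statistical behavior scales.

## 7. Numerical and interface choices

- Internal coordinates are 1-based everywhere; readers/writers are the only
  conversion points (VCF via pysam, methylation tables 0-based half-open).
  Chromosome names are normalized to the `chr` prefix on ingestion.
- Empirical p-values use strict tails without pseudo-counts; zero is a
  legitimate value at finite N and is displayed as "< 1/N".
- BH adjustment is delegated to `statsmodels`; binomial and correlation
  machinery to `scipy`; file formats to `pysam`/`pyfaidx`. The permutation
  engine, grid search, timing classifier, context classifier and generators
  are implemented here because their specific conventions are the substance
  of the package.
- Percentiles use `numpy.percentile` linear interpolation.
- The purity grid step (0.0125) resolves the ±0.03 recovery target with
  margin; the near-tie epsilon `0.005·(1 + best)` is small enough not to
  merge genuinely different fits at study coverage but wide enough to
  capture exact mean-level aliases under sampling noise.

## 8. Limitations

- The recurrence test conditions on each tumor's observed ploidy multiset;
  it cannot detect recurrence expressed only in arm-level events, which are
  deliberately excluded from the matrix.
- The purity search assumes one dominant clone and integer whole-chromosome
  states; focal events influence it only through the per-chromosome medians.
- Timing classification assumes mutations arise on a single homolog and
  ignores subclonality; `indeterminate` absorbs low-depth ambiguity but not
  model misspecification.
- The methylation enrichment treats variants as independent Bernoulli trials
  with a genome-wide background fraction; regional mutation-rate and
  methylation covariation would require a matched-background test.
- The packaged comparator spectrum is synthetic (Section 4); correlations
  against it validate machinery, not biology.
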