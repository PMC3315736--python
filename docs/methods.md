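# Methods

This note documents the models behind each pooldiver module, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data does and does not capture.

## Divergent-group selection

Candidates carry an EBV (predicted transmitting ability for calving
interval, in days — lower is better for fertility) and a pedigree.
Relationships are Wright's numerator relationships computed by the tabular
method: founders have diagonal 1 and off-diagonal 0; in parent-first order
`a_ij = (a_{s(i),j} + a_{d(i),j})/2` with unknown parents contributing 0,
and `a_ii = 1 + a_{s(i),d(i)}/2`. Co-ancestry (kinship) is `a_ij/2` and is
reported in percent.

The selection index combines two z-scores: EBVs are standardised over the
candidate set, and relationship values are standardised over all
off-diagonal candidate pairs. The low group is seeded with the minimum-EBV
animal; each later member is the available candidate minimising
`w_ebv·z_EBV + w_rel·(mean standardized relationship to the already-selected
members)`, defaults 0.6/0.4. The high group is built afterwards from the
remaining candidates with the merit sign flipped and seed at the maximum
EBV. Design choices that were genuinely open and are fixed here: the index
is re-averaged against the *growing* selected set (not computed once
against all animals); the high-group seed mirrors the low-group rule; ties
break to the lowest animal id so runs are reproducible. The greedy trace
(chosen id and score per step) is retained so any step can be replayed and
audited.

Known behaviour: the co-ancestry penalty trades merit for diversity, so
group-mean EBVs are slightly less extreme than a pure EBV ranking; raising
`w_rel` lowers within-group co-ancestry monotonically on the cohorts
tested, but greedy selection carries no global optimality guarantee.

## Pooled read counts and variant calling

Read evidence is reduced to per-site, per-pool counts. Quality filtering
discards reads with mapping quality ≤ 50 or base quality ≤ 20 (the cutoffs
are inclusive discards; both are configurable). A site is called when the
alt-supporting reads summed across both pools reach `min_alt_reads`
(default 4); the rule is deliberately summed, not per pool, so a site can
be called on one pool's evidence alone, in which case the zero-depth pool's
frequency is reported as missing rather than 0. Allele frequency is the
alt fraction of post-filter depth. Multi-allelic evidence is expected to be
reduced upstream to the most frequent non-reference allele; the calling
layer is strictly biallelic.

Coverage summaries: per pool, covered length is the number of target bases
with depth ≥ 1 and mean fold coverage is the mean depth over covered
bases; the combined mean is the mean of the two per-pool means and the
combined total their sum (56× and 32× pools give 44× mean, 88× total).

## Fisher's exact test and FDR control

Each testable site (called, non-zero depth in both pools) yields the 2×2
table `[[ref_low, alt_low], [ref_high, alt_high]]`. The two-sided p-value
uses the point-probability rule: with margins fixed, sum the hypergeometric
probabilities of all tables whose point probability is at most that of the
observed table. Point probabilities are computed from a cached
log-factorial table (`gammaln`), so arbitrary depths cannot overflow, and
near-ties are included using a relative tolerance of 1e-12 — the same
convention standard exact-test implementations use. The batch path
evaluates the whole support of many tables at once in chunks (~1 µs per
table at pool-seq depths), which makes replicate-level calibration studies
cheap.

Benjamini–Hochberg is the standard step-up: `q_(i) = min_{j≥i} p_(j)·m/j`
clipped to 1, one family per analysis (all tested sites together). A site
is significant when `q < α`; defaults α = 0.01 for the between-pool
comparison and α = 0.1 for the genotype-concordance comparison. Sites with
zero depth in one pool are excluded from testing since no 2×2 table
exists.

Top lists are greedy by ascending p with a minimum spacing (default 10 Mb)
enforced per chromosome among accepted sites; when per-category lists are
requested the spacing is enforced within each category independently.
Distribution summaries report histogram counts, sample skewness, excess
kurtosis and theoretical-vs-sample normal quantiles; a zero-variance
sample reports missing moments.

## Concordance and false-negative validation

Actual frequencies come from diploid genotypes: alt copies / (2 × number
of non-missing animals), missing genotypes dropped per SNP, never imputed.
Each SNP is tested once per pool (alleles × method 2×2) and BH spans all
SNP×pool tests.

False-negative rates take a reference set of loci asserted to segregate.
With the default fixed-denominator convention,
`FNR(t) = 100 · #(undetected with depth ≥ t) / #reference`, the convention
that produces figures like 5/67 = 7.5% and 2/67 = 3.0% at the ≥ 10× and
≥ 30× tiers; it makes FNR non-increasing in the tier by construction. A
tier-restricted denominator is available for database-style comparisons
where only in-tier loci are meaningful. Depth quartiles by detection
status are Tukey hinges (medians of the sorted halves, each half including
the overall median when n is odd) — chosen over interpolated percentiles
for exact reproducibility.

## Variant annotation

Transcript models hold exon and CDS intervals (0-based half-open
internally; GTF/VCF 1-based inclusive on disk, converted only in the
readers). Classification per transcript: CDS → coding exon; exonic
non-CDS → 5'/3' UTR by strand and position relative to the CDS span;
inside the transcript but not exonic → intron; within `flank` bases
(default 3,000, matching a capture design that targets 3 kb each side of a
gene) → 5'/3' flank by strand; otherwise intergenic. Across transcripts
the precedence is coding exon > UTR > intron > flank > intergenic, then
longest CDS, then lowest transcript id. Published-style category tables
merge UTRs with flanks into a single "UTR" row (the capture's "UTR" baits
covered the flanks); the unmerged view is also available since the
internal classes stay distinct.

Coding effects: the affected codon is located from the cumulative CDS
position (strand-aware, alleles complemented on the minus strand) and
translated with the standard nuclear code; synonymous iff the amino acid
is unchanged. Transcripts whose total CDS length is not a multiple of 3
are flagged unusable for coding calls rather than guessed at. Indels get a
feature class from their anchor base but no effect call. A variant whose
stated reference allele disagrees with the reference sequence is a data
error, not a silent skip.

## Design calculations

`min_detectable_maf = k / C` (threshold k reads, combined coverage C) is
the average-case bound — at C = 88 and k = 4 it is 4.5% — and is exposed
separately from the exact detection probability
`P(X_low + X_high ≥ k)` with `X_pool ~ Binomial(depth_pool, f')`,
`f' = f(1−e) + (1−f)e`, computed by exact convolution. The ratio answers
"what MAF yields k alt reads on average"; the convolution answers "with
what probability is a given MAF actually detected", which is materially
lower near the bound (≈ 0.56 at MAF 4.5%, depths 56/32, k = 4). Power for
the two-pool Fisher comparison is Monte-Carlo (binomial tables at the true
frequencies; reported with its binomial standard error).

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical skeleton of the design:

* **Pedigree:** paternal half-sib families — `n_sires` founder sires,
  offspring with unknown, mutually unrelated dams; EBVs additive
  (offspring = half the sire EBV + Mendelian-sampling noise with variance
  0.75·σ²; σ = 4 days, giving PTA spreads of a few days as seen in
  progeny-tested bulls). Reliability and daughter counts are decorative
  metadata with realistic magnitudes.
* **Frequencies:** base alt frequency uniform on [0.05, 0.5] (the spectrum
  of the real gene set is unknown; this stand-in is configurable). A
  fraction `frac_differential` (default 0.15, in the region of the ~17%
  of SNPs the design flags) of loci get an exact ±`differential_effect`
  (default 0.35, the scale of published top differentials) shift in a
  randomly chosen pool, clipped-feasible so the planted difference is
  exact.
* **Read counts:** per-locus, per-pool depths are negative-binomial with
  means 56/32 (the unequal capture efficiency of the two pools) and
  dispersion `d` (variance µ + dµ², default d = 0.3 so depth SDs are of
  order half the mean, echoing the large between-pool and between-locus
  coverage variability of capture data; d = 0 gives Poisson). Alt counts
  are binomial at the error-folded frequency; the default substitution
  error 0.001 reflects post-quality-filter rates. Counts are emitted
  post-filter; raw per-read MQ/BQ records can be generated separately to
  exercise the filter.
* **Toy genome:** one gene per chromosome, 2–4 exons, both strands, UTRs,
  stop-free frame-consistent CDS, 3 kb flanks inside a 600 b intergenic
  margin, with planted variants of every class whose labels are re-derived
  through the annotation module before the bundle is emitted.
* **Genotypes:** per animal Binomial(2, f) in the pool's true frequency —
  i.e. Hardy–Weinberg within pool, no family structure at the genotype
  level.

Not modelled: raw reads, adapters, duplicates, capture chemistry,
alignment or recalibration artefacts, linkage disequilibrium between loci
(loci are independent, whereas real capture targets are genic and locally
correlated), allele-specific capture bias, and pooling inequality between
individuals. Tests passing on this data therefore validate the statistical
machinery — calling thresholds, exact-test calibration, FDR control,
estimator bias, annotation logic — not robustness to those upstream
artefacts.

## Numerical conventions and problem sizes

Coordinates are 1-based inclusive externally and 0-based half-open
internally, converted only in the IO layer; missing values are `.` in VCF
and `NA` in TSV. All randomness flows through `numpy` Generators seeded
from a single global seed with fixed per-generator stream offsets, so
equal configurations give byte-identical outputs. Exact-test tie tolerance
is 1e-12 (relative); BH uses a stable mergesort so equal p-values keep
input order.

The shipped test and demonstration sizes — 2,000 loci, 698 pedigree
candidates, 500 calibration replicates, 10⁶-draw Monte-Carlo checks — were
chosen so the complete suite runs in well under a minute of CPU for the
unit tests and a few tens of seconds for the calibration studies, while
keeping Monte-Carlo standard errors small enough for 3-SE acceptance
bands to be meaningful.

## Known limitations

* Greedy selection is a heuristic; no claim of optimality of the chosen
  groups under the index.
* The Fisher test conditions on both margins; with very shallow pools it
  is markedly conservative, which the power module makes visible.
* The per-pool frequency estimator ignores the finite pool size (2N allele
  draws underlying the reads); at 75 animals per pool this extra variance
  is small relative to read sampling at the default depths but is not
  corrected for.
* Annotation handles SNP coding effects only; indel frameshifts,
  splice-site disruption and regulatory-motif effects are out of scope.
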