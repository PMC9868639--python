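# Methods

## The analysis in brief

Crossbred cows carry chromosomes that are mosaics of segments inherited
from indigenous *B. indicus*, Holstein-Friesian (HF) and Jersey ancestors.
`boagwas` labels each haplotype window with its ancestral origin, lets
every SNP allele inherit that label, and then partitions the association
signal at each SNP into a breed-origin effect (the count of haplotype
copies from one ancestor, capturing loci fixed for alternative alleles
between ancestors) and within-origin allele-substitution effects (an
in-crossbred expression of each ancestor's own GWAS). All models are
generalized least squares under a genomic-relationship + herd covariance
estimated once by REML and held fixed across SNPs.

## Simulation model

**Ancestral allele frequencies.** A shared ancestral frequency per SNP is
drawn uniformly on (.05, .95) and drifted into each population by
Balding–Nichols steps: Beta with mean p and variance F·p(1−p). Default
drifts: indicus 0.22 and taurus 0.12 from the root (deep indicus/taurus
split), then HF and Jersey each 0.05 from the taurus node (shallow
within-taurus split). These defaults give Hudson Fst ≈ 0.3–0.4 between
indicus and taurus panels and ≈ 0.1 between HF and Jersey, reproducing
the ordering that the between-subspecies differentiation far exceeds the
within-taurus one. No coalescent machinery is used; between-population
differentiation is what the ancestry classifier needs.

**Array ascertainment.** With `maf_skew="array"` a candidate SNP is
retained with probability proportional to its heterozygosity in the
exotic (HF/Jersey mean) frequencies. This mimics a genotyping array
designed on *B. taurus*: the exotic-origin MAF spectrum is pushed high
while the indigenous-origin spectrum stays skewed low — the asymmetry
that makes within-indigenous scans harder, and that the per-origin MAF
masks react to.

**Within-population LD.** Panel haplotypes can be drawn as mosaics of a
finite founder pool (default 30 founders, switch rate 1/cM). This is a
first-order haplotype-copying scheme, not a population-genetic LD model;
it exists so that within-ancestor QTL have tagging SNPs and so that
crossbred cows share founder segments (giving the GRM usable off-diagonal
variance).

**Crossbreeding.** Each transmitted haplotype is built by placing
recombination breakpoints as a Poisson process with rate n_generations
per Morgan on the genetic map (uniform 1 cM/Mb by default) and drawing
each segment's origin i.i.d. from the target ancestry proportions
(.36/.49/.15 by default), then copying alleles from a random founder
haplotype of that origin. This "copying" scheme is distributionally
equivalent to the backcross-style mating description for the marginal
law of a single genome: expected composition equals the target exactly,
tract lengths scale as 1/(generations), and the realized mean composition
of 2,000 cows lands within ~±.01 of the target. An explicit `"f1"`
scheme produces true first crosses (one pure haplotype from each of two
origins) for the structural limit cases. The number of generations is a
free parameter because the real population mixes deep and very recent
crossbreeding; studies in this package choose it per purpose (see
"Problem sizes" below).

**QTL.** Breed-origin QTL have dosage equal to the count of
favored-origin haplotypes at the locus (the idealization of a locus fixed
for alternative alleles between ancestors). Within-ancestor QTL draw a
segregating allele (default frequency 0.3) on the named ancestor's panel
haplotypes, zero elsewhere, and ride into crossbreds through the recorded
segment sources. QTL loci are hidden from the marker set by default.

**Test-day records.** yield = μ + parity + CDC + year-month + per-parity
and per-CDC third-order Legendre lactation curves + herd + animal +
permanent environment + residual, with ~6 monthly records per cow between
8 and 340 days in milk and herd sizes 1 + Poisson(1.17) (mean ≈ 2.17).
Default magnitudes: grand mean 7.22 kg/day, test-day phenotypic SD
2.0 kg, repeatability .35, herd share .10, factor-effect SDs 0.25–0.4 kg.

**Heritability scale.** The `h2` parameter refers, by default, to the
trait actually analyzed downstream — the per-cow mean adjusted test-day
yield y* — because that is the scale on which power statements about the
GWAS live. Averaging r records shrinks the residual but not the animal,
permanent-environment or herd components, so a cow-mean h² of .18
corresponds to a smaller single-test-day additive share (≈ .10 at 6
records with the default shares); the simulator derives the test-day
components internally and stores both scales in `SimTruth`.
`h2_scale="testday"` switches the interpretation.

**Moment matching.** The simulated animal, permanent-environment, herd
and polygenic draws are standardized to their exact target variances
(centered, scaled by the sample SD). This is a conventional
variance-reduction device for simulation studies: the realized variance
shares equal their nominal values, so recovery experiments measure
estimator error rather than the sampling noise of the generator.

**Polygenic background.** When the crossbred panel is supplied, the
residual polygene is the sum of ~2,000 randomly chosen segregating SNPs
with i.i.d. normal effects, scaled to the target additive variance, so
breeding values carry the genomic covariance a GRM model assumes. Without
a panel the polygene is i.i.d. per cow — useful for null phenotypes, but
then no marker-based analysis can (or should) recover the heritability.

## Test-day adjustment

The repeatability model is solved through its mixed-model equations.
Variance components are estimated by EM-REML (Henderson's updates, dense
MME inverse per iteration) with first-level-zero reference constraints,
CDC×year-month cells below 3 records merged into the margins, and aliased
columns dropped by pivoted QR and reported by name. For populations whose
MME exceed ~3,500 equations the components are estimated on a
herd-stratified subsample (default 1,200 cows) and the full solutions
obtained by one sparse solve at those components; `AdjustConfig.vc` fixes
the components directly (used by the large simulation studies, with the
estimation step validated separately). Because residuals satisfy
e = y − Xb − a − h record by record, y* equals the cow mean of
(y − fitted fixed part); it is therefore invariant to record order and to
duplication of all records, while the *fixed-effect solutions themselves*
shift slightly under duplication because the variance components re-fit —
the invariance that matters downstream is y*'s.

## Local ancestry

Windows are consecutive blocks of W SNPs per chromosome; a trailing
window is kept only if it reaches 80% of W (default W = 500 for
production-style runs; the calibration studies below use smaller windows
on their denser-recombination genomes). Per window, a PCA is trained on
pooled reference haplotypes (default K = 10 components) and each origin
is summarized by its projected mean and diagonal variance floored at
`ridge` = 1e-4. Emission = Gaussian log-density; transition = constant
switch probability τ (default .01) split evenly across the other origins,
or optionally a genetic-map-scaled probability 1−exp(−τ·d) per boundary
gap d in cM; decoding = forward–backward in log space per chromosome,
vectorized across haplotypes. Hard labels are posterior argmax with ties broken
toward the higher-prior origin. On default-divergence purebred panels
the window accuracy is ≥ .99, mirroring the near-perfect validation
accuracies the method is known for; HF/Jersey confusion dominates the
residual error, as expected from their shallow divergence.

## Origin coding

Ordered ancestry-genotype states are the 4·n² combinations of ordered
genotype and ordered origin pair; distinguishable locus states collapse
each state with its haplotype-slot swap. Brute-force collapse gives 10
classes for two ancestors and **21** for three. (The figure of 24
sometimes quoted for the three-ancestor table is inconsistent with the
swap rule that yields 10 in the two-ancestor case; the multiset formula
n(2n+1) — 3, 10, 21, 36 for n = 1…4 — confirms the computed counts, and
the package reports the computed value.)

Cows with no haplotype of an origin contribute 0 to that origin's dosage
vector — the only coding under which w2+w3 (two-way) and w2+w4+w5
(three-way) reproduce the raw genotype dosage exactly, making the
within-origin effects conditional allele substitutions. Per-origin allele
frequencies are computed on the crossbred cows' origin-assigned
haplotypes; an origin unobserved at a SNP is masked rather than an error.
When a within-origin term is masked (MAF ≤ 1%) the model variant drops
that column (removal, not a zero constraint — the fits are identical);
when HF and Jersey are both rare, both within-taurus terms drop; the
mixed case drops only the rare one.

## Association models and inference

The null covariance V = σ²ₐG + σ²ₕZZ′ + σ²ₑI is estimated by
average-information REML with Levenberg–Marquardt damping, an active set
at the zero boundary, and rejected-step backtracking; convergence
requires a log-likelihood change < 1e-6 at an undamped step plus a small
scale-free gradient. The damping matters: when crossbreds carry many
generations of recombination the GRM off-diagonals shrink toward zero,
σ²ₐ and σ²ₑ become nearly unidentifiable, and the plain AI update
oscillates (the fit is validated against direct dense-V likelihood
maximization in the tests, including at that boundary).

Scans whiten once with the Cholesky factor of V and fit each SNP's model
by small-system GLS assembled from cached cross-products; Wald χ²(1 df)
per fitted effect. An exact variant (`snp_scan_exact`) re-estimates the
variance components per SNP with the SNP's terms in the fixed part — it
agrees with the fixed-V scan to a fraction of a standard error on null
traits and exists for spot checks, not genome scans. Linearly dependent columns are dropped within-origin
terms first. A leave-one-chromosome-out (LOCO) variant rebuilds the GRM
without the tested chromosome; it is off by default (matching the
production pipeline) and used by the null-calibration study, where
keeping tested SNPs inside the GRM visibly deflates the tests
(λ ≈ 0.985 without LOCO, ≈ 0.996 with).

Genomic control divides each effect's χ² by λ = median(χ²)/0.4549 (also
when λ < 1); Benjamini–Hochberg q-values are computed within effect type;
the FDR tier is the smallest of 5/10/20/30% at which the SNP stays
significant. Regions merge significant SNPs within 2 Mbp and report the
homozygote difference 2|ĝ| with its share of mean yield.

## Problem sizes of the built-in studies

The test suite's simulation studies each fix their own study conditions:

- **Heritability recovery**: 5,000 cows, 20,000 SNPs on 10 chromosomes,
  4 generations of recombination (few generations keep founder-segment
  sharing, hence GRM information, high), cow-mean h² = .18; REML on y*
  recovers ĥ² within ±.03.
- **Null calibration**: three independent replicates of 800 cows ×
  20,010 SNPs on 29 autosomes with h² = 0 (no additive variance at all —
  with a polygenic background the breed-origin test would correctly pick
  up local origin-differentiated polygenes, and "type-I error" would be
  ill-defined), 30 generations and 12-SNP windows to maximize the number
  of effectively independent ancestry tracts, LOCO GRMs. Across seeds the
  pooled genome-wide λ is centered at 1.00 (SD ≈ 0.02 per replicate) and
  the g1 type-I error at ≈ .049.
- **Power**: 10 replicates of 2,000 cows × 5,000 SNPs on 10 chromosomes,
  8 generations, 25-SNP windows, LOCO scans, one hidden breed-origin QTL
  with homozygote difference equal to 10% of mean yield (2α =
  0.722 kg/day); detection = any breed-origin test at FDR 5% within
  15 Mbp of the QTL. On a shorter genome the QTL's chromosome-scale
  ancestry signal inflates the g1 median χ² so strongly that genomic
  control masks the QTL itself (λ(g1) ≈ 1.5 with one QTL on a
  5-chromosome genome), and a full GRM absorbs the tested signal; the
  10-chromosome LOCO design keeps both effects at realistic size.

## Known limitations

- No sequence-level simulation, mutation, genotyping error, missingness,
  or X chromosome; phased and complete genotypes are assumed throughout.
- The founder-copying LD model produces realistic tagging but not a
  calibrated LD decay curve; absolute within-origin power on real data
  will differ.
- Ancestry posteriors are collapsed to hard labels before origin coding
  (no dosage-uncertainty propagation), as in the analysis this package
  follows.
- The two-step adjust-then-associate scheme is reproduced deliberately;
  a joint fit would propagate adjustment uncertainty but would not match
  the reference workflow.
- EM-REML for the adjustment model is dense and practical to ~3,500
  equations; beyond that the subsample-then-solve path trades a little
  variance-component precision for tractability.
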