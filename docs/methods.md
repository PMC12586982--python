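# Methods

`histomics` implements the bespoke computational stages of a multi-omic
comparison of carcinoma histotypes (ovarian/uterine endometrioid and
ovarian/GI mucinous being the motivating setting): sample identity
verification, somatic copy-number and structural-variant interpretation,
Bayesian comparison of gene alteration prevalence, methylation-based
tissue-of-origin projection, and pathway-level survival analysis. Each
stage is exercised end to end on synthetic cohorts with known ground
truth; this note records the models, the tunable parameters and the design
choices made where the procedure was genuinely open.

## Genotype-concordance sample matching

When several sequencing libraries exist per patient, sample swaps are
detected from consensus genotypes at a shared panel of biallelic SNP sites
(default 10,000 single-base-substitution positions sampled without
replacement from a site catalog). A site is *evaluable* in a sample when
it has at least 20 qualified reads (mapping/base quality filtering is
assumed upstream of the base counts) and at least 95% of reads support one
base; the 95% boundary is treated as inclusive. Pair concordance is the
fraction of jointly evaluable sites whose consensus bases agree; a pair
with no jointly evaluable site is flagged non-comparable and excluded.

The null distribution of concordance between unrelated samples is built
from 1,000 randomly sampled pairs (annotated/known pairs are excluded so
they cannot inflate the upper quartile; this is switchable). Quartiles use
the linear-interpolation convention, recorded in the output because IQR
thresholds are convention-sensitive. A pair is an outlier — a genotype
match — when its concordance exceeds Q3 + 1.5·IQR.

Matching is *mutual-best*: each sample's candidate partner is its
highest-concordance partner above the threshold, and a pair is emitted
only when the choice is reciprocal. A sample is declared ambiguous and
excluded only when a runner-up partner lies within 1.5·IQR (the null's own
dispersion scale) of the best. The rationale: in a 200-sample cohort there
are ~20,000 unrelated pairs and the concordance null is close to normal,
so the Q3 + 1.5·IQR point sits near the 99.7th percentile and a handful of
unrelated pairs necessarily straggle over it; discarding a perfect
(concordance ≈ 1) match because one marginal outlier also cleared the
threshold would misclassify valid pairs, whereas two genuinely
indistinguishable partners (e.g. triplicate libraries or contamination)
still trigger exclusion. Genotype-matched pairs whose annotated tumor
types differ are both excluded; when the genotype match contradicts the
annotated pairing, the genotype match wins.

## Integer copy number and structural variants

Observed log2 ratios of segmented read depth (matched-normal log ratios
subtracted to cancel technical bias and germline copy events) are modeled
as a tumor/normal cell mixture:

    R = log2( (C_T·p + C_N·(1−p)) / (P_T·p + P_N·(1−p)) )

with purity `p`, tumor segment copies `C_T`, normal segment copies `C_N`
(default 2), tumor ploidy `P_T`, normal ploidy `P_N` (default 2). Integer
copy number inverts this relationship, rounding to the nearest integer
with ties away from zero and clipping at 0; `C_T = 0` with `p = 1` maps to
a −∞ sentinel that round-trips correctly. Sex chromosomes are processed
only when a per-segment `C_N` is supplied, since `C_N = 2` is wrong for
X/Y in males and sex is not always recorded. Samples with missing purity,
purity ≤ 0.20, or tumor cellularity ≤ 20% are excluded with recorded
reasons. For purity > 0.2 the noiseless forward model is inverted exactly
over the whole grid of copy states 0–12 and ploidies 1.8–3.2 (tested).

Call rules, with thresholds kept exactly as stated:

* **Focal deletions** — segments < 3 Mb with integer copies 0 (homozygous)
  or 1 (hemizygous). The call gains a "+" (supported) flag when ≥ 2
  improper read pairs are consistent with the deletion: inward-pointing
  ("+−") orientation with breakends within a 10 kb flank of each segment
  end. The flank width is not a published constant; it is an explicit
  configuration default.
* **Amplicon graphs** — seeds are segments with copies strictly greater
  than 2.5× the sample's average ploidy; low-copy gains with copies ≥ 1.5×
  ploidy join a seed's component when ≥ 2 read pairs bridge them to a node
  of the component (transitively). Candidates with no path to a seed are
  dropped; isolated seeds are kept as singleton nodes. The gain criterion
  is read as a lower bound (a point value would select almost nothing),
  and node weight is the integer copy number. Every emitted graph is
  checked against its invariants (edges ≥ 2 bridging pairs, every
  component contains a seed).
* **Rearrangements** — ≥ 2 improper pairs and ≥ 1 split read; events whose
  both breakends fall within 1 kb (config default) of a matched-normal
  event are removed as germline/artifact.

Coordinates are 0-based half-open in memory; SEG-like files are 1-based
inclusive and BEDPE 0-based half-open, converted only at the I/O boundary.

## Alteration prevalence between histology groups

Sequence and structural alterations are integrated into a binary
gene × sample matrix: a gene is altered in a sample if a kept mutation
names it or a deletion/amplicon/rearrangement breakend overlaps its
interval (idempotent under duplicate records). Mutation read-support
filters: targeted assays require an altered fraction strictly above 10%;
WES additionally requires ≥ 5 altered reads in at least one sample
carrying the variant. Samples with more than 500 mutations per exome are
hypermutators; they are excluded from model fitting and from the
gene-frequency denominator but stay in descriptive output. Comparison
genes are driver genes altered in at least 10% (inclusive) of the combined
non-hypermutator cohort.

For each gene, with `y_j` altered of `n_j` samples in group `j`:

    y_j ~ Binomial(θ_j, n_j),   logit(θ_j) = α0 + α1·x_j
    α0 ~ Normal(0, sd 10),      α1 ~ Laplace(0, 1)

`x_j` is 0 for the reference group, 1 for the comparator. The Normal prior
is parameterized by its standard deviation. The reported log odds ratio is
log-odds(reference) − log-odds(comparator) = −α1, so positive values mean
the alteration is more prevalent in the first-named group; the convention
is carried in the output because the dummy coding alone would imply the
opposite sign. Summaries are the posterior mean and the 5th/95th
percentiles (90% credible interval); a gene differs significantly when
that interval strictly excludes zero.

Two independent routes compute the posterior. The reference route is a 2-D
trapezoidal quadrature over α0, α1 ∈ [−12, 12] at step 0.01 (truncation
error is negligible: the Laplace prior leaves < 1e−5 relative mass beyond
the bounds, and halving the step moves the LOR mean by < 1e−3). The
sampling route is an adaptive random-walk Metropolis (4 chains, 5,000
burn-in per chain, proposal scale tuned toward ~35% acceptance during
burn-in only, 50,000 pooled draws by default; effective sample size by
initial-positive-sequence autocorrelation, summed over chains). The two
routes agree within Monte-Carlo standard errors across random count
configurations; for posterior percentiles the MC standard error uses the
asymptotic quantile formula sqrt(p(1−p)/ESS)/f(q) with the density at the
quantile estimated from the draws, since these posteriors are strongly
skewed when a group's count sits at a boundary.

The multiplicity question — how surprising is the *number* of significant
genes — is answered by a Monte-Carlo null: a reps × P matrix of
Uniform(0,1) deviates binarized at α (default 0.1), row sums forming the
null count distribution, p = fraction of rows with at least the observed
count, no continuity correction. At large reps this converges to the
binomial tail Σ_{k≥n} C(P,k)α^k(1−α)^{P−k} (tested at 10^6 replicates).

A binomial proportion-CI helper with selectable method (Clopper–Pearson,
Jeffreys, Wilson) is provided for descriptive zero-numerator summaries; no
single method is asserted as canonical.

## Methylation tissue-of-origin projection

Probes on chromosomes X/Y, with detection p > 0.5, or overlapping a SNP
with minor-allele frequency > 10% are removed (thresholds strict, order
independent). The 0.5 detection-p default is retained as stated even
though 0.01 is the field's convention; it is configurable and logged. The
per-sample methylated fraction is the share of probes with β strictly
above 0.3.

The projection model is fit on a labeled reference cohort only: the 1,000
most variable probes (sample variance across reference samples), PCA on
reference-centered values keeping 5 components, then linear discriminant
axes from the generalized eigenproblem of between- vs pooled within-class
scatter of the PC scores (k − 1 axes for k classes). PC scores enter the
LDA unscaled. Class priors are uniform to avoid reference-cohort size
bias. Every axis (PC and LD) is oriented so its largest-magnitude loading
is positive, making runs comparable. Query samples are restricted to the
model's probes; up to 5% missing probes are imputed at reference means,
more is an error. Class probabilities are Gaussian posteriors with the
pooled within-class covariance in LD space; projecting the reference
samples reproduces the fit-time coordinates exactly. Class ellipses are
level sets of the fitted bivariate normal with squared Mahalanobis radius
at the chi-square(2) quantile (5.991 at 95%).

## Pathway survival comparison

A sample is pathway-altered when any gene in the pathway set carries a
somatic mutation or structural variant in that sample (set semantics;
genes missing from the matrix warn and are ignored). Survival is
summarized with the Kaplan–Meier product-limit estimator and compared with
the two-group log-rank test (chi-square, 1 df), both via `lifelines`; ties
at an event time share the risk set just before that time. A group with
zero observed events is an error with guidance rather than a silent NaN.
Records with missing follow-up are dropped with a logged count.

## Synthetic cohorts

The generators forward-simulate exactly the data models above, so
downstream recovery can be checked against known truth. One integer seed
drives named substreams (CRC32 of the generator name mixed into the seed
sequence), so identical arguments are byte-reproducible and adding a
generator never perturbs the others.

* **Pileup panels** — biallelic sites with allele frequency ~
  Uniform(0.05, 0.5) (chosen so unrelated-pair concordance sits well below
  1; real dbSNP panels are not modeled), Hardy–Weinberg genotypes,
  Poisson(depth) reads, per-read error uniform over the three wrong bases.
  Duplicated individuals yield two independently sequenced panels from the
  same genotypes. Under this model the expected unrelated concordance has
  a closed form (evaluable ⇔ both samples homozygous at deep, error-free
  coverage), used as the generator's analytic oracle.
* **Copy-number cohorts** — piecewise-constant copy states pushed through
  the mixture equation plus Normal(0, noise_sd) log-ratio noise; deletion
  states get focal (< 3 Mb) segments and inward-facing improper pairs,
  amplified states get bridging pairs to the first seed, each with a
  stated support count.
* **Alteration matrices** — Bernoulli(θ[gene, group]) entries; per-sample
  exome burdens ~ Poisson(54) (the cohort-typical median), with a stated
  fraction inflated past the 500-mutation hypermutator threshold by a
  +501 + Poisson(2000) draw. Hypermutation is simulated in the burden
  field only; per-gene θ is untouched.
* **Beta matrices** — Beta-distributed probes (concentration 20 around a
  probe-specific mean in 0.15–0.85); each informative probe is assigned a
  marker class whose samples are shifted by `effect` toward the far side
  of the unit interval. Annotations pass the probe filters by
  construction; filter behavior is tested on hand-made matrices. Real
  array features *not* emulated: probe-type chemistry effects, batch
  structure, CpG-island spatial correlation — so passing tests demonstrate
  correctness of the projection machinery, not robustness to array
  artifacts.
* **Survival tables** — exponential event times at baseline_rate
  (× hazard_ratio in the altered group) with independent exponential
  censoring; censor_rate 0 is accepted as the no-censoring limit.
* **The structural-variant fixture** — a deterministic 12-segment,
  9-record configuration in which every calling threshold (size, copy
  state, orientation, pair/split evidence, normal overlap) is exercised on
  both sides, with the full expected call set enumerated by hand.

## Problem sizes used in the standard checks

The shipped test suite and `scripts/acceptance.py` run: the full
copy-number inversion grid (312 configurations); 50 genotype cohorts of
200 samples × 10,000 sites at 1% read error and 50× depth; 20 random count
configurations for sampler-vs-quadrature agreement plus 200 simulated
matrices (10,000 draws each) for interval calibration; 10^6 replicates of
the multiplicity null; 3-class methylation cohorts with 200 training and
40 test samples per class over 2,000 probes (500 informative); and 1,000
null plus 100 high-hazard survival cohorts. These sizes give Monte-Carlo
error comfortably inside every tolerance while keeping a full run in a
few minutes on one core.

## Known limitations

* The prevalence sampler's heavy-tailed posteriors (a group count at 0 or
  n) mix slowly in the tail; the quadrature route is the reference for
  such configurations and is what the worked example reports.
* Amplicon linking is O(n²) in candidate segments per sample — fine for
  per-sample focal amplifications, not intended for genome-wide bins.
* The projection model assumes query betas are normalized like the
  reference; no cross-platform normalization is provided.
* Matching assumes at most one genuine partner per sample; triplicates are
  deliberately excluded as ambiguous rather than grouped.
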