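# Methods

This note documents the models, defaults and numerical choices behind
`poolgwas`, and what the synthetic-data tests do and do not establish
about real pooled-GWAS data.

## Synthetic data model

The generator produces the three layers of a pooled case-control study.

**Genotypes.** Each SNP has a reference-panel allele frequency for its
"A" (red-channel) allele, drawn with minor-allele frequency uniform on
a configurable range and assigned to either allele with probability ½
(so the mean red-allele frequency over a panel is 0.5 — the assumption
the correction-factor calibration rests on). Controls are sampled under
Hardy–Weinberg equilibrium at the panel frequency; cases at the
frequency implied by a per-SNP allelic odds ratio,
p_case/(1−p_case) = OR · p/(1−p). ORs are specified for the minor
allele and inverted internally when the reference allele is the major
one. Sex and age are drawn per group (defaults ~80% female cases at age
45.3 ± 14.5 vs ~50% female controls at 56.3 ± 24.4, approximating an
autoimmune-thyroid cohort) so the covariate-adjusted stage has real
confounding structure to work with when enabled; genotypes are
independent of sex/age by default.

**Pools.** A pool's true per-SNP allele fraction is the
contribution-weighted mean dosage, Σwᵢdᵢ / 2Σwᵢ, with weights
wᵢ = max(0, 1 + cv·zᵢ) modelling unequal DNA amounts; truncation at
zero keeps fractions physical. cv = 0 gives the exact equimolar mean.
The default design mirrors a three-pool discovery study: 154/198,
218/213 and 40/87 cases/controls (412/498 total), with 4, 3 and 2
replicate arrays per group respectively — replicate counts within the
2–4 range such designs use; the exact per-pool allocation is this
package's choice.

**Arrays.** Probe intensities are linear in the pool fraction p with
multiplicative Gaussian channel noise:
red = S·p·(1+cε), green = S·c_imb·(1−p)·(1+cε′). This is the simplest
model under which the correction factor corresponds exactly to the
generative channel imbalance and red/(red+green) = p in the noiseless
balanced limit. Failed probes are represented by sign-flipping a random
subset (negative beadscores); probe counts per SNP are the design's
expected counts perturbed multiplicatively. A frequency-scale
counterpart, `simulate_paf_measurements`, adds N(0, σ²_pool) noise
directly to per-array PAFs (clipped to [0,1]) for calibration studies;
its default variance 6.8×10⁻⁵ is a published per-array figure for
1M-class bead arrays.

**What the generator does not emulate:** real probe-level intensity
distributions (saturation, background, heteroskedasticity by intensity),
strand-specific chemistry beyond a single label, linkage disequilibrium
between panel SNPs (SNPs are independent, so the proxy check usually
returns `no_proxy` on synthetic panels), population stratification, and
genotyping error in the validation cohorts. Passing tests therefore
establish the *arithmetic and calibration* of the pipeline under its
stated error model, not robustness to every artefact of real arrays.

## Correction factor and PAF

corr is solved per array and strand so that the mean over SNPs of the
mean-probe PAF equals 0.5, by bisection on log-scale over
[10⁻³, 10³] to |mean PAF − 0.5| < 10⁻⁶ (PAF is strictly increasing in
corr, so bisection cannot fail inside the bracket). Probes are usable
when both channels are non-negative and not both zero. Calibration is
run on SNPs passing the PAF-independent filters (panel MAF,
negative-beadscore, intensity-sum), then PAF is recomputed for all
SNPs. Note the method's identifying assumption: the mean true frequency
of the red allele across calibration SNPs is 0.5. On large symmetric
panels this holds to sampling error; on small hand-built SNP sets it
does not, which is why exactness tests evaluate PAF at the generative
corr instead.

## Filter cascade

Defaults: panel MAF > 0.01; negative-beadscore fraction ≤ 0.10 (pooled
over all probes on all arrays; a per-array variant is a config switch);
mean red + mean green ≥ 1200 on *every* array; autosomes only;
case/control replicate-variance F-test two-sided p ≥ 0.001 in every
pool (the variance-difference rule's test and level are this package's
choice — conservative, removing only gross artefacts — and are
configurable); probe count strictly over ½ (panel MAF in (0.01, 0.05])
or ⅓ (MAF > 0.05) of the design's expected probe count, averaged over
arrays; and |overall mean PAF − reference frequency| ≤ 0.3 (boundary
inclusive). SNPs absent from the panel fail a `matched` rule. A SNP is
retained iff all rules pass, and the per-rule flags are reported so
every exclusion has a recorded reason.

## Pooling-error-corrected test

For one pool, d = mean case PAF − mean control PAF across replicate
arrays, and

var(d) = p̄(1−p̄)(1/2n_case + 1/2n_control) + σ²_pool(1/k_case + 1/k_control),

with p̄ the sample-size-weighted pooled frequency. The first term is
the binomial sampling variance of allele frequencies in cohorts of the
pooled sizes; the second is the array measurement variance reduced by
replicate averaging. χ² = d²/var(d) is referred to a 1-df chi-square.
This is the standard pooled-GWAS variance decomposition; it reduces to
the classical two-proportion test at σ²_pool = 0. The test compares
group means rather than regressing PAF on group across arrays; the two
are identical for balanced replicate counts (k_case = k_control, the
default design) and differ only by weighting otherwise.

σ²_pool is a single global scalar: either fixed by config, or
estimated as the median over SNP × pool × group cells of the
replicate-array PAF variance, floored at 6.8×10⁻⁵ (2–4 replicates per
cell are far too few for per-SNP variance estimates; the median over
thousands of SNPs is stable).

Pools are combined by fixed-effect inverse-variance weighting:
w = 1/var(d), combined d = Σwd/Σw, combined var = 1/Σw. Ranking is by
meta p ascending with ties broken by |combined d| descending then SNP
id (deterministic output ordering). Tiers: genome-wide at p ≤ 5×10⁻⁸
(boundary inclusive), suggestive at p < 10⁻⁶. The proxy check labels an
index SNP `supported`/`unsupported`/`no_proxy` using r² > 0.5 proxies
and a support threshold of p < 10⁻³ (the support level is a package
choice, configurable). No genomic-control correction is applied.

## Validation statistics

The crude test is allele-based (each chromosome an observation):
Pearson χ² (1 df, no continuity correction) on the 2×2 allele table,
cross-product OR, Woolf CI exp(ln OR ± z·√Σ1/cell). Zero cells get the
Haldane–Anscombe +0.5 on all cells for the OR and CI only — the χ²
stays uncorrected. The adjusted model is per-individual: logistic
regression of phenotype on dosage with sex and age entered
untransformed (no interactions), fitted by Newton–Raphson/IRLS
(statsmodels), Wald p-values. Perfect separation raises an explicit
error; constant covariate columns are absorbed into the intercept;
rank-deficient designs are rejected. The crude (allele-level) and
adjusted (individual-level dosage) ORs answer slightly different
questions, which is why both are reported side by side.

Two-stage gates: validated at discovery p ≤ 10⁻⁴ (inclusive),
replicated additionally at replication p < 0.05 (strict) with the same
log-OR sign. Pooled-vs-individual concordance is the Pearson
correlation of log ORs (symmetric under allele relabelling, unlike the
OR scale).

## EM haplotypes and LD

From a 3×3 two-locus genotype table only the double-heterozygote class
is phase-ambiguous; EM splits it between coupling and repulsion phases
by the current haplotype-frequency products, starting from linkage
equilibrium, until the largest frequency change is < 10⁻¹⁰ (max 1000
iterations). The observed-data likelihood is non-decreasing per
iteration and the allele-frequency margins are conserved exactly.

Summaries: D = p_AB − p_A p_B; D′ = |D|/D_max with
D_max = min(p_A p_b, p_a p_B) for D > 0 and min(p_A p_B, p_a p_b)
otherwise; r² = D²/(p_A p_a p_B p_b); LOD = log₁₀ of the likelihood
ratio against independence on the unphased genotype data. Confidence
bounds on |D′| normalize the genotype likelihood over a 101-point D′
grid with margins fixed at their MLEs and read off the 2.5% and 97.5%
quantiles (level configurable; the grid-likelihood construction is this
package's choice of CI method). When only haplotype frequencies are
available, expected haplotype counts 2n·h stand in for the genotype
likelihood — exact when phase is unambiguous. Monomorphic loci are
flagged as undefined rather than raising.

## Pipeline and reproducibility

A single seed fans out to per-stage child seeds through numpy
`SeedSequence` spawn keys, so identical configs produce byte-identical
outputs while stages remain independently reproducible. All tables are
TSV with fixed column order; genotypes are PED/MAP with a covariate
TSV; the run summary is JSON whose counts equal the row counts of the
corresponding tables.

## Problem sizes

The default config simulates 2,000 panel SNPs; the test suite and the
acceptance script use 150–400-SNP panels for end-to-end runs,
1,000-SNP recovery studies, and 10,000-SNP type-I calibration — sizes
at which every quoted rate has a binomial SE a few times smaller than
the tolerance it is checked against. The type-I demonstration uses
per-array SD 0.011 (the upper end of published bead-array pooling SDs)
with 2 replicate arrays, where omitting σ²_pool visibly inflates the
5% rejection rate; the adjusted-logistic recovery study uses 500
replicates of n = 1000, large enough that the O(1/n) logistic MLE bias
is negligible against the 3-SE recovery criterion.

## Known limitations

- The correction-factor calibration assumes a frequency-symmetric SNP
  panel; applying it to small or skewed SNP sets biases PAF.
- σ²_pool is global; arrays with SNP-dependent measurement variance
  (e.g. intensity-dependent error) are not modelled.
- The F-test for the variance-difference filter is sensitive to
  non-normal replicate error; with 2–4 replicates its power is low and
  it serves only to catch gross artefacts.
- LD machinery is limited to two loci; no haplotype blocks or phasing
  beyond the double-heterozygote split.
- X-chromosome SNPs are carried only to be excluded by the autosome
  filter; no dosage-compensation model.
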