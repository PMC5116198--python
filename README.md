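# poolgwas

Pooled-DNA genome-wide association analysis: allele-frequency estimation
from two-channel bead-array intensities, SNP quality control, a
pooling-error-corrected association test with inverse-variance
meta-analysis across pools, two-stage individual-genotyping validation,
and two-locus linkage-disequilibrium statistics.

## The problem

Genotyping every individual in a GWAS is expensive. An alternative is to
pool DNA from all cases into one tube and all controls into another, run
a handful of bead arrays per pool, and estimate the case and control
allele frequencies of every SNP from the array's red/green channel
intensities. The cost drops by orders of magnitude, but two extra error
sources appear on top of binomial sampling: pool-construction error
(unequal DNA contributions per person) and array measurement error.
A test that ignores them is anti-conservative. This package implements
the full analysis chain for such a design, and a synthetic-data
generator with known ground truth so every stage can be verified.

## The method

**Pooling allele frequency (PAF).** For a SNP measured by several probes,
each probe reports red and green intensities for the two alleles. The
green channel is systematically dimmer or brighter than the red, so a
per-array, per-strand correction factor *corr* is solved (by bisection;
PAF is monotone in *corr*) such that the mean PAF over all SNPs is 0.5,
and then

    PAF = red / (red + green / corr)

averaged over usable probes (negative "beadscores" mark failed probes
and are excluded).

**SNP filters.** A SNP enters association testing only if: reference-panel
MAF > 1%; at most 10% negative beadscores; mean red + green ≥ 1200 on
every array; autosomal; no significant case/control replicate-variance
difference; probe count over ½ of the design's expected count (MAF 1–5%)
or over ⅓ (MAF > 5%); and |PAF − reference frequency| ≤ 0.3.

**Corrected association test.** Per pool, with d the case−control
difference of replicate-mean PAFs,

    var(d) = p̄(1−p̄) (1/2n_case + 1/2n_control) + σ²_pool (1/k_case + 1/k_control)
    χ² = d² / var(d)   (1 df)

where n are the pooled sample counts, k the replicate-array counts and
σ²_pool the per-array measurement variance (default 6.8×10⁻⁵, a
published bead-array figure; or estimated from the replicates). Pools
are combined by fixed-effect inverse-variance meta-analysis; SNPs at
p ≤ 5×10⁻⁸ are genome-wide significant and p < 10⁻⁶ suggestive, with an
r² > 0.5 proxy-SNP consistency check.

**Validation.** Candidate SNPs are tested on individual genotypes:
allelic Pearson χ², cross-product odds ratio with Woolf 95% CI, and a
sex/age-adjusted logistic regression. A SNP is *validated* at discovery
p ≤ 10⁻⁴ and *replicated* if an independent cohort adds p < 0.05 with
the same effect direction.

**LD.** Two-locus haplotype frequencies are estimated from unphased
genotypes by EM (only the double heterozygote is phase-ambiguous),
yielding D, D′, r², a base-10 LOD against linkage equilibrium and
likelihood-based confidence bounds on |D′|.

## Worked example

The replication-cohort allele table for a chromosome-8 SNP,
reconstructed from minor-allele frequencies 0.219 in 539 cases and
0.174 in 1230 controls:

```python
>>> import poolgwas as pg
>>> t = pg.allele_table_from(0.219, 0.174, 539, 1230)
>>> t
AlleleTable(a_case=236, b_case=842, a_control=428, b_control=2032)
>>> chi2, p, or_crude = pg.allelic_test(t)
>>> round(or_crude, 2), pg.woolf_ci(t)
(1.33, (1.1136511653656094, 1.5900490301785277))
```

The minor allele carries 1.33× the odds of disease, with 95% CI
(1.11, 1.59) excluding 1 — a modest but significant association
(p ≈ 1.6×10⁻³ from the χ²).

A full synthetic run — three pools of 154/198, 218/213 and 40/87
cases/controls (412/498 total) with one planted OR = 2 SNP:

```python
>>> from poolgwas.config import config_from_dict
>>> from poolgwas.pipeline import run_pipeline
>>> cfg = config_from_dict({"seed": 7, "panel": {"n_snps": 300},
...                         "effects": {5: 2.0}})
>>> s = run_pipeline(cfg, "out/")
>>> s["n_snps_retained"], s["tier_counts"], s["replicated"]
(297, {'none': 296, 'genome_wide': 1}, ['snp000005'])
```

297 of 300 SNPs survive QC, the planted SNP is the single genome-wide
hit, and it replicates in the simulated independent cohort.

The same stages are available from the shell:
`poolgwas simulate|qc|assoc|validate|ld|run`.

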