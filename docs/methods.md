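# Methods

This document specifies the statistical model implemented by `mendelscan`, the
defaults it ships with, and the reasoning behind the numerical choices.

## 1. Setting

The experiment is a set of factorial (North Carolina II) breeding blocks: in
each block every sire is mated to every dam, producing full-sib families that
share parents within the block. From each family, a pool of surviving larvae is
sequenced under each of two rearing treatments — a stressor (`low`, e.g. low
salinity) and a `reference` control. Parents are genotyped individually.

If genotypes at a locus affect survival under the stressor, the allele
frequency of the surviving pool is distorted away from its Mendelian
expectation *in that treatment only*. The scan detects such treatment-specific
segregation distortion and localises it.

## 2. Per-SNP G test against Mendelian expectations

For family $f$ with sire dosage $d_s$ and dam dosage $d_m$ at a biallelic
locus (dosage = copies of the alternative allele, 0/1/2), the expected
alternative-allele frequency among offspring is the Mendelian midpoint

$$p = (d_s + d_m)/4 .$$

With observed pool read counts $(O_{ref}, O_{alt})$ and depth
$N = O_{ref}+O_{alt}$, the expected counts are $E_{alt} = pN$ and
$E_{ref} = (1-p)N$, kept real-valued. The goodness-of-fit statistic is the
likelihood-ratio (G) statistic

$$G = 2\sum_{a \in \{ref,alt\}} O_a \ln(O_a/E_a), \qquad 0\ln 0 := 0,$$

with one degree of freedom. A locus is **usable** for a family/treatment only
when both expected counts strictly exceed 5 — the usual small-sample guard for
likelihood-ratio tests. The comparison is strict and applied to the
real-valued expectations; no continuity correction is used. Loci where a
parent's genotype is missing, non-biallelic sites, and sites monomorphic
across the parental panel are removed before testing.

## 3. Window scores and the treatment contrast

Per-SNP G values are summed in non-overlapping 100-kb windows tiled from
position 0 of each chromosome (1-based position $p$ falls in window
$\lfloor (p-1)/W \rfloor$). Because a sum of $k$ null G statistics has
expectation $k$, the window total is standardised by its SNP count:

$$G_S = \frac{\text{Total } G}{\#\text{ SNP tests in window}},$$

so the null expectation of $G_S$ is ~1 regardless of SNP density. Windows
with fewer than 5 usable SNPs for a family/treatment are skipped.

Families carry *load*: deleterious alleles segregating in particular crosses
distort segregation in **both** treatments. The treatment effect is therefore
isolated per family as

$$\Delta G_S = G_S(\text{low}) - G_S(\text{reference}),$$

which cancels any treatment-independent distortion. Only families with a
usable window block in both treatments contribute.

## 4. Bootstrap confidence intervals and outlier calling

For each window, the mean $\Delta G_S$ across contributing families receives a
95% percentile bootstrap CI from resampling whole families with replacement
(default 1000 iterations; the resampling unit is the family, the natural
exchangeable unit). Windows with fewer than 2 contributing families are
skipped.

A window is called an **outlier** when its lower CI bound exceeds the
genome-wide 0.999 quantile of window mean $\Delta G_S$. This operationalises
the visual criterion "CI does not overlap the bulk of the genome-wide
distribution" as a reproducible rule; the threshold is reported alongside the
calls. With fewer than ~100 windows the extreme quantile is unstable and a
warning is emitted.

## 5. SNP-level resolution

Inside candidate windows the signal is localised by the per-SNP, per-family
difference $\Delta G = G(\text{low}) - G(\text{reference})$, restricted to
loci usable in *both* treatments for that family. Loci with at least 6
contributing families are summarised by the mean $\Delta G$ with a family
bootstrap CI (same engine as the window scan).

## 6. Parental-effects model

To ask *which parent* carries the causal variation, per-(family, locus)
$\Delta G$ values in a peak region are modelled as

$$\Delta G \sim \text{block} + \text{MHET} + \text{FHET} + (1\,|\,\text{sire}) + (1\,|\,\text{dam})$$

a Gaussian linear mixed model with breeding block as fixed effect, fixed
indicators MHET/FHET for sire/dam heterozygosity at the locus (dosage exactly
1), and crossed random intercepts for parent identities. Only a heterozygous
parent produces two gamete classes, so selection acting through one parent's
gametes (e.g. on sperm) makes that parent's heterozygosity — and not the
other's — predictive of $\Delta G$.

Blocks contributing fewer than 3 families are dropped (under-sampled).
Significance of MHET and FHET is assessed by likelihood-ratio tests between
maximum-likelihood fits with and without the term. Variance components sit
near the boundary in realistic data, which makes single optimizers fragile;
the implementation tries several (`lbfgs`, `cg`, `bfgs`, `powell`) and keeps
the best-likelihood converged fit. If the mixed fit fails entirely, the model
falls back to fixed effects only (OLS) with a warning, and a rank-deficient
fixed design is an error naming the confounded columns.

**Limitation — curvature of the G scale.** G is convex in the expected
frequency: for the same allele-frequency shift, a family whose Mendelian
expectation is 0.25 or 0.75 yields a larger G than one at 0.5. Under strong
paternal selection this induces a small genuine *negative* association between
dam heterozygosity and $\Delta G$ (given a heterozygous sire), so FHET can
reach nominal significance at very high power even when the dam is causally
irrelevant. At moderate effect sizes the sire term dominates cleanly.

## 7. Diversity statistics

Windowed nucleotide diversity treats the $n = 2 \times (\#\text{parents})$
parental chromosomes as an allele-count sample. Per site
$\pi = c_{ref} c_{alt} / \binom{n}{2}$; windowed $\pi$ divides the per-site
sum by the window length (10 kb default). Tajima's D uses the standard
$a_1, a_2, b_1, b_2, c_1, c_2, e_1, e_2$ constants and is reported as missing
for windows with fewer than 3 segregating sites or a non-positive variance
term. Both are implemented directly (closed-form estimators) and validated
against brute-force pairwise enumeration and an independent from-scratch D in
the test suite.

## 8. VCF hard filters

Parental VCFs pass GATK-style hard filters before genotype extraction. A
record is removed iff any condition holds:

| annotation | removed when |
|---|---|
| QD | < 2.0 |
| QUAL | < 30.0 |
| SOR | > 3.0 |
| FS | > 60.0 |
| MQ | < 40.0 |
| MQRankSum | < −12.5 |
| ReadPosRankSum | < −8.0 |

Comparisons are strict (boundary values survive) and a missing annotation
never fires its filter — homozygous-only sites routinely lack the rank-sum
annotations. Multiallelic records and non-SNPs are dropped, not decomposed.

## 9. Synthetic data generator

`simulate_dataset(SimulationConfig())` produces a complete experiment with
known ground truth. The defaults *are* the emulated study conditions:

| parameter | default | rationale |
|---|---|---|
| blocks × sires × dams | 5 × 3 × 3 | 45 full-sib families |
| missing_family_fraction | 12/45 | 33 families sequenced in both treatments |
| linkage groups | 10 × 20 Mb | desk-scale genome: ~2000 scan windows |
| SNPs per linkage group | 5000 | ~25 usable SNPs per 100-kb window |
| depth law | NB(mean 15, CV 0.5) | overdispersed pool-seq coverage ~15× |
| base error | 0.001 | symmetric sequencing/mapping error |
| allele frequencies | Uniform(0.05, 0.95) | segregating parental panel |

Parental genotypes are Hardy–Weinberg draws; loci monomorphic across the
panel are redrawn. The larval pool is treated as effectively infinite: the
post-selection pool frequency is an exact enumeration over the four
paternal × maternal gamete combinations, each zygote class weighted by its
viability $w = 1 - s \cdot \text{effect}$ with three selection modes —
`genotypic-additive` (effect = target copies / 2), `genotypic-dominant`
(effect = 1 for carriers) and `paternal-allele` (selection on the paternal
gamete only, e.g. sperm). An optional finite pool size adds binomial larval
sampling. Load (`LoadSpec`) applies the same machinery in both treatments,
optionally with per-family strengths. Reads are binomial draws at the
(error-folded) pool frequency with depth from the depth law.

`SelectionSpec`/`LoadSpec` accept optional `alt_freq` (population frequency at
the designated locus) and `parent_dosage=1` (force all parents heterozygous).
These exist because with fully random parents a planted locus is monomorphic
within most families and therefore cannot be distorted; power studies need
selection planted at loci that actually segregate in the crosses. They alter
only the designated loci of the simulated scenario, never the generator's
background behaviour.

Loci are unlinked; windowed signal is created by placing several selected
loci inside one window.

## 10. Numerical and reproducibility notes

- Every stochastic stage takes an explicit seed; `simulate_dataset` runs all
  stages off a single `numpy` Generator stream, so identical configs are
  bit-identical.
- The family bootstrap resamples index tensors in vectorised chunks
  (deterministic for a given seed, independent of chunking).
- The pipeline (`run_all`) writes a manifest with config hash, package
  versions, per-stage row counts and SHA-256 checksums of every output; no
  timestamps, so reruns are byte-identical.
- Percentile bootstrap CIs are an asymptotic tool: with few SNPs per window
  (heavily skewed per-family $G_S$) their real coverage dips a few points
  below nominal (~0.93 at ~30 SNPs/window vs ~0.95 at ~50). Interpret CIs
  for sparsely covered windows with care.
- **Depth and the outlier threshold.** At ~15× mean pool depth the
  expected-count usability guard censors many family/locus tests, so some
  windows retain only 2–3 contributing families. Their extreme window means
  inflate the genome-wide 0.999 quantile and can mask genuine selection
  signal — a detectability floor of shallow pool sequencing, not of the
  scan. At ~40× every Mendelian expectation class is usable, windows are
  densely populated, and moderate planted selection is detected reliably.
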