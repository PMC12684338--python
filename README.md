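# mendelscan

Genome scan for **treatment-specific segregation distortion** in
pool-sequenced experimental crosses, with a built-in synthetic-data
generator for power studies and validation.

## The problem

In a factorial breeding design (North Carolina II blocks: every sire ×
every dam), each full-sib family inherits alleles from known parental
genotypes, so the allele frequency of any offspring pool has an exact
Mendelian expectation. If genotypes at a locus affect survival under an
environmental stressor (e.g. low salinity for oyster larvae), the allele
frequency of the pool of *survivors* is distorted away from that
expectation — but only in the stressful treatment. `mendelscan` detects
and localises such loci from pooled sequencing of sibling larval pools
reared under a stressor and under a reference condition:

1. **Per-SNP G test** of pool read counts against the Mendelian
   expectation `(sire dosage + dam dosage)/4`, per family × treatment.
2. **Window scores**: per-SNP G summed in 100-kb windows and divided by
   the number of tests (`G_S`, null expectation ≈ 1).
3. **Treatment contrast** `ΔG_S = G_S(stress) − G_S(reference)` per
   family, cancelling family-specific genetic load that distorts
   segregation in *both* treatments.
4. **Family bootstrap** 95% CIs on each window's mean ΔG_S; a window is
   an outlier when its lower CI bound exceeds the genome-wide 0.999
   quantile of window means.
5. **SNP-level resolution** of candidate windows via per-SNP mean ΔG.
6. **Parental-effects model**
   `ΔG ~ block + MHET + FHET + (1|sire) + (1|dam)` — does the signal
   track sire or dam heterozygosity (e.g. selection on sperm)?
7. **Diversity screen**: windowed π and Tajima's D on the parental panel,
   and GATK-style hard filtering of parental VCFs.

The full statistical specification is in [`docs/methods.md`](docs/methods.md).

## Quick start (Python API)

The API follows the statsmodels pattern: build a model object, call
`fit()`, work with the results object.

```python
from mendelscan import MendelianScan, SelectionSpec, SimulationConfig, simulate_dataset

# Simulate a study-scale experiment (5 blocks of 3x3 crosses, 10 linkage
# groups, 5000 SNPs each) with selection planted in one 10-kb region,
# acting only under the "low" (stress) treatment.
selection = tuple(
    SelectionSpec("LG1", 10_001_000 + 2_000 * k, s=0.8,
                  mode="genotypic-dominant", treatment="low", alt_freq=0.5)
    for k in range(5)
)
dataset = simulate_dataset(SimulationConfig(
    selection_loci=selection,
    depth_law=("negative-binomial", 40.0, 0.5),
    rng_seed=42,
))

scan = MendelianScan(dataset.counts, dataset.parents, dataset.design)
results = scan.fit(seed=1)
print(results.summary())

snps = results.snp_resolution(seed=1)   # per-SNP dG inside outlier windows
effects = results.parental_effects()    # which parent carries the signal?
print(effects.fit().summary())
```

Output:

```text
Mendelian segregation-distortion scan (dGS)
  families: 45 (33 in both treatments)
  loci tested: 50005; windows (100 kb): 2000
  genome-wide mean dGS: 0.0005
  outlier threshold (CI_low > 0.3588): 1 outlier window(s)
    LG1:10000000-10100000  mean dGS = 0.937 [0.713, 1.153] (n = 33 families)
Parental-effects model: delta_g ~ block + mhet + fhet + (1|sire) + (1|dam)
  fit: mixed (converged=True), n = 668
  variance components: sire = 1.004e-07, dam = 1.57e-09
  fixed effects:
    Intercept                -0.4574
    C(block_id)[T.B2]         0.2195
    C(block_id)[T.B3]         0.4428
    C(block_id)[T.B4]         0.4984
    C(block_id)[T.B5]         0.7675
    mhet                      1.045
    fhet                      0.8477
  LRT p(MHET) = 0.000707; LRT p(FHET) = 0.00672
```

The single outlier window is exactly the planted one, and both parents'
heterozygosity predicts ΔG — as expected for genotypic-dominant
selection, which acts through both parents' gametes.

Real data enters the same way: `MendelianScan.from_files(counts_tsv,
parents_vcf, design_tsv)` reads a pool-count table, a (hard-filtered)
parental VCF and a cross-design table.

## Command line

Each stage is a subcommand; `run-all` chains them and writes a manifest
with checksums so reruns are byte-identical:

```sh
mendelscan simulate --out sim/ --seed 42
mendelscan filter   --parents sim/parents.vcf --out filtered
mendelscan scan     --counts sim/counts.tsv --parents sim/parents.vcf \
                    --design sim/design.tsv --seed 1 --out windows.tsv
mendelscan snps     --counts sim/counts.tsv --parents sim/parents.vcf \
                    --design sim/design.tsv --blocks windows.tsv --seed 1 --out snps.tsv
mendelscan effects  --counts sim/counts.tsv --parents sim/parents.vcf \
                    --design sim/design.tsv --region LG1:10000001-10100000 --out effects.tsv
mendelscan diversity --parents sim/parents.vcf --out pi.tsv
mendelscan run-all  --counts sim/counts.tsv --parents sim/parents.vcf \
                    --design sim/design.tsv --out results/
```

## The synthetic-data generator

`simulate_dataset(SimulationConfig())` emulates the full study design:
5 NCII blocks of 3×3 crosses (45 families, 33 sequenced in both
treatments), 10 linkage groups × 20 Mb × 5000 SNPs, overdispersed
pool depth NB(mean 15, CV 0.5), sequencing error folded into pool
frequencies. Selection (`SelectionSpec`) supports additive, dominant and
paternal-gamete modes with treatment-specific action; `LoadSpec` plants
family-specific load acting in both treatments. Post-selection pool
frequencies are exact gamete-enumeration calculations, so the ground
truth is analytic. See `docs/methods.md` §9.

## Tests and reproduction

```sh
python -m pytest -q                                  # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` re-derives the headline statistical properties
(null calibration of G and G_S, load cancellation in ΔG_S, detection and
localisation power for a planted selection window, bootstrap CI
coverage, sire-effect recovery by the parental-effects model, diversity
statistics) on seeded synthetic data and writes them as JSON.
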