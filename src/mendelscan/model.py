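"""Model/Results interface to the segregation-distortion scan.

:class:`MendelianScan` bundles the three inputs of the analysis — parental
genotypes, pool read counts and the cross design — and ``fit()`` runs the
whole scan (per-SNP G, windowed G_S, per-family dGS, family bootstrap,
outlier calling), returning a :class:`ScanResults` with the estimates and
downstream analyses (SNP-level resolution, parental-effects model, diversity
screen) as methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import effects as _effects
from . import gtest as _gtest
from . import popgen as _popgen
from . import scan as _scan
from . import snps as _snps
from .design import CrossDesign
from .io import DosageMatrix, read_pool_counts, select_scan_loci


class MendelianScan:
    """Scan model for treatment-specific deviations from Mendelian inheritance.

    Parameters
    ----------
    counts : DataFrame
        Long pool count table (chrom, pos, ref, alt, family_id, treatment,
        ref_count, alt_count), joined against ``parents``.
    parents : DosageMatrix
        Parental genotypes. Loci failing the scan-locus criteria are removed
        unless ``select_loci=False``.
    design : CrossDesign
        The mating design with per-family treatment availability.

    Examples
    --------
    >>> scan = MendelianScan(counts, parents, design)
    >>> res = scan.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, counts, parents, design, select_loci: bool = True):
        if select_loci:
            from .io import scan_locus_mask

            mask = scan_locus_mask(parents)
            filtered = parents.subset_loci(mask)
            if "_locus_i" in counts.columns:
                # remap existing matrix ordinals through the retained subset
                old_i = counts["_locus_i"].to_numpy()
                new_of_old = np.cumsum(mask) - 1
                keep = mask[old_i]
                counts = counts.loc[keep].reset_index(drop=True)
                counts["_locus_i"] = new_of_old[old_i[keep]]
            else:
                ordinals = filtered.locus_ordinals(counts["chrom"], counts["pos"])
                counts = counts.loc[ordinals >= 0].reset_index(drop=True)
                counts["_locus_i"] = ordinals[ordinals >= 0]
            parents = filtered
        self.counts = counts
        self.parents = parents
        self.design = design

    @classmethod
    def from_files(cls, counts_path, vcf_path, design_path, hard_filter: bool = True):
        """Build the model from interchange files (VCF parents)."""
        if hard_filter:
            parents, tally = DosageMatrix.from_vcf(vcf_path, hard_filter=True)
        else:
            parents, tally = DosageMatrix.from_vcf(vcf_path), None
        parents = select_scan_loci(parents)
        design = CrossDesign.from_table(design_path)
        counts = read_pool_counts(counts_path, parents)
        model = cls(counts, parents, design, select_loci=False)
        model.filter_tally = tally
        return model

    def fit(
        self,
        window_size: int = _scan.DEFAULT_WINDOW,
        n_boot: int = 1000,
        min_snps_per_block: int = 5,
        min_families: int = 2,
        outlier_quantile: float = 0.999,
        seed: int | None = None,
    ) -> "ScanResults":
        gscores = _gtest.gscore_table(self.counts, self.parents, self.design)
        blocks = _scan.block_gscores(gscores, window_size, min_snps_per_block)
        delta = _scan.delta_gs(blocks)
        summary = _scan.summarize_bootstrap(
            delta, n_boot=n_boot, seed=seed, min_families=min_families
        )
        summary = _scan.call_outliers(summary, outlier_quantile)
        return ScanResults(
            model=self,
            gscores=gscores,
            blocks=blocks,
            delta=delta,
            windows=summary,
            window_size=window_size,
            n_boot=n_boot,
            seed=seed,
        )


@dataclass
class ScanResults:
    """Fitted scan: per-SNP G-scores, per-family window scores, window
    summaries with bootstrap CIs and outlier flags."""

    model: MendelianScan
    gscores: pd.DataFrame
    blocks: pd.DataFrame
    delta: pd.DataFrame
    windows: pd.DataFrame
    window_size: int
    n_boot: int
    seed: int | None

    @property
    def outliers(self) -> pd.DataFrame:
        return self.windows.loc[self.windows["outlier"]].reset_index(drop=True)

    @property
    def outlier_threshold(self) -> float:
        if self.windows.empty:
            return float("nan")
        return float(self.windows["threshold"].iloc[0])

    def summary(self) -> str:
        n_win = len(self.windows)
        n_out = len(self.outliers)
        lines = [
            "Mendelian segregation-distortion scan (dGS)",
            f"  families: {len(self.model.design.families)} "
            f"({len(self.model.design.dual_treatment_families())} in both treatments)",
            f"  loci tested: {self.model.parents.n_loci}; "
            f"windows ({self.window_size // 1000} kb): {n_win}",
            f"  genome-wide mean dGS: {self.windows['mean_dgs'].mean():.4f}",
            f"  outlier threshold (CI_low > {self.outlier_threshold:.4f}): "
            f"{n_out} outlier window(s)",
        ]
        for _, row in self.outliers.iterrows():
            lines.append(
                f"    {row['chrom']}:{int(row['start'])}-{int(row['end'])}  "
                f"mean dGS = {row['mean_dgs']:.3f} "
                f"[{row['ci_lo']:.3f}, {row['ci_hi']:.3f}] "
                f"(n = {int(row['n_families'])} families)"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------ downstream
    def snp_resolution(
        self,
        regions: pd.DataFrame | None = None,
        min_families: int = 6,
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> pd.DataFrame:
        """Per-SNP mean ΔG with bootstrap CIs inside candidate regions
        (default: the outlier windows of this fit)."""
        if regions is None:
            regions = self.outliers[["chrom", "start", "end"]]
        per_fam = _snps.per_family_snp_delta_g(self.gscores, regions)
        return _snps.summarize_snps(
            per_fam, n_boot=n_boot, min_families=min_families, seed=seed
        )

    def parental_effects(
        self,
        region: pd.DataFrame | None = None,
        min_families_per_block: int = 3,
    ) -> "ParentalEffectsModel":
        """Parental-effects model over a peak region (default: outliers)."""
        if region is None:
            region = self.outliers[["chrom", "start", "end"]]
        per_fam = _snps.per_family_snp_delta_g(self.gscores, region)
        table = _effects.build_effects_table(
            per_fam,
            self.model.parents,
            self.model.design,
            min_families_per_block=min_families_per_block,
        )
        return ParentalEffectsModel(table)

    def diversity(self, window_size: int = _popgen.DIVERSITY_WINDOW, chroms=None) -> pd.DataFrame:
        """Windowed π / Tajima's D over the parental genotypes."""
        return _popgen.windowed_diversity(self.model.parents, window_size, chroms=chroms)

    def plot_manhattan(self, ax=None):
        """Manhattan-style plot of window mean dGS with CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0
        for chrom, grp in self.windows.groupby("chrom", sort=True):
            x = grp["start"].to_numpy() + offset
            ax.errorbar(
                x,
                grp["mean_dgs"],
                yerr=[grp["mean_dgs"] - grp["ci_lo"], grp["ci_hi"] - grp["mean_dgs"]],
                fmt=".",
                ms=3,
                elinewidth=0.5,
                label=chrom,
            )
            offset = x.max() + self.window_size
        ax.axhline(self.outlier_threshold, color="k", lw=0.8, ls="--")
        ax.set_xlabel("genome position (concatenated)")
        ax.set_ylabel("mean dGS")
        return ax


class ParentalEffectsModel:
    """Mixed model of SNP-level ΔG on parental identity and heterozygosity.

    Built from an effects table (one row per family x locus with block, sire,
    dam, MHET, FHET); ``fit()`` returns a
    :class:`mendelscan.effects.EffectsFit`.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table

    @classmethod
    def from_components(cls, per_family, parents, design, region=None, **kw):
        table = _effects.build_effects_table(per_family, parents, design, region, **kw)
        return cls(table)

    def fit(self, use_mixed: bool = True) -> _effects.EffectsFit:
        return _effects.fit_effects_model(self.table, use_mixed=use_mixed)
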