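"""End-to-end pipeline: filter -> G-tests -> window scan -> SNP resolution ->
parental effects -> diversity, with a reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); rerunning with the
same config and seed reproduces byte-identical outputs. The manifest records
the configuration, seeds, package versions, per-stage row counts and a SHA-256
checksum of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import CrossDesign
from .effects import build_effects_table, fit_effects_model
from .gtest import gscore_table
from .io import DosageMatrix, read_pool_counts, select_scan_loci, write_table
from .popgen import windowed_diversity
from .scan import block_gscores, call_outliers, delta_gs, summarize_bootstrap
from .snps import per_family_snp_delta_g, summarize_snps

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run."""

    parents_vcf: str
    counts: str
    design: str
    outdir: str
    scan_window: int = 100_000
    diversity_window: int = 10_000
    n_boot: int = 1000
    seed: int = 0
    hard_filter: bool = True
    outlier_quantile: float = 0.999
    min_snps_per_block: int = 5
    min_families: int = 2
    snp_min_families: int = 6
    effects_min_families_per_block: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage, write all outputs under ``config.outdir`` and return
    the manifest (also written as ``manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {"mendelscan": __version__, "pandas": pd.__version__},
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        def deco(fn):
            def run(*a, **k):
                try:
                    return fn(*a, **k)
                except Exception as exc:
                    raise PipelineError(f"stage {name!r}: {exc}") from exc

            return run

        return deco

    @stage("filter")
    def _filter():
        path = Path(config.parents_vcf)
        if not path.exists():
            raise FileNotFoundError(path)
        if config.hard_filter:
            parents, tally = DosageMatrix.from_vcf(path, hard_filter=True)
        else:
            parents, tally = DosageMatrix.from_vcf(path), {}
        parents = select_scan_loci(parents)
        return parents, tally

    parents, tally = _filter()
    manifest["stages"]["filter"] = {"tally": tally, "n_loci": parents.n_loci}

    @stage("inputs")
    def _inputs():
        for p in (config.counts, config.design):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return read_pool_counts(config.counts, parents), CrossDesign.from_table(config.design)

    counts, design = _inputs()
    manifest["stages"]["inputs"] = {
        "n_count_rows": len(counts),
        "n_families": len(design.families),
    }

    @stage("gtest")
    def _gtest():
        return gscore_table(counts, parents, design)

    gscores = _gtest()
    write_table(gscores, outdir / "gscores.tsv")
    manifest["stages"]["gtest"] = {
        "n_rows": len(gscores),
        "n_usable": int(gscores["usable"].sum()),
    }

    @stage("scan")
    def _scan():
        blocks = block_gscores(gscores, config.scan_window, config.min_snps_per_block)
        delta = delta_gs(blocks)
        summary = summarize_bootstrap(
            delta,
            n_boot=config.n_boot,
            seed=config.seed,
            min_families=config.min_families,
        )
        return blocks, delta, call_outliers(summary, config.outlier_quantile)

    blocks, delta, windows = _scan()
    write_table(blocks, outdir / "block_gscores.tsv")
    write_table(delta, outdir / "delta_gs.tsv")
    write_table(windows, outdir / "scan_windows.tsv")
    outliers = windows.loc[windows["outlier"]]
    write_table(
        outliers[["chrom", "start", "end", "n_families", "mean_dgs", "ci_lo", "ci_hi"]],
        outdir / "outlier_windows.bed",
    )
    manifest["stages"]["scan"] = {
        "n_windows": len(windows),
        "n_outliers": len(outliers),
        "threshold": None if windows.empty else float(windows["threshold"].iloc[0]),
    }

    @stage("snps")
    def _snps():
        regions = outliers[["chrom", "start", "end"]]
        per_fam = per_family_snp_delta_g(gscores, regions if len(regions) else regions)
        summary = summarize_snps(
            per_fam,
            n_boot=config.n_boot,
            min_families=config.snp_min_families,
            seed=config.seed,
        )
        return per_fam, summary

    per_fam, snp_summary = _snps()
    write_table(per_fam, outdir / "snp_delta_g_per_family.tsv")
    write_table(snp_summary, outdir / "snp_delta_g.tsv")
    manifest["stages"]["snps"] = {"n_loci": len(snp_summary)}

    @stage("effects")
    def _effects():
        if outliers.empty or per_fam.empty:
            return None
        table = build_effects_table(
            per_fam,
            parents,
            design,
            min_families_per_block=config.effects_min_families_per_block,
        )
        if table.empty or table["sire_id"].nunique() < 2 or table["dam_id"].nunique() < 2:
            return None
        return fit_effects_model(table)

    fit = _effects()
    if fit is not None:
        write_table(fit.to_frame(), outdir / "parental_effects.tsv")
        (outdir / "parental_effects.txt").write_text(fit.summary() + "\n")
        manifest["stages"]["effects"] = {
            "method": fit.method,
            "p_mhet": fit.p_mhet,
            "p_fhet": fit.p_fhet,
        }
    else:
        manifest["stages"]["effects"] = {"skipped": "no outlier regions or too few parents"}

    @stage("diversity")
    def _diversity():
        return windowed_diversity(parents, config.diversity_window)

    div = _diversity()
    write_table(div, outdir / "diversity.tsv")
    manifest["stages"]["diversity"] = {"n_windows": len(div)}

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
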