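"""SNP-level resolution of candidate windows.

Inside candidate (typically outlier) windows, the treatment effect is
localised by the per-SNP, per-family difference ΔG = G(low) − G(reference).
A family contributes at a locus only if the locus is usable (both expected
read counts > 5) in *both* treatments for that family, and a locus is
summarised only when at least ``min_families`` families contribute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import TREATMENT_LOW, TREATMENT_REFERENCE
from .scan import _bootstrap_group_means


def _in_regions(chrom: pd.Series, pos: pd.Series, regions: pd.DataFrame) -> np.ndarray:
    """Membership of 1-based positions in 0-based half-open regions
    (columns chrom, start, end)."""
    mask = np.zeros(len(chrom), dtype=bool)
    c = chrom.to_numpy()
    p = pos.to_numpy()
    for _, r in regions.iterrows():
        mask |= (c == r["chrom"]) & (p > r["start"]) & (p <= r["end"])
    return mask


def per_family_snp_delta_g(
    gtable: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    low: str = TREATMENT_LOW,
    reference: str = TREATMENT_REFERENCE,
) -> pd.DataFrame:
    """Per-(family, locus) ΔG restricted to dual-treatment-usable loci.

    ``regions`` (columns chrom, start, end; e.g. the outlier rows of a scan
    summary) restricts output to those windows; ``None`` means genome-wide.
    Returns columns chrom, pos, family_id, g_low, g_ref, delta_g.
    """
    use = gtable.loc[gtable["usable"]]
    if regions is not None:
        use = use.loc[_in_regions(use["chrom"], use["pos"], regions)]
    keys = ["family_id", "chrom", "pos"]
    lo = use.loc[use["treatment"] == low, keys + ["g"]]
    re = use.loc[use["treatment"] == reference, keys + ["g"]]
    merged = lo.merge(re, on=keys, how="inner", suffixes=("_low", "_ref"))
    merged = merged.rename(columns={"g_low": "g_low", "g_ref": "g_ref"})
    merged["delta_g"] = merged["g_low"] - merged["g_ref"]
    return merged[["chrom", "pos", "family_id", "g_low", "g_ref", "delta_g"]]


def snp_delta_g(gtable: pd.DataFrame, family_id: str, chrom: str, pos: int) -> float:
    """ΔG of a single family at a single locus; NaN when the locus is not
    usable in both treatments for that family."""
    table = per_family_snp_delta_g(
        gtable.loc[
            (gtable["family_id"] == family_id)
            & (gtable["chrom"] == chrom)
            & (gtable["pos"] == pos)
        ]
    )
    if table.empty:
        return float("nan")
    return float(table["delta_g"].iloc[0])


def summarize_snps(
    per_family: pd.DataFrame,
    n_boot: int = 1000,
    min_families: int = 6,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean ΔG and family-bootstrap percentile CI per locus.

    Loci with fewer than ``min_families`` contributing families are dropped.
    Uses the same family-resampling bootstrap engine as the window scan.
    """
    rng = np.random.default_rng(seed)
    loci = (
        per_family[["chrom", "pos"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(loci)
    codes = key.get_indexer(pd.MultiIndex.from_frame(per_family[["chrom", "pos"]]))
    n, mean, lo, hi = _bootstrap_group_means(
        per_family["delta_g"].to_numpy(), codes, len(loci), n_boot, level, rng
    )
    out = loci.assign(n_families=n, mean_dg=mean, ci_lo=lo, ci_hi=hi)
    return out.loc[out["n_families"] >= min_families].reset_index(drop=True)
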