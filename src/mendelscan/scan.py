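"""Window-level aggregation of G-scores and the per-family ΔG_S scan.

Per-SNP G-scores are summed within non-overlapping windows (default 100 kb)
tiled from position 0 of each chromosome. Because the null expectation of a
summed G equals the number of tests, the Total G of a window is standardised
by its SNP count, giving G_S with null expectation ~1 regardless of SNP
density. The treatment effect is isolated per family as

    dGS = G_S(low) - G_S(reference)

which cancels family-specific (treatment-independent) distortion such as
genetic load. Window means of dGS across families get percentile bootstrap
confidence intervals from resampling whole families, and windows whose lower
CI bound exceeds a high genome-wide quantile of the window means are flagged
as outliers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import TREATMENT_LOW, TREATMENT_REFERENCE, TREATMENTS

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000


def assign_windows(pos, window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """Window index of 1-based positions: window k covers the 0-based
    half-open interval [k*W, (k+1)*W), so position p maps to (p-1) // W."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    return (np.asarray(pos, dtype=np.int64) - 1) // window_size


def block_gscores(
    gtable: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    min_snps_per_block: int = 5,
) -> pd.DataFrame:
    """Aggregate usable per-SNP G into per-(family, treatment, window) scores.

    Returns columns family_id, treatment, chrom, start, end (0-based
    half-open), n_snps, total_g, g_s; windows with fewer than
    ``min_snps_per_block`` usable SNPs are omitted for that family/treatment.
    """
    use = gtable.loc[gtable["usable"]]
    if use.empty:
        return pd.DataFrame(
            columns=[
                "family_id",
                "treatment",
                "chrom",
                "start",
                "end",
                "n_snps",
                "total_g",
                "g_s",
            ]
        )
    fam_codes, fam_ids = pd.factorize(use["family_id"], sort=True)
    tr_codes, tr_ids = pd.factorize(use["treatment"], sort=True)
    ch_codes, ch_ids = pd.factorize(use["chrom"], sort=True)
    win = assign_windows(use["pos"].to_numpy(), window_size)
    n_w = int(win.max()) + 1
    key = (
        (fam_codes.astype(np.int64) * len(tr_ids) + tr_codes) * len(ch_ids) + ch_codes
    ) * n_w + win
    uniq, inv = np.unique(key, return_inverse=True)
    total = np.bincount(inv, weights=use["g"].to_numpy())
    n = np.bincount(inv)

    w = uniq % n_w
    rest = uniq // n_w
    c = rest % len(ch_ids)
    rest //= len(ch_ids)
    t = rest % len(tr_ids)
    f = rest // len(tr_ids)
    out = pd.DataFrame(
        {
            "family_id": np.asarray(fam_ids)[f],
            "treatment": np.asarray(tr_ids)[t],
            "chrom": np.asarray(ch_ids)[c],
            "start": w * window_size,
            "end": (w + 1) * window_size,
            "n_snps": n,
            "total_g": total,
            "g_s": total / n,
        }
    )
    return out.loc[out["n_snps"] >= min_snps_per_block].reset_index(drop=True)


def delta_gs(
    blocks: pd.DataFrame,
    low: str = TREATMENT_LOW,
    reference: str = TREATMENT_REFERENCE,
) -> pd.DataFrame:
    """Per-family window-level dGS = G_S(low) - G_S(reference).

    Family/window combinations lacking a usable block in either treatment are
    skipped (their count is logged). Unknown treatment labels are an error.
    """
    labels = set(blocks["treatment"].unique())
    unknown = labels - {low, reference}
    if unknown:
        raise ValueError(f"unknown treatment labels in block table: {sorted(unknown)}")
    keys = ["family_id", "chrom", "start", "end"]
    lo = blocks.loc[blocks["treatment"] == low, keys + ["g_s"]]
    re = blocks.loc[blocks["treatment"] == reference, keys + ["g_s"]]
    merged = lo.merge(re, on=keys, how="outer", suffixes=("_low", "_ref"))
    one_sided = merged["g_s_low"].isna() | merged["g_s_ref"].isna()
    if one_sided.any():
        logger.info(
            "skipped %d family/window combinations with only one treatment",
            int(one_sided.sum()),
        )
    out = merged.loc[~one_sided].reset_index(drop=True)
    out["delta_gs"] = out["g_s_low"] - out["g_s_ref"]
    return out


def _bootstrap_group_means(
    values: np.ndarray,
    group_codes: np.ndarray,
    n_groups: int,
    n_boot: int,
    level: float,
    rng: np.random.Generator,
    max_chunk_elems: int = 30_000_000,
):
    """Mean and percentile bootstrap CI of ``values`` within each group.

    Group members are resampled with replacement (group size preserved);
    groups are processed in ascending code order, batched by size, so the
    result is deterministic for a given RNG state. Returns
    (n, mean, ci_lo, ci_hi) arrays indexed by group code.
    """
    order = np.argsort(group_codes, kind="stable")
    vals = values[order]
    codes = group_codes[order]
    counts = np.bincount(codes, minlength=n_groups)
    starts = np.concatenate([[0], np.cumsum(counts)])

    n_out = counts.astype(int)
    mean_out = np.full(n_groups, np.nan)
    lo_out = np.full(n_groups, np.nan)
    hi_out = np.full(n_groups, np.nan)
    alpha = (1.0 - level) / 2.0

    sizes = np.unique(counts[counts > 0])
    for size in sizes:
        gids = np.flatnonzero(counts == size)
        mat = np.empty((len(gids), size))
        for row, g in enumerate(gids):
            mat[row] = vals[starts[g] : starts[g] + size]
        mean_out[gids] = mat.mean(axis=1)
        chunk = max(1, int(max_chunk_elems / (n_boot * size)))
        for lo_i in range(0, len(gids), chunk):
            sl = slice(lo_i, min(lo_i + chunk, len(gids)))
            sub = mat[sl]
            idx = rng.integers(0, size, size=(sub.shape[0], n_boot, size))
            boot_means = np.take_along_axis(sub[:, None, :], idx, axis=2).mean(axis=2)
            qs = np.quantile(boot_means, [alpha, 1.0 - alpha], axis=1)
            lo_out[gids[sl]] = qs[0]
            hi_out[gids[sl]] = qs[1]
    return n_out, mean_out, lo_out, hi_out


def summarize_bootstrap(
    delta: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    min_families: int = 2,
) -> pd.DataFrame:
    """Window summary of per-family dGS: mean and percentile bootstrap CI.

    Families are resampled with replacement within each window (sample size =
    number of families contributing to that window). Windows with fewer than
    ``min_families`` families are skipped with a log entry.
    """
    rng = np.random.default_rng(seed)
    win = delta[["chrom", "start", "end"]].drop_duplicates().sort_values(
        ["chrom", "start"]
    )
    win = win.reset_index(drop=True)
    key = pd.MultiIndex.from_frame(win[["chrom", "start"]])
    codes = key.get_indexer(pd.MultiIndex.from_frame(delta[["chrom", "start"]]))
    n, mean, lo, hi = _bootstrap_group_means(
        delta["delta_gs"].to_numpy(), codes, len(win), n_boot, level, rng
    )
    out = win.assign(n_families=n, mean_dgs=mean, ci_lo=lo, ci_hi=hi)
    thin = out["n_families"] < min_families
    if thin.any():
        logger.info("skipped %d windows with < %d families", int(thin.sum()), min_families)
    return out.loc[~thin].reset_index(drop=True)


def call_outliers(summary: pd.DataFrame, quantile: float = 0.999) -> pd.DataFrame:
    """Flag outlier windows.

    The visual criterion "confidence interval not overlapping the main
    distribution" is operationalised as: a window is an outlier iff its lower
    CI bound exceeds the genome-wide ``quantile`` of window mean dGS. The
    threshold used is reported in a ``threshold`` column.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    if len(summary) < 100:
        logger.warning(
            "only %d windows available; the %.4f quantile threshold is unstable",
            len(summary),
            quantile,
        )
    out = summary.copy()
    if out.empty:
        out["threshold"] = np.nan
        out["outlier"] = pd.Series(dtype=bool)
        return out
    threshold = float(np.quantile(out["mean_dgs"].to_numpy(), quantile))
    out["threshold"] = threshold
    out["outlier"] = out["ci_lo"] > threshold
    return out
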