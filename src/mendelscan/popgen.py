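"""Windowed nucleotide diversity (π) and Tajima's D over parental genotypes.

Both statistics treat the 2N parental chromosomes as an unphased allele-count
sample. Per site,

    pi_site = c_ref * c_alt / C(n, 2),      n = 2N chromosomes,

the unbiased mean pairwise difference; windowed π divides the per-site sum by
the window length (monomorphic positions contribute zero). Tajima's D is the
standardised difference between the pairwise-diversity and segregating-sites
estimators of θ, using the standard a1, a2, b1, b2, c1, c2, e1, e2 constants;
it is reported as missing for windows with fewer than 3 segregating sites or
a non-positive variance term.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import MISSING, DosageMatrix
from .scan import assign_windows

logger = logging.getLogger(__name__)

DIVERSITY_WINDOW = 10_000


def tajima_constants(n: int) -> dict:
    """Standard constants of Tajima's D for a sample of ``n`` chromosomes."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def windowed_diversity(
    matrix: DosageMatrix,
    window_size: int = DIVERSITY_WINDOW,
    chroms: list[str] | None = None,
) -> pd.DataFrame:
    """Per-window n_segregating sites, π (per bp) and Tajima's D.

    Windows tile each chromosome from position 0 through the window containing
    its last genotyped site; windows without segregating sites report π = 0
    and a missing D. Requires complete genotypes (no missing dosages).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if (matrix.dosages == MISSING).any():
        raise ValueError("windowed diversity requires complete genotypes")
    n_chromosomes = 2 * matrix.n_samples
    if n_chromosomes < 4:
        logger.warning("fewer than 4 chromosomes; Tajima's D undefined everywhere")

    loci = matrix.loci
    mask = np.ones(len(loci), dtype=bool)
    if chroms is not None:
        mask = loci["chrom"].isin(chroms).to_numpy()
    alt = matrix.dosages.sum(axis=0).astype(float)
    ref = n_chromosomes - alt
    pairs = n_chromosomes * (n_chromosomes - 1) / 2.0
    pi_site = alt * ref / pairs
    seg = (alt > 0) & (alt < n_chromosomes)

    consts = tajima_constants(n_chromosomes) if n_chromosomes >= 2 else None
    out_rows = []
    for chrom in pd.unique(loci.loc[mask, "chrom"]):
        cmask = mask & (loci["chrom"] == chrom).to_numpy()
        win = assign_windows(loci.loc[cmask, "pos"].to_numpy(), window_size)
        n_win = int(win.max()) + 1
        pi_sum = np.bincount(win, weights=pi_site[cmask], minlength=n_win)
        s_count = np.bincount(win, weights=seg[cmask].astype(float), minlength=n_win)
        for k in range(n_win):
            S = int(s_count[k])
            d = np.nan
            if S >= 3 and n_chromosomes >= 4:
                var = consts["e1"] * S + consts["e2"] * S * (S - 1)
                if var > 0:
                    d = (pi_sum[k] - S / consts["a1"]) / np.sqrt(var)
            out_rows.append(
                {
                    "chrom": chrom,
                    "start": k * window_size,
                    "end": (k + 1) * window_size,
                    "n_sites": S,
                    "pi": pi_sum[k] / window_size,
                    "tajimas_d": d,
                }
            )
    return pd.DataFrame(
        out_rows, columns=["chrom", "start", "end", "n_sites", "pi", "tajimas_d"]
    )


def windowed_pi(matrix: DosageMatrix, window_size: int = DIVERSITY_WINDOW, **kw) -> pd.DataFrame:
    """Windowed nucleotide diversity table (see :func:`windowed_diversity`)."""
    return windowed_diversity(matrix, window_size, **kw)


def windowed_tajimas_d(matrix: DosageMatrix, window_size: int = DIVERSITY_WINDOW, **kw) -> pd.DataFrame:
    """Windowed Tajima's D table (see :func:`windowed_diversity`)."""
    return windowed_diversity(matrix, window_size, **kw)
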