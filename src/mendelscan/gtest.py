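"""Per-locus Mendelian expectations and the G goodness-of-fit statistic.

For each family the expected alternative-allele frequency in the larval pool
is the Mendelian midpoint of the parental dosages, ``(d_sire + d_dam) / 4``.
Expected read counts are that frequency times the observed sequencing depth
(kept real-valued), and the likelihood-ratio statistic

    G = 2 * sum_a O_a * ln(O_a / E_a),   a in {ref, alt}

compares observed with expected counts (1 degree of freedom; terms with
``O_a = 0`` contribute 0). Loci are usable for testing only when both
expected counts exceed 5, the usual small-sample guard for the G-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CrossDesign
from .io import MISSING, DosageMatrix

USABLE_MIN_EXPECTED = 5.0


def expected_alt_frequency(sire_dosage: int, dam_dosage: int) -> float:
    """Mendelian expected alt-allele frequency among offspring of one cross."""
    for d, who in ((sire_dosage, "sire"), (dam_dosage, "dam")):
        if d not in (0, 1, 2):
            raise ValueError(f"{who} dosage must be 0, 1 or 2 (got {d!r})")
    return (sire_dosage + dam_dosage) / 4.0


def expected_counts(freq: float, depth: float) -> tuple[float, float]:
    """Expected (ref, alt) read counts at a locus: frequency times depth,
    real-valued (no rounding)."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must lie in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return (1.0 - freq) * depth, freq * depth


def locus_usable(e_ref: float, e_alt: float) -> bool:
    """True iff both expected read counts strictly exceed 5."""
    return e_ref > USABLE_MIN_EXPECTED and e_alt > USABLE_MIN_EXPECTED


def g_statistic(o_ref: float, o_alt: float, e_ref: float, e_alt: float) -> float:
    """Likelihood-ratio goodness-of-fit G for one locus (df = 1)."""
    if e_ref <= 0 or e_alt <= 0:
        raise ValueError(
            "expected count of zero reached the G computation; the usability "
            "filter should have excluded this locus"
        )
    g = 0.0
    for o, e in ((o_ref, e_ref), (o_alt, e_alt)):
        if o > 0:
            g += o * np.log(o / e)
    return 2.0 * g


def g_statistic_array(o_ref, o_alt, e_ref, e_alt) -> np.ndarray:
    """Vectorised :func:`g_statistic`; entries with a non-positive expected
    count yield NaN (they are unusable by construction)."""
    o_ref = np.asarray(o_ref, dtype=float)
    o_alt = np.asarray(o_alt, dtype=float)
    e_ref = np.asarray(e_ref, dtype=float)
    e_alt = np.asarray(e_alt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ref = np.where(o_ref > 0, o_ref * np.log(np.where(o_ref > 0, o_ref, 1.0) / e_ref), 0.0)
        t_alt = np.where(o_alt > 0, o_alt * np.log(np.where(o_alt > 0, o_alt, 1.0) / e_alt), 0.0)
        g = 2.0 * (t_ref + t_alt)
    bad = (e_ref <= 0) | (e_alt <= 0)
    return np.where(bad, np.nan, g)


def gscore_table(
    counts: pd.DataFrame,
    parents: DosageMatrix,
    design: CrossDesign,
) -> pd.DataFrame:
    """Per-(family, treatment, locus) G-score table.

    ``counts`` is a pool count table joined to the parent matrix (as returned
    by :func:`mendelscan.io.read_pool_counts` or the simulator; a ``_locus_i``
    column with matrix column indices is used when present, otherwise the join
    is recomputed). Output columns: family_id, treatment, chrom, pos, o_ref,
    o_alt, e_ref, e_alt, usable, g — with ``g`` set to NaN at unusable loci.
    """
    fam = design.families.set_index("family_id")
    fam_codes, fam_ids = pd.factorize(counts["family_id"])
    unknown = [f for f in fam_ids if f not in fam.index]
    if unknown:
        raise KeyError(f"count rows for families absent from the design: {unknown}")
    sire_idx = np.array([parents.sample_index(fam.loc[f, "sire_id"]) for f in fam_ids])
    dam_idx = np.array([parents.sample_index(fam.loc[f, "dam_id"]) for f in fam_ids])

    if "_locus_i" in counts.columns:
        loc_i = counts["_locus_i"].to_numpy()
    else:
        loc_i = parents.locus_ordinals(counts["chrom"], counts["pos"])
        if (loc_i < 0).any():
            raise KeyError("count rows at loci absent from the parent matrix")

    sire_d = parents.dosages[sire_idx[fam_codes], loc_i].astype(np.int16)
    dam_d = parents.dosages[dam_idx[fam_codes], loc_i].astype(np.int16)
    if (sire_d == MISSING).any() or (dam_d == MISSING).any():
        raise ValueError(
            "missing parental dosage at a tested locus; run select_scan_loci first"
        )
    freq = (sire_d + dam_d) / 4.0
    o_ref = counts["ref_count"].to_numpy(dtype=float)
    o_alt = counts["alt_count"].to_numpy(dtype=float)
    depth = o_ref + o_alt
    e_alt = freq * depth
    e_ref = depth - e_alt
    usable = (e_ref > USABLE_MIN_EXPECTED) & (e_alt > USABLE_MIN_EXPECTED)
    g = np.full(len(counts), np.nan)
    g[usable] = g_statistic_array(
        o_ref[usable], o_alt[usable], e_ref[usable], e_alt[usable]
    )
    # numeric columns as one pre-stacked block, labels appended afterwards:
    # avoids a second full-table consolidation copy at this size
    out = pd.DataFrame(
        np.column_stack([o_ref, o_alt, e_ref, e_alt, g]),
        columns=["o_ref", "o_alt", "e_ref", "e_alt", "g"],
    )
    out["pos"] = counts["pos"].to_numpy()
    out["usable"] = usable
    out["family_id"] = _as_label_array(counts["family_id"])
    out["treatment"] = _as_label_array(counts["treatment"])
    out["chrom"] = _as_label_array(counts["chrom"])
    return out


def _as_label_array(series: pd.Series):
    """Categorical passthrough (no object conversion) for label columns."""
    arr = series.array
    return arr if isinstance(arr.dtype, pd.CategoricalDtype) else series.to_numpy()
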