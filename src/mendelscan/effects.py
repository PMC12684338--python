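"""Parental-effects model for SNP-level ΔG in peak regions.

Tests whether the treatment-specific distortion at candidate loci tracks the
sire or the dam: per-(family, locus) ΔG values are modelled as

    delta_g ~ block + MHET + FHET + (1 | sire) + (1 | dam)

a Gaussian linear mixed model with breeding block as a fixed effect, fixed
indicators for whether the sire (MHET) and dam (FHET) are heterozygous at the
locus, and crossed random intercepts for sire and dam identity. If selection
acts through one parent's gametes (e.g. on sperm), heterozygosity of that
parent — the only state in which a parent's gametes differ — should predict
ΔG, while the other parent's heterozygosity should not.

Significance of MHET and FHET is assessed by likelihood-ratio tests of the
dropped term (maximum likelihood fits). When the random-effects fit fails or
is singular, the model falls back to fixed effects only, with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CrossDesign
from .io import MISSING, DosageMatrix

logger = logging.getLogger(__name__)


def build_effects_table(
    per_family: pd.DataFrame,
    parents: DosageMatrix,
    design: CrossDesign,
    region: pd.DataFrame | None = None,
    min_families_per_block: int = 3,
) -> pd.DataFrame:
    """One row per (family, locus) with parental covariates.

    ``per_family`` is the per-family SNP ΔG table
    (:func:`mendelscan.snps.per_family_snp_delta_g`); ``region`` optionally
    restricts loci (columns chrom, start, end; 0-based half-open). Breeding
    blocks contributing fewer than ``min_families_per_block`` distinct
    families are dropped, mirroring the removal of under-sampled blocks.
    """
    rows = per_family
    if region is not None:
        from .snps import _in_regions

        rows = rows.loc[_in_regions(rows["chrom"], rows["pos"], region)]
    rows = rows.merge(
        design.families[["family_id", "sire_id", "dam_id", "block_id"]],
        on="family_id",
        how="left",
    )
    out_columns = [
        "delta_g", "block_id", "sire_id", "dam_id", "mhet", "fhet", "chrom", "pos", "family_id"
    ]
    if rows.empty:
        return pd.DataFrame(columns=out_columns)
    if rows[["sire_id", "dam_id"]].isna().any().any():
        raise KeyError("families in the ΔG table are absent from the design")
    loc_i = parents.locus_ordinals(rows["chrom"], rows["pos"])
    if (loc_i < 0).any():
        raise KeyError("ΔG rows at loci absent from the parent matrix")
    sire_i = np.array([parents.sample_index(s) for s in rows["sire_id"]])
    dam_i = np.array([parents.sample_index(d) for d in rows["dam_id"]])
    sire_d = parents.dosages[sire_i, loc_i]
    dam_d = parents.dosages[dam_i, loc_i]
    if (sire_d == MISSING).any() or (dam_d == MISSING).any():
        raise ValueError("missing parental genotype for an effects-table row")
    out = rows.assign(mhet=(sire_d == 1).astype(int), fhet=(dam_d == 1).astype(int))

    fam_per_block = out.groupby("block_id")["family_id"].nunique()
    keep_blocks = fam_per_block.index[fam_per_block >= min_families_per_block]
    dropped = sorted(set(fam_per_block.index) - set(keep_blocks))
    if dropped:
        logger.info("dropped under-sampled blocks: %s", dropped)
    out = out.loc[out["block_id"].isin(keep_blocks)].reset_index(drop=True)
    return out[out_columns]


@dataclass
class EffectsFit:
    """Result of the parental-effects model fit."""

    params: pd.Series
    vc_sire: float
    vc_dam: float
    p_mhet: float
    p_fhet: float
    loglike: float
    method: str  # "mixed" or "ols"
    converged: bool
    n_obs: int
    model_description: str = "delta_g ~ block + mhet + fhet + (1|sire) + (1|dam)"

    def summary(self) -> str:
        lines = [
            "Parental-effects model: " + self.model_description,
            f"  fit: {self.method} (converged={self.converged}), n = {self.n_obs}",
            f"  variance components: sire = {self.vc_sire:.4g}, dam = {self.vc_dam:.4g}",
            "  fixed effects:",
        ]
        for name, val in self.params.items():
            lines.append(f"    {name:<24s} {val: .4g}")
        lines.append(f"  LRT p(MHET) = {self.p_mhet:.3g}; LRT p(FHET) = {self.p_fhet:.3g}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": k, "estimate": v} for k, v in self.params.items()]
        rows += [
            {"term": "var(sire)", "estimate": self.vc_sire},
            {"term": "var(dam)", "estimate": self.vc_dam},
            {"term": "p_MHET", "estimate": self.p_mhet},
            {"term": "p_FHET", "estimate": self.p_fhet},
        ]
        return pd.DataFrame(rows)


def _check_rank(table: pd.DataFrame) -> None:
    import patsy

    y, X = patsy.dmatrices(
        "delta_g ~ C(block_id) + mhet + fhet", table, return_type="dataframe"
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify dependent columns by incremental rank
        dependent = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            r0 = np.linalg.matrix_rank(X.iloc[:, cols + [j]].to_numpy())
            if r0 == len(cols):
                dependent.append(X.columns[j])
            else:
                cols.append(j)
        raise ValueError(
            f"fixed-effect design is rank deficient; confounded columns: {dependent}"
        )


def _mixed_loglike(table: pd.DataFrame, formula: str):
    """ML fit of the crossed sire/dam random-intercept model.

    Variance components near the boundary make single optimizers fragile, so
    several are tried and the best-likelihood successful fit is returned.
    """
    import statsmodels.formula.api as smf

    data = table.copy()
    data["_one"] = 1
    vc = {"sire": "0 + C(sire_id)", "dam": "0 + C(dam_id)"}
    md = smf.mixedlm(formula, data, groups="_one", vc_formula=vc, re_formula="0")
    best = None
    for method in ("lbfgs", "cg", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = md.fit(reml=False, method=method, maxiter=2000)
        except Exception:
            continue
        if np.isfinite(fit.llf) and (best is None or fit.llf > best.llf):
            best = fit
    if best is None:
        raise RuntimeError("all mixed-model optimizers failed")
    return best


def fit_effects_model(table: pd.DataFrame, use_mixed: bool = True) -> EffectsFit:
    """Fit the parental-effects model and LRT the heterozygosity terms.

    Requires at least two sires and two dams. A constant response returns a
    trivial all-zero fit. ``use_mixed=False`` forces the fixed-effects-only
    fallback (ordinary least squares, LRTs from nested OLS fits).
    """
    if table["sire_id"].nunique() < 2 or table["dam_id"].nunique() < 2:
        raise ValueError("need at least two sires and two dams to fit the model")
    if not np.isfinite(table["delta_g"]).all():
        raise ValueError("non-finite response values")
    _check_rank(table)

    y = table["delta_g"].to_numpy()
    if np.ptp(y) == 0.0:
        params = pd.Series(dtype=float)
        return EffectsFit(
            params=params,
            vc_sire=0.0,
            vc_dam=0.0,
            p_mhet=1.0,
            p_fhet=1.0,
            loglike=0.0,
            method="degenerate",
            converged=True,
            n_obs=len(table),
        )

    full_formula = "delta_g ~ C(block_id) + mhet + fhet"
    if use_mixed:
        try:
            full = _mixed_loglike(table, full_formula)
            no_m = _mixed_loglike(table, "delta_g ~ C(block_id) + fhet")
            no_f = _mixed_loglike(table, "delta_g ~ C(block_id) + mhet")
            vcomp = dict(zip(full.model.exog_vc.names, np.asarray(full.vcomp).ravel()))
            singular = not np.isfinite(full.llf)
            if not singular:
                p_m = stats.chi2.sf(2.0 * (full.llf - no_m.llf), 1)
                p_f = stats.chi2.sf(2.0 * (full.llf - no_f.llf), 1)
                return EffectsFit(
                    params=full.fe_params,
                    vc_sire=float(vcomp.get("sire", np.nan)),
                    vc_dam=float(vcomp.get("dam", np.nan)),
                    p_mhet=float(p_m),
                    p_fhet=float(p_f),
                    loglike=float(full.llf),
                    method="mixed",
                    converged=bool(full.converged),
                    n_obs=len(table),
                )
        except Exception as exc:  # singular Hessian, separation, etc.
            logger.warning("mixed-model fit failed (%s); falling back to OLS", exc)

    import statsmodels.formula.api as smf

    full = smf.ols(full_formula, table).fit()
    no_m = smf.ols("delta_g ~ C(block_id) + fhet", table).fit()
    no_f = smf.ols("delta_g ~ C(block_id) + mhet", table).fit()
    p_m = stats.chi2.sf(2.0 * (full.llf - no_m.llf), 1)
    p_f = stats.chi2.sf(2.0 * (full.llf - no_f.llf), 1)
    return EffectsFit(
        params=full.params,
        vc_sire=0.0,
        vc_dam=0.0,
        p_mhet=float(p_m),
        p_fhet=float(p_f),
        loglike=float(full.llf),
        method="ols",
        converged=True,
        n_obs=len(table),
    )
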