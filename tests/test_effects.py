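import numpy as np
import pandas as pd
import pytest

from mendelscan import (
    CrossDesign,
    DosageMatrix,
    build_effects_table,
    fit_effects_model,
)


def toy_parents():
    loci = pd.DataFrame(
        {
            "chrom": ["LG1", "LG1"],
            "pos": [100, 200],
            "ref": ["A", "A"],
            "alt": ["G", "G"],
        }
    )
    # dosages: S1 het at both, S2 hom; D1 hom, D2 het at locus 2
    d = np.array(
        [
            [1, 1],  # S1
            [0, 2],  # S2
            [0, 0],  # D1
            [2, 1],  # D2
        ],
        dtype=np.int8,
    )
    return DosageMatrix(["S1", "S2", "D1", "D2"], loci, d)


def toy_design(extra_block=True):
    rows = [
        ("F1", "S1", "D1", "B1"),
        ("F2", "S1", "D2", "B1"),
        ("F3", "S2", "D1", "B1"),
        ("F4", "S2", "D2", "B1"),
    ]
    if extra_block:
        rows.append(("F5", "S1", "D2", "B2"))  # lone family: block under-sampled
    fam = pd.DataFrame(rows, columns=["family_id", "sire_id", "dam_id", "block_id"])
    fam["treatments"] = "low,reference"
    return CrossDesign(fam)


def toy_per_family(design):
    rows = []
    for fam_id in design.families["family_id"]:
        for pos in (100, 200):
            rows.append(
                {
                    "chrom": "LG1",
                    "pos": pos,
                    "family_id": fam_id,
                    "g_low": 1.0,
                    "g_ref": 0.5,
                    "delta_g": 0.5,
                }
            )
    return pd.DataFrame(rows)


class TestBuildEffectsTable:
    def test_het_indicators(self):
        design = toy_design(extra_block=False)
        table = build_effects_table(
            toy_per_family(design), toy_parents(), design, min_families_per_block=1
        )
        by = table.set_index(["family_id", "pos"])
        # MHET = 1 iff the sire's dosage is exactly 1 at the locus
        assert by.loc[("F1", 100), "mhet"] == 1  # S1 dosage 1
        assert by.loc[("F3", 100), "mhet"] == 0  # S2 dosage 0
        assert by.loc[("F3", 200), "mhet"] == 0  # S2 dosage 2 (hom alt is not het)
        # FHET likewise for the dam
        assert by.loc[("F1", 100), "fhet"] == 0  # D1 dosage 0
        assert by.loc[("F2", 200), "fhet"] == 1  # D2 dosage 1
        assert by.loc[("F2", 100), "fhet"] == 0  # D2 dosage 2

    def test_under_sampled_block_dropped(self):
        design = toy_design(extra_block=True)
        table = build_effects_table(
            toy_per_family(design), toy_parents(), design, min_families_per_block=3
        )
        assert set(table["block_id"]) == {"B1"}
        assert "F5" not in set(table["family_id"])

    def test_empty_region_gives_empty_table(self):
        design = toy_design(extra_block=False)
        region = pd.DataFrame({"chrom": ["LG9"], "start": [0], "end": [100]})
        table = build_effects_table(
            toy_per_family(design), toy_parents(), design, region=region
        )
        assert table.empty

    def test_unknown_family_errors(self):
        design = toy_design(extra_block=False)
        per_fam = toy_per_family(design)
        per_fam.loc[0, "family_id"] = "ghost"
        with pytest.raises(KeyError, match="absent"):
            build_effects_table(per_fam, toy_parents(), design)


def synthetic_table(rng, n_families=33, n_loci=20, beta_mhet=5.0, noise_sd=1.0):
    """Synthetic effects table: known MHET effect, no FHET effect."""
    sires = [f"S{i}" for i in range(15)]
    dams = [f"D{i}" for i in range(15)]
    blocks = [f"B{i % 5}" for i in range(n_families)]
    rows = []
    for i in range(n_families):
        sire = sires[i % len(sires)]
        dam = dams[(i * 7) % len(dams)]
        for j in range(n_loci):
            mhet = int(rng.random() < 0.5)
            fhet = int(rng.random() < 0.5)
            rows.append(
                {
                    "delta_g": beta_mhet * mhet + rng.normal(0, noise_sd),
                    "block_id": blocks[i],
                    "sire_id": sire,
                    "dam_id": dam,
                    "mhet": mhet,
                    "fhet": fhet,
                    "chrom": "LG1",
                    "pos": j + 1,
                    "family_id": f"F{i}",
                }
            )
    return pd.DataFrame(rows)


class TestFitEffectsModel:
    def test_needs_two_parents_per_role(self):
        table = synthetic_table(np.random.default_rng(0))
        table["sire_id"] = "S0"
        with pytest.raises(ValueError, match="two sires"):
            fit_effects_model(table)

    def test_constant_response_degenerate(self):
        table = synthetic_table(np.random.default_rng(0))
        table["delta_g"] = 3.0
        fit = fit_effects_model(table)
        assert fit.method == "degenerate"
        assert fit.vc_sire == fit.vc_dam == 0.0
        assert fit.p_mhet == fit.p_fhet == 1.0

    def test_rank_deficiency_names_columns(self):
        table = synthetic_table(np.random.default_rng(0))
        table["fhet"] = table["mhet"]  # perfectly confounded
        with pytest.raises(ValueError, match="fhet"):
            fit_effects_model(table)

    def test_nonfinite_response_rejected(self):
        table = synthetic_table(np.random.default_rng(0))
        table.loc[0, "delta_g"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_effects_model(table)

    def test_parameter_recovery(self):
        """Known MHET effect (beta = 5, noise SD 1): the estimate lands near 5
        with a significant LRT, and the null FHET stays non-significant, in
        nearly all replicates."""
        n_est_ok = n_m_sig = n_f_ns = 0
        n_sims = 20
        for rep in range(n_sims):
            table = synthetic_table(np.random.default_rng(1000 + rep))
            fit = fit_effects_model(table)
            est = fit.params.get("mhet", np.nan)
            n_est_ok += 4.0 <= est <= 6.0
            n_m_sig += fit.p_mhet < 0.05
            n_f_ns += fit.p_fhet >= 0.05
        assert n_est_ok >= 0.9 * n_sims
        assert n_m_sig >= 0.9 * n_sims
        assert n_f_ns >= 0.8 * n_sims

    def test_label_swap_symmetry(self):
        table = synthetic_table(np.random.default_rng(7))
        fit = fit_effects_model(table)
        swapped = table.rename(
            columns={
                "sire_id": "dam_id",
                "dam_id": "sire_id",
                "mhet": "fhet",
                "fhet": "mhet",
            }
        )
        fit_sw = fit_effects_model(swapped)
        assert fit_sw.p_fhet == pytest.approx(fit.p_mhet, abs=1e-4)
        assert fit_sw.p_mhet == pytest.approx(fit.p_fhet, abs=1e-4)
        assert fit_sw.vc_sire == pytest.approx(fit.vc_dam, abs=1e-4)

    def test_row_order_invariance(self):
        table = synthetic_table(np.random.default_rng(3))
        fit = fit_effects_model(table)
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        fit_sh = fit_effects_model(shuffled)
        assert fit_sh.p_mhet == pytest.approx(fit.p_mhet, abs=1e-6)
        assert fit_sh.loglike == pytest.approx(fit.loglike, abs=1e-4)

    def test_ols_fallback(self):
        table = synthetic_table(np.random.default_rng(2))
        fit = fit_effects_model(table, use_mixed=False)
        assert fit.method == "ols"
        assert fit.p_mhet < 0.05
        assert fit.p_fhet >= 0.05

    def test_summary_and_frame(self):
        table = synthetic_table(np.random.default_rng(4))
        fit = fit_effects_model(table)
        text = fit.summary()
        assert "MHET" in text and "variance components" in text
        frame = fit.to_frame()
        assert {"var(sire)", "var(dam)", "p_MHET", "p_FHET"} <= set(frame["term"])
        # variance components are non-negative
        vc = frame.set_index("term")["estimate"]
        assert vc["var(sire)"] >= 0 and vc["var(dam)"] >= 0
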