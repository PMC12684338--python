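import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mendelscan import (
    LoadSpec,
    SelectionSpec,
    SimulationConfig,
    family_pool_frequency,
    read_pool_counts,
    simulate_dataset,
    simulate_parents,
    simulate_read_counts,
    write_fixture_set,
)
from mendelscan.design import build_design
from mendelscan.simulate import draw_depths

DOSAGE_PAIRS = [(s, d) for s in (0, 1, 2) for d in (0, 1, 2)]


class TestFamilyPoolFrequency:
    def test_mendelian_baseline(self):
        for s, d in DOSAGE_PAIRS:
            assert family_pool_frequency(s, d) == (s + d) / 4.0

    def test_selection_off_treatment_is_mendelian(self):
        sel = SelectionSpec("LG1", 1, s=0.9, treatment="low")
        for s, d in DOSAGE_PAIRS:
            got = family_pool_frequency(s, d, selection=sel, treatment="reference")
            assert got == (s + d) / 4.0

    @pytest.mark.parametrize("mode", ["genotypic-additive", "genotypic-dominant", "paternal-allele"])
    @given(s=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_direction(self, mode, s):
        sel = SelectionSpec("LG1", 1, s=s, mode=mode, target_allele="alt")
        for sd, dd in DOSAGE_PAIRS:
            f = family_pool_frequency(sd, dd, selection=sel, treatment="low")
            assert 0.0 <= f <= 1.0
            # selection against alt never increases the alt frequency
            assert f <= (sd + dd) / 4.0 + 1e-12

    @pytest.mark.parametrize("mode", ["genotypic-additive", "genotypic-dominant", "paternal-allele"])
    def test_monotone_in_s(self, mode):
        for sd, dd in DOSAGE_PAIRS:
            freqs = [
                family_pool_frequency(
                    sd, dd, selection=SelectionSpec("LG1", 1, s=s, mode=mode), treatment="low"
                )
                for s in (0.0, 0.25, 0.5, 0.75, 1.0)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(freqs, freqs[1:]))

    def test_paternal_mode_needs_het_sire(self):
        sel = SelectionSpec("LG1", 1, s=0.8, mode="paternal-allele")
        # homozygous sire: every sperm identical, so no distortion possible
        for sd in (0, 2):
            for dd in (0, 1, 2):
                got = family_pool_frequency(sd, dd, selection=sel, treatment="low")
                assert got == pytest.approx((sd + dd) / 4.0)
        # heterozygous sire is distorted whatever the dam is
        assert family_pool_frequency(1, 1, selection=sel, treatment="low") < 0.5

    def test_paternal_mode_exact_value(self):
        # sire het, dam hom-ref, s = 0.5 against alt. Zygote classes:
        # (pat=1, mat=0) probability 1/2, fitness 1/2, one alt copy;
        # (pat=0, mat=0) probability 1/2, fitness 1, zero alt copies.
        # post-selection alt frequency = (1/4 * 1) / (1/4 + 1/2) / 2 = 1/6
        sel = SelectionSpec("LG1", 1, s=0.5, mode="paternal-allele")
        got = family_pool_frequency(1, 0, selection=sel, treatment="low")
        assert got == pytest.approx(1 / 6)

    def test_complete_selection_empties_pool(self):
        sel = SelectionSpec("LG1", 1, s=1.0, mode="genotypic-dominant", target_allele="alt")
        assert family_pool_frequency(2, 2, selection=sel, treatment="low") == 0.0

    def test_load_acts_in_both_treatments(self):
        load = LoadSpec("LG1", 1, strength=0.5)
        f_low = family_pool_frequency(1, 1, load=load, treatment="low")
        f_ref = family_pool_frequency(1, 1, load=load, treatment="reference")
        assert f_low == f_ref < 0.5

    def test_dict_load_needs_resolved_strength(self):
        load = LoadSpec("LG1", 1, strength={"F1": 0.5})
        with pytest.raises(ValueError, match="resolved"):
            family_pool_frequency(1, 1, load=load)
        f = family_pool_frequency(1, 1, load=load, load_strength=0.5)
        assert f < 0.5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="dosage"):
            family_pool_frequency(3, 1)
        with pytest.raises(ValueError, match="treatment"):
            family_pool_frequency(1, 1, treatment="briny")


class TestDepthsAndReads:
    def test_negative_binomial_moments(self, rng):
        mean, cv = 15.0, 0.5
        depths = draw_depths(("negative-binomial", mean, cv), 200_000, rng)
        assert depths.mean() == pytest.approx(mean, rel=0.02)
        assert depths.std() == pytest.approx(mean * cv, rel=0.02)

    def test_point_depth(self, rng):
        depths = draw_depths(("point", 20), 10, rng)
        assert (depths == 20).all()

    def test_read_counts_sum_to_depth(self, rng):
        ref, alt = simulate_read_counts(np.full(1000, 0.3), ("point", 50), rng)
        assert ((ref + alt) == 50).all()
        assert alt.mean() / 50 == pytest.approx(0.3, abs=0.02)

    def test_error_rate_folds_in(self, rng):
        # at pool frequency 0 the only alt reads are errors
        _, alt = simulate_read_counts(np.zeros(200_000), ("point", 10), rng, error_rate=0.01)
        assert alt.mean() / 10 == pytest.approx(0.01, rel=0.1)

    def test_invalid_frequency(self, rng):
        with pytest.raises(ValueError, match="pool_freq"):
            simulate_read_counts(np.array([1.2]), ("point", 10), rng)


class TestSimulateParents:
    def test_all_loci_polymorphic(self):
        cfg = SimulationConfig(n_blocks=1, n_linkage_groups=1, lg_length_bp=50_000,
                               n_snps_per_lg=200, rng_seed=3)
        rng = np.random.default_rng(3)
        design = build_design(cfg, rng)
        parents = simulate_parents(cfg, design, rng)
        totals = parents.dosages.sum(axis=0)
        assert (totals > 0).all() and (totals < 2 * parents.n_samples).all()
        assert parents.n_loci == 200

    def test_designated_locus_honoured(self):
        spec = SelectionSpec("LG1", 12_345, s=0.5, parent_dosage=1)
        cfg = SimulationConfig(n_blocks=1, n_linkage_groups=1, lg_length_bp=50_000,
                               n_snps_per_lg=50, selection_loci=(spec,), rng_seed=5)
        rng = np.random.default_rng(5)
        design = build_design(cfg, rng)
        parents = simulate_parents(cfg, design, rng)
        j = parents.locus_ordinals(["LG1"], [12_345])[0]
        assert j >= 0
        assert (parents.dosages[:, j] == 1).all()


class TestSimulateDataset:
    def test_deterministic(self):
        cfg = SimulationConfig(n_blocks=1, n_linkage_groups=1, lg_length_bp=100_000,
                               n_snps_per_lg=40, rng_seed=11)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.counts, d2.counts)
        np.testing.assert_array_equal(d1.parents.dosages, d2.parents.dosages)

    def test_seed_changes_data(self):
        cfg = SimulationConfig(n_blocks=1, n_linkage_groups=1, lg_length_bp=100_000,
                               n_snps_per_lg=40, rng_seed=11)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg.replace(rng_seed=12))
        assert not d1.counts["alt_count"].equals(d2.counts["alt_count"])

    def test_counts_cover_design(self, small_dataset):
        ds = small_dataset
        pools = ds.counts.groupby(["family_id", "treatment"], observed=True).size()
        expected_pools = sum(
            len(t.split(",")) for t in ds.design.families["treatments"]
        )
        assert len(pools) == expected_pools
        assert (pools == ds.parents.n_loci).all()

    def test_mean_frequency_tracks_truth(self, small_dataset):
        ds = small_dataset
        fam = ds.design.families
        i = next(
            k for k, t in enumerate(fam["treatments"]) if "low" in t.split(",")
        )  # pool_freq rows follow the design table order
        fam_id = fam["family_id"].iloc[i]
        low = ds.counts.loc[ds.counts["treatment"] == "low"]
        sub = low.loc[low["family_id"] == fam_id].sort_values("_locus_i")
        obs = sub["alt_count"].to_numpy() / (
            sub["alt_count"] + sub["ref_count"]
        ).to_numpy()
        want = ds.pool_freq["low"][i, sub["_locus_i"].to_numpy()]
        assert np.nanmean(obs - want) == pytest.approx(0.0, abs=0.02)

    def test_truth_table(self):
        sel = SelectionSpec("LG1", 5_000, s=0.6, treatment="low")
        load = LoadSpec("LG1", 9_000, strength=0.4)
        cfg = SimulationConfig(n_blocks=1, n_linkage_groups=1, lg_length_bp=50_000,
                               n_snps_per_lg=30, selection_loci=(sel,), load_loci=(load,),
                               rng_seed=2)
        ds = simulate_dataset(cfg)
        assert set(ds.truth["kind"]) == {"selection", "load"}
        assert ds.truth.loc[ds.truth["kind"] == "load", "treatment"].iloc[0] == "both"

    def test_finite_pool_option(self):
        cfg = SimulationConfig(n_blocks=1, n_linkage_groups=1, lg_length_bp=50_000,
                               n_snps_per_lg=30, n_larvae=100, rng_seed=2)
        ds = simulate_dataset(cfg)
        # realised frequencies are multiples of 1/(2 * n_larvae)
        f = ds.pool_freq["low"] * 200
        np.testing.assert_allclose(f, np.round(f), atol=1e-9)

    def test_fixture_set_round_trip(self, small_dataset, tmp_path):
        ds = small_dataset
        paths = write_fixture_set(ds, tmp_path)
        for p in paths.values():
            assert str(p).endswith("parents") or p.exists()
        from mendelscan import DosageMatrix

        parents = DosageMatrix.from_vcf(paths["parents_vcf"])
        np.testing.assert_array_equal(parents.dosages, ds.parents.dosages)
        counts = read_pool_counts(paths["counts"], parents)
        assert len(counts) == len(ds.counts)
        np.testing.assert_array_equal(
            counts["alt_count"].to_numpy(), ds.counts["alt_count"].to_numpy()
        )
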