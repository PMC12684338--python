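"""Synthetic factorial-cross pool-seq generator with known ground truth.

The generator produces, from a :class:`~mendelscan.design.SimulationConfig`:

1. a factorial mating design (:func:`~mendelscan.design.build_design`),
2. parental genotypes drawn from Hardy-Weinberg proportions at loci whose
   population alternative-allele frequency follows a configurable law,
3. the expected alternative-allele frequency of each family's surviving larval
   pool under Mendelian segregation, optionally distorted by treatment-specific
   viability selection and/or family-specific load, and
4. pooled sequencing read counts, binomially sampled at a per-locus depth drawn
   from a configurable depth law with a small symmetric base-calling error.

Larval pools are modelled as effectively infinite, so the post-selection pool
frequency is an exact enumeration over the four possible gamete combinations;
an optional finite pool size adds binomial sampling of larvae. Loci are
unlinked: windowed signal is created by placing several selected loci inside
one window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    TREATMENTS,
    CrossDesign,
    LoadSpec,
    SelectionSpec,
    SimulationConfig,
    build_design,
)
from .io import DosageMatrix, write_pool_counts

logger = logging.getLogger(__name__)

_ALLELES = ("A", "C", "G", "T")


def _draw_freqs(law: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    if kind == "beta":
        return rng.beta(law[1], law[2], size=size)
    if kind == "point":
        return np.full(size, float(law[1]))
    raise ValueError(f"unknown allele_freq_law {kind!r}")


def draw_depths(law: tuple, size, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "negative-binomial":
        mean, cv = law[1], law[2]
        var = (cv * mean) ** 2
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)
    if kind == "point":
        depth = int(law[1])
        if depth < 0:
            raise ValueError("depth_law yielded negative depth")
        return np.full(size, depth, dtype=np.int64)
    raise ValueError(f"unknown depth_law {kind!r}")


def _build_locus_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random SNP positions per linkage group, plus any designated selection or
    load loci inserted at their exact positions."""
    frames = []
    designated = {}
    for spec in list(config.selection_loci) + list(config.load_loci):
        designated.setdefault((spec.chrom, spec.pos), spec)
    for chrom in config.chrom_names():
        want = config.n_snps_per_lg
        pos = np.unique(rng.integers(1, config.lg_length_bp + 1, size=int(want * 1.1)))
        while len(pos) < want:
            extra = rng.integers(1, config.lg_length_bp + 1, size=want)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        extra = [p for (c, p) in designated if c == chrom and p not in set(pos)]
        if extra:
            pos = np.unique(np.concatenate([pos, np.array(extra, dtype=pos.dtype)]))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    loci = pd.concat(frames, ignore_index=True)
    ref_i = rng.integers(0, 4, size=len(loci))
    alt_i = (ref_i + rng.integers(1, 4, size=len(loci))) % 4
    loci["ref"] = np.array(_ALLELES)[ref_i]
    loci["alt"] = np.array(_ALLELES)[alt_i]
    return loci


def simulate_parents(
    config: SimulationConfig,
    design: CrossDesign,
    rng: np.random.Generator | None = None,
) -> DosageMatrix:
    """Draw parental genotypes.

    Per locus the population alternative-allele frequency comes from
    ``config.allele_freq_law`` and each parent's dosage is Binomial(2, freq)
    (Hardy-Weinberg). Loci that come out monomorphic across all parents are
    redrawn, so every emitted locus is polymorphic in the parental panel.
    Designated loci (selection/load specs with ``alt_freq`` or
    ``parent_dosage``) are honoured.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    parents = design.parents()
    loci = _build_locus_map(config, rng)
    n_par, n_loc = len(parents), len(loci)
    freqs = _draw_freqs(config.allele_freq_law, n_loc, rng)

    key_to_col = {
        (c, p): j for j, (c, p) in enumerate(zip(loci["chrom"], loci["pos"]))
    }
    forced_het_cols = []
    for spec in list(config.selection_loci) + list(config.load_loci):
        j = key_to_col[(spec.chrom, spec.pos)]
        if spec.alt_freq is not None:
            freqs[j] = spec.alt_freq
        if spec.parent_dosage is not None:
            forced_het_cols.append(j)

    dosages = rng.binomial(2, freqs, size=(n_par, n_loc)).astype(np.int8)
    for j in forced_het_cols:
        dosages[:, j] = 1
    # redraw monomorphic columns until all loci segregate in the panel
    for _ in range(1000):
        totals = dosages.sum(axis=0)
        mono = (totals == 0) | (totals == 2 * n_par)
        if not mono.any():
            break
        freqs[mono] = _draw_freqs(config.allele_freq_law, int(mono.sum()), rng)
        dosages[:, mono] = rng.binomial(2, freqs[mono], size=(n_par, int(mono.sum()))).astype(np.int8)
    else:
        raise RuntimeError("could not draw polymorphic loci; allele_freq_law too extreme")
    return DosageMatrix(list(parents), loci, dosages)


def _gamete_fitness(mode: str, s: float, target: int, paternal: int, maternal: int) -> float:
    """Fitness of the zygote (paternal allele, maternal allele); alleles coded
    0 = ref, 1 = alt, ``target`` likewise."""
    n_target = int(paternal == target) + int(maternal == target)
    if mode == "genotypic-additive":
        return 1.0 - s * n_target / 2.0
    if mode == "genotypic-dominant":
        return 1.0 - s * (1.0 if n_target >= 1 else 0.0)
    if mode == "paternal-allele":
        return 1.0 - s * (1.0 if paternal == target else 0.0)
    raise ValueError(f"unknown selection mode {mode!r}")


def family_pool_frequency(
    sire_dosage: int,
    dam_dosage: int,
    selection: SelectionSpec | None = None,
    load: LoadSpec | None = None,
    treatment: str = TREATMENTS[0],
    load_strength: float | None = None,
) -> float:
    """Expected alternative-allele frequency in a family's surviving larvae.

    Without selection or load this is the Mendelian expectation
    ``(sire_dosage + dam_dosage) / 4``. With selection and/or load, the four
    paternal x maternal gamete combinations are enumerated, each zygote class
    is weighted by its viability, and the post-selection allele frequency is
    the renormalised fitness-weighted mean zygote allele frequency. Selection
    acts only in its own treatment; load acts identically in both treatments.

    ``load_strength`` overrides the load spec's strength (used to apply a
    family-specific coefficient); when ``None`` the scalar strength of the
    spec is used.
    """
    for d, who in ((sire_dosage, "sire"), (dam_dosage, "dam")):
        if d not in (0, 1, 2):
            raise ValueError(f"invalid {who} dosage {d!r}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")

    weights = []  # (probability, fitness, zygote alt copies)
    p_pat = sire_dosage / 2.0
    p_mat = dam_dosage / 2.0
    sel_active = selection is not None and selection.treatment == treatment and selection.s > 0
    if load is not None:
        ls = load.strength if load_strength is None else load_strength
        if isinstance(ls, dict):
            raise ValueError("pass a resolved per-family load_strength for dict-valued load")
    for pat in (0, 1):
        pp = p_pat if pat == 1 else 1.0 - p_pat
        if pp == 0.0:
            continue
        for mat in (0, 1):
            pm = p_mat if mat == 1 else 1.0 - p_mat
            if pm == 0.0:
                continue
            w = 1.0
            if sel_active:
                t = 1 if selection.target_allele == "alt" else 0
                w *= _gamete_fitness(selection.mode, selection.s, t, pat, mat)
            if load is not None and ls > 0:
                t = 1 if load.target_allele == "alt" else 0
                w *= _gamete_fitness(load.mode, ls, t, pat, mat)
            weights.append((pp * pm, w, pat + mat))
    total_w = sum(p * w for p, w, _ in weights)
    if total_w == 0.0:
        # all surviving classes eliminated; the pool is empty of the target —
        # only possible at s = 1 with every zygote a carrier
        return 0.0 if (selection and selection.target_allele == "alt") or (
            load and load.target_allele == "alt"
        ) else 1.0
    return sum(p * w * g for p, w, g in weights) / total_w / 2.0


def simulate_read_counts(
    pool_freq,
    depth_law: tuple,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool-seq read counts at given pool allele frequencies.

    Depth is drawn from ``depth_law``; the alternative-allele count is
    Binomial(depth, f') where ``f'`` folds a symmetric base error into the pool
    frequency. Returns ``(ref_count, alt_count)`` arrays.
    """
    pool_freq = np.asarray(pool_freq, dtype=float)
    if ((pool_freq < 0) | (pool_freq > 1)).any():
        raise ValueError("pool_freq must lie in [0, 1]")
    depth = draw_depths(depth_law, pool_freq.shape, rng)
    if (depth < 0).any():
        raise ValueError("depth_law yielded negative depth")
    p_obs = pool_freq * (1.0 - error_rate) + (1.0 - pool_freq) * error_rate
    alt = rng.binomial(depth, p_obs)
    return depth - alt, alt


@dataclass
class SimulatedDataset:
    """A complete synthetic experiment: design, parents, ground-truth pool
    frequencies per treatment, read counts, and the truth table of planted
    selection/load loci."""

    config: SimulationConfig
    design: CrossDesign
    parents: DosageMatrix
    pool_freq: dict  # treatment -> (n_families, n_loci) expected frequency
    counts: pd.DataFrame
    truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator under a single seeded RNG stream.

    Identical configs (including seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(config.rng_seed)
    design = build_design(config, rng)
    parents = simulate_parents(config, design, rng)

    fam = design.families
    sire_idx = np.array([parents.sample_index(s) for s in fam["sire_id"]])
    dam_idx = np.array([parents.sample_index(d) for d in fam["dam_id"]])
    sire_d = parents.dosages[sire_idx, :].astype(np.int16)
    dam_d = parents.dosages[dam_idx, :].astype(np.int16)
    base = (sire_d + dam_d) / 4.0  # Mendelian expectation, (n_fam, n_loci)

    col_of = {
        (c, p): j
        for j, (c, p) in enumerate(zip(parents.loci["chrom"], parents.loci["pos"]))
    }
    # resolve family-specific load strengths up front (deterministic)
    pool_freq = {}
    for treatment in TREATMENTS:
        freq = base.copy()
        for spec in config.selection_loci:
            if spec.treatment != treatment:
                continue
            j = col_of[(spec.chrom, spec.pos)]
            for i in range(len(fam)):
                freq[i, j] = family_pool_frequency(
                    int(sire_d[i, j]), int(dam_d[i, j]), selection=spec, treatment=treatment
                )
        for spec in config.load_loci:
            j = col_of[(spec.chrom, spec.pos)]
            sel_here = next(
                (
                    s
                    for s in config.selection_loci
                    if (s.chrom, s.pos) == (spec.chrom, spec.pos) and s.treatment == treatment
                ),
                None,
            )
            for i, family_id in enumerate(fam["family_id"]):
                freq[i, j] = family_pool_frequency(
                    int(sire_d[i, j]),
                    int(dam_d[i, j]),
                    selection=sel_here,
                    load=spec,
                    treatment=treatment,
                    load_strength=spec.strength_for(family_id),
                )
        pool_freq[treatment] = freq

    # finite-pool option: binomially resample the realised larval pool
    if config.n_larvae is not None:
        for treatment in TREATMENTS:
            f = pool_freq[treatment]
            n2 = 2 * config.n_larvae
            pool_freq[treatment] = rng.binomial(n2, f) / n2

    # sequencing: one (family, treatment) pool per row-block, assembled into a
    # single long table with categorical label columns (cheap at scale)
    n_loci = parents.n_loci
    loci = parents.loci
    pools = [
        (i, t)
        for i, row in fam.iterrows()
        for t, treatment in enumerate(TREATMENTS)
        if treatment in row["treatments"].split(",")
    ]
    ref_mat = np.empty((len(pools), n_loci), dtype=np.int32)
    alt_mat = np.empty_like(ref_mat)
    for k, (i, t) in enumerate(pools):
        ref_mat[k], alt_mat[k] = simulate_read_counts(
            pool_freq[TREATMENTS[t]][i], config.depth_law, rng, config.error_rate
        )
    fam_codes = np.repeat(np.array([i for i, _ in pools], dtype=np.int16), n_loci)
    tr_codes = np.repeat(np.array([t for _, t in pools], dtype=np.int8), n_loci)
    chrom_codes, chrom_cats = pd.factorize(loci["chrom"])
    ref_codes, ref_cats = pd.factorize(loci["ref"])
    alt_codes, alt_cats = pd.factorize(loci["alt"])
    n_pools = len(pools)
    counts = pd.DataFrame(
        np.column_stack(
            [
                np.tile(loci["pos"].to_numpy().astype(np.int64), n_pools),
                ref_mat.ravel().astype(np.int64),
                alt_mat.ravel().astype(np.int64),
                np.tile(np.arange(n_loci, dtype=np.int64), n_pools),
            ]
        ),
        columns=["pos", "ref_count", "alt_count", "_locus_i"],
    )
    counts["chrom"] = pd.Categorical.from_codes(np.tile(chrom_codes, n_pools), chrom_cats)
    counts["ref"] = pd.Categorical.from_codes(np.tile(ref_codes, n_pools), ref_cats)
    counts["alt"] = pd.Categorical.from_codes(np.tile(alt_codes, n_pools), alt_cats)
    counts["family_id"] = pd.Categorical.from_codes(fam_codes, fam["family_id"].to_numpy())
    counts["treatment"] = pd.Categorical.from_codes(tr_codes, list(TREATMENTS))

    truth_rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "kind": "selection",
            "mode": s.mode,
            "s": s.s,
            "treatment": s.treatment,
        }
        for s in config.selection_loci
    ] + [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "kind": "load",
            "mode": s.mode,
            "s": s.strength if not isinstance(s.strength, dict) else float("nan"),
            "treatment": "both",
        }
        for s in config.load_loci
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "kind", "mode", "s", "treatment"]
    )
    return SimulatedDataset(config, design, parents, pool_freq, counts, truth)


def write_fixture_set(dataset: SimulatedDataset, outdir) -> dict:
    """Write the interchange files for a simulated dataset.

    Emits ``parents.vcf``, the -012 companion files, ``design.tsv``,
    ``counts.tsv`` and ``truth.tsv``; returns the path map.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "parents_vcf": outdir / "parents.vcf",
        "parents_012": outdir / "parents",
        "design": outdir / "design.tsv",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
    }
    contigs = {c: dataset.config.lg_length_bp for c in dataset.config.chrom_names()}
    dataset.parents.to_vcf(paths["parents_vcf"], contig_lengths=contigs)
    dataset.parents.to_012(paths["parents_012"])
    dataset.design.to_table(paths["design"])
    write_pool_counts(dataset.counts, paths["counts"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
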