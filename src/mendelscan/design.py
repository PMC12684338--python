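"""Cross designs and simulation configuration.

The experimental unit is a factorial (North Carolina II) breeding block: every
sire in a block is mated to every dam in the same block, producing full-sib
families that share sires and dams within the block. Larval pools from each
family are reared under two treatments ("low" salinity and a "reference"
salinity control); a subset of families yields a sequenceable pool in only one
treatment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENT_LOW = "low"
TREATMENT_REFERENCE = "reference"
TREATMENTS = (TREATMENT_LOW, TREATMENT_REFERENCE)

SELECTION_MODES = ("genotypic-additive", "genotypic-dominant", "paternal-allele")


@dataclass(frozen=True)
class SelectionSpec:
    """Treatment-specific viability selection acting at one locus.

    Fitness of a zygote is ``w = 1 - s * effect`` where the effect depends on
    ``mode``:

    - ``genotypic-additive``: effect = (copies of target allele) / 2
    - ``genotypic-dominant``:  effect = 1 if the zygote carries >= 1 target copy
    - ``paternal-allele``:     effect = 1 if the *paternally inherited* allele
      is the target (selection on the sperm/paternal gamete only)

    ``alt_freq`` / ``parent_dosage`` optionally pin the population frequency or
    every parent's genotype at the locus, so that power studies can guarantee
    the locus segregates in the crosses (a locus monomorphic within a family
    cannot be distorted, whatever ``s`` is).
    """

    chrom: str
    pos: int
    s: float
    mode: str = "genotypic-additive"
    treatment: str = TREATMENT_LOW
    target_allele: str = "alt"
    alt_freq: float | None = None
    parent_dosage: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"selection coefficient must be in [0, 1], got {self.s}")
        if self.mode not in SELECTION_MODES:
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.target_allele not in ("ref", "alt"):
            raise ValueError("target_allele must be 'ref' or 'alt'")
        if self.alt_freq is not None and not 0.0 < self.alt_freq < 1.0:
            raise ValueError("alt_freq must lie strictly inside (0, 1)")
        if self.parent_dosage is not None and self.parent_dosage != 1:
            raise ValueError(
                "parent_dosage may only force heterozygosity (1); forcing all "
                "parents homozygous would create a monomorphic locus"
            )


@dataclass(frozen=True)
class LoadSpec:
    """Family-specific distortion (genetic load) at one locus.

    Load acts identically in both treatments of a family: it models mortality
    caused by deleterious alleles segregating in particular crosses, not by the
    treatment. ``strength`` is either a single selection coefficient applied in
    every family or a mapping ``family_id -> s``; families absent from the
    mapping are unaffected.
    """

    chrom: str
    pos: int
    strength: float | dict[str, float] = 0.5
    mode: str = "genotypic-additive"
    target_allele: str = "alt"
    alt_freq: float | None = None
    parent_dosage: int | None = None

    def __post_init__(self) -> None:
        strengths = (
            list(self.strength.values())
            if isinstance(self.strength, dict)
            else [self.strength]
        )
        for s in strengths:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"load strength must be in [0, 1], got {s}")
        if self.mode not in SELECTION_MODES:
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.target_allele not in ("ref", "alt"):
            raise ValueError("target_allele must be 'ref' or 'alt'")
        if self.parent_dosage is not None and self.parent_dosage != 1:
            raise ValueError("parent_dosage may only force heterozygosity (1)")

    def strength_for(self, family_id: str) -> float:
        if isinstance(self.strength, dict):
            return self.strength.get(family_id, 0.0)
        return self.strength


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic factorial-cross pool-seq generator.

    Defaults emulate the study design this package targets: 5 blocks of 3x3
    crosses (45 full-sib families, of which 33 have sequenced pools in both
    treatments), 10 linkage groups, a pooled sequencing depth averaging ~15x,
    and a small symmetric base-calling error.
    """

    n_blocks: int = 5
    sires_per_block: int = 3
    dams_per_block: int = 3
    n_linkage_groups: int = 10
    lg_length_bp: int = 20_000_000
    n_snps_per_lg: int = 5_000
    allele_freq_law: tuple = ("uniform", 0.05, 0.95)
    depth_law: tuple = ("negative-binomial", 15.0, 0.5)
    error_rate: float = 0.001
    selection_loci: tuple[SelectionSpec, ...] = ()
    load_loci: tuple[LoadSpec, ...] = ()
    missing_family_fraction: float = 12 / 45
    n_larvae: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_blocks",
            "sires_per_block",
            "dams_per_block",
            "n_linkage_groups",
            "lg_length_bp",
            "n_snps_per_lg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.missing_family_fraction < 1.0:
            raise ValueError("missing_family_fraction must be in [0, 1)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_larvae is not None and self.n_larvae <= 0:
            raise ValueError("n_larvae must be positive when given")
        self._validate_freq_law()
        self._validate_depth_law()
        # normalise lists to tuples so configs are hashable/frozen
        object.__setattr__(self, "selection_loci", tuple(self.selection_loci))
        object.__setattr__(self, "load_loci", tuple(self.load_loci))
        chroms = set(self.chrom_names())
        for spec in list(self.selection_loci) + list(self.load_loci):
            if spec.chrom not in chroms:
                raise ValueError(f"spec locus on unknown linkage group {spec.chrom!r}")
            if not 1 <= spec.pos <= self.lg_length_bp:
                raise ValueError(f"spec locus position {spec.pos} outside linkage group")

    def _validate_freq_law(self) -> None:
        law = self.allele_freq_law
        kind = law[0]
        if kind == "uniform":
            lo, hi = law[1], law[2]
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("uniform allele_freq_law needs 0 <= lo < hi <= 1")
            if hi <= 0.0 or lo >= 1.0:
                raise ValueError("degenerate allele_freq_law")
        elif kind == "beta":
            if law[1] <= 0 or law[2] <= 0:
                raise ValueError("beta allele_freq_law needs positive shapes")
        elif kind == "point":
            if not 0.0 < law[1] < 1.0:
                raise ValueError(
                    "point-mass allele_freq_law at 0 or 1 is degenerate: every "
                    "locus would be monomorphic"
                )
        else:
            raise ValueError(f"unknown allele_freq_law {kind!r}")

    def _validate_depth_law(self) -> None:
        law = self.depth_law
        kind = law[0]
        if kind == "negative-binomial":
            mean, cv = law[1], law[2]
            if mean <= 0 or cv <= 0:
                raise ValueError("negative-binomial depth_law needs mean > 0, cv > 0")
            if cv * cv * mean <= 1.0:
                raise ValueError(
                    "negative-binomial depth_law requires variance > mean (cv^2 * mean > 1)"
                )
        elif kind == "point":
            if law[1] < 0:
                raise ValueError("depth_law must not yield negative depth")
        else:
            raise ValueError(f"unknown depth_law {kind!r}")

    def chrom_names(self) -> list[str]:
        return [f"LG{i + 1}" for i in range(self.n_linkage_groups)]

    def n_families(self) -> int:
        return self.n_blocks * self.sires_per_block * self.dams_per_block

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CrossDesign:
    """The mating design: which sire x dam produced each family, in which
    block, and which treatments have a sequenced larval pool.

    ``families`` columns: family_id, sire_id, dam_id, block_id, treatments
    (comma-joined treatment labels).
    """

    families: pd.DataFrame

    REQUIRED = ("family_id", "sire_id", "dam_id", "block_id", "treatments")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.families.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.families["family_id"].duplicated().any():
            raise ValueError("duplicate family ids in design")
        if not len(self.dual_treatment_families()):
            raise ValueError("design has no family sequenced in both treatments")

    def treatments_of(self, family_id: str) -> tuple[str, ...]:
        row = self.families.loc[self.families["family_id"] == family_id]
        if row.empty:
            raise KeyError(f"unknown family {family_id!r}")
        return tuple(row["treatments"].iloc[0].split(","))

    def dual_treatment_families(self) -> list[str]:
        mask = self.families["treatments"].map(
            lambda t: set(t.split(",")) >= set(TREATMENTS)
        )
        return list(self.families.loc[mask, "family_id"])

    def parents(self) -> list[str]:
        """All parent ids, sires then dams, in stable order."""
        seen: dict[str, None] = {}
        for col in ("sire_id", "dam_id"):
            for p in self.families[col]:
                seen.setdefault(p, None)
        return list(seen)

    def to_table(self, path) -> None:
        self.families.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path) -> "CrossDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def build_design(config: SimulationConfig, rng: np.random.Generator | None = None) -> CrossDesign:
    """Construct the factorial mating design described by ``config``.

    Every sire in a block is crossed to every dam in the same block. A
    reproducible subset of families (``missing_family_fraction`` of the total)
    lacks a sequenced pool in one randomly chosen treatment, mirroring library
    failures in the real experiment.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    rows = []
    for b in range(1, config.n_blocks + 1):
        sires = [f"B{b}_S{i + 1}" for i in range(config.sires_per_block)]
        dams = [f"B{b}_D{j + 1}" for j in range(config.dams_per_block)]
        for s in sires:
            for d in dams:
                rows.append(
                    {
                        "family_id": f"{s}x{d.split('_')[1]}",
                        "sire_id": s,
                        "dam_id": d,
                        "block_id": f"B{b}",
                        "treatments": ",".join(TREATMENTS),
                    }
                )
    fam = pd.DataFrame(rows)
    n_missing = int(round(config.missing_family_fraction * len(fam)))
    n_missing = min(n_missing, len(fam) - 1)  # keep >= 1 dual-treatment family
    if n_missing:
        drop_idx = rng.choice(len(fam), size=n_missing, replace=False)
        which = rng.integers(0, 2, size=n_missing)
        for i, w in zip(drop_idx, which):
            fam.loc[i, "treatments"] = TREATMENTS[1 - w]
    return CrossDesign(fam)
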