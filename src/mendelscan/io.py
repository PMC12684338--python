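"""Genotype and count-table input/output.

Parental genotypes travel either as a VCF (biallelic SNPs, GT field) or as a
"-012" dosage matrix (one row per sample, one column per locus, entries
0/1/2 = alternative-allele dosage, -1 = missing, with companion ``.indv`` and
``.pos`` files). Larval pool data are long tab-separated tables of per-locus
reference/alternative read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .design import TREATMENTS

logger = logging.getLogger(__name__)

MISSING = -1

#: GATK-style hard filters: (name, source, threshold, direction).
#: ``source`` is "QUAL" or an INFO key; a record is removed iff *any* condition
#: holds. Comparisons are strict, so boundary values survive, and a missing
#: annotation never fires its filter (homozygous-only sites routinely lack the
#: rank-sum annotations).
HARD_FILTERS = (
    ("QD", "QD", 2.0, "lt"),
    ("QUAL", "QUAL", 30.0, "lt"),
    ("SOR", "SOR", 3.0, "gt"),
    ("FS", "FS", 60.0, "gt"),
    ("MQ", "MQ", 40.0, "lt"),
    ("MQRankSum", "MQRankSum", -12.5, "lt"),
    ("ReadPosRankSum", "ReadPosRankSum", -8.0, "lt"),
)


def _info_scalar(value):
    # pysam returns tuples for Number=A/R INFO fields
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    return value


def apply_hard_filters(records):
    """Apply the hard quality filters to an iterable of VCF records.

    Returns ``(kept_records, tally)`` where ``tally`` maps each filter name to
    the number of records at which its condition held (a record can fire
    several filters), plus ``"removed"`` and ``"retained"`` totals.
    """
    tally = {name: 0 for name, *_ in HARD_FILTERS}
    tally["removed"] = 0
    tally["retained"] = 0
    kept = []
    for rec in records:
        fired = False
        for name, source, threshold, direction in HARD_FILTERS:
            if source == "QUAL":
                value = rec.qual
            else:
                try:
                    value = _info_scalar(rec.info.get(source))
                except (KeyError, ValueError):
                    # INFO key not defined in this VCF's header: treat like a
                    # missing annotation (the filter cannot fire)
                    value = None
            if value is None:
                continue
            value = float(value)
            hit = value < threshold if direction == "lt" else value > threshold
            if hit:
                tally[name] += 1
                fired = True
        if fired:
            tally["removed"] += 1
        else:
            tally["retained"] += 1
            kept.append(rec)
    return kept, tally


def _is_biallelic_snp(rec) -> bool:
    if rec.alts is None or len(rec.alts) != 1:
        return False
    ref, alt = rec.ref, rec.alts[0]
    return len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT"


@dataclass
class DosageMatrix:
    """Parent-by-locus alternative-allele dosages.

    ``dosages`` has shape (n_samples, n_loci) with entries in {0, 1, 2} or
    ``MISSING`` (-1). Loci are kept sorted by (chrom, pos) and unique.
    """

    samples: list[str]
    loci: pd.DataFrame  # columns chrom, pos (1-based), ref, alt
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError("dosage array shape does not match samples x loci")
        order = np.lexsort((self.loci["pos"].to_numpy(), self.loci["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.loci = self.loci.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
        if self.loci.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) loci in dosage matrix")
        if not np.isin(self.dosages, (0, 1, 2, MISSING)).all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def locus_ordinals(self, chrom, pos) -> np.ndarray:
        """Map (chrom, pos) pairs to column indices; -1 where absent."""
        idx = pd.MultiIndex.from_frame(self.loci[["chrom", "pos"]])
        query = pd.MultiIndex.from_arrays([np.asarray(chrom), np.asarray(pos)])
        return idx.get_indexer(query)

    def subset_loci(self, mask: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(list(self.samples), self.loci.loc[mask], self.dosages[:, mask])

    # ------------------------------------------------------------------ VCF
    @classmethod
    def from_vcf(cls, path, hard_filter: bool = False):
        """Read parental genotypes from a VCF.

        Multiallelic records and non-SNPs are dropped (not decomposed). With
        ``hard_filter=True`` the quality filters are applied first and the
        per-filter tally is returned alongside the matrix.
        """
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            records = list(vf)
        tally = None
        if hard_filter:
            records, tally = apply_hard_filters(records)
        rows = []
        dosage_cols = []
        for rec in records:
            if not _is_biallelic_snp(rec):
                continue
            col = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in gt if a == 1)
            rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            dosage_cols.append(col)
        loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        dosages = (
            np.stack(dosage_cols, axis=1)
            if dosage_cols
            else np.empty((len(samples), 0), dtype=np.int8)
        )
        matrix = cls(samples, loci, dosages)
        if hard_filter:
            return matrix, tally
        return matrix

    def to_vcf(self, path, contig_lengths: dict[str, int] | None = None) -> None:
        header = pysam.VariantHeader()
        chroms = list(dict.fromkeys(self.loci["chrom"]))
        for c in chroms:
            length = None if contig_lengths is None else contig_lengths.get(c)
            if length is None:
                length = int(self.loci.loc[self.loci["chrom"] == c, "pos"].max()) + 1
            header.contigs.add(c, length=length)
        header.add_meta(
            "FORMAT",
            items=[
                ("ID", "GT"),
                ("Number", "1"),
                ("Type", "String"),
                ("Description", "Genotype"),
            ],
        )
        for s in self.samples:
            header.add_sample(s)
        gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for j in range(self.n_loci):
                locus = self.loci.iloc[j]
                rec = vf.new_record(
                    contig=locus["chrom"],
                    start=int(locus["pos"]) - 1,
                    stop=int(locus["pos"]),
                    alleles=(locus["ref"], locus["alt"]),
                )
                for i, s in enumerate(self.samples):
                    rec.samples[s]["GT"] = gt_codes[int(self.dosages[i, j])]
                    rec.samples[s].phased = False
                vf.write(rec)

    # ----------------------------------------------------------------- -012
    def to_012(self, prefix) -> None:
        prefix = str(prefix)
        np.savetxt(prefix + ".012", self.dosages, fmt="%d", delimiter="\t")
        Path(prefix + ".012.indv").write_text("".join(s + "\n" for s in self.samples))
        self.loci[["chrom", "pos"]].to_csv(
            prefix + ".012.pos", sep="\t", header=False, index=False
        )

    @classmethod
    def from_012(cls, prefix, ref_alt: pd.DataFrame | None = None) -> "DosageMatrix":
        """Read a -012 dosage matrix. The dialect carries no allele identities;
        ``ref_alt`` (columns ref, alt, aligned with the .pos file) may supply
        them, otherwise placeholder alleles A/T are used."""
        prefix = str(prefix)
        dosages = np.loadtxt(prefix + ".012", dtype=np.int8, delimiter="\t", ndmin=2)
        samples = Path(prefix + ".012.indv").read_text().split()
        loci = pd.read_csv(
            prefix + ".012.pos", sep="\t", header=None, names=["chrom", "pos"]
        )
        if ref_alt is not None:
            loci = loci.assign(ref=ref_alt["ref"].values, alt=ref_alt["alt"].values)
        else:
            loci = loci.assign(ref="A", alt="T")
        return cls(samples, loci, dosages)


def scan_locus_mask(matrix: DosageMatrix) -> np.ndarray:
    """Boolean mask of loci satisfying the scan-locus retention predicates
    (biallelic SNP, polymorphic among parents, no missing dosage)."""
    d = matrix.dosages
    snp = (
        matrix.loci["ref"].str.len().eq(1)
        & matrix.loci["alt"].str.len().eq(1)
        & matrix.loci["ref"].isin(list("ACGT"))
        & matrix.loci["alt"].isin(list("ACGT"))
    ).to_numpy()
    no_missing = (d != MISSING).all(axis=0)
    alt_chroms = np.where(d == MISSING, 0, d).sum(axis=0)
    polymorphic = (alt_chroms > 0) & (alt_chroms < 2 * matrix.n_samples)
    return snp & no_missing & polymorphic


def select_scan_loci(matrix: DosageMatrix) -> DosageMatrix:
    """Restrict to loci usable for Mendelian-expectation scans.

    Keeps biallelic SNPs that are polymorphic among the parents (both alleles
    observed at least once across all parental chromosomes — in particular,
    loci at which every parent is a non-reference homozygote are removed) and
    that have no missing dosage.
    """
    keep = scan_locus_mask(matrix)
    if not keep.any():
        logger.warning("no loci survive scan-locus selection")
    return matrix.subset_loci(keep)


COUNT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "family_id",
    "treatment",
    "ref_count",
    "alt_count",
)


def write_pool_counts(counts: pd.DataFrame, path) -> None:
    counts.loc[:, list(COUNT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_pool_counts(path, matrix: DosageMatrix) -> pd.DataFrame:
    """Read a pool count table and join it to the loci of ``matrix``.

    Rows at loci absent from the matrix (or whose alleles disagree with it)
    are dropped with a logged count; the returned frame carries the matrix
    column index of each locus in ``_locus_i``. Negative counts or unknown
    treatment labels are errors.
    """
    counts = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chrom": str,
            "pos": np.int64,
            "ref": str,
            "alt": str,
            "family_id": str,
            "treatment": str,
            "ref_count": np.int64,
            "alt_count": np.int64,
        },
    )
    missing_cols = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing_cols:
        raise ValueError(f"count table missing columns: {missing_cols}")
    if (counts[["ref_count", "alt_count"]].to_numpy() < 0).any():
        raise ValueError("negative read counts in count table")
    bad_treat = set(counts["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise ValueError(f"unknown treatment labels: {sorted(bad_treat)}")
    ordinals = matrix.locus_ordinals(counts["chrom"], counts["pos"])
    known = ordinals >= 0
    if known.any():
        mref = matrix.loci["ref"].to_numpy()[ordinals[known]]
        malt = matrix.loci["alt"].to_numpy()[ordinals[known]]
        match = (counts.loc[known, "ref"].to_numpy() == mref) & (
            counts.loc[known, "alt"].to_numpy() == malt
        )
        known[np.flatnonzero(known)[~match]] = False
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropped %d count rows at loci absent from the matrix", n_dropped)
    out = counts.loc[known].reset_index(drop=True)
    out["_locus_i"] = ordinals[known]
    return out


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
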