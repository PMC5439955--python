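"""Core in-memory containers shared across the pipeline.

All internal coordinates are 1-based; file readers/writers are the only
place offsets change. Chromosome names are normalized to the ``chr``-prefixed
form on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMOSOMES: tuple[str, ...] = ("chrX", "chrY")
ALL_CHROMOSOMES: tuple[str, ...] = AUTOSOMES + SEX_CHROMOSOMES


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed convention."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True)
class VariantRecord:
    """One called variant with its supporting read counts.

    ``variant_type`` tags SNVs vs indels/MNVs; non-SNV records are parsed but
    excluded from all downstream single-nucleotide statistics.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    sample_id: str = ""
    variant_type: str = "snv"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.alt_count < 0 or self.depth < self.alt_count:
            raise ValueError(
                f"require 0 <= alt_count <= depth, got {self.alt_count}/{self.depth}"
            )
        if self.variant_type == "snv" and not (
            len(self.ref) == 1 and len(self.alt) == 1
        ):
            raise ValueError(
                f"SNV record must have single-nucleotide alleles: {self.ref}>{self.alt}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.variant_type == "snv"


class CallSet:
    """A caller's variant records, keyed by (chrom, pos, ref, alt).

    Duplicate keys are an invariant violation and raise on insertion.
    """

    def __init__(
        self,
        records: Iterable[VariantRecord] = (),
        caller_name: str = "",
        sample_id: str = "",
    ) -> None:
        self.caller_name = caller_name
        self.sample_id = sample_id
        self._records: dict[tuple[str, int, str, str], VariantRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: VariantRecord) -> None:
        if rec.key in self._records:
            raise ValueError(f"duplicate variant key {rec.key} in call set")
        self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self._records.values())

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._records

    def __getitem__(self, key: tuple[str, int, str, str]) -> VariantRecord:
        return self._records[key]

    def keys(self) -> set[tuple[str, int, str, str]]:
        return set(self._records)

    def snvs(self) -> "CallSet":
        """Subset to single-nucleotide variants."""
        return CallSet(
            (r for r in self if r.is_snv),
            caller_name=self.caller_name,
            sample_id=self.sample_id,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["chrom", "pos", "ref", "alt", "alt_count", "depth", "sample_id", "variant_type"]
        return pd.DataFrame(
            [[getattr(r, c) for c in cols] for r in self], columns=cols
        )


class KaryotypeTable:
    """Per-tumor, per-chromosome integer copy number and major:minor split.

    Whole-chromosome values only; sub-chromosomal (arm) amplifications are
    carried separately and never enter the copy-number columns, so statistics
    always use the lowest (full integral) chromosome copy number.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        required = {"tumor_id", "chrom", "copy_number"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"karyotype table missing columns {sorted(missing)}")
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["copy_number"] = df["copy_number"].astype(int)
        if (df["copy_number"] < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if df.duplicated(["tumor_id", "chrom"]).any():
            raise ValueError("duplicate (tumor, chromosome) rows")
        if {"major", "minor"} <= set(df.columns):
            has = df["major"].notna() & df["minor"].notna()
            bad = has & (
                df.loc[has, "major"].astype(int) + df.loc[has, "minor"].astype(int)
                != df.loc[has, "copy_number"]
            )
            if bad.any():
                rows = df.loc[bad, ["tumor_id", "chrom"]].to_records(index=False)
                raise ValueError(f"copy_number != major + minor at {list(rows)}")
        for tumor, sub in df.groupby("tumor_id"):
            present = set(sub["chrom"])
            absent = [c for c in AUTOSOMES if c not in present]
            if absent:
                raise ValueError(f"tumor {tumor} missing autosomes {absent}")
        self.df = df

    @property
    def tumors(self) -> list[str]:
        return list(dict.fromkeys(self.df["tumor_id"]))

    def autosome_matrix(self) -> pd.DataFrame:
        """Tumors x chr1..chr22 integer copy-number matrix (X/Y excluded)."""
        sub = self.df[self.df["chrom"].isin(AUTOSOMES)]
        mat = sub.pivot(index="tumor_id", columns="chrom", values="copy_number")
        return mat.loc[self.tumors, list(AUTOSOMES)].astype(int)

    def autosome_sums(self) -> pd.Series:
        return self.autosome_matrix().sum(axis=1)

    def copies(self, tumor_id: str, chrom: str) -> int:
        chrom = normalize_chrom(chrom)
        row = self.df[(self.df["tumor_id"] == tumor_id) & (self.df["chrom"] == chrom)]
        if row.empty:
            raise KeyError(f"no karyotype entry for {tumor_id} {chrom}")
        return int(row["copy_number"].iloc[0])

    def subset(self, tumor_id: str) -> "KaryotypeTable":
        return KaryotypeTable(self.df[self.df["tumor_id"] == tumor_id])


class MarkerProfile:
    """Per-SNP-marker tumor/normal depths and allele counts for one tumor.

    Derived columns: ``ratio`` (tumor/normal depth, NaN where the normal has
    zero coverage) and ``baf`` (folded B-allele frequency, min allele / total,
    at heterozygous markers only).
    """

    COLUMNS = ["chrom", "pos", "tumor_depth", "normal_depth", "tumor_alt", "tumor_ref", "het"]

    def __init__(self, df: pd.DataFrame, tumor_id: str = "") -> None:
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"marker profile missing columns {sorted(missing)}")
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        for col in ("tumor_depth", "normal_depth", "tumor_alt", "tumor_ref"):
            if (df[col] < 0).any():
                raise ValueError(f"negative values in {col}")
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ratio"] = np.where(
                df["normal_depth"] > 0, df["tumor_depth"] / df["normal_depth"], np.nan
            )
            tot = df["tumor_alt"] + df["tumor_ref"]
            baf = np.minimum(df["tumor_alt"], df["tumor_ref"]) / tot
        df["baf"] = np.where(df["het"].astype(bool) & (tot > 0), baf, np.nan)
        self.df = df
        self.tumor_id = tumor_id

    def sorted_check(self) -> None:
        for _, sub in self.df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("markers must be sorted by (chrom, pos)")

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


class MethylationSiteSet:
    """CpG sites with two replicate methylated fractions (internal 1-based).

    Sites missing either replicate are dropped on construction and counted in
    ``n_dropped``. The ``methylated`` flag requires > 50% methylated reads in
    both replicates.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        required = {"chrom", "pos", "rep1_fraction", "rep2_fraction"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"methylation table missing columns {sorted(missing)}")
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        keep = df["rep1_fraction"].notna() & df["rep2_fraction"].notna()
        self.n_dropped = int((~keep).sum())
        df = df[keep].reset_index(drop=True)
        for col in ("rep1_fraction", "rep2_fraction"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate methylation sites")
        df["methylated"] = (df["rep1_fraction"] > 0.5) & (df["rep2_fraction"] > 0.5)
        self.df = df

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def methylated_fraction(self) -> float:
        if self.n_sites == 0:
            return float("nan")
        return float(self.df["methylated"].mean())


@dataclass
class ChromosomeCall:
    """Whole-chromosome copy-number call with allelic decomposition."""

    chrom: str
    copy_number: int
    major: int
    minor: int
    n_markers: int
    suppressed: bool = False
    arm_events: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def loh_flag(self) -> bool:
        return self.minor == 0 and self.copy_number > 0

    def __post_init__(self) -> None:
        if self.major + self.minor != self.copy_number:
            raise ValueError("copy_number must equal major + minor")


@dataclass
class PurityPloidyEstimate:
    """Tumor purity and haploid coverage (reads per unit copy number)."""

    purity: float
    haploid_coverage: float
    mean_ploidy: float = float("nan")
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        if self.haploid_coverage <= 0:
            raise ValueError("haploid_coverage must be positive")


@dataclass
class EnrichmentResult:
    """Binomial mutation-enrichment test outcome at methylated CpG sites."""

    q: int
    n: int
    p: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.q <= self.n):
            raise ValueError("require 0 <= q <= n")
        if not (0 <= self.p <= 1):
            raise ValueError("background fraction p must lie in [0, 1]")
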