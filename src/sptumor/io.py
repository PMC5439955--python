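"""Readers and writers for every external format the pipeline touches.

VCF is 1-based; the bedMethyl-like methylation tables are 0-based half-open
with percent-scale methylation columns. Internal containers are always
1-based with fractions in [0, 1]; these functions are the only place offsets
and scales change.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
import pysam

from .core import (
    CallSet,
    KaryotypeTable,
    MarkerProfile,
    MethylationSiteSet,
    VariantRecord,
    normalize_chrom,
)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _variant_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    if len(ref) == len(alt):
        return "mnv"
    return "indel"


def read_vcf(path: str | Path, caller_name: str = "", sample: str | None = None) -> CallSet:
    """Read a VCF 4.x into a :class:`CallSet`, one record per ALT allele.

    Allele depths are taken from the ``AD`` FORMAT field of the chosen sample
    (default: first sample); total depth is the sum of the AD entries. Indel
    and MNV records are retained with a type tag but excluded from downstream
    SNV statistics.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns with allele depths")
    sample_name = sample if sample is not None else samples[0]
    if sample_name not in samples:
        raise FormatError(f"{path}: sample {sample_name!r} not in VCF")
    callset = CallSet(caller_name=caller_name, sample_id=sample_name)
    with open(path) as fh:
        n_header = sum(1 for line in fh if line.startswith("#"))
    for i, rec in enumerate(vcf):
        line_no = n_header + i + 1
        call = rec.samples[sample_name]
        ad = call.get("AD")
        if ad is None or ad[0] is None:
            raise FormatError(f"{path}:{line_no}: missing AD allele-depth field")
        depth = int(sum(a for a in ad if a is not None))
        for alt_idx, alt in enumerate(rec.alts or ()):
            alt_count = int(ad[alt_idx + 1]) if len(ad) > alt_idx + 1 else 0
            try:
                callset.add(
                    VariantRecord(
                        chrom=normalize_chrom(rec.chrom),
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        alt_count=alt_count,
                        depth=depth,
                        sample_id=sample_name,
                        variant_type=_variant_type(rec.ref, alt),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
    return callset


def write_vcf(
    callset: CallSet,
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a :class:`CallSet` as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"),
                                     ("Type", "Integer"),
                                     ("Description", "Allelic depths")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"),
                                     ("Type", "Integer"),
                                     ("Description", "Read depth")])
    if contigs is None:
        contigs = {}
        for rec in callset:
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.pos + 1000)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    sample = callset.sample_id or "TUMOR"
    header.add_sample(sample)
    out = pysam.VariantFile(str(path), "w", header=header)
    recs = sorted(callset, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    for rec in recs:
        row = out.new_record(
            contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
        )
        row.samples[sample]["AD"] = (rec.depth - rec.alt_count, rec.alt_count)
        row.samples[sample]["DP"] = rec.depth
        out.write(row)
    out.close()


def consensus_intersection(a: CallSet, b: CallSet, counts_from: str = "a") -> CallSet:
    """Variants identified by both callers (exact (chrom,pos,ref,alt) match).

    Read counts are taken from set ``a`` by default (``counts_from='b'`` for
    the other caller; the source of counts for consensus records is a
    convention, not data).
    """
    if a.sample_id and b.sample_id and a.sample_id != b.sample_id:
        raise ValueError(
            f"call sets from different samples: {a.sample_id!r} vs {b.sample_id!r}"
        )
    if counts_from not in ("a", "b"):
        raise ValueError("counts_from must be 'a' or 'b'")
    source = a if counts_from == "a" else b
    shared = a.keys() & b.keys()
    name = "+".join(n for n in (a.caller_name, b.caller_name) if n) or "consensus"
    out = CallSet(caller_name=name, sample_id=a.sample_id or b.sample_id)
    for rec in source:
        if rec.key in shared:
            out.add(rec)
    return out


# ---------------------------------------------------------------------------
# Karyotype tables
# ---------------------------------------------------------------------------

def read_karyotype_table(path: str | Path) -> KaryotypeTable:
    """Read a whole-chromosome karyotype TSV.

    Columns: tumor_id, chrom, copy_number, major, minor, and optional
    arm_copy / arm_zygosity columns holding sub-chromosomal amplification
    values that are stored but excluded from the whole-chromosome numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"arm_copy": str, "arm_zygosity": str})
    try:
        return KaryotypeTable(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_karyotype_table(table: KaryotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def load_table1() -> KaryotypeTable:
    """The packaged five-tumor whole-chromosome karyotype fixture."""
    ref = importlib.resources.files("sptumor") / "data" / "table1_karyotype.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_karyotype_table(path)


# ---------------------------------------------------------------------------
# Marker profiles
# ---------------------------------------------------------------------------

def read_marker_profile(path: str | Path, tumor_id: str = "") -> MarkerProfile:
    df = pd.read_csv(path, sep="\t")
    try:
        profile = MarkerProfile(df[MarkerProfile.COLUMNS], tumor_id=tumor_id)
        profile.sorted_check()
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return profile


def write_marker_profile(profile: MarkerProfile, path: str | Path) -> None:
    profile.df[MarkerProfile.COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Methylation tables (bedMethyl-like dialect)
# ---------------------------------------------------------------------------

METHYL_COLUMNS = ["chrom", "start", "end", "rep1_pct", "rep2_pct"]


def read_methylation_table(path: str | Path) -> MethylationSiteSet:
    """Read a two-replicate bedMethyl-like TSV (0-based half-open, percent).

    Positions are converted to the internal 1-based convention and percent
    columns to fractions on read.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(METHYL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(int) + 1,
            "rep1_fraction": df["rep1_pct"] / 100.0,
            "rep2_fraction": df["rep2_pct"] / 100.0,
        }
    )
    try:
        return MethylationSiteSet(out)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_methylation_table(sites: MethylationSiteSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": sites.df["chrom"],
            "start": sites.df["pos"] - 1,
            "end": sites.df["pos"],
            "rep1_pct": sites.df["rep1_fraction"] * 100.0,
            "rep2_pct": sites.df["rep2_fraction"] * 100.0,
        }
    )
    df.to_csv(path, sep="\t", index=False)
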