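"""Variant-allele-fraction analysis and mutation timing.

The central quantity is the expected VAF of a somatic SNV present on m of the
c copies of its chromosome in a tumor of purity rho:

    E[VAF] = rho * m / (rho * c + 2 * (1 - rho))

At rho = 1 this gives the classic anchors for a trisomy: 1/3 for a mutation
postdating the gain (m = 1) and 2/3 for one predating it on the duplicated
homolog (m = 2). A variant's multiplicity is estimated as the m whose
expectation is nearest its observed VAF; when the two nearest expectations
both sit inside the binomial noise band around the observation the call is
indeterminate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import CallSet, ChromosomeCall, KaryotypeTable, VariantRecord


def compute_vaf(record: VariantRecord) -> float:
    """Variant allele fraction, alt reads over total reads."""
    if record.depth == 0:
        raise ValueError(f"VAF undefined at zero depth ({record.chrom}:{record.pos})")
    return record.alt_count / record.depth


def expected_vaf(copy: int, multiplicity: int, purity: float) -> float:
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    if multiplicity < 1 or multiplicity > copy:
        raise ValueError(
            f"multiplicity must lie in [1, copy]; got m={multiplicity}, c={copy}"
        )
    return purity * multiplicity / (purity * copy + 2.0 * (1.0 - purity))


def classify_timing(
    vaf: float, depth: int, chrom_copy: int, purity: float
) -> tuple[int, str]:
    """Estimate multiplicity and timing label for one variant.

    Returns (multiplicity, label) with label in {pre_gain, post_gain,
    indeterminate}: pre_gain when the best multiplicity is >= 2 (the mutation
    predates the chromosome gain), post_gain when it is 1. The call is
    indeterminate when the two nearest expectations both lie within
    +/- 2*sqrt(vaf*(1-vaf)/depth) of the observed VAF.
    """
    if chrom_copy < 1:
        raise ValueError("chromosome copy number must be >= 1")
    ms = np.arange(1, chrom_copy + 1)
    expectations = np.array([expected_vaf(chrom_copy, int(m), purity) for m in ms])
    order = np.argsort(np.abs(expectations - vaf))
    m_best = int(ms[order[0]])
    if len(ms) > 1 and depth > 0:
        band = 2.0 * np.sqrt(max(vaf * (1.0 - vaf), 0.0) / depth)
        second = expectations[order[1]]
        best = expectations[order[0]]
        if abs(vaf - best) <= band and abs(vaf - second) <= band:
            return m_best, "indeterminate"
    return m_best, "pre_gain" if m_best >= 2 else "post_gain"


def annotate_variants(
    variants: CallSet,
    chromosome_calls: list[ChromosomeCall] | KaryotypeTable,
    purity: float,
    tumor_id: str | None = None,
) -> pd.DataFrame:
    """Per-variant table with VAF, chromosome copy number, multiplicity and
    timing label. Copy numbers come from chromosome calls (or a karyotype
    table); variants on uncalled chromosomes are dropped.
    """
    if isinstance(chromosome_calls, KaryotypeTable):
        tid = tumor_id or chromosome_calls.tumors[0]
        sub = chromosome_calls.df[chromosome_calls.df["tumor_id"] == tid]
        copies = dict(zip(sub["chrom"], sub["copy_number"].astype(int)))
    else:
        copies = {
            c.chrom: c.copy_number for c in chromosome_calls if not c.suppressed
        }
    rows = []
    for rec in variants:
        if not rec.is_snv or rec.chrom not in copies or copies[rec.chrom] < 1:
            continue
        v = compute_vaf(rec)
        m, label = classify_timing(v, rec.depth, copies[rec.chrom], purity)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "vaf": v,
                "depth": rec.depth,
                "chrom_copy": copies[rec.chrom],
                "multiplicity": m,
                "timing": label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "vaf", "depth",
            "chrom_copy", "multiplicity", "timing",
        ],
    )


def vaf_copy_correlation(variants: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between VAF and chromosome copy number.

    Requires >= 3 variants spanning >= 2 copy states. A constant VAF vector
    returns rho = 0 (tie convention).
    """
    if len(variants) < 3:
        raise ValueError("need at least 3 variants")
    vaf = variants["vaf"].to_numpy(dtype=float)
    copy = variants["chrom_copy"].to_numpy(dtype=float)
    if np.ptp(copy) == 0:
        raise ValueError("variants span a single copy state; correlation undefined")
    if np.ptp(vaf) == 0:
        return 0.0, 1.0
    rho, p = stats.spearmanr(vaf, copy)
    return float(rho), float(p)


def vaf_percentiles(
    variants: pd.DataFrame, group_by: str = "chrom"
) -> pd.DataFrame:
    """50th/90th/99th VAF percentiles per group (linear interpolation)."""
    rows = []
    for key, sub in variants.groupby(group_by, sort=False):
        if sub.empty:
            continue
        v = sub["vaf"].to_numpy(dtype=float)
        rows.append(
            {
                group_by: key,
                "n": len(v),
                "p50": float(np.percentile(v, 50)),
                "p90": float(np.percentile(v, 90)),
                "p99": float(np.percentile(v, 99)),
            }
        )
    return pd.DataFrame(rows, columns=[group_by, "n", "p50", "p90", "p99"])


def burden_vs_chromosome_count(
    per_tumor_snv_counts, per_tumor_autosome_counts
) -> tuple[float, float]:
    """Pearson correlation of SNV burden with total autosome count."""
    x = np.asarray(per_tumor_snv_counts, dtype=float)
    y = np.asarray(per_tumor_autosome_counts, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched burden/autosome counts for >= 3 tumors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
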