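"""Pyrimidine-normalized 6-class and 96-trinucleotide mutation spectra.

Every SNV is expressed with a pyrimidine (C or T) reference base: mutations
reported on the purine strand are mapped to the reverse-complement class with
reverse-complemented flanking context, giving the standard 96 mutation types
(6 substitution classes x 16 flanking-base combinations).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import CallSet

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
TRANSITIONS = {("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")}

#: all 96 (substitution, 5' base, 3' base) keys in canonical order
BIN_KEYS: list[tuple[str, str, str]] = [
    (sub, five, three) for sub in SUBSTITUTIONS for five in BASES for three in BASES
]
_BIN_INDEX = {key: i for i, key in enumerate(BIN_KEYS)}


def bin_label(key: tuple[str, str, str]) -> str:
    sub, five, three = key
    return f"{five}[{sub}]{three}"


class EdgePositionError(ValueError):
    """Variant too close to a contig edge to have a trinucleotide context."""


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the reference sequence."""


class SpectrumVector:
    """96-bin trinucleotide mutation-type counts."""

    def __init__(self, counts=None) -> None:
        if counts is None:
            counts = np.zeros(96, dtype=np.int64)
        counts = np.asarray(counts)
        if counts.shape != (96,):
            raise ValueError("a spectrum has exactly 96 bins")
        if (counts < 0).any():
            raise ValueError("bin counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, key: tuple[str, str, str]) -> int:
        return int(self.counts[_BIN_INDEX[key]])

    def add(self, key: tuple[str, str, str], n: int = 1) -> None:
        self.counts[_BIN_INDEX[key]] += n

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return self.counts / self.total

    def as_series(self, normalized: bool = False) -> pd.Series:
        vals = self.frequencies() if normalized else self.counts
        return pd.Series(vals, index=[bin_label(k) for k in BIN_KEYS])


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """1-based inclusive fetch from a pyfaidx.Fasta or a {chrom: str} dict."""
    if isinstance(reference, dict):
        return reference[chrom][start - 1 : end].upper()
    return str(reference[chrom][start - 1 : end]).upper()


def _contig_length(reference, chrom: str) -> int:
    if isinstance(reference, dict):
        return len(reference[chrom])
    return len(reference[chrom])


def classify_snv(
    chrom: str, pos: int, ref: str, alt: str, reference
) -> tuple[str, str, str]:
    """Map one SNV to its 96-bin (substitution, 5' base, 3' base) key.

    ``reference`` is a ``pyfaidx.Fasta`` (or a chrom -> sequence mapping).
    Purine-reference mutations are reverse-complemented into the pyrimidine
    frame together with their context.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if pos < 2 or pos > _contig_length(reference, chrom) - 1:
        raise EdgePositionError(f"{chrom}:{pos} lacks a full trinucleotide context")
    tri = _fetch(reference, chrom, pos - 1, pos + 1)
    if tri[1] != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos}: VCF ref {ref} != reference base {tri[1]}"
        )
    if ref in "AG":  # purine frame: flip to the pyrimidine strand
        tri = _revcomp(tri)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return (f"{ref}>{alt}", tri[0], tri[2])


def build_spectrum(variants: CallSet, reference) -> tuple[SpectrumVector, dict]:
    """96-bin spectrum of a call set's SNVs plus summary fractions.

    Returns the spectrum and a summary dict with the transition fraction, the
    C>T (pyrimidine-frame) fraction, the CpG fraction among C>T mutations
    (3' base = G), and the number of edge variants skipped.
    """
    spectrum = SpectrumVector()
    n_skipped = 0
    for rec in variants:
        if not rec.is_snv:
            continue
        try:
            key = classify_snv(rec.chrom, rec.pos, rec.ref, rec.alt, reference)
        except EdgePositionError:
            n_skipped += 1
            continue
        spectrum.add(key)
    total = spectrum.total
    summary: dict = {"n_classified": total, "n_skipped_edge": n_skipped}
    if total == 0:
        summary.update(
            transition_fraction=np.nan,
            c_to_t_fraction=np.nan,
            cpg_fraction_of_c_to_t=np.nan,
        )
        return spectrum, summary
    by_sub = {
        sub: sum(spectrum[(sub, f, t)] for f in BASES for t in BASES)
        for sub in SUBSTITUTIONS
    }
    transitions = by_sub["C>T"] + by_sub["T>C"]
    c_to_t = by_sub["C>T"]
    cpg_c_to_t = sum(spectrum[("C>T", f, "G")] for f in BASES)
    summary.update(
        transition_fraction=transitions / total,
        c_to_t_fraction=c_to_t / total,
        cpg_fraction_of_c_to_t=(cpg_c_to_t / c_to_t) if c_to_t else np.nan,
    )
    return spectrum, summary


def compare_spectra(a: SpectrumVector, b: SpectrumVector) -> tuple[float, float]:
    """Pearson correlation between two spectra's 96 bin frequencies."""
    fa, fb = a.frequencies(), b.frequencies()
    if np.ptp(fa) == 0 or np.ptp(fb) == 0:
        raise ValueError("spectrum with zero variance across bins")
    r, p = stats.pearsonr(fa, fb)
    return float(r), float(p)


def context_enrichment_test(
    per_tumor_spectra: list[SpectrumVector],
    bin_a: tuple[str, str, str] = ("C>T", "A", "G"),
    bin_b: tuple[str, str, str] = ("C>T", "C", "G"),
) -> tuple[float, float]:
    """One-sided paired t-test that context ``bin_a`` exceeds ``bin_b``.

    The paired variable is each tumor's normalized bin frequency (tumors
    differ in total burden, so raw counts would weight tumors unevenly).
    Returns (t statistic, one-sided p); equal frequencies in every tumor give
    t = 0 and p = 0.5 by convention.
    """
    if len(per_tumor_spectra) < 2:
        raise ValueError("paired test requires at least 2 tumors")
    fa = np.array([s.frequencies()[_BIN_INDEX[bin_a]] for s in per_tumor_spectra])
    fb = np.array([s.frequencies()[_BIN_INDEX[bin_b]] for s in per_tumor_spectra])
    if np.allclose(fa, fb):
        return 0.0, 0.5
    res = stats.ttest_rel(fa, fb, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def germline_like_signature() -> np.ndarray:
    """A 96-bin probability vector emulating the germline de novo spectrum.

    CpG-transition dominated: 75.3% transitions overall, 51.4% C>T of which
    56.6% occur at CpG dinucleotides, with the ACG>ATG context the single
    most frequent bin followed by CCG>CTG. This is a synthetic stand-in for
    published trio-sequencing compilations, built to match their headline
    summary fractions rather than any measured 96-bin table.
    """
    sig = np.zeros(96)
    c_to_t = 0.514
    cpg_mass = c_to_t * 0.566
    cpg_weights = {"A": 0.40, "C": 0.26, "G": 0.18, "T": 0.16}
    for five, w in cpg_weights.items():
        sig[_BIN_INDEX[("C>T", five, "G")]] = cpg_mass * w
    non_cpg = c_to_t - cpg_mass
    non_cpg_bins = [("C>T", f, t) for f in BASES for t in BASES if t != "G"]
    for key in non_cpg_bins:
        sig[_BIN_INDEX[key]] = non_cpg / len(non_cpg_bins)
    class_mass = {"T>C": 0.239, "C>A": 0.090, "C>G": 0.040, "T>A": 0.050, "T>G": 0.067}
    for sub, mass in class_mass.items():
        for five in BASES:
            for three in BASES:
                sig[_BIN_INDEX[(sub, five, three)]] = mass / 16.0
    return sig / sig.sum()


def load_dnm_reference() -> SpectrumVector:
    """Packaged synthetic germline-like comparator spectrum (per-mille counts)."""
    ref = importlib.resources.files("sptumor") / "data" / "dnm_spectrum_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    counts = np.zeros(96, dtype=np.int64)
    for _, row in df.iterrows():
        key = (row["substitution"], row["five_prime"], row["three_prime"])
        counts[_BIN_INDEX[key]] = int(row["count"])
    return SpectrumVector(counts)
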