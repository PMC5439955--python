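"""Synthetic tumor-normal datasets with the statistical structure the
analysis assumes.

The generator emulates the study conditions: heavily aneuploid karyotypes
with per-tumor purity (normal contamination), Poisson read depths and
binomially split allele counts at heterozygous SNP markers, somatic SNVs
whose per-chromosome count scales with copy number, whose variant allele
fraction follows the copy-number/timing mixing model

    VAF = rho * m / (rho * c + 2 * (1 - rho))

(m = mutation multiplicity, c = chromosome copies, rho = purity), whose
trinucleotide contexts are drawn from a germline-like CpG-transition-enriched
signature, and two-replicate CpG methylation tables in which methylated CpGs
may mutate at an elevated rate. All outputs are deterministic given
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ALL_CHROMOSOMES,
    AUTOSOMES,
    CallSet,
    KaryotypeTable,
    MarkerProfile,
    MethylationSiteSet,
    VariantRecord,
    normalize_chrom,
)
from .spectrum import BASES, BIN_KEYS, COMPLEMENT, germline_like_signature

_BASE_LENGTHS = {
    **{f"chr{i}": 200_000 - (i - 1) * 4_800 for i in range(1, 23)},
    "chrX": 150_000,
    "chrY": 60_000,
}


def chromosome_lengths(scale: float = 1.0) -> dict[str, int]:
    """Synthetic chromosome lengths (22 autosomes + X, Y), scaled."""
    return {c: max(int(round(n * scale)), 2_000) for c, n in _BASE_LENGTHS.items()}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the sequenced cohort: 52x tumor / 26x normal coverage,
    ~0.2 SNVs per Mb, 23.2% of CpG sites methylated, and a germline-like
    CpG-transition-enriched signature. ``purity`` defaults to 1 (contamination
    was minimal for most tumors; a contaminated tumor is simulated by setting
    e.g. 0.825, the midpoint of a 15-20% wild-type admixture).
    """

    n_tumors: int = 5
    ploidy_profile: KaryotypeTable | None = None
    purity: float = 1.0
    mean_coverage_tumor: float = 52.0
    mean_coverage_normal: float = 26.0
    n_markers: int = 60_000
    mutation_rate_per_mb: float = 0.2
    signature: np.ndarray = field(default_factory=germline_like_signature)
    timing_fraction_pre_gain: float = 0.0
    methylated_fraction: float = 0.232
    methylation_mutation_multiplier: float = 30.0
    het_fraction: float = 0.5
    genome_scale: float = 1.0
    n_variants: int | None = None
    caller_private_fraction: float = 0.10
    planted_gains: tuple[str, ...] = ()
    planted_losses: tuple[str, ...] = ()
    depth_noise: bool = True
    max_methylation_sites: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        sig = np.asarray(self.signature, dtype=float)
        if sig.shape != (96,) or (sig < 0).any() or not np.isclose(sig.sum(), 1.0):
            raise ValueError("signature must be a 96-bin probability vector")
        self.signature = sig / sig.sum()
        for name in (
            "mean_coverage_tumor", "mean_coverage_normal", "mutation_rate_per_mb",
            "methylated_fraction", "timing_fraction_pre_gain",
            "methylation_mutation_multiplier", "caller_private_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.methylated_fraction <= 1):
            raise ValueError("methylated_fraction must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------

_BASE_PROBS = np.array([0.29, 0.21, 0.21, 0.29])  # A, C, G, T


def simulate_reference(config: SimulationConfig) -> dict[str, str]:
    """Random reference genome as a chrom -> sequence mapping."""
    rng = config.rng(1)
    lengths = chromosome_lengths(config.genome_scale)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        chrom: rng.choice(bases, size=n, p=_BASE_PROBS).tobytes().decode()
        for chrom, n in lengths.items()
    }


def write_reference_fasta(reference: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Karyotypes
# ---------------------------------------------------------------------------

def simulate_karyotype(config: SimulationConfig) -> KaryotypeTable:
    """Aneuploid per-tumor karyotypes, optionally with planted recurrence.

    With an explicit ``ploidy_profile`` the table is passed through
    unchanged. Otherwise each tumor draws a basic ploidy in {2, 3, 4} and
    per-chromosome jitter, then any ``planted_gains`` / ``planted_losses``
    are applied to every tumor; the planted events are recorded on the
    returned table as ``planted_events`` ground truth.
    """
    if config.ploidy_profile is not None:
        table = KaryotypeTable(config.ploidy_profile.df)
        table.planted_events = []
        return table
    rng = config.rng(2)
    gains = {normalize_chrom(c) for c in config.planted_gains}
    losses = {normalize_chrom(c) for c in config.planted_losses}
    rows = []
    for t in range(config.n_tumors):
        tumor = f"T{t + 1}"
        base = int(rng.choice([2, 3, 4], p=[0.2, 0.6, 0.2]))
        for chrom in AUTOSOMES:
            c = base + int(rng.choice([-1, 0, 1], p=[0.2, 0.6, 0.2]))
            if chrom in gains:
                c += 1
            if chrom in losses:
                c -= 1
            c = max(c, 1)
            if c >= 2 and rng.random() < 0.08:
                minor = 0  # whole-chromosome LOH / UPD
            else:
                minor = min(int(rng.binomial(c, 0.45)), c // 2)
            rows.append((tumor, chrom, c, c - minor, minor))
        x, y = max(1, -(-base // 2)), max(1, base // 2)
        rows.append((tumor, "chrX", x, x, 0))
        rows.append((tumor, "chrY", y, y, 0))
    df = pd.DataFrame(rows, columns=["tumor_id", "chrom", "copy_number", "major", "minor"])
    table = KaryotypeTable(df)
    table.planted_events = [f"gain:{c}" for c in sorted(gains)] + [
        f"loss:{c}" for c in sorted(losses)
    ]
    return table


def _tumor_karyotype(karyotype: KaryotypeTable, tumor_id: str | None) -> pd.DataFrame:
    tumors = karyotype.tumors
    if tumor_id is None:
        tumor_id = tumors[0]
    if tumor_id not in tumors:
        raise KeyError(f"tumor {tumor_id!r} not in karyotype table")
    return karyotype.df[karyotype.df["tumor_id"] == tumor_id]


def _mean_ploidy(kdf: pd.DataFrame, lengths: dict[str, int]) -> float:
    w = np.array([lengths[c] for c in kdf["chrom"]], dtype=float)
    return float(np.average(kdf["copy_number"].astype(float), weights=w))


# ---------------------------------------------------------------------------
# Marker profiles
# ---------------------------------------------------------------------------

def simulate_marker_profile(
    karyotype: KaryotypeTable,
    config: SimulationConfig,
    tumor_id: str | None = None,
) -> MarkerProfile:
    """Tumor/normal read depths and allele counts at SNP markers.

    Markers are assigned to chromosomes proportionally to length. Tumor depth
    at a marker on a chromosome of copy c has mean
    cov_t * (rho*c + 2(1-rho)) / (rho*Psi + 2(1-rho)) with Psi the
    length-weighted mean ploidy; normal depth has mean cov_n. At heterozygous
    markers the alt count is binomial with success probability
    (rho*minor + (1-rho)) / (rho*c + 2(1-rho)). With ``depth_noise=False``
    all draws are replaced by their expectations (noise-free profiles for
    parameter-recovery checks).
    """
    kdf = _tumor_karyotype(karyotype, tumor_id)
    tumor_id = kdf["tumor_id"].iloc[0]
    rng = config.rng(3)
    lengths = chromosome_lengths(config.genome_scale)
    rho = config.purity
    psi = _mean_ploidy(kdf, lengths)
    total_len = sum(lengths[c] for c in kdf["chrom"])
    frames = []
    for _, row in kdf.iterrows():
        chrom, c, minor = row["chrom"], int(row["copy_number"]), row["minor"]
        minor = int(minor) if pd.notna(minor) else c // 2
        n = max(int(round(config.n_markers * lengths[chrom] / total_len)), 10)
        pos = np.sort(rng.choice(np.arange(2, lengths[chrom]), size=min(n, lengths[chrom] - 3), replace=False))
        mean_t = (
            config.mean_coverage_tumor
            * (rho * c + 2 * (1 - rho))
            / (rho * psi + 2 * (1 - rho))
        )
        het = (
            rng.random(len(pos)) < config.het_fraction
            if chrom in AUTOSOMES
            else np.zeros(len(pos), dtype=bool)
        )
        p_alt = (rho * minor + (1 - rho)) / (rho * c + 2 * (1 - rho))
        if config.depth_noise:
            t_depth = rng.poisson(mean_t, size=len(pos))
            n_depth = rng.poisson(config.mean_coverage_normal, size=len(pos))
            alt = np.where(het, rng.binomial(np.maximum(t_depth, 0), p_alt), 0)
        else:
            t_depth = np.full(len(pos), mean_t)
            n_depth = np.full(len(pos), config.mean_coverage_normal)
            alt = np.where(het, t_depth * p_alt, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "tumor_depth": t_depth,
                    "normal_depth": n_depth,
                    "tumor_alt": alt,
                    "tumor_ref": t_depth - alt,
                    "het": het,
                }
            )
        )
    order = {c: i for i, c in enumerate(ALL_CHROMOSOMES)}
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    return MarkerProfile(df.reset_index(drop=True), tumor_id=tumor_id)


# ---------------------------------------------------------------------------
# Somatic variants
# ---------------------------------------------------------------------------

class _TrinucleotideIndex:
    """Positions (1-based, center base) of every trinucleotide per chromosome."""

    def __init__(self, reference: dict[str, str]) -> None:
        self._codes: dict[str, np.ndarray] = {}
        lookup = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate(BASES):
            lookup[ord(b)] = i
        for chrom, seq in reference.items():
            s = lookup[np.frombuffer(seq.encode(), dtype=np.uint8)]
            self._codes[chrom] = s[:-2] * 16 + s[1:-1] * 4 + s[2:]
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    @staticmethod
    def _code(tri: str) -> int:
        return BASES.index(tri[0]) * 16 + BASES.index(tri[1]) * 4 + BASES.index(tri[2])

    def positions(self, chrom: str, tri: str) -> np.ndarray:
        key = (chrom, tri)
        if key not in self._cache:
            self._cache[key] = np.where(self._codes[chrom] == self._code(tri))[0] + 2
        return self._cache[key]


def _revcomp3(tri: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(tri))


def simulate_variants(
    karyotype: KaryotypeTable,
    config: SimulationConfig,
    reference: dict[str, str],
    tumor_id: str | None = None,
    methylation: MethylationSiteSet | None = None,
) -> tuple[CallSet, CallSet, pd.DataFrame]:
    """Somatic SNVs for one tumor as two near-identical call sets plus truth.

    Per-chromosome counts are proportional to copy number times length (so a
    tumor's burden scales with its total chromosome count). Each SNV draws a
    96-bin context from the signature and lands on a matching reference
    trinucleotide (either strand). Timing: with probability
    ``timing_fraction_pre_gain`` the SNV predates the gain and sits on the
    duplicated homolog (multiplicity = major copy), otherwise it is a late
    event with multiplicity 1. The expected VAF follows the mixing formula;
    read counts are binomial at Poisson depth. If a methylation site set is
    given, CpG C>T variants choose methylated CpGs with relative weight
    ``methylation_mutation_multiplier``.

    Both call sets contain every true variant; each caller additionally
    reports its own private (false-positive) calls so that the two-caller
    consensus recovers exactly the truth table.
    """
    kdf = _tumor_karyotype(karyotype, tumor_id)
    tumor_id = kdf["tumor_id"].iloc[0]
    rng = config.rng(4)
    lengths = chromosome_lengths(config.genome_scale)
    missing = [c for c in kdf["chrom"] if c not in reference]
    if missing:
        raise ValueError(f"reference lacks chromosomes {missing}")
    index = _TrinucleotideIndex(reference)
    rho = config.purity
    psi = _mean_ploidy(kdf, lengths)
    meth_flags: dict[tuple[str, int], bool] = {}
    if methylation is not None:
        meth_flags = {
            (r.chrom, int(r.pos)): bool(r.methylated)
            for r in methylation.df.itertuples()
        }

    # per-chromosome expected counts proportional to copy number x length
    weights = kdf["copy_number"].astype(float).to_numpy() * np.array(
        [lengths[c] for c in kdf["chrom"]], dtype=float
    )
    if config.n_variants is not None:
        counts = rng.multinomial(config.n_variants, weights / weights.sum())
    else:
        lam = (
            config.mutation_rate_per_mb
            * np.array([lengths[c] for c in kdf["chrom"]]) / 1e6
            * kdf["copy_number"].to_numpy() / 2.0
        )
        counts = rng.poisson(lam)

    used: set[tuple[str, int]] = set()
    truth_rows = []
    records = []
    for (_, krow), n_chrom in zip(kdf.iterrows(), counts):
        chrom = krow["chrom"]
        c = int(krow["copy_number"])
        major = int(krow["major"]) if pd.notna(krow["major"]) else c - c // 2
        mean_depth = (
            config.mean_coverage_tumor
            * (rho * c + 2 * (1 - rho))
            / (rho * psi + 2 * (1 - rho))
        )
        bins = rng.choice(96, size=n_chrom, p=config.signature)
        for b in bins:
            sub, five, three = BIN_KEYS[b]
            pyr_ref, pyr_alt = sub[0], sub[2]
            tri = five + pyr_ref + three
            is_cpg_ct = sub == "C>T" and three == "G"
            pos, strand = _draw_position(
                rng, index, chrom, tri, used, meth_flags,
                weighted=is_cpg_ct and bool(meth_flags),
                multiplier=config.methylation_mutation_multiplier,
            )
            if pos is None:
                raise ValueError(
                    f"no reference site for context {tri} on {chrom}"
                )
            used.add((chrom, pos))
            if strand == "+":
                ref, alt = pyr_ref, pyr_alt
            else:
                ref, alt = COMPLEMENT[pyr_ref], COMPLEMENT[pyr_alt]
            pre_gain = (
                major >= 2 and rng.random() < config.timing_fraction_pre_gain
            )
            m = major if pre_gain else 1
            evaf = rho * m / (rho * c + 2 * (1 - rho))
            depth = max(int(rng.poisson(mean_depth)), 1)
            alt_count = min(max(int(rng.binomial(depth, evaf)), 1), depth)
            cpg_pos = pos if strand == "+" else pos - 1
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "alt_count": alt_count,
                    "depth": depth,
                    "chrom_copy": c,
                    "multiplicity": m,
                    "timing": "pre_gain" if m >= 2 else "post_gain",
                    "expected_vaf": evaf,
                    "bin": b,
                    "methylated_site": meth_flags.get((chrom, cpg_pos), False),
                }
            )
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    alt_count=alt_count, depth=depth, sample_id=tumor_id,
                )
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "alt_count", "depth", "chrom_copy",
            "multiplicity", "timing", "expected_vaf", "bin", "methylated_site",
        ],
    )
    set_a = CallSet(records, caller_name="callerA", sample_id=tumor_id)
    set_b = CallSet(records, caller_name="callerB", sample_id=tumor_id)
    n_private = int(round(config.caller_private_fraction * len(records)))
    for cs in (set_a, set_b):
        _add_private_calls(cs, n_private, reference, rng, used, tumor_id)
    return set_a, set_b, truth


def _draw_position(
    rng, index, chrom, tri, used, meth_flags, weighted: bool, multiplier: float
):
    """Pick an unused reference position matching ``tri`` on either strand."""
    plus = index.positions(chrom, tri)
    minus = index.positions(chrom, _revcomp3(tri))
    pools = [("+", plus), ("-", minus)]
    if weighted:
        cand_pos = np.concatenate([plus, minus])
        strands = np.array(["+"] * len(plus) + ["-"] * len(minus))
        cpg = np.concatenate([plus, minus - 1])
        w = np.array(
            [multiplier if meth_flags.get((chrom, int(p)), False) else 1.0 for p in cpg]
        )
        if len(cand_pos) == 0:
            return None, None
        for _ in range(20):
            i = rng.choice(len(cand_pos), p=w / w.sum())
            pos = int(cand_pos[i])
            if (chrom, pos) not in used:
                return pos, str(strands[i])
        return None, None
    total = len(plus) + len(minus)
    if total == 0:
        return None, None
    for _ in range(20):
        i = int(rng.integers(total))
        strand, pool = ("+", plus) if i < len(plus) else ("-", minus)
        pos = int(pool[i - len(plus)] if strand == "-" else pool[i])
        if (chrom, pos) not in used:
            return pos, strand
    return None, None


def _add_private_calls(callset, n_private, reference, rng, used, tumor_id):
    chroms = list(reference)
    made = 0
    taken = set(used)
    while made < n_private:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(2, len(reference[chrom]) - 1))
        if (chrom, pos) in taken:
            continue
        ref = reference[chrom][pos - 1].upper()
        alt = rng.choice([b for b in BASES if b != ref])
        depth = max(int(rng.poisson(40)), 1)
        alt_count = min(max(int(rng.binomial(depth, 0.1)), 1), depth)
        callset.add(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=str(alt),
                alt_count=alt_count, depth=depth, sample_id=tumor_id,
            )
        )
        taken.add((chrom, pos))
        made += 1


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    reference: dict[str, str], config: SimulationConfig
) -> MethylationSiteSet:
    """Two-replicate methylated fractions at every CpG site of the reference.

    A ``methylated_fraction`` share of sites is methylated; their replicate
    fractions are drawn above 0.55 (and unmethylated sites below 0.45), so the
    both-replicates > 50% classification recovers the truth exactly.
    """
    rng = config.rng(5)
    frames = []
    for chrom, seq in reference.items():
        s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        cpg = np.where((s[:-1] == ord("C")) & (s[1:] == ord("G")))[0] + 1  # 1-based C
        if config.max_methylation_sites is not None and len(cpg) > 0:
            k = max(
                int(round(config.max_methylation_sites * len(seq)
                          / sum(len(v) for v in reference.values()))),
                1,
            )
            if k < len(cpg):
                cpg = np.sort(rng.choice(cpg, size=k, replace=False))
        methylated = rng.random(len(cpg)) < config.methylated_fraction
        rep1 = np.where(methylated, rng.uniform(0.55, 1.0, len(cpg)),
                        rng.uniform(0.0, 0.45, len(cpg)))
        rep2 = np.where(methylated, rng.uniform(0.55, 1.0, len(cpg)),
                        rng.uniform(0.0, 0.45, len(cpg)))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": cpg,
                    "rep1_fraction": rep1,
                    "rep2_fraction": rep2,
                }
            )
        )
    return MethylationSiteSet(pd.concat(frames, ignore_index=True))
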