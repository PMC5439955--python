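"""Copy-number, zygosity, LOH and purity inference from marker profiles.

The model: a tumor of purity rho (fraction of tumor cells) mixed with
2-copy normal tissue yields, at a marker on a chromosome present in c copies
with a minor-allele count m,

    expected depth ratio  mu_c     = h * (rho*c + 2*(1-rho))
    expected folded BAF   beta_c,m = (rho*m + (1-rho)) / (rho*c + 2*(1-rho))

where h (the "haploid ratio unit") converts one tumor copy into depth-ratio
units. Purity and h are found by a grid search scoring the per-chromosome
median smoothed ratio and median folded BAF against their nearest
integer-copy expectations, measured in copy-number units.

Aliasing: marker means cannot always distinguish a contaminated genome from
a purer genome with uniformly higher copies (e.g. rho=0.5 with copies c is
mean-identical to rho=1 with copies c+2). Candidate solutions that force
whole-chromosome nullisomy are heavily penalized, and near-ties are broken
toward the lowest mean ploidy, then toward the highest purity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ChromosomeCall, MarkerProfile, PurityPloidyEstimate

MIN_MARKERS = 1500  # minimum evidence for a whole-chromosome or segment call


def moving_average_ratio(
    profile: MarkerProfile, window: int = 500, column: str = "ratio"
) -> pd.Series:
    """Centered moving average of the depth ratio, computed per chromosome.

    Windows never span chromosome boundaries; edges use shrunken windows.
    Returns a series aligned with ``profile.df``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    profile.sorted_check()
    out = profile.df.groupby("chrom", sort=False)[column].transform(
        lambda s: s.rolling(window, center=True, min_periods=1).mean()
    )
    out.name = "smoothed_ratio"
    return out


def _expected_ratio(copy: np.ndarray | float, purity: float, h: float):
    return h * (purity * np.asarray(copy, dtype=float) + 2.0 * (1.0 - purity))


def _expected_baf(copy: int, minor: int, purity: float) -> float:
    return (purity * minor + (1.0 - purity)) / (purity * copy + 2.0 * (1.0 - purity))


def _chromosome_stats(profile: MarkerProfile, window: int = 500) -> pd.DataFrame:
    """Per-chromosome median smoothed ratio, median folded BAF, marker count."""
    df = profile.df.copy()
    df["smoothed"] = moving_average_ratio(profile, window=window)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        baf = sub["baf"].dropna()
        rows.append(
            {
                "chrom": chrom,
                "median_ratio": sub["smoothed"].median(),
                "median_baf": baf.median() if len(baf) else np.nan,
                "n_markers": len(sub),
            }
        )
    return pd.DataFrame(rows)


MAX_COPY = 12


def _score_candidate(
    stats_df: pd.DataFrame, purity: float, h: float, nullisomy_penalty: float = 25.0
) -> tuple[float, float]:
    """Score a (purity, h) grid point; returns (score, mean ploidy).

    Residuals are expressed in copy-number units so depth and BAF terms are
    commensurate; each chromosome is weighted by its marker count. A
    whole-chromosome assignment of zero copies incurs a flat penalty
    (nullisomy is not a plausible whole-genome explanation).
    """
    copies = np.arange(0, MAX_COPY + 1)
    mu = _expected_ratio(copies, purity, h)
    score = 0.0
    total_weight = 0.0
    weighted_copy = 0.0
    for _, row in stats_df.iterrows():
        r, b, n = row["median_ratio"], row["median_baf"], row["n_markers"]
        if not np.isfinite(r):
            continue
        resid_r = (r - mu) / (h * purity)  # residual in copy units
        c = int(copies[np.argmin(np.abs(resid_r))])
        term = resid_r[np.argmin(np.abs(resid_r))] ** 2
        if c == 0:
            term += nullisomy_penalty
        if np.isfinite(b) and c >= 1:
            denom = purity * c + 2.0 * (1.0 - purity)
            betas = np.array(
                [_expected_baf(c, m, purity) for m in range(0, c // 2 + 1)]
            )
            resid_b = (b - betas) * denom / purity  # minor-copy units
            term += np.min(resid_b**2)
        w = float(n)
        score += w * term
        total_weight += w
        weighted_copy += w * c
    if total_weight == 0:
        return np.inf, np.nan
    return score / total_weight, weighted_copy / total_weight


def estimate_purity_ploidy(
    profile: MarkerProfile,
    window: int = 500,
    purity_grid: np.ndarray | None = None,
    max_anchor_copy: int = 8,
) -> PurityPloidyEstimate:
    """Grid search over (purity, haploid coverage) fitting ratios and BAFs.

    Candidate haploid units are generated by anchoring the median chromosome
    ratio at each integer copy number; near-tied scores are resolved toward
    the lowest mean ploidy and then the highest purity. Genomes with a single
    copy-number state are flagged low-confidence.
    """
    if purity_grid is None:
        purity_grid = np.round(np.arange(0.30, 1.0001, 0.0125), 4)
    stats_df = _chromosome_stats(profile, window=window)
    r_med = stats_df["median_ratio"].median()
    if not np.isfinite(r_med) or r_med <= 0:
        raise ValueError("no usable depth ratios in profile")
    candidates = []
    for purity in purity_grid:
        for anchor in range(1, max_anchor_copy + 1):
            h = r_med / (purity * anchor + 2.0 * (1.0 - purity))
            score, ploidy = _score_candidate(stats_df, purity, h)
            candidates.append((score, ploidy, purity, h))
    best_score = min(c[0] for c in candidates)
    # Near-ties (exact mean-level aliases plus sampling noise) are resolved by
    # parsimony: lowest mean ploidy first, then best score, then purity.
    eps = 0.005 * (1.0 + best_score)
    near = [c for c in candidates if c[0] <= best_score + eps]
    near.sort(key=lambda c: (round(c[1], 1), c[0], -c[2]))
    _, ploidy, purity, h = near[0]
    # haploid coverage in read units: one copy unit's worth of tumor reads
    median_normal = float(profile.df["normal_depth"].median())
    haploid_coverage = h * median_normal
    calls = _assign_copies(stats_df, purity, h)
    low_confidence = len(set(calls)) < 2
    return PurityPloidyEstimate(
        purity=float(purity),
        haploid_coverage=float(haploid_coverage),
        mean_ploidy=float(ploidy),
        low_confidence=bool(low_confidence),
    )


def _assign_copies(stats_df: pd.DataFrame, purity: float, h: float) -> list[int]:
    copies = np.arange(0, MAX_COPY + 1)
    mu = _expected_ratio(copies, purity, h)
    out = []
    for r in stats_df["median_ratio"]:
        if not np.isfinite(r):
            out.append(-1)
        else:
            out.append(int(copies[np.argmin(np.abs(r - mu))]))
    return out


def _fractional_copy(ratio, purity: float, h: float):
    return (np.asarray(ratio, dtype=float) / h - 2.0 * (1.0 - purity)) / purity


def call_chromosomes(
    profile: MarkerProfile,
    estimate: PurityPloidyEstimate,
    window: int = 500,
    min_markers: int = MIN_MARKERS,
) -> list[ChromosomeCall]:
    """Per-chromosome integer copy number and (major, minor) decomposition.

    The copy number is the nearest integer to the purity-corrected median
    smoothed ratio, with exact half-integer ties broken toward the
    genome-wide modal ploidy. The minor allele count minimizes the distance
    between the median folded BAF and its expectation. Chromosomes supported
    by ``min_markers`` markers or fewer are suppressed. Runs of at least
    ``min_markers`` consecutive markers whose integer copy differs from the
    chromosome call become arm events.
    """
    purity = estimate.purity
    median_normal = float(profile.df["normal_depth"].median())
    h = estimate.haploid_coverage / median_normal
    df = profile.df.copy()
    df["smoothed"] = moving_average_ratio(profile, window=window)
    stats_df = _chromosome_stats(profile, window=window)
    frac = _fractional_copy(stats_df["median_ratio"].to_numpy(), purity, h)
    modal_copy = int(
        pd.Series(np.round(frac[np.isfinite(frac)]).astype(int)).mode().iloc[0]
    )
    calls: list[ChromosomeCall] = []
    for (_, row), f in zip(stats_df.iterrows(), frac):
        chrom, n = row["chrom"], int(row["n_markers"])
        if not np.isfinite(f) or n <= min_markers:
            calls.append(
                ChromosomeCall(
                    chrom=chrom, copy_number=0, major=0, minor=0,
                    n_markers=n, suppressed=True,
                )
            )
            continue
        lo = int(np.floor(f))
        if abs(f - lo - 0.5) < 1e-9:  # exact tie: toward modal ploidy
            c = lo if abs(lo - modal_copy) <= abs(lo + 1 - modal_copy) else lo + 1
        else:
            c = int(np.round(f))
        c = max(c, 0)
        b = row["median_baf"]
        if c >= 1 and np.isfinite(b):
            minors = np.arange(0, c // 2 + 1)
            betas = np.array([_expected_baf(c, m, purity) for m in minors])
            minor = int(minors[np.argmin(np.abs(b - betas))])
        else:
            minor = c // 2
        sub = df[df["chrom"] == chrom]
        arm_events = _arm_events(sub, c, purity, h, min_markers)
        calls.append(
            ChromosomeCall(
                chrom=chrom, copy_number=c, major=c - minor, minor=minor,
                n_markers=n, arm_events=arm_events,
            )
        )
    return calls


def _arm_events(
    sub: pd.DataFrame, chrom_copy: int, purity: float, h: float, min_markers: int
) -> list[tuple[int, int, int]]:
    """Runs of >= min_markers markers at a copy differing from the call."""
    frac = _fractional_copy(sub["smoothed"].to_numpy(), purity, h)
    per_marker = np.round(frac).astype(int)
    per_marker = np.clip(per_marker, 0, MAX_COPY)
    pos = sub["pos"].to_numpy()
    events = []
    i = 0
    n = len(per_marker)
    while i < n:
        c = per_marker[i]
        j = i
        while j < n and per_marker[j] == c:
            j += 1
        if c != chrom_copy and (j - i) >= min_markers:
            events.append((int(pos[i]), int(pos[j - 1]), int(c)))
        i = j
    return events


def singleton_profile(
    tumor_profile: MarkerProfile,
    expected_diploid_coverage: float | None = None,
    window: int = 500,
) -> pd.Series:
    """Smoothed ratio for a tumor without a matched normal.

    The ratio is taken against a constant diploid baseline (supplied, or the
    modal tumor coverage); zero-coverage markers are masked. A ratio of 1.0
    corresponds to two copies, so downstream calling is unchanged.
    """
    df = tumor_profile.df
    if expected_diploid_coverage is None:
        depths = df.loc[df["tumor_depth"] > 0, "tumor_depth"]
        expected_diploid_coverage = float(depths.mode().iloc[0])
    if expected_diploid_coverage <= 0:
        raise ValueError("baseline coverage must be positive")
    ratio = np.where(
        df["tumor_depth"] > 0, df["tumor_depth"] / expected_diploid_coverage, np.nan
    )
    shim = MarkerProfile(
        df.assign(normal_depth=1, tumor_depth=df["tumor_depth"])[MarkerProfile.COLUMNS],
        tumor_id=tumor_profile.tumor_id,
    )
    shim.df["ratio"] = ratio
    return moving_average_ratio(shim, window=window)


def exon_ratio_screen(
    exon_table: pd.DataFrame,
    estimate: PurityPloidyEstimate,
    chromosome_calls: list[ChromosomeCall],
    median_normal_depth: float | None = None,
) -> pd.DataFrame:
    """Exons whose depth ratio deviates from the chromosome-level expectation
    by strictly more than one haploid copy unit.

    ``exon_table`` columns: chrom, start, end, tumor_mean, normal_mean.
    """
    calls = {c.chrom: c for c in chromosome_calls if not c.suppressed}
    if median_normal_depth is None:
        median_normal_depth = float(exon_table["normal_mean"].median())
    h = estimate.haploid_coverage / median_normal_depth
    purity = estimate.purity
    rows = []
    for _, row in exon_table.iterrows():
        call = calls.get(row["chrom"])
        if call is None or row["normal_mean"] <= 0:
            continue
        ratio = row["tumor_mean"] / row["normal_mean"]
        implied = _fractional_copy(ratio, purity, h)
        deviation = float(implied - call.copy_number)
        if abs(deviation) > 1.0:
            rows.append(
                {
                    "chrom": row["chrom"],
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "implied_copy": float(implied),
                    "expected_copy": call.copy_number,
                    "deviation": deviation,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "implied_copy", "expected_copy", "deviation"]
    )
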