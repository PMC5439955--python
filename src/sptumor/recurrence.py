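"""Permutation test for recurrent whole-chromosome gains and losses.

Each tumor's 22 autosome copy numbers are shuffled independently, preserving
the tumor's own ploidy multiset. For every chromosome the cross-tumor sum of
the permuted values is compared with the observed sum under strict
inequalities: a permutation contributes to the gain tail only when its null
sum strictly exceeds the observed sum, and to the loss tail only when it is
strictly below. Ties count toward neither tail and no pseudo-count is added,
so an empirical p-value of zero is representable (reported as, e.g.,
"< 1e-05" at 100,000 permutations). Gain and loss p-values are each adjusted
with Benjamini-Hochberg across the 22 autosomes. Sex chromosomes never enter
the test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import AUTOSOMES, KaryotypeTable

_MAX_ENUMERABLE = 10_000_000


@dataclass
class RecurrenceResult:
    """Per-chromosome, per-direction recurrence statistics."""

    table: pd.DataFrame  # chrom, direction, observed_sum, raw_p, adj_p
    n_permutations: int
    degenerate: bool = False

    def adjusted_p(self, chrom: str, direction: str) -> float:
        sel = (self.table["chrom"] == chrom) & (self.table["direction"] == direction)
        if not sel.any():
            raise KeyError(f"no result for {chrom} {direction}")
        return float(self.table.loc[sel, "adj_p"].iloc[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _result_from_counts(
    gain_counts: np.ndarray,
    loss_counts: np.ndarray,
    observed: np.ndarray,
    chroms: list[str],
    total: int,
    degenerate: bool,
) -> RecurrenceResult:
    gain_p = gain_counts / total
    loss_p = loss_counts / total
    gain_adj = bh_adjust(gain_p)
    loss_adj = bh_adjust(loss_p)
    rows = []
    for i, chrom in enumerate(chroms):
        rows.append((chrom, "gain", int(observed[i]), gain_p[i], gain_adj[i]))
        rows.append((chrom, "loss", int(observed[i]), loss_p[i], loss_adj[i]))
    table = pd.DataFrame(
        rows, columns=["chrom", "direction", "observed_sum", "raw_p", "adj_p"]
    )
    return RecurrenceResult(table=table, n_permutations=total, degenerate=degenerate)


def _matrix(karyotypes) -> tuple[np.ndarray, list[str]]:
    """Coerce input to a tumors x chromosomes integer matrix.

    Accepts a :class:`KaryotypeTable` (autosomes chr1..chr22, X/Y excluded),
    a tumors x chromosomes DataFrame, or a plain 2-D array (small synthetic
    instances for the enumeration oracle).
    """
    if isinstance(karyotypes, KaryotypeTable):
        mat = karyotypes.autosome_matrix()
        return mat.to_numpy(dtype=np.int64), list(mat.columns)
    if isinstance(karyotypes, pd.DataFrame):
        return karyotypes.to_numpy(dtype=np.int64), [str(c) for c in karyotypes.columns]
    arr = np.asarray(karyotypes, dtype=np.int64)
    if arr.ndim != 2:
        raise ValueError("copy-number matrix must be 2-D (tumors x chromosomes)")
    return arr, [f"chr{i + 1}" for i in range(arr.shape[1])]


def permutation_test(
    karyotypes: KaryotypeTable,
    n_permutations: int = 100_000,
    seed: int | np.random.Generator | None = None,
    strategy: str = "within_tumor",
    chunk_size: int = 50_000,
) -> RecurrenceResult:
    """Monte-Carlo permutation test for recurrent gains and losses.

    ``strategy='within_tumor'`` (default) shuffles each tumor's autosome
    values independently; ``'pooled'`` permutes all values across the whole
    tumor-by-chromosome matrix, destroying per-tumor ploidy structure (kept
    only for comparison).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if strategy not in ("within_tumor", "pooled"):
        raise ValueError(f"unknown strategy {strategy!r}")
    mat, chroms = _matrix(karyotypes)
    if mat.shape[0] < 2:
        raise ValueError("permutation test requires at least 2 tumors")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = mat.sum(axis=0)
    n_chrom = mat.shape[1]
    gain_counts = np.zeros(n_chrom, dtype=np.int64)
    loss_counts = np.zeros(n_chrom, dtype=np.int64)
    remaining = n_permutations
    while remaining > 0:
        m = min(chunk_size, remaining)
        if strategy == "within_tumor":
            null_sums = np.zeros((m, n_chrom), dtype=np.int64)
            for row in mat:
                null_sums += rng.permuted(np.tile(row, (m, 1)), axis=1)
        else:
            flat = np.tile(mat.ravel(), (m, 1))
            null_sums = (
                rng.permuted(flat, axis=1)
                .reshape(m, mat.shape[0], n_chrom)
                .sum(axis=1)
            )
        gain_counts += (null_sums > observed).sum(axis=0)
        loss_counts += (null_sums < observed).sum(axis=0)
        remaining -= m
    degenerate = bool(np.all(mat == mat[:, :1]))
    return _result_from_counts(
        gain_counts, loss_counts, observed, chroms, n_permutations, degenerate
    )


def exhaustive_recurrence(karyotypes: KaryotypeTable) -> RecurrenceResult:
    """Exact p-values by full enumeration of within-tumor permutations.

    Only feasible on small instances; intended as the testing oracle for the
    Monte-Carlo path.
    """
    mat, chroms = _matrix(karyotypes)
    n_tumors, n_chrom = mat.shape
    total = math.factorial(n_chrom) ** n_tumors
    if total > _MAX_ENUMERABLE:
        raise ValueError(
            f"{total} permutations exceed the enumeration limit; "
            "use permutation_test for Monte-Carlo estimation"
        )
    observed = mat.sum(axis=0)
    gain_counts = np.zeros(n_chrom, dtype=np.int64)
    loss_counts = np.zeros(n_chrom, dtype=np.int64)
    for arrangement in itertools.product(
        *(itertools.permutations(row) for row in mat)
    ):
        s = np.sum(arrangement, axis=0)
        gain_counts += s > observed
        loss_counts += s < observed
    degenerate = bool(np.all(mat == mat[:, :1]))
    return _result_from_counts(
        gain_counts, loss_counts, observed, chroms, total, degenerate
    )
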