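"""CpG methylation classification and mutation-enrichment testing.

A CpG site is methylated when more than 50% of reads are methylated in both
replicates (strict inequality; sites present in only one replicate are
dropped). Somatic variants are overlapped with retained sites — either CpG
strand position maps to the plus-strand C — and the enrichment of mutations
at methylated sites is scored with an upper-tail binomial test
P(X >= q), X ~ Binomial(n, p), where q is the number of methylated overlapping
variants, n the total overlapping variants, and p the background methylated
fraction of the site set.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .core import CallSet, EnrichmentResult, MethylationSiteSet


def classify_methylation(raw: pd.DataFrame) -> MethylationSiteSet:
    """Build a site set from a raw two-replicate table.

    ``raw`` columns: chrom, pos (1-based), rep1_fraction, rep2_fraction.
    Sites missing either replicate are dropped and counted in ``n_dropped``.
    """
    return MethylationSiteSet(raw)


def overlap_variants(
    variants: CallSet, sites: MethylationSiteSet
) -> tuple[int, int]:
    """Count variants at retained CpG sites: returns (q methylated, n total).

    A variant at the C of a CpG matches directly; one at the G (the reverse
    strand of the same dinucleotide) maps to the site one base upstream.
    """
    flags = {
        (r.chrom, int(r.pos)): bool(r.methylated) for r in sites.df.itertuples()
    }
    q = n = 0
    for rec in variants:
        if not rec.is_snv:
            continue
        hit = None
        if (rec.chrom, rec.pos) in flags:
            hit = (rec.chrom, rec.pos)
        elif rec.ref in "GA" and (rec.chrom, rec.pos - 1) in flags:
            hit = (rec.chrom, rec.pos - 1)
        if hit is not None:
            n += 1
            q += flags[hit]
    return q, n


def binomial_enrichment(q: int, n: int, p: float) -> EnrichmentResult:
    """Upper-tail binomial probability P(X >= q) for X ~ Binomial(n, p)."""
    if not (0 <= q <= n):
        raise ValueError("require 0 <= q <= n")
    if not (0 <= p <= 1):
        raise ValueError("require 0 <= p <= 1")
    p_value = float(stats.binom.sf(q - 1, n, p)) if n > 0 else 1.0
    if q == 0:
        p_value = 1.0
    return EnrichmentResult(q=q, n=n, p=p, p_value=min(p_value, 1.0))


def enrichment_from_data(
    variants: CallSet, sites: MethylationSiteSet
) -> EnrichmentResult:
    """End-to-end: overlap variants with sites and test enrichment against
    the site set's own methylated fraction."""
    q, n = overlap_variants(variants, sites)
    return binomial_enrichment(q, n, sites.methylated_fraction)
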