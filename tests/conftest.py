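"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's interval algebra: they
paint per-base bitmaps on toy genomes, or sum exact rational
probabilities, so the fast implementations can be checked against them.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from mircnv import GenomicInterval, paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture(scope="session")
def all_table1_calls(fixtures):
    from mircnv import call_cnv_mirnas

    smc = call_cnv_mirnas(fixtures.smc_loci, list(fixtures.smc_regions))
    dc = call_cnv_mirnas(fixtures.dc_loci, list(fixtures.dc_regions))
    return smc, dc


# --- bitmap oracles --------------------------------------------------------

def bitmap_union_bp(intervals, chrom_lengths: dict[str, int]) -> int:
    """Per-base union size by painting boolean masks."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return int(sum(m.sum() for m in masks.values()))


def bitmap_depth(intervals, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base record depth."""
    depth = {c: np.zeros(l, dtype=int) for c, l in chrom_lengths.items()}
    for iv in intervals:
        depth[iv.chrom][iv.start : iv.end] += 1
    return depth


def bitmap_overlap_bp(a: GenomicInterval, b: GenomicInterval, chrom_len: int) -> int:
    """Per-base membership count over both spans."""
    if a.chrom != b.chrom:
        return 0
    ma = np.zeros(chrom_len, dtype=bool)
    mb = np.zeros(chrom_len, dtype=bool)
    ma[a.start : a.end] = True
    mb[b.start : b.end] = True
    return int((ma & mb).sum())


def random_intervals(rng, n, chrom_lengths: dict[str, int], max_len=2_000):
    """Uniform random toy intervals for oracle-equivalence checks."""
    chroms = list(chrom_lengths)
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        length = min(length, chrom_lengths[c])
        start = int(rng.integers(0, chrom_lengths[c] - length + 1))
        out.append(GenomicInterval(c, start, start + length))
    return out


# --- exact probability oracles ---------------------------------------------

def binom_cdf_fraction(k: int, n: int, p: float) -> float:
    """Exact rational lower-tail binomial CDF."""
    if k >= n:
        return 1.0
    fp = Fraction(p)
    total = sum(
        comb(n, i) * fp**i * (1 - fp) ** (n - i) for i in range(k + 1)
    )
    return float(total)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher probability by enumerating all tables with the
    observed margins and summing those no more probable than observed."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(x: int) -> Fraction:
        return Fraction(comb(c1, x) * comb(n - c1, r1 - x), comb(n, r1))

    p_obs = pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs)
    return float(total)
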