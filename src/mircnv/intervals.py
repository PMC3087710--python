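"""Genomic interval algebra.

All coordinates are stored 0-based, half-open (``start`` inclusive,
``end`` exclusive).  Printed/serialized coordinates follow the 1-based
inclusive browser dialect (``chrN:a-b``), so a printed span ``a-b`` has
length ``b - a + 1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GenomeModel",
    "MITOCHONDRIAL",
    "normalize_chrom",
    "parse_region",
    "overlap_bp",
    "merge",
    "total_bp",
    "intersect_all",
    "flank_distances",
]

#: Canonical label for the mitochondrial chromosome.
MITOCHONDRIAL = "chrM"

_MITO_ALIASES = {"chrM", "chrMT", "M", "MT"}

_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>-?\d+)-(?P<end>-?\d+)$")


class RegionParseError(ValueError):
    """Raised when a printed region string cannot be parsed."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome label; mitochondrial aliases collapse to ``chrM``."""
    name = name.strip()
    if name in _MITO_ALIASES:
        return MITOCHONDRIAL
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored coordinate span (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos < self.end

    def region_string(self) -> str:
        """Serialize in the 1-based inclusive printed dialect."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.region_string()


def parse_region(text: str) -> GenomicInterval:
    """Parse a printed ``chrom:start-end`` region (1-based, inclusive).

    >>> parse_region("chrX:76056092-76056179").length
    88
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    chrom = normalize_chrom(m.group("chrom"))
    start1 = int(m.group("start"))
    end1 = int(m.group("end"))
    if start1 <= 0:
        raise RegionParseError(f"non-positive start coordinate in {text!r}: {start1}")
    if end1 <= 0:
        raise RegionParseError(f"non-positive end coordinate in {text!r}: {end1}")
    if start1 > end1:
        raise RegionParseError(f"start exceeds end in {text!r}: {start1} > {end1}")
    return GenomicInterval(chrom, start1 - 1, end1)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if disjoint or trans-chromosomal)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse intervals into a disjoint, sorted union.

    Output is sorted by (chrom, start); adjacent-but-touching intervals
    are fused so no two outputs share or abut a base on the same
    chromosome boundary-to-boundary only when they actually overlap or
    touch (``[0,10)`` and ``[10,20)`` fuse to ``[0,20)``).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Sum of interval lengths (callers merge first when overlap is possible)."""
    return sum(iv.length for iv in intervals)


def intersect_all(intervals: Sequence[GenomicInterval]) -> GenomicInterval | None:
    """Common span of all intervals, or None when they share no base.

    All intervals must lie on one chromosome.
    """
    if not intervals:
        raise ValueError("intersect_all requires a non-empty collection")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intersect_all over mixed chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start >= end:
        return None
    return GenomicInterval(intervals[0].chrom, start, end)


def flank_distances(
    feature: GenomicInterval, region: GenomicInterval
) -> tuple[int, int]:
    """Distances from a contained feature to its region's boundaries.

    Returns ``(left, right)`` with ``left + right + feature.length ==
    region.length``.  Raises if the region does not fully contain the
    feature — partial overlaps must be handled by the caller.
    """
    if not region.contains(feature):
        raise ValueError(
            f"feature {feature.region_string()} not fully contained in "
            f"region {region.region_string()}"
        )
    return feature.start - region.start, region.end - feature.end


@dataclass
class GenomeModel:
    """Ordered chromosome sizes plus a set of excluded chromosomes.

    ``effective_bp`` (the denominator of every genome-fraction
    computation) excludes the excluded chromosomes — by default the
    mitochondrial genome.
    """

    chromosomes: list[tuple[str, int]]
    excluded: set[str] = field(default_factory=lambda: {MITOCHONDRIAL})

    def __post_init__(self) -> None:
        names = [normalize_chrom(n) for n, _ in self.chromosomes]
        lengths = [int(l) for _, l in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome model")
        for n, l in zip(names, lengths):
            if l <= 0:
                raise ValueError(f"non-positive length for chromosome {n}: {l}")
        self.chromosomes = list(zip(names, lengths))
        self.excluded = {normalize_chrom(n) for n in self.excluded}
        self._sizes = dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @property
    def effective_bp(self) -> int:
        return sum(l for n, l in self.chromosomes if n not in self.excluded)

    def length_of(self, chrom: str) -> int:
        try:
            return self._sizes[normalize_chrom(chrom)]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome model") from None

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._sizes

    def validate_interval(self, iv: GenomicInterval) -> None:
        """Raise if the interval exceeds its chromosome bounds."""
        if iv.chrom not in self._sizes:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome model")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.region_string()} exceeds {iv.chrom} length "
                f"{self._sizes[iv.chrom]}"
            )
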