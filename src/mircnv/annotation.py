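"""CNV-miRNA call production and classification.

A call pairs one miRNA locus identity with one CNV set: the locus must
share at least one base with the merged set.  Calls carry overlap
geometry (containment, flank distances), the minimal region supported by
every overlapping record, a copy-number summary from genotypes, a flank
class and (when a gene sketch is available) a predicted dosage effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .intervals import GenomicInterval, flank_distances, intersect_all, merge, overlap_bp
from .io import CnvRegion, MirnaLocus

logger = logging.getLogger("mircnv")

__all__ = [
    "CnvMirnaCall",
    "GeneModelSketch",
    "CopyNumberSummary",
    "call_cnv_mirnas",
    "dedupe_loci",
    "minimal_region",
    "copy_number_summary",
    "is_multiallelic",
    "classify_flanks",
    "classify_dosage",
    "disease_region_overlap",
]

FLANK_SHORT_BP = 5_000
FLANK_LARGE_BP = 20_000


@dataclass(frozen=True)
class CnvMirnaCall:
    """One (miRNA locus x CNV set) co-localization result."""

    locus: MirnaLocus
    region: CnvRegion
    overlap_bp: int
    fully_contained: bool
    flanks: tuple[int, int] | None = None
    minimal_region: GenomicInterval | None = None
    minimal_contains_locus: bool = True
    n_supporting_records: int = 1
    copy_range: tuple[int, int] | None = None
    multiallelic: bool | None = None
    flank_class: str | None = None
    dosage_effect: str | None = None

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("a call requires overlap_bp >= 1")
        if self.fully_contained:
            if self.flanks is None:
                raise ValueError("contained call must carry flank distances")
            if self.overlap_bp != self.locus.interval.length:
                raise ValueError("contained call must overlap the full locus")
        if self.copy_range is not None and self.copy_range[0] > self.copy_range[1]:
            raise ValueError(f"inverted copy range {self.copy_range}")


@dataclass(frozen=True)
class GeneModelSketch:
    """Minimal gene architecture for dosage prediction: a transcript
    span, the promoter/TSS anchor at its 5' boundary, and the pre-miRNA
    hairpin inside the span."""

    transcript: GenomicInterval
    hairpin: GenomicInterval
    promoter_pos: int | None = None  # 0-based; defaults to transcript start

    def __post_init__(self) -> None:
        if not self.transcript.contains(self.hairpin):
            raise ValueError("hairpin must lie inside the transcript span")
        if self.promoter_pos is None:
            object.__setattr__(self, "promoter_pos", self.transcript.start)
        if not (self.transcript.start <= self.promoter_pos < self.transcript.end):
            raise ValueError("promoter anchor must lie at/within the transcript span")


@dataclass(frozen=True)
class CopyNumberSummary:
    copy_min: int
    copy_max: int
    multiallelic_calls: tuple[bool, ...]
    n_with_genotypes: int


def is_multiallelic(genotypes: Sequence[int]) -> bool:
    """More than a simple two-allele deletion/duplication signature:
    at least two copy numbers strictly above 2, or more than 3 states."""
    states = set(genotypes)
    return sum(1 for g in states if g > 2) >= 2 or len(states) > 3


def minimal_region(
    locus: MirnaLocus, overlapping_records: Sequence[CnvRegion | GenomicInterval]
) -> tuple[GenomicInterval | None, int, bool]:
    """Narrowest segment supported by every record overlapping the locus.

    Returns (interval, n_records, contains_locus).  The interval is the
    base-wise intersection of all records; when the records do not all
    contain the locus the intersection may exclude part of it (flagged
    via ``contains_locus``), and when two records share no base at all
    the interval is None.
    """
    if not overlapping_records:
        raise ValueError("minimal_region requires at least one record")
    ivs = [r.interval if isinstance(r, CnvRegion) else r for r in overlapping_records]
    for iv in ivs:
        if overlap_bp(iv, locus.interval) < 1:
            raise ValueError(
                f"record {iv.region_string()} does not overlap locus "
                f"{locus.interval.region_string()}"
            )
    inter = intersect_all(ivs)
    contains = inter is not None and inter.contains(locus.interval)
    return inter, len(ivs), contains


def classify_flanks(
    call: CnvMirnaCall,
    short_bp: int = FLANK_SHORT_BP,
    large_bp: int = FLANK_LARGE_BP,
) -> str:
    """Flank geometry class of a call.

    ``short_both`` — both flanks < ``short_bp``; ``large_both`` — both
    >= ``large_bp``; ``partial_overlap`` — locus not fully contained;
    anything else ``mixed``.
    """
    if not call.fully_contained or call.flanks is None:
        return "partial_overlap"
    left, right = call.flanks
    if left < short_bp and right < short_bp:
        return "short_both"
    if left >= large_bp and right >= large_bp:
        return "large_both"
    return "mixed"


def classify_dosage(
    gene: GeneModelSketch, cnv_interval: GenomicInterval, cnv_kind: str
) -> str:
    """Predicted miRNA dosage effect of a CNV on a sketched gene.

    Deletions: removing any part of the hairpin, or the promoter anchor,
    lowers dosage; a purely 3' deletion downstream of the hairpin leaves
    a truncated transcript whose fate is indeterminate; an intragenic
    deletion sparing both hairpin and promoter changes nothing.

    Tandem duplications: increase dosage when the duplicated segment
    carries the whole hairpin and either carries the promoter too or
    lies wholly inside the transcript (extra hairpin copies in one
    primary transcript); otherwise no change.
    """
    if cnv_kind not in {"deletion", "duplication"}:
        raise ValueError(f"unknown CNV kind {cnv_kind!r}")
    if overlap_bp(cnv_interval, gene.transcript) < 1:
        raise ValueError("CNV does not overlap the gene span")

    hits_hairpin = overlap_bp(cnv_interval, gene.hairpin) >= 1
    contains_hairpin = cnv_interval.contains(gene.hairpin)
    covers_promoter = cnv_interval.contains_pos(gene.promoter_pos)
    inside_transcript = gene.transcript.contains(cnv_interval)

    if cnv_kind == "deletion":
        if hits_hairpin:
            return "decrease"
        if covers_promoter:
            return "decrease"  # no promoter, no transcript
        if cnv_interval.start >= gene.hairpin.end:
            return "indeterminate"  # 3'-truncated transcript, fate unknown
        return "none"

    if contains_hairpin and (covers_promoter or inside_transcript):
        return "increase"
    return "none"


def _summarize_copy_range(region: CnvRegion) -> tuple[tuple[int, int] | None, bool | None]:
    if not region.genotypes:
        return None, None
    return (min(region.genotypes), max(region.genotypes)), is_multiallelic(region.genotypes)


def call_cnv_mirnas(
    loci: Iterable[MirnaLocus],
    regions: Sequence[CnvRegion],
    set_label: str | None = None,
    min_overlap_bp: int = 1,
    classify: bool = True,
) -> list[CnvMirnaCall]:
    """Produce one call per (distinct locus identity, region set).

    Overlap is evaluated against the merged region set; the call's
    carrier region is the single input region with the largest overlap
    (ties broken by coordinate).  Ordering is deterministic: calls are
    sorted by (chrom, start, id).
    """
    if set_label is not None:
        regions = [replace(r, set_label=set_label) for r in regions]
    merged = merge(r.interval for r in regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    seen: set = set()
    calls: list[CnvMirnaCall] = []
    for locus in sorted(loci, key=lambda l: (l.interval.chrom, l.interval.start, l.id)):
        if locus.identity in seen:
            continue
        seen.add(locus.identity)
        fiv = locus.interval
        union_ov = sum(
            max(0, min(fiv.end, m.end) - max(fiv.start, m.start))
            for m in by_chrom.get(fiv.chrom, ())
        )
        if union_ov < min_overlap_bp:
            continue
        hits = [r for r in regions if overlap_bp(r.interval, fiv) >= 1]
        carrier = max(
            hits,
            key=lambda r: (
                overlap_bp(r.interval, fiv),
                -r.interval.length,
                -r.interval.start,
            ),
        )
        contained = carrier.interval.contains(fiv)
        flanks = flank_distances(fiv, carrier.interval) if contained else None
        min_iv, n_rec, min_contains = minimal_region(locus, hits)
        copy_range, multi = _summarize_copy_range(carrier)
        call = CnvMirnaCall(
            locus=locus,
            region=carrier,
            overlap_bp=union_ov if contained is False else fiv.length,
            fully_contained=contained,
            flanks=flanks,
            minimal_region=min_iv,
            minimal_contains_locus=min_contains,
            n_supporting_records=n_rec,
            copy_range=copy_range,
            multiallelic=multi,
        )
        if classify:
            call = replace(call, flank_class=classify_flanks(call))
        calls.append(call)
    return calls


def dedupe_loci(calls: Iterable[CnvMirnaCall]) -> list[tuple[str, str, int, int]]:
    """Distinct locus identities (id, chrom, start, end) across call sets,
    in deterministic coordinate order."""
    idents = {c.locus.identity for c in calls}
    return sorted(idents, key=lambda t: (t[1], t[2], t[3], t[0]))


def copy_number_summary(calls: Sequence[CnvMirnaCall]) -> CopyNumberSummary:
    """Global genotype range and per-call multiallelic flags.

    Calls without genotypes are skipped with a warning; at least one
    call must carry genotypes.
    """
    flags: list[bool] = []
    lo: int | None = None
    hi: int | None = None
    n_with = 0
    for c in calls:
        gts = c.region.genotypes
        if not gts:
            logger.warning(
                "call %s/%s has no genotypes; skipped in copy-number summary",
                c.locus.id, c.region.cnv_id,
            )
            flags.append(False)
            continue
        n_with += 1
        flags.append(is_multiallelic(gts))
        lo = min(gts) if lo is None else min(lo, min(gts))
        hi = max(gts) if hi is None else max(hi, max(gts))
    if n_with == 0:
        raise ValueError("no call carries genotypes")
    return CopyNumberSummary(
        copy_min=lo, copy_max=hi, multiallelic_calls=tuple(flags), n_with_genotypes=n_with
    )


def disease_region_overlap(
    loci: Iterable[MirnaLocus], disease_regions: Sequence[CnvRegion]
) -> dict[str, list[CnvMirnaCall]]:
    """Call loci against disease-implicated regions, grouped by region name."""
    calls = call_cnv_mirnas(loci, disease_regions, set_label="disease")
    grouped: dict[str, list[CnvMirnaCall]] = {}
    for c in calls:
        grouped.setdefault(c.region.cnv_id or c.region.interval.region_string(), []).append(c)
    return grouped
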