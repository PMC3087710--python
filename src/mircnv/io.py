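"""Readers and writers for the tabular formats every stage touches.

Supported dialects:

* miRNA locus tables — headered TSV (``id``, ``chrom``, ``start``,
  ``end``; 1-based inclusive) or a GFF-like 9-column layout.
* CNV region tables — generic DGV-style headered TSV, plain BED
  (0-based half-open) or the packaged paper-table transcription.
* SNP position lists — headered TSV of (chrom, 1-based pos) or BED.
* Genome models — two-column TSV of chromosome name and length.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import (
    MITOCHONDRIAL,
    GenomeModel,
    GenomicInterval,
    normalize_chrom,
    parse_region,
)

logger = logging.getLogger("mircnv")
if not logger.handlers:  # level-prefixed lines on stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s: %(message)s"))
    logger.addHandler(_h)

__all__ = [
    "MirnaLocus",
    "CnvRegion",
    "SnpSet",
    "CNV_SET_LABELS",
    "read_genome_model",
    "read_mirna_table",
    "filter_nuclear",
    "read_cnv_table",
    "read_snp_table",
    "write_calls_tsv",
    "read_calls_tsv",
]

#: Registry of recognised CNV set labels; anything else is user-defined.
CNV_SET_LABELS = {"DGV", "polymorphic-SMC", "polymorphic-DC", "disease"}


@dataclass(frozen=True)
class MirnaLocus:
    """A pre-miRNA locus.  Identity for counting is (id, chrom, start, end)."""

    id: str
    interval: GenomicInterval
    duplicate_chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("miRNA id must be non-empty")

    @property
    def mitochondrial(self) -> bool:
        return self.interval.chrom == MITOCHONDRIAL

    @property
    def identity(self) -> tuple[str, str, int, int]:
        iv = self.interval
        return (self.id, iv.chrom, iv.start, iv.end)


@dataclass(frozen=True)
class CnvRegion:
    """A CNV region with its validation metadata.

    ``n_records``/``n_references``/``frequency`` are the three
    validation factors (overlapping deposited records, reporting
    publications, discovery-study observations); ``genotypes`` lists the
    observed integer copy numbers where available.
    """

    interval: GenomicInterval
    set_label: str = "user-defined"
    n_records: int = 1
    n_references: int = 0
    frequency: int = 0
    genotypes: tuple[int, ...] | None = None
    cnv_id: str = ""
    reference: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_records, self.n_references, self.frequency) < 0:
            raise ValueError("validation-factor counts must be non-negative")
        if self.genotypes is not None and any(g < 0 for g in self.genotypes):
            raise ValueError(f"negative copy number in genotypes: {self.genotypes}")


@dataclass
class SnpSet:
    """Unique (chrom, 1-based position) pairs."""

    positions: set[tuple[str, int]] = field(default_factory=set)
    build_label: str = ""

    def __len__(self) -> int:
        return len(self.positions)


def _parse_genotypes(text: object) -> tuple[int, ...] | None:
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return None
    s = str(text).strip()
    if not s:
        return None
    try:
        return tuple(int(tok) for tok in s.split(","))
    except ValueError as exc:
        raise ValueError(f"malformed genotype list {s!r}") from exc


def read_genome_model(path: str | Path, excluded: set[str] | None = None) -> GenomeModel:
    """Read a two-column (chromosome, length) TSV; a header line is optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: genome model needs two columns (chrom, length)")
    rows = df.iloc[:, :2].values.tolist()
    if rows and not str(rows[0][1]).strip().isdigit():  # header line
        rows = rows[1:]
    chroms = [(str(c), int(l)) for c, l in rows]
    kwargs = {} if excluded is None else {"excluded": excluded}
    return GenomeModel(chroms, **kwargs)


def read_mirna_table(path: str | Path, format: str = "tsv") -> list[MirnaLocus]:
    """Read miRNA loci from a headered TSV or a GFF-like table.

    TSV columns: ``id``, ``chrom``, ``start``, ``end`` (1-based
    inclusive) and optionally ``dupl`` (comma-separated chromosomes
    carrying near-identical copies).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("id", "chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        loci = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                iv = GenomicInterval(
                    normalize_chrom(str(row.chrom)),
                    int(row.start) - 1,
                    int(row.end),
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
            dupl: tuple[str, ...] = ()
            if "dupl" in df.columns:
                raw = getattr(row, "dupl")
                if isinstance(raw, str) and raw.strip():
                    dupl = tuple(
                        normalize_chrom(tok.strip()) for tok in raw.split(",") if tok.strip()
                    )
            loci.append(MirnaLocus(str(row.id), iv, dupl))
    elif format in {"gff", "gff-like"}:
        names = [
            "seqid", "source", "type", "start", "end",
            "score", "strand", "frame", "attributes",
        ]
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#", dtype=str)
        loci = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            attrs = dict(
                kv.split("=", 1)
                for kv in str(row.attributes).rstrip(";").split(";")
                if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID")
            if not name:
                raise ValueError(f"{path}: row {i}: no Name/ID attribute")
            try:
                iv = GenomicInterval(
                    normalize_chrom(str(row.seqid)), int(row.start) - 1, int(row.end)
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
            loci.append(MirnaLocus(name, iv))
    else:
        raise ValueError(f"unknown miRNA table format {format!r}")
    if not loci:
        logger.warning("%s: no miRNA loci parsed", path)
    else:
        logger.info("%s: read %d miRNA loci", path, len(loci))
    return loci


def filter_nuclear(loci: Iterable[MirnaLocus]) -> list[MirnaLocus]:
    """Drop mitochondrial loci."""
    loci = list(loci)
    kept = [l for l in loci if not l.mitochondrial]
    logger.info(
        "nuclear filter: %d of %d loci retained (%d mitochondrial excluded)",
        len(kept), len(loci), len(loci) - len(kept),
    )
    return kept


def read_cnv_table(
    path: str | Path,
    dialect: str = "dgv-tsv",
    set_label: str = "user-defined",
    include_type: str = "Copy Number",
) -> list[CnvRegion]:
    """Read CNV regions.

    dgv-tsv
        Headered TSV with columns ``chrom``, ``start``, ``end`` (1-based
        inclusive) and optionally ``id``, ``variation_type``,
        ``n_records``, ``n_references``, ``frequency``, ``genotypes``,
        ``reference``.  Only rows whose ``variation_type`` equals
        ``include_type`` are retained (rows lacking the column pass).
    bed
        3+ column BED, 0-based half-open, optional name in column 4.
    paper-table
        The packaged transcription layout (see :mod:`mircnv.fixtures`).
    """
    path = Path(path)
    regions: list[CnvRegion] = []
    if dialect == "dgv-tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        has = df.columns
        for i, row in enumerate(df.itertuples(index=False), start=2):
            if "variation_type" in has and str(row.variation_type) != include_type:
                continue
            try:
                iv = GenomicInterval(
                    normalize_chrom(str(row.chrom)), int(row.start) - 1, int(row.end)
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc

            def _int(col: str, default: int) -> int:
                if col not in has:
                    return default
                v = getattr(row, col)
                return default if pd.isna(v) or str(v) == "" else int(v)

            regions.append(
                CnvRegion(
                    interval=iv,
                    set_label=set_label,
                    n_records=_int("n_records", 1),
                    n_references=_int("n_references", 0),
                    frequency=_int("frequency", 0),
                    genotypes=_parse_genotypes(getattr(row, "genotypes", None))
                    if "genotypes" in has
                    else None,
                    cnv_id=str(getattr(row, "id", "") or "") if "id" in has else "",
                    reference=(
                        str(row.reference)
                        if "reference" in has and not pd.isna(row.reference)
                        else None
                    ),
                )
            )
    elif dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 3:
            raise ValueError(f"{path}: BED needs at least 3 columns")
        for i, row in enumerate(df.itertuples(index=False), start=1):
            vals = list(row)
            iv = GenomicInterval(normalize_chrom(str(vals[0])), int(vals[1]), int(vals[2]))
            name = str(vals[3]) if len(vals) > 3 and not pd.isna(vals[3]) else ""
            regions.append(CnvRegion(interval=iv, set_label=set_label, cnv_id=name))
    elif dialect == "paper-table":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for i, row in enumerate(df.itertuples(index=False), start=2):
            regions.append(
                CnvRegion(
                    interval=parse_region(str(row.cnv_region)),
                    set_label=str(getattr(row, "set_label", set_label)),
                    genotypes=_parse_genotypes(getattr(row, "genotypes", None)),
                    cnv_id=str(getattr(row, "cnv_id", "") or ""),
                )
            )
    else:
        raise ValueError(f"unknown CNV table dialect {dialect!r}")
    logger.info("%s: read %d CNV regions (%s)", path, len(regions), dialect)
    return regions


def read_snp_table(path: str | Path, dialect: str = "tsv", build_label: str = "") -> SnpSet:
    """Read SNP positions from a headered (chrom, pos) TSV or BED."""
    path = Path(path)
    positions: set[tuple[str, int]] = set()
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("chrom", "pos"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        for row in df.itertuples(index=False):
            positions.add((normalize_chrom(str(row.chrom)), int(row.pos)))
    elif dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        for row in df.itertuples(index=False):
            vals = list(row)
            positions.add((normalize_chrom(str(vals[0])), int(vals[1]) + 1))
    else:
        raise ValueError(f"unknown SNP table dialect {dialect!r}")
    return SnpSet(positions=positions, build_label=build_label)


# --- calls TSV -------------------------------------------------------------

_CALL_COLUMNS = [
    "set_label", "mirna_id", "chrom", "start", "end", "region",
    "overlap_bp", "fully_contained", "left_flank", "right_flank",
    "minimal_region", "n_supporting_records", "genotypes",
    "copy_min", "copy_max", "multiallelic", "flank_class", "dosage_effect",
    "cnv_id", "region_n_records", "region_n_references", "region_frequency",
]


def calls_to_frame(calls: Sequence) -> pd.DataFrame:
    """Flatten CnvMirnaCall objects into the canonical TSV layout."""
    rows = []
    for c in calls:
        iv = c.locus.interval
        gts = c.region.genotypes
        rows.append(
            {
                "set_label": c.region.set_label,
                "mirna_id": c.locus.id,
                "chrom": iv.chrom,
                "start": iv.start + 1,
                "end": iv.end,
                "region": c.region.interval.region_string(),
                "overlap_bp": c.overlap_bp,
                "fully_contained": c.fully_contained,
                "left_flank": c.flanks[0] if c.flanks else "",
                "right_flank": c.flanks[1] if c.flanks else "",
                "minimal_region": c.minimal_region.region_string()
                if c.minimal_region
                else "",
                "n_supporting_records": c.n_supporting_records,
                "genotypes": ",".join(map(str, gts)) if gts else "",
                "copy_min": c.copy_range[0] if c.copy_range else "",
                "copy_max": c.copy_range[1] if c.copy_range else "",
                "multiallelic": c.multiallelic if c.multiallelic is not None else "",
                "flank_class": c.flank_class or "",
                "dosage_effect": c.dosage_effect or "",
                "cnv_id": c.region.cnv_id,
                "region_n_records": c.region.n_records,
                "region_n_references": c.region.n_references,
                "region_frequency": c.region.frequency,
            }
        )
    df = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    return df.sort_values(["chrom", "start", "set_label"], kind="mergesort").reset_index(
        drop=True
    )


def write_calls_tsv(calls: Sequence, path: str | Path) -> None:
    """Write calls in a deterministic column order and row sort."""
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path):
    """Re-read a calls TSV back into CnvMirnaCall objects."""
    from .annotation import CnvMirnaCall  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    calls = []
    for row in df.itertuples(index=False):
        locus = MirnaLocus(
            row.mirna_id,
            GenomicInterval(normalize_chrom(row.chrom), int(row.start) - 1, int(row.end)),
        )
        region = CnvRegion(
            interval=parse_region(row.region),
            set_label=row.set_label,
            n_records=int(row.region_n_records),
            n_references=int(row.region_n_references),
            frequency=int(row.region_frequency),
            genotypes=_parse_genotypes(row.genotypes),
            cnv_id=row.cnv_id,
        )
        flanks = (
            (int(row.left_flank), int(row.right_flank))
            if row.left_flank != "" and row.right_flank != ""
            else None
        )
        calls.append(
            CnvMirnaCall(
                locus=locus,
                region=region,
                overlap_bp=int(row.overlap_bp),
                fully_contained=str(row.fully_contained) == "True",
                flanks=flanks,
                minimal_region=parse_region(row.minimal_region)
                if row.minimal_region
                else None,
                n_supporting_records=int(row.n_supporting_records),
                copy_range=(int(row.copy_min), int(row.copy_max))
                if row.copy_min != ""
                else None,
                multiallelic=str(row.multiallelic) == "True"
                if row.multiallelic != ""
                else None,
                flank_class=row.flank_class or None,
                dosage_effect=row.dosage_effect or None,
            )
        )
    return calls
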