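"""Packaged fixture tables: machine-readable transcriptions of the two
printed CNV-miRNA tables (highly polymorphic sets and top-validated
deposited regions)."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .intervals import normalize_chrom, parse_region
from .io import CnvRegion, MirnaLocus

__all__ = ["PaperFixtures", "Table2Entry", "paper_fixtures"]


@dataclass(frozen=True)
class Table2Entry:
    """One top-validated deposited CNV-miRNA: locus, the minimal region
    supported by every overlapping deposited record, and that record count."""

    locus: MirnaLocus
    minimal_region: object  # GenomicInterval
    n_records: int


@dataclass(frozen=True)
class PaperFixtures:
    smc_loci: tuple[MirnaLocus, ...]
    smc_regions: tuple[CnvRegion, ...]
    dc_loci: tuple[MirnaLocus, ...]
    dc_regions: tuple[CnvRegion, ...]
    table2: tuple[Table2Entry, ...]

    @property
    def polymorphic_sets(self) -> dict[str, tuple[tuple[MirnaLocus, ...], tuple[CnvRegion, ...]]]:
        return {
            "polymorphic-SMC": (self.smc_loci, self.smc_regions),
            "polymorphic-DC": (self.dc_loci, self.dc_regions),
        }


def _dupl(raw: object) -> tuple[str, ...]:
    if not isinstance(raw, str) or not raw.strip():
        return ()
    return tuple(normalize_chrom(tok.strip()) for tok in raw.split(",") if tok.strip())


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("mircnv").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def paper_fixtures() -> PaperFixtures:
    """Load the packaged transcriptions as typed collections.

    Rows are kept exactly as printed: the DC block lists two loci
    against one shared CNV region, and one locus appears in both the
    SMC and DC blocks.
    """
    t1 = _read_packaged("table1.tsv")
    blocks: dict[str, tuple[list[MirnaLocus], list[CnvRegion]]] = {
        "polymorphic-SMC": ([], []),
        "polymorphic-DC": ([], []),
    }
    for row in t1.itertuples(index=False):
        loci, regions = blocks[row.set_label]
        loci.append(
            MirnaLocus(row.mirna_id, parse_region(row.mirna_position), _dupl(row.dupl))
        )
        regions.append(
            CnvRegion(
                interval=parse_region(row.cnv_region),
                set_label=row.set_label,
                genotypes=tuple(int(g) for g in str(row.genotypes).split(",")),
                cnv_id=str(row.cnv_id),
            )
        )

    t2 = _read_packaged("table2.tsv")
    table2 = tuple(
        Table2Entry(
            locus=MirnaLocus(row.mirna_id, parse_region(row.mirna_position), _dupl(row.dupl)),
            minimal_region=parse_region(row.minimal_region),
            n_records=int(row.n_records),
        )
        for row in t2.itertuples(index=False)
    )
    smc_loci, smc_regions = blocks["polymorphic-SMC"]
    dc_loci, dc_regions = blocks["polymorphic-DC"]
    return PaperFixtures(
        smc_loci=tuple(smc_loci),
        smc_regions=tuple(smc_regions),
        dc_loci=tuple(dc_loci),
        dc_regions=tuple(dc_regions),
        table2=table2,
    )
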