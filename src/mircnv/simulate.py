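"""Synthetic genomes, miRNA loci, CNV sets and SNP sets.

The generator emulates the input structure the analysis assumes:

* miRNA loci are placed uniformly and non-overlapping;
* CNVs are placed uniformly with a configurable relative propensity
  ``rho`` to overlap miRNA loci — overlapping proposals are rejection
  thinned by ``rho`` (``rho < 1`` yields purifying depletion, 1 is
  neutral, ``> 1`` enrichment);
* SNPs fall as per-bp Bernoulli events at separate inside/outside rates.

One seeded generator per dataset, with independent sub-streams per
component, so e.g. adding SNPs never perturbs CNV placement.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomeModel, GenomicInterval
from .io import CnvRegion, MirnaLocus, SnpSet

from .fixtures import paper_fixtures  # re-exported: the bundled printed-table dataset

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "write_dataset",
    "paper_fixtures",
]

_STREAMS = {"loci": 1, "cnvs": 2, "snps": 3, "records": 4, "genotypes": 5}


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 2_000_000),
        ("chr2", 2_000_000),
        ("chr3", 2_000_000),
        ("chr4", 2_000_000),
        ("chr5", 2_000_000),
    )
    n_mirnas: int = 200
    mirna_length: tuple[int, int] = (60, 150)
    n_cnvs: int = 100
    cnv_length: tuple[int, int] = (1_000, 1_000_000)  # log-uniform bounds
    rho: float = 1.0
    snp_rate_in: float = 0.0  # SNPs per 1,000 bp inside miRNA loci
    snp_rate_out: float = 0.0
    records_per_region_mean: float = 1.0
    genotype_model: tuple[tuple[int, float], ...] = (
        (1, 0.2), (2, 0.6), (3, 0.2),
    )
    set_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.snp_rate_in < 0 or self.snp_rate_out < 0:
            raise ValueError("SNP rates must be >= 0")
        if not (1 <= self.mirna_length[0] <= self.mirna_length[1]):
            raise ValueError(f"bad mirna_length bounds {self.mirna_length}")
        if not (1 <= self.cnv_length[0] <= self.cnv_length[1]):
            raise ValueError(f"bad cnv_length bounds {self.cnv_length}")
        if self.records_per_region_mean < 1:
            raise ValueError("records_per_region_mean must be >= 1")
        freqs = [f for _, f in self.genotype_model]
        if any(f < 0 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("genotype_model frequencies must be a distribution")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeModel
    loci: list[MirnaLocus]
    cnv_regions: list[CnvRegion]
    record_stacks: dict[str, list[GenomicInterval]]
    snps: SnpSet
    true_params: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        """Stable digest of the generated content (reproducibility checks)."""
        h = hashlib.sha256()
        for name, length in self.genome.chromosomes:
            h.update(f"G{name}:{length};".encode())
        for l in self.loci:
            h.update(f"L{l.id}:{l.interval.region_string()};".encode())
        for r in self.cnv_regions:
            h.update(
                f"C{r.cnv_id}:{r.interval.region_string()}:{r.n_records}:"
                f"{r.genotypes};".encode()
            )
        for cid in sorted(self.record_stacks):
            for iv in self.record_stacks[cid]:
                h.update(f"R{cid}:{iv.region_string()};".encode())
        for chrom, pos in sorted(self.snps.positions):
            h.update(f"S{chrom}:{pos};".encode())
        return h.hexdigest()


def _stream(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[component]])


def _place_nonoverlapping(
    rng: np.random.Generator, chrom: str, chrom_len: int, lengths: np.ndarray
) -> list[GenomicInterval]:
    """Uniform placement of non-overlapping spans via the gap method."""
    n = len(lengths)
    if n == 0:
        return []
    free = chrom_len - int(lengths.sum())
    if free < 0:
        raise ValueError(
            f"infeasible packing: {int(lengths.sum())} locus bp on {chrom} "
            f"({chrom_len} bp)"
        )
    order = rng.permutation(n)  # random length-to-slot assignment
    offsets = np.sort(rng.integers(0, free + 1, size=n))
    starts = offsets + np.concatenate(([0], np.cumsum(lengths[order][:-1])))
    return [
        GenomicInterval(chrom, int(s), int(s + l))
        for s, l in zip(starts, lengths[order])
    ]


def _sample_genotypes(
    rng: np.random.Generator, model: Sequence[tuple[int, float]], n_draws: int = 10
) -> tuple[int, ...]:
    states = np.array([s for s, _ in model])
    probs = np.array([p for _, p in model])
    drawn = rng.choice(states, size=n_draws, p=probs)
    return tuple(sorted(set(int(g) for g in drawn)))


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset under ``config``; identical config => identical data."""
    genome = GenomeModel(list(config.chromosomes))
    chrom_names = [n for n, _ in genome.chromosomes if n not in genome.excluded]
    chrom_lens = np.array(
        [l for n, l in genome.chromosomes if n not in genome.excluded], dtype=np.int64
    )
    probs = chrom_lens / chrom_lens.sum()

    # --- miRNA loci -------------------------------------------------------
    rng = _stream(config.seed, "loci")
    per_chrom = rng.multinomial(config.n_mirnas, probs)
    loci: list[MirnaLocus] = []
    loci_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cname, clen, n_here in zip(chrom_names, chrom_lens, per_chrom):
        lengths = rng.integers(
            config.mirna_length[0], config.mirna_length[1] + 1, size=n_here
        )
        ivs = sorted(
            _place_nonoverlapping(rng, cname, int(clen), lengths),
            key=lambda iv: iv.start,
        )
        for iv in ivs:
            loci.append(MirnaLocus(f"syn-mir-{len(loci) + 1}", iv))
        loci_by_chrom[cname] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )

    def overlaps_locus(chrom: str, start: int, end: int) -> bool:
        starts, ends = loci_by_chrom[chrom]
        i = int(np.searchsorted(starts, end))
        return i > 0 and ends[i - 1] > start

    # --- CNVs with rho-thinned locus overlap ------------------------------
    rng = _stream(config.seed, "cnvs")
    rng_rec = _stream(config.seed, "records")
    rng_gt = _stream(config.seed, "genotypes")
    log_lo, log_hi = np.log(config.cnv_length[0]), np.log(config.cnv_length[1])
    thin_overlap = min(config.rho, 1.0)
    thin_nonoverlap = min(1.0 / config.rho, 1.0) if config.rho > 0 else 1.0
    cnvs: list[CnvRegion] = []
    record_stacks: dict[str, list[GenomicInterval]] = {}
    n_overlapping = 0
    for i in range(config.n_cnvs):
        for _attempt in range(100_000):
            ci = int(rng.choice(len(chrom_names), p=probs))
            cname, clen = chrom_names[ci], int(chrom_lens[ci])
            length = int(round(np.exp(rng.uniform(log_lo, log_hi))))
            length = max(1, min(length, clen))
            start = int(rng.integers(0, clen - length + 1))
            hits = overlaps_locus(cname, start, start + length)
            keep_p = thin_overlap if hits else thin_nonoverlap
            if keep_p >= 1.0 or rng.random() < keep_p:
                break
        else:  # pragma: no cover - requires pathological config
            raise RuntimeError("CNV rejection sampling failed to converge")
        n_overlapping += int(hits)
        cnv_id = f"syn-cnv-{i + 1}"
        iv = GenomicInterval(cname, start, start + length)
        n_records = 1 + int(rng_rec.poisson(config.records_per_region_mean - 1.0))
        stack = []
        for _ in range(n_records):
            jl = int(rng_rec.integers(0, max(1, length // 4)))
            jr = int(rng_rec.integers(0, max(1, length // 4)))
            stack.append(GenomicInterval(cname, start + jl, start + length - jr))
        record_stacks[cnv_id] = stack
        cnvs.append(
            CnvRegion(
                interval=iv,
                set_label=config.set_label,
                n_records=n_records,
                genotypes=_sample_genotypes(rng_gt, config.genotype_model),
                cnv_id=cnv_id,
            )
        )

    # --- SNPs: per-bp Bernoulli at inside/outside rates -------------------
    rng = _stream(config.seed, "snps")
    positions: set[tuple[str, int]] = set()

    def drop_snps(chrom: str, seg_start: int, seg_end: int, rate_per_kb: float) -> None:
        seg_len = seg_end - seg_start
        if seg_len <= 0 or rate_per_kb <= 0:
            return
        n = int(rng.binomial(seg_len, min(1.0, rate_per_kb / 1000.0)))
        if n == 0:
            return
        offs = rng.choice(seg_len, size=n, replace=False)
        for o in offs:
            positions.add((chrom, seg_start + int(o) + 1))  # 1-based

    if config.snp_rate_in > 0 or config.snp_rate_out > 0:
        for cname, clen in zip(chrom_names, chrom_lens):
            starts, ends = loci_by_chrom[cname]
            cursor = 0
            for s, e in zip(starts, ends):
                drop_snps(cname, cursor, int(s), config.snp_rate_out)
                drop_snps(cname, int(s), int(e), config.snp_rate_in)
                cursor = int(e)
            drop_snps(cname, cursor, int(clen), config.snp_rate_out)

    locus_bp = sum(l.interval.length for l in loci)
    return SyntheticDataset(
        config=config,
        genome=genome,
        loci=loci,
        cnv_regions=cnvs,
        record_stacks=record_stacks,
        snps=SnpSet(positions=positions, build_label="synthetic"),
        true_params={
            "rho": config.rho,
            "n_cnvs_overlapping_loci": n_overlapping,
            "locus_bp": locus_bp,
            "nonlocus_bp": int(chrom_lens.sum()) - locus_bp,
        },
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the dialects the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.tsv",
        "mirnas": outdir / "mirnas.tsv",
        "cnvs": outdir / "cnvs.tsv",
        "snps": outdir / "snps.tsv",
    }
    with paths["genome"].open("w") as fh:
        for name, length in dataset.genome.chromosomes:
            fh.write(f"{name}\t{length}\n")
    with paths["mirnas"].open("w") as fh:
        fh.write("id\tchrom\tstart\tend\n")
        for l in dataset.loci:
            iv = l.interval
            fh.write(f"{l.id}\t{iv.chrom}\t{iv.start + 1}\t{iv.end}\n")
    with paths["cnvs"].open("w") as fh:
        fh.write("id\tchrom\tstart\tend\tvariation_type\tn_records\tgenotypes\n")
        for r in dataset.cnv_regions:
            iv = r.interval
            gts = ",".join(map(str, r.genotypes)) if r.genotypes else ""
            fh.write(
                f"{r.cnv_id}\t{iv.chrom}\t{iv.start + 1}\t{iv.end}\t"
                f"Copy Number\t{r.n_records}\t{gts}\n"
            )
    with paths["snps"].open("w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in sorted(dataset.snps.positions):
            fh.write(f"{chrom}\t{pos}\n")
    return paths
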