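"""End-to-end orchestration from a single YAML config.

Stages: read inputs -> nuclear filter -> per-set CNV-miRNA calling ->
support-stratified depletion tests -> SNP density -> classification ->
capture-recapture extrapolation -> machine-readable run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import call_cnv_mirnas, copy_number_summary, dedupe_loci
from .intervals import GenomicInterval, merge, overlap_bp as _ov, total_bp
from .io import (
    calls_to_frame,
    filter_nuclear,
    read_cnv_table,
    read_genome_model,
    read_mirna_table,
    read_snp_table,
)
from .stats import (
    base_coverage_fraction,
    capture_recapture_union,
    count_snps_in_intervals,
    depletion_test,
    extrapolate_cnv_mirna_count,
    feature_coverage_count,
    narrow_by_support,
    snp_density_test,
)

logger = logging.getLogger("mircnv")

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class CnvSetSpec:
    label: str
    path: Path
    dialect: str = "dgv-tsv"
    genome_fraction: float | None = None  # explicit value wins over computation


@dataclass
class RunConfig:
    genome: Path
    mirna_table: Path
    cnv_sets: list[CnvSetSpec]
    output_dir: Path
    mirna_format: str = "tsv"
    snp_table: Path | None = None
    snp_dialect: str = "tsv"
    disease_regions: Path | None = None
    disease_dialect: str = "bed"
    min_overlap_bp: int = 1
    short_flank_kb: float = 5.0
    large_flank_kb: float = 20.0
    narrow_k: list[int] = field(default_factory=lambda: [1])
    narrow_criterion: str = "records"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        try:
            mirna = raw["mirna_table"]
            if isinstance(mirna, dict):
                mirna_path, mirna_format = mirna["path"], mirna.get("format", "tsv")
            else:
                mirna_path, mirna_format = mirna, "tsv"
            sets = [
                CnvSetSpec(
                    label=s["label"],
                    path=Path(s["path"]),
                    dialect=s.get("dialect", "dgv-tsv"),
                    genome_fraction=s.get("genome_fraction"),
                )
                for s in raw["cnv_sets"]
            ]
            thresholds = raw.get("thresholds", {})
            cfg = cls(
                genome=Path(raw["genome"]),
                mirna_table=Path(mirna_path),
                mirna_format=mirna_format,
                cnv_sets=sets,
                output_dir=Path(raw["output_dir"]),
                snp_table=Path(raw["snp_table"]) if raw.get("snp_table") else None,
                disease_regions=Path(raw["disease_regions"])
                if raw.get("disease_regions")
                else None,
                min_overlap_bp=int(thresholds.get("min_overlap_bp", 1)),
                short_flank_kb=float(thresholds.get("short_flank_kb", 5)),
                large_flank_kb=float(thresholds.get("large_flank_kb", 20)),
                narrow_k=[int(k) for k in thresholds.get("narrow_k", [1])],
                narrow_criterion=str(thresholds.get("narrow_criterion", "records")),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing config key {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [self.genome, self.mirna_table, *(s.path for s in self.cnv_sets)]:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        for p in (self.snp_table, self.disease_regions):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not self.cnv_sets:
            raise ConfigError("at least one CNV set is required")
        if any(b <= a for a, b in zip(self.narrow_k, self.narrow_k[1:])):
            raise ConfigError(f"narrow_k grid must be strictly increasing: {self.narrow_k}")
        if self.min_overlap_bp < 1:
            raise ConfigError("min_overlap_bp must be >= 1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _pairwise_overlap_fraction(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> float:
    """Fraction of A's covered bases that are also covered by B."""
    a, b = merge(a), merge(b)
    bp_a = total_bp(a)
    if bp_a == 0:
        return 0.0
    shared = sum(_ov(x, y) for x in a for y in b)
    return shared / bp_a


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, object] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    genome = stage("read-genome")(lambda: read_genome_model(config.genome))
    loci_all = stage("read-mirnas")(
        lambda: read_mirna_table(config.mirna_table, format=config.mirna_format)
    )
    loci = filter_nuclear(loci_all)

    set_regions = {}
    for spec in config.cnv_sets:
        set_regions[spec.label] = stage(f"read-cnvs[{spec.label}]")(
            lambda s=spec: read_cnv_table(s.path, dialect=s.dialect, set_label=s.label)
        )

    # ---- calls + classification -----------------------------------------
    all_calls = {}
    class_rows = []
    for label, regions in set_regions.items():
        calls = stage(f"call[{label}]")(
            lambda l=label, r=regions: call_cnv_mirnas(
                loci, r, set_label=l, min_overlap_bp=config.min_overlap_bp
            )
        )
        all_calls[label] = calls
        path = out / f"calls_{label}.tsv"
        calls_to_frame(calls).to_csv(path, sep="\t", index=False)
        outputs[f"calls_{label}"] = path
        counts = {"short_both": 0, "large_both": 0, "mixed": 0, "partial_overlap": 0}
        for c in calls:
            counts[c.flank_class] = counts.get(c.flank_class, 0) + 1
        row = {"set_label": label, "n_calls": len(calls), **counts}
        if any(c.region.genotypes for c in calls):
            summ = copy_number_summary(calls)
            row.update(copy_min=summ.copy_min, copy_max=summ.copy_max,
                       n_multiallelic=sum(summ.multiallelic_calls))
        class_rows.append(row)
    pd.DataFrame(class_rows).to_csv(out / "classification.tsv", sep="\t", index=False)
    outputs["classification"] = out / "classification.tsv"
    outputs["n_distinct_loci"] = len(
        dedupe_loci(c for calls in all_calls.values() for c in calls)
    )

    # ---- depletion strata ------------------------------------------------
    n_total = len({l.identity for l in loci})
    dep_rows = []
    set_fractions = {}
    for spec in config.cnv_sets:
        regions = set_regions[spec.label]
        for k in config.narrow_k:
            narrowed = stage(f"narrow[{spec.label},k={k}]")(
                lambda r=regions, kk=k: narrow_by_support(
                    r, kk, criterion=config.narrow_criterion
                )
            )
            if k == min(config.narrow_k) and spec.genome_fraction is not None:
                frac = spec.genome_fraction
                logger.info(
                    "set %s: using explicit genome fraction %.4g (computed value ignored)",
                    spec.label, frac,
                )
            else:
                frac = base_coverage_fraction(narrowed, genome)
            n_cov = feature_coverage_count(loci, narrowed, config.min_overlap_bp)
            res = depletion_test(n_cov, n_total, frac)
            if k == min(config.narrow_k):
                set_fractions[spec.label] = frac
            dep_rows.append(
                {
                    "set_label": spec.label,
                    "criterion": config.narrow_criterion,
                    "k": k,
                    "n_total": n_total,
                    "n_covered": n_cov,
                    "genome_fraction": frac,
                    "expected": res.expected,
                    "ratio": res.n_covered / res.expected if res.expected > 0 else float("nan"),
                    "p_lower_tail": res.p_lower_tail,
                }
            )
    dep_df = pd.DataFrame(dep_rows)
    dep_df.to_csv(out / "depletion.tsv", sep="\t", index=False, float_format="%.6g")
    outputs["depletion"] = out / "depletion.tsv"

    # ---- SNP density -----------------------------------------------------
    if config.snp_table is not None:
        def _snp_stage():
            snps = read_snp_table(config.snp_table, dialect=config.snp_dialect)
            merged_loci = merge(l.interval for l in loci)
            bp_in = total_bp(merged_loci)
            snps_in = count_snps_in_intervals(snps, merged_loci)
            bp_out = genome.effective_bp - bp_in
            snps_out = len(snps.positions) - snps_in
            res = snp_density_test(snps_in, bp_in, snps_out, bp_out)
            pd.DataFrame(
                [
                    {
                        "snps_in": res.snps_in,
                        "bp_in": res.bp_in,
                        "snps_out": res.snps_out,
                        "bp_out": res.bp_out,
                        "rate_in_per_kb": round(res.rate_in, 1),
                        "rate_out_per_kb": round(res.rate_out, 1),
                        "p_fisher": res.p_fisher,
                    }
                ]
            ).to_csv(out / "snp_density.tsv", sep="\t", index=False)
            return out / "snp_density.tsv"

        outputs["snp_density"] = stage("snp-density")(_snp_stage)

    # ---- extrapolation ---------------------------------------------------
    if len(config.cnv_sets) >= 2:
        a, b = config.cnv_sets[0].label, config.cnv_sets[1].label
        ivs_a = [r.interval for r in set_regions[a]]
        ivs_b = [r.interval for r in set_regions[b]]
        frac_a_in_b = _pairwise_overlap_fraction(ivs_a, ivs_b)
        frac_b_in_a = _pairwise_overlap_fraction(ivs_b, ivs_a)
        try:
            cr = capture_recapture_union(
                set_fractions[a], set_fractions[b], frac_a_in_b, frac_b_in_a
            )
            first_k = min(config.narrow_k)
            ratios = [
                r["ratio"] for r in dep_rows if r["k"] == first_k and r["expected"] > 0
            ]
            dep_ratio = sum(ratios) / len(ratios) if ratios else 1.0
            n_extrap = extrapolate_cnv_mirna_count(
                n_total, min(cr.estimate, 1.0), min(dep_ratio, 1.0)
            )
            pd.DataFrame(
                [
                    {
                        "set_a": a, "set_b": b,
                        "cov_a": set_fractions[a], "cov_b": set_fractions[b],
                        "frac_a_in_b": frac_a_in_b, "frac_b_in_a": frac_b_in_a,
                        "union_estimate": cr.estimate,
                        "union_low": cr.low, "union_high": cr.high,
                        "depletion_ratio": dep_ratio,
                        "extrapolated_count": n_extrap,
                    }
                ]
            ).to_csv(out / "extrapolation.tsv", sep="\t", index=False, float_format="%.6g")
            outputs["extrapolation"] = out / "extrapolation.tsv"
        except ZeroDivisionError:
            logger.warning("sets %s/%s share no coverage; extrapolation skipped", a, b)

    # ---- run log ---------------------------------------------------------
    cfg_digest = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True
        ).encode()
    ).hexdigest()
    log = {
        "version": __version__,
        "config_sha256": cfg_digest,
        "inputs": {
            str(p): _sha256(p)
            for p in [config.genome, config.mirna_table, *(s.path for s in config.cnv_sets)]
        },
        "n_loci_input": len(loci_all),
        "n_loci_nuclear": len(loci),
        "n_calls": {label: len(calls) for label, calls in all_calls.items()},
        "n_distinct_cnv_mirnas": outputs["n_distinct_loci"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    outputs["run_log"] = out / "run_log.json"
    outputs["depletion_rows"] = dep_rows
    return outputs
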