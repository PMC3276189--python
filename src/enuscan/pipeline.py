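"""End-to-end orchestration: annotate -> filter -> interval -> segregate.

This module houses no science of its own; every number in its reports is
produced by the annotation, cascade and segregation modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import io as eio
from .annotate import annotate_all
from .cascade import (
    CascadeOptions,
    interval_filter,
    positive_control_check,
    run_cascade,
    write_candidates,
    write_summary,
)
from .model import FunctionalClass, MappedInterval, VariantSite
from .segregation import Method, segregation_test, write_segregation

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


@dataclass
class RunConfig:
    """Flat configuration for one line's end-to-end run."""

    vcf: Path
    roles: Path
    genes: Path
    reference: Path
    dbsnp: Path
    out_dir: Path
    line_id: str = "line"
    interval: Optional[Path] = None
    pedigree: Optional[Path] = None
    candidate_site: Optional[str] = None  # chrom:pos:ref:alt
    control_site: Optional[str] = None
    min_depth: int = 8
    strict_parental: bool = False
    require_class: Optional[str] = None
    report: str = "tsv"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for name, value in raw.items():
            if name not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {name!r}")
            kwargs[name] = value
        for key in ("vcf", "roles", "genes", "reference", "dbsnp", "out_dir",
                    "interval", "pedigree"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        for key in ("vcf", "roles", "genes", "reference", "dbsnp"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} path does not exist: {p}")
        for key in ("interval", "pedigree"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} path does not exist: {p}")


def parse_site(text: str) -> VariantSite:
    chrom, pos, ref, alt = text.split(":")
    return VariantSite(chrom, int(pos), ref.upper(), alt.upper())


def run_end_to_end(config: RunConfig) -> Dict[str, Path]:
    """Run the whole per-line workflow; returns the written report paths."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(f"{name}: {exc}") from exc

    roles = stage("read-roles", eio.read_roles, config.roles)
    callset = stage(
        "read-vcf", eio.read_variant_calls, config.vcf, roles, config.line_id
    )
    genes = stage("read-genes", eio.read_gene_models, config.genes)
    ref = stage("read-reference", eio.ReferenceSequence.from_fasta, config.reference)
    known = stage("read-dbsnp", eio.read_known_sites, config.dbsnp)
    interval = (
        stage("read-interval", eio.read_mapped_interval, config.interval)
        if config.interval
        else None
    )

    annotations = stage("annotate", annotate_all, callset, genes, ref)
    opts = CascadeOptions(
        min_depth=config.min_depth,
        strict_parental=config.strict_parental,
        require_class=(
            FunctionalClass(config.require_class.upper())
            if config.require_class
            else None
        ),
    )
    candidates, summary = stage("cascade", run_cascade, callset, annotations, known, opts)

    paths: Dict[str, Path] = {}
    paths["candidates"] = out / "candidates.tsv"
    write_candidates(candidates, paths["candidates"])
    paths["summary"] = out / "summary.tsv"
    write_summary([summary], paths["summary"])

    if interval is not None:
        in_region = stage("interval-filter", interval_filter, candidates, interval)
        log.info(
            "%s: interval filter kept %d of %d candidates",
            config.line_id, len(in_region), len(candidates),
        )
        paths["interval_candidates"] = out / "interval_candidates.tsv"
        write_candidates(in_region, paths["interval_candidates"])

    if config.control_site:
        report = stage(
            "control-check",
            positive_control_check,
            callset,
            parse_site(config.control_site),
            opts,
        )
        paths["control_check"] = out / "control_check.txt"
        with open(paths["control_check"], "w") as fh:
            fh.write(f"status\t{'PASS' if report.passed else 'FAIL'}\n")
            fh.write(f"reason\t{report.reason}\n")
            if report.genotype is not None:
                fh.write(f"genotype\t{report.genotype.value}\n")
                fh.write(f"depth\t{report.depth}\n")

    if config.pedigree and config.candidate_site:
        records = stage("read-pedigree", eio.read_pedigree, config.pedigree)
        result = stage("segregation", segregation_test, records, method=Method.BOTH)
        paths["segregation"] = out / "segregation.tsv"
        write_segregation(result, paths["segregation"])

    if config.report == "markdown":
        paths["report"] = out / "report.md"
        _write_markdown_report(summary, candidates, paths["report"])
    return paths


def _write_markdown_report(summary, candidates, path) -> None:
    df = summary.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# Filtering report: {summary.line_id}\n\n")
        fh.write(df.to_markdown(index=False))
        fh.write("\n\n## Candidates\n\n")
        for c in candidates:
            v = c.variant
            fh.write(
                f"- {v.site.chrom}:{v.site.pos} {v.site.ref_allele}>"
                f"{v.site.alt_allele} {v.func_class.value} {v.gene_id or ''} "
                f"{v.aa_change} [{c.consistency.value}]\n"
            )
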