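"""End-to-end orchestration: VCF -> filters -> scan -> score -> ranked candidates.

One :func:`run_pipeline` call reproduces the whole discovery workflow on
real or simulated inputs and leaves a self-describing output directory:
candidate table, filter trace (TSV + JSON), filtered VCF, microsatellite
BED and a run log with every parameter and seed needed to re-execute.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import repeats, scoring, simulate, variants

logger = logging.getLogger(__name__)


def configure_logging(level: str = "INFO", log_file: Path | None = None) -> None:
    """Log to stderr and, when given, to a file inside the run directory."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run."""

    vcf: Path
    out_dir: Path
    fasta: Path | None = None
    msat_table: Path | None = None  # MISA-style TSV; overrides scanning fasta
    condition_names: tuple[str, str, str] = variants.DEFAULT_CONDITIONS
    dp_min: int = variants.DEFAULT_DP_MIN
    mq_min: float = variants.DEFAULT_MQ_MIN
    per_sample_dp: bool = True
    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(repeats.DEFAULT_MIN_REPEATS)
    )
    assume_prefiltered: bool = False  # entry point for pre-filtered indel sets
    seed: int | None = None  # recorded for provenance when input was simulated
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.vcf).exists():
            raise FileNotFoundError(f"VCF not found: {self.vcf}")
        if self.msat_table is None:
            if self.fasta is None:
                raise ValueError("need either fasta (to scan) or msat_table")
            if not Path(self.fasta).exists():
                raise FileNotFoundError(f"FASTA not found: {self.fasta}")
        elif not Path(self.msat_table).exists():
            raise FileNotFoundError(f"msat table not found: {self.msat_table}")
        if self.dp_min < 0 or self.mq_min < 0:
            raise ValueError("dp_min and mq_min must be >= 0")


@dataclass
class PipelineResult:
    candidates: list[scoring.CandidateMSILocus]
    table: pd.DataFrame
    trace: scoring.FilterTrace
    msats: list[repeats.MicrosatelliteLocus]
    prefilter_counts: list[tuple[str, int]]
    out_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configure_logging(config.log_level, out / "pipeline.log")

    sites = variants.read_vcf(config.vcf, config.condition_names)
    prefilter: list[tuple[str, int]] = [("variants_read", len(sites))]
    if not config.assume_prefiltered:
        sites = variants.hard_filter(
            sites, config.dp_min, config.mq_min, config.per_sample_dp
        )
        prefilter.append(("hard_filtered", len(sites)))
        sites = variants.drop_group_shared(sites, config.condition_names)
        prefilter.append(("group_shared_removed", len(sites)))
        sites = variants.keep_treatment_differs(sites, config.condition_names)
        prefilter.append(("treatment_differs", len(sites)))
    indels = variants.select_indels(sites)
    prefilter.append(("indels", len(indels)))
    for stage, count in prefilter:
        logger.info("pre-cascade %s: %d", stage, count)

    if config.msat_table is not None:
        msats = repeats.read_msat_table(config.msat_table, dialect="misa")
    else:
        reference = simulate.read_reference_fasta(config.fasta)
        msats = repeats.scan_fasta(
            reference, repeats.RepeatThresholds(dict(config.min_repeats))
        )
    logger.info("microsatellites available for intersection: %d", len(msats))

    scored = scoring.score_sites(indels, config.condition_names)
    candidates, trace = scoring.run_cascade(scored, msats, config.condition_names)
    table = scoring.candidates_to_table(candidates)

    table.to_csv(out / "candidates.tsv", sep="\t", index=False)
    trace.to_tsv(out / "filter_trace.tsv")
    trace.to_json(out / "filter_trace.json")
    variants.write_vcf(indels, out / "filtered_indels.vcf", config.condition_names)
    repeats.write_msat_table(msats, out / "msats.bed", dialect="bed")
    _write_run_log(config, prefilter, trace, out / "run_log.json")
    (out / "report.txt").write_text(make_report(table, trace, prefilter))
    return PipelineResult(
        candidates=candidates, table=table, trace=trace, msats=msats,
        prefilter_counts=prefilter, out_dir=out,
    )


def _write_run_log(
    config: RunConfig,
    prefilter: list[tuple[str, int]],
    trace: scoring.FilterTrace,
    path: Path,
) -> None:
    cfg = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    cfg["min_repeats"] = {str(k): v for k, v in cfg["min_repeats"].items()}
    payload = {
        "tool": "msiscan",
        "version": _pkg_version("msiscan"),
        "config": cfg,
        "seed": config.seed,
        "prefilter_counts": [{"stage": s, "remaining": n} for s, n in prefilter],
        "cascade_trace": [{"stage": s, "remaining": n} for s, n in trace.stages],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


def replay_score_table(
    table: pd.DataFrame, out_dir: Path | None = None
) -> tuple[pd.DataFrame, scoring.FilterTrace]:
    """Score-stage entry point: run the cascade on a pre-computed score table."""
    retained, trace = scoring.cascade_on_scores(table)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        retained.to_csv(out / "candidates.tsv", sep="\t", index=False)
        trace.to_tsv(out / "filter_trace.tsv")
        trace.to_json(out / "filter_trace.json")
    return retained, trace


def make_report(
    table: pd.DataFrame,
    trace: scoring.FilterTrace,
    prefilter: Sequence[tuple[str, int]] = (),
) -> str:
    """Human-readable run report: filter progression, per-motif-class counts
    and score distributions of the final candidates."""
    lines = ["Candidate MSI locus discovery report", "=" * 38, ""]
    if prefilter:
        lines.append("Pre-cascade variant filtering")
        lines.append("-" * 29)
        for stage, count in prefilter:
            lines.append(f"  {stage:<28} {count:>8}")
        lines.append("")
    lines.append("Filter progression")
    lines.append("-" * 18)
    for stage, count in trace.stages:
        lines.append(f"  {stage:<28} {count:>8}")
    lines.append("")
    lines.append(f"Final candidates: {len(table)}")
    if len(table) and "Motif" in table.columns:
        unit_len = (
            table["Motif"].str.extract(r"\(([ACGT]+)\)", expand=False).str.len()
        )
        by_class = unit_len.map({2: "di", 3: "tri", 4: "tetra"}).value_counts()
        lines.append("")
        lines.append("Candidates per motif class")
        lines.append("-" * 26)
        for cls in ("di", "tri", "tetra"):
            lines.append(f"  {cls:<8} {int(by_class.get(cls, 0)):>6}")
    score_cols = [
        c for c in ("Score10", "Score30", "ScoreControl") if c in table.columns
    ]
    if len(table) and score_cols:
        lines.append("")
        lines.append("Score distributions (percent)")
        lines.append("-" * 29)
        desc = table[score_cols].describe().loc[["min", "25%", "50%", "75%", "max"]]
        lines.append("  " + "\t".join(["stat"] + score_cols))
        for stat, row in desc.iterrows():
            lines.append(
                "  " + "\t".join([stat] + [f"{v:.2f}" for v in row.tolist()])
            )
    lines.append("")
    return "\n".join(lines)
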