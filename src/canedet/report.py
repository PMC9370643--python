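"""Pipeline orchestration and the summary report.

``run_pipeline`` executes the stages in order — DET calling per comparison,
genotype-exclusive calling, Venn partitioning, same-direction intersection
of colonized vs. bacteria-free comparisons, term enrichment — writes every
stage table as TSV, and renders a plain-text summary whose every number can
be re-derived from the shipped tables.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .det import (
    Call,
    ComparisonSpec,
    DetTable,
    ReplicateMode,
    call_dets,
    call_exclusive,
)
from .enrich import Adjustment, enrich_terms, write_enrichment_tsv
from .errors import SpecificationError
from .io import (
    AnnotationMap,
    CountMatrix,
    LibraryDescriptor,
    n_material_groups,
    read_annotation_map,
    read_count_matrix,
    read_sample_sheet,
)
from .setops import DirectionalSet, common_pattern, mapping_percentage, region_counts, venn_partition

logger = logging.getLogger("canedet")


@dataclass
class PipelineConfig:
    """Inputs, comparisons and thresholds for one pipeline run."""

    counts_path: str
    lengths_path: str
    sample_sheet_path: str
    outdir: str
    annotation_path: str | None = None
    totals_path: str | None = None
    comparisons: list[dict] = field(default_factory=list)
    # pairs of comparison labels: (naturally colonized, bacteria-free)
    common_pattern_pairs: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = 0.05
    min_abs_log2fc: float = 0.0
    pseudo: float = 0.25
    min_positive_libraries: int = 5
    enrichment_alpha: float = 0.05
    enrichment_adjust: str = "NONE"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        pairs = [tuple(p) for p in data.pop("common_pattern_pairs", [])]
        return cls(common_pattern_pairs=pairs, **data)

    def comparison_specs(self) -> list[ComparisonSpec]:
        specs = []
        for c in self.comparisons:
            specs.append(
                ComparisonSpec(
                    label=c["label"],
                    group_a=tuple(c["group_a"]),
                    group_b=tuple(c["group_b"]),
                    replicate_mode=ReplicateMode(c.get("replicate_mode", "POOLED")),
                )
            )
        return specs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    matrix: CountMatrix | None = None,
    sheet: Sequence[LibraryDescriptor] | None = None,
    annotations: AnnotationMap | None = None,
) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``.

    In-memory inputs may be passed directly (the simulate subcommand does);
    otherwise they are read from the configured paths.  Returns a summary
    dictionary mirroring the written report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage io: loading inputs")
    if matrix is None:
        matrix = read_count_matrix(config.counts_path, config.lengths_path, config.totals_path)
    if sheet is None:
        sheet = read_sample_sheet(config.sample_sheet_path)
    if annotations is None and config.annotation_path:
        annotations = read_annotation_map(config.annotation_path)

    summary: dict = {
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "n_libraries": len(sheet),
        "n_material_groups": n_material_groups(sheet),
        "n_transcripts": len(matrix.transcript_ids),
        "thresholds": {
            "alpha": config.alpha,
            "min_abs_log2fc": config.min_abs_log2fc,
            "pseudo": config.pseudo,
            "min_positive_libraries": config.min_positive_libraries,
            "enrichment_alpha": config.enrichment_alpha,
            "enrichment_adjust": config.enrichment_adjust,
        },
    }

    # --- stage det -------------------------------------------------------
    logger.info("stage det: %d comparisons", len(config.comparisons))
    det_tables: dict[str, DetTable] = {}
    det_counts: dict[str, dict[str, int]] = {}
    for spec in config.comparison_specs():
        table = call_dets(
            matrix,
            spec,
            alpha=config.alpha,
            min_abs_log2fc=config.min_abs_log2fc,
            pseudo=config.pseudo,
        )
        table.write_tsv(outdir / f"det_{spec.label}.tsv")
        det_tables[spec.label] = table
        det_counts[spec.label] = table.counts_by_direction()
    summary["det_counts_by_direction"] = det_counts
    all_dets = set()
    for table in det_tables.values():
        all_dets |= set(table.called.index)
    summary["total_distinct_dets"] = len(all_dets)

    # --- stage exclusive -------------------------------------------------
    logger.info("stage exclusive")
    exclusive = call_exclusive(matrix, sheet, config.min_positive_libraries)
    with open(outdir / "exclusive.tsv", "w") as fh:
        fh.write("transcript_id\texclusive_to\n")
        for t, e in sorted(exclusive.items()):
            fh.write(f"{t}\t{e.value}\n")
    summary["exclusive_counts"] = {
        "EXCLUSIVE_A": sum(1 for e in exclusive.values() if e.value == "EXCLUSIVE_A"),
        "EXCLUSIVE_B": sum(1 for e in exclusive.values() if e.value == "EXCLUSIVE_B"),
    }
    summary["exclusive_also_det"] = len(set(exclusive) & all_dets)

    # --- stage intersect -------------------------------------------------
    directional = {
        label: DirectionalSet.from_det_table(table) for label, table in det_tables.items()
    }
    if len(directional) >= 2:
        logger.info("stage intersect: venn over %d sets", len(directional))
        partition = venn_partition(list(directional.values()), ignore_direction=True)
        counts = region_counts(partition)
        with open(outdir / "venn_regions.tsv", "w") as fh:
            fh.write("region\tcount\ttranscript_ids\n")
            for sig in sorted(counts, key=lambda s: (len(s), sorted(s))):
                ids = ",".join(sorted(str(m) for m in partition[sig]))
                fh.write(f"{'&'.join(sorted(sig))}\t{counts[sig]}\t{ids}\n")
        summary["venn_region_counts"] = {
            "&".join(sorted(sig)): c for sig, c in counts.items()
        }

    pattern_counts: dict[str, int] = {}
    for colonized_label, free_label in config.common_pattern_pairs:
        if colonized_label not in directional or free_label not in directional:
            raise SpecificationError(
                f"common-pattern pair ({colonized_label}, {free_label}) references unknown comparisons"
            )
        shared = common_pattern(directional[colonized_label], directional[free_label])
        pattern_counts[f"{colonized_label}&{free_label}"] = len(shared)
        with open(outdir / f"common_pattern_{colonized_label}__{free_label}.tsv", "w") as fh:
            fh.write("transcript_id\tdirection\n")
            for t, d in sorted(shared):
                fh.write(f"{t}\t{d.value}\n")
    if pattern_counts:
        # tissues are disjoint, so the total is the plain sum
        summary["common_pattern_counts"] = pattern_counts
        summary["common_pattern_total"] = sum(pattern_counts.values())

    # --- stage enrich ----------------------------------------------------
    if annotations is not None:
        logger.info("stage enrich")
        background = annotations.annotated_transcripts & set(matrix.transcript_ids)
        enrichment_summary = {}
        for label, table in det_tables.items():
            foreground = set(table.called.index) & background
            if not foreground:
                enrichment_summary[label] = {"n_foreground": 0, "n_significant": 0}
                continue
            records = enrich_terms(
                foreground,
                annotations,
                background,
                alpha=config.enrichment_alpha,
                adjust=Adjustment(config.enrichment_adjust),
            )
            write_enrichment_tsv(records, outdir / f"enrichment_{label}.tsv")
            enrichment_summary[label] = {
                "n_foreground": len(foreground),
                "n_significant": sum(r.significant for r in records),
            }
        summary["enrichment"] = enrichment_summary
        summary["annotated_percent"] = mapping_percentage(
            len(background), len(matrix.transcript_ids)
        )

    # --- report ----------------------------------------------------------
    _write_summary_text(summary, outdir / "summary.txt")
    manifest = {
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in {
                "counts": config.counts_path,
                "lengths": config.lengths_path,
                "sample_sheet": config.sample_sheet_path,
                "annotation": config.annotation_path,
            }.items()
            if p and Path(p).exists()
        },
        "parameters": summary["thresholds"],
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _write_summary_text(summary: Mapping, path: Path) -> None:
    lines = [
        "canedet pipeline summary",
        "========================",
        f"version: {summary['version']}   run: {summary['timestamp']}",
        f"libraries: {summary['n_libraries']} ({summary['n_material_groups']} material groups)",
        f"transcripts: {summary['n_transcripts']}",
        "",
        "thresholds: "
        + ", ".join(f"{k}={v}" for k, v in summary["thresholds"].items()),
        "",
        "DET counts by direction (UP_A = higher in group A):",
    ]
    for label, counts in summary.get("det_counts_by_direction", {}).items():
        lines.append(f"  {label}: UP_A={counts['UP_A']}  UP_B={counts['UP_B']}")
    lines.append(f"distinct DETs across comparisons: {summary.get('total_distinct_dets', 0)}")
    excl = summary.get("exclusive_counts", {})
    lines.append(
        f"exclusive transcripts: high-BNF={excl.get('EXCLUSIVE_A', 0)} "
        f"low-BNF={excl.get('EXCLUSIVE_B', 0)} "
        f"(also called DET: {summary.get('exclusive_also_det', 0)})"
    )
    if "venn_region_counts" in summary:
        lines.append("")
        lines.append("Venn regions:")
        for sig, count in sorted(summary["venn_region_counts"].items()):
            lines.append(f"  {sig}: {count}")
    if "common_pattern_counts" in summary:
        lines.append("")
        lines.append("same-direction (colonized & bacteria-free) transcripts:")
        for pair, count in summary["common_pattern_counts"].items():
            lines.append(f"  {pair}: {count}")
        lines.append(f"  total (disjoint tissues): {summary['common_pattern_total']}")
    if "enrichment" in summary:
        lines.append("")
        lines.append("enrichment (significant terms per comparison):")
        for label, info in summary["enrichment"].items():
            lines.append(
                f"  {label}: foreground={info['n_foreground']} significant={info['n_significant']}"
            )
        lines.append(f"annotated transcripts: {summary['annotated_percent']}%")
    path.write_text("\n".join(lines) + "\n")
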