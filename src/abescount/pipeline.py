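"""End-to-end orchestration: PSM tables in, tiered classification out.

Stages run in a fixed order -- confidence filter, dataset-wide unique
peptide map, per-run counting, per-replicate evidence, classification,
optional annotation summary -- and all tabular outputs are sorted by
protein accession so reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation_summary import SummaryReport, summarize_report, write_report_json
from .psm_io import (
    AnnotationRow,
    ExclusionEntry,
    PSMRecord,
    read_annotations,
    read_exclusions,
    read_psm_table,
)
from .selection import (
    ClassificationResult,
    EvidenceRecord,
    build_evidence,
    classify_all,
    write_classification_table,
    write_summary_json,
)
from .spectral_counting import (
    CountingConfig,
    RunCounts,
    count_run,
    filter_confident,
    split_runs,
    unique_peptide_map,
)

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_paths", "config_hash"]


@dataclass(frozen=True)
class PipelineResult:
    counts: tuple[RunCounts, ...]
    evidence: Mapping[str, EvidenceRecord]
    results: tuple[ClassificationResult, ...]
    tally: dict
    report: SummaryReport | None


def config_hash(cfg: CountingConfig) -> str:
    payload = json.dumps(
        {
            "protein_prob_cutoff": cfg.protein_prob_cutoff,
            "peptide_prob_cutoff": cfg.peptide_prob_cutoff,
            "spectrum_prob_cutoff": cfg.spectrum_prob_cutoff,
            "ratio_threshold": cfg.ratio_threshold,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    records: Sequence[PSMRecord],
    cfg: CountingConfig = CountingConfig(),
    exclusions: Iterable[ExclusionEntry] = (),
    annotations: Sequence[AnnotationRow] | None = None,
    out_dir: Path | str | None = None,
) -> PipelineResult:
    """Run the full selection procedure over in-memory records.

    When ``out_dir`` is given, writes ``classification.tsv``,
    ``summary.json`` (tally + thresholds + config hash) and, if
    annotations were supplied, ``report.json``.
    """
    confident = filter_confident(records, cfg)
    unique_map, _dropped = unique_peptide_map(confident)
    counts = tuple(
        count_run(run_records, unique_map, cfg)
        for run, run_records in sorted(
            split_runs(confident).items(),
            key=lambda kv: (kv[0].replicate, kv[0].condition.value),
        )
        if run_records
    )
    evidence = build_evidence(counts, cfg)
    results, tally = classify_all(evidence, exclusions)
    report = summarize_report(results, annotations) if annotations is not None else None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_classification_table(results, out_dir / "classification.tsv")
        write_summary_json(
            tally, cfg, out_dir / "summary.json", extra={"config_hash": config_hash(cfg)}
        )
        if report is not None:
            write_report_json(report, out_dir / "report.json")
    return PipelineResult(
        counts=counts,
        evidence=evidence,
        results=tuple(results),
        tally=tally,
        report=report,
    )


def run_pipeline_paths(
    psm_paths: Sequence[Path | str],
    cfg: CountingConfig = CountingConfig(),
    exclusion_path: Path | str | None = None,
    annotation_path: Path | str | None = None,
    out_dir: Path | str | None = None,
) -> PipelineResult:
    """File-based entry point: read the tables, then :func:`run_pipeline`."""
    records: list[PSMRecord] = []
    for path in psm_paths:
        records.extend(read_psm_table(path))
    exclusions = read_exclusions(exclusion_path) if exclusion_path else ()
    annotations = read_annotations(annotation_path) if annotation_path else None
    return run_pipeline(
        records, cfg, exclusions=exclusions, annotations=annotations, out_dir=out_dir
    )
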