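"""Descriptive cross-tabulations over the high-confidence protein set.

Functional-class percentages, kinase-class tallies, TMD-count buckets,
predicted lipid-modification site tallies and the overlap with the
detergent-resistant-membrane (DRM) proteome are all *descriptive*
summaries over annotation inputs produced by external predictors; nothing
here is predicted or inferred.  Two reference tables ship as package
fixtures: the 52 S-acylated protein kinases with their iTAK classes, and
the 24 S-acylated DRM-enriched proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .psm_io import AnnotationRow, ValidationError
from .selection import Category, ClassificationResult

__all__ = [
    "KinaseTableRow",
    "DRMOverlap",
    "SummaryReport",
    "load_kinase_table",
    "load_drm_table",
    "summarize_kinase_classes",
    "summarize_drm_overlap",
    "summarize_report",
    "write_report_json",
]


@dataclass(frozen=True)
class KinaseTableRow:
    """One kinase family row: label, numeric class, member accessions."""

    family_label: str
    kinase_class: int
    accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValidationError(
                f"kinase family {self.family_label!r} has no accessions"
            )


@dataclass(frozen=True)
class DRMOverlap:
    n_drm_enriched: int
    n_overlap: int
    n_overlap_with_sites: int

    @property
    def overlap_fraction(self) -> float:
        return self.n_overlap / self.n_drm_enriched if self.n_drm_enriched else 0.0


@dataclass(frozen=True)
class SummaryReport:
    """Cross-tabulation of the high-confidence set against its annotations."""

    n_total: int
    by_functional_class: Mapping[str, tuple[int, int]]  # label -> (count, pct)
    by_kinase_class: Mapping[int, int]
    tmd_distribution: Mapping[str, int]  # buckets "0", "1", "2+"
    site_tallies: Mapping[str, int]  # palmitoylation / myristoylation / prenylation
    drm_overlap: DRMOverlap


def _fixture_text(name: str) -> str:
    return (resources.files("abescount") / "data" / name).read_text(encoding="utf-8")


def load_kinase_table() -> list[KinaseTableRow]:
    """Load the packaged S-acylated protein-kinase reference table.

    The flat fixture stores one accession per line; rows sharing a family
    label and class are folded into one :class:`KinaseTableRow`.
    """
    families: dict[tuple[str, int], list[str]] = {}
    lines = _fixture_text("table1_kinases.tsv").splitlines()
    for line in lines[1:]:
        if not line:
            continue
        label, class_s, accession = line.split("\t")
        families.setdefault((label, int(class_s)), []).append(accession)
    return [
        KinaseTableRow(label, kclass, tuple(accs))
        for (label, kclass), accs in families.items()
    ]


def load_drm_table() -> list[tuple[str, str]]:
    """Load the packaged DRM-enriched S-acylated protein table.

    Returns (accession, description) pairs; an accession can recur when two
    gene models share a description, so callers needing the protein set
    should deduplicate.
    """
    rows: list[tuple[str, str]] = []
    lines = _fixture_text("table2_drm.tsv").splitlines()
    for line in lines[1:]:
        if not line:
            continue
        accession, description = line.split("\t")
        rows.append((accession, description))
    return rows


def summarize_kinase_classes(
    rows: Sequence[KinaseTableRow],
) -> tuple[dict[int, int], int]:
    """Count kinases per numeric class; returns (class -> count, total).

    An accession appearing in more than one row is a validation error.
    """
    seen: set[str] = set()
    by_class: dict[int, int] = {}
    total = 0
    for row in rows:
        for acc in row.accessions:
            if acc in seen:
                raise ValidationError(
                    f"accession {acc!r} appears in more than one kinase row"
                )
            seen.add(acc)
        by_class[row.kinase_class] = by_class.get(row.kinase_class, 0) + len(row.accessions)
        total += len(row.accessions)
    return dict(sorted(by_class.items())), total


def summarize_drm_overlap(
    classification: Sequence[ClassificationResult],
    annotations: Sequence[AnnotationRow],
) -> DRMOverlap:
    """Overlap between DRM-enriched proteins and the HIGH tier.

    Missing ``drm_enriched`` flags count as False; ``n_overlap_with_sites``
    additionally requires at least one predicted palmitoylation site.
    """
    high = {r.protein_id for r in classification if r.category is Category.HIGH}
    n_drm = 0
    n_overlap = 0
    n_sites = 0
    for a in annotations:
        if not a.drm_enriched:
            continue
        n_drm += 1
        if a.protein_id in high:
            n_overlap += 1
            if a.palm_site_count is not None and a.palm_site_count >= 1:
                n_sites += 1
    return DRMOverlap(n_drm, n_overlap, n_sites)


def summarize_report(
    classification: Sequence[ClassificationResult],
    annotations: Sequence[AnnotationRow],
) -> SummaryReport:
    """Cross-tabulate annotations over the HIGH-tier proteins.

    Functional-class percentages are reported to the whole percent;
    proteins without an annotation row or with an empty label fall into
    the "unknown" class, so class counts always sum to the HIGH total.
    TMD counts are bucketed 0 / 1 / 2+ over proteins with a non-missing
    count; site tallies count proteins with at least one predicted site
    of each kind.
    """
    high = sorted({r.protein_id for r in classification if r.category is Category.HIGH})
    ann_by_id = {a.protein_id: a for a in annotations}
    n_total = len(high)

    class_counts: dict[str, int] = {}
    kinase_counts: dict[int, int] = {}
    tmd = {"0": 0, "1": 0, "2+": 0}
    sites = {"palmitoylation": 0, "myristoylation": 0, "prenylation": 0}
    for pid in high:
        a = ann_by_id.get(pid)
        label = (a.functional_class if a else "") or "unknown"
        class_counts[label] = class_counts.get(label, 0) + 1
        if a is None:
            continue
        if a.kinase_class is not None:
            kinase_counts[a.kinase_class] = kinase_counts.get(a.kinase_class, 0) + 1
        if a.tmd_count is not None:
            bucket = "2+" if a.tmd_count >= 2 else str(a.tmd_count)
            tmd[bucket] += 1
        if a.palm_site_count is not None and a.palm_site_count >= 1:
            sites["palmitoylation"] += 1
        if a.myristoylated:
            sites["myristoylation"] += 1
        if a.prenylated:
            sites["prenylation"] += 1

    by_functional = {
        label: (count, round(100 * count / n_total) if n_total else 0)
        for label, count in sorted(class_counts.items())
    }
    return SummaryReport(
        n_total=n_total,
        by_functional_class=by_functional,
        by_kinase_class=dict(sorted(kinase_counts.items())),
        tmd_distribution=tmd,
        site_tallies=sites,
        drm_overlap=summarize_drm_overlap(classification, annotations),
    )


def write_report_json(report: SummaryReport, path: Path | str) -> None:
    payload = {
        "n_total": report.n_total,
        "by_functional_class": {
            label: {"count": c, "percent": p}
            for label, (c, p) in report.by_functional_class.items()
        },
        "by_kinase_class": {str(k): v for k, v in report.by_kinase_class.items()},
        "tmd_distribution": dict(report.tmd_distribution),
        "site_tallies": dict(report.site_tallies),
        "drm_overlap": {
            "n_drm_enriched": report.drm_overlap.n_drm_enriched,
            "n_overlap": report.drm_overlap.n_overlap,
            "n_overlap_with_sites": report.drm_overlap.n_overlap_with_sites,
        },
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
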