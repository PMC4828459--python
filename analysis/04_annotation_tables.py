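"""Tabulate the packaged reference tables.

Reproduces the descriptive tallies over the two packaged fixtures: the
kinase-class breakdown of the 52 S-acylated protein kinases and the
overlap between the high-confidence set and the 80-protein DRM-enriched
proteome.  Writes results/annotation_tables.json.

Run from the repository root:  python analysis/04_annotation_tables.py
"""

from __future__ import annotations

import json
from pathlib import Path

from abescount.annotation_summary import (
    load_drm_table,
    load_kinase_table,
    summarize_drm_overlap,
    summarize_kinase_classes,
)
from abescount.psm_io import AnnotationRow
from abescount.selection import Category, ClassificationResult, HighSubtype

ROOT = Path(__file__).resolve().parents[1]
N_DRM_TOTAL = 80


def main() -> None:
    by_class, total = summarize_kinase_classes(load_kinase_table())
    rlck = [r for r in load_kinase_table() if r.family_label.startswith("RLCK")]
    n_rlck = sum(len(r.accessions) for r in rlck)

    drm_accessions = sorted({acc for acc, _ in load_drm_table()})
    classification = [
        ClassificationResult(
            protein_id=acc,
            category=Category.HIGH,
            subtype=HighSubtype.PLUS_ONLY,
            exclusion_reason=None,
            rule_trace=("R1", "R2", "R3", "R4", "R5", "R6"),
            q=2, t=2, ever_in_minus=False,
        )
        for acc in drm_accessions
    ]
    annotations = [
        AnnotationRow(acc, drm_enriched=True) for acc in drm_accessions
    ] + [
        AnnotationRow(f"SYNTHFILL{i:03d}", drm_enriched=True)
        for i in range(N_DRM_TOTAL - len(drm_accessions))
    ]
    overlap = summarize_drm_overlap(classification, annotations)

    payload = {
        "kinases": {
            "total": total,
            "by_class": {str(k): v for k, v in by_class.items()},
            "rlck_families": n_rlck,
        },
        "drm": {
            "n_drm_enriched": overlap.n_drm_enriched,
            "n_overlap": overlap.n_overlap,
            "overlap_percent": round(100 * overlap.overlap_fraction, 1),
        },
    }
    results_dir = ROOT / "results"
    results_dir.mkdir(exist_ok=True)
    (results_dir / "annotation_tables.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    print(json.dumps(payload, indent=2, sort_keys=True))
    print(
        f"\nOf {total} S-acylated protein kinases, class 1 (receptor kinases "
        f"and relatives) dominates with {by_class[1]} members, {n_rlck} of "
        f"them receptor-like cytoplasmic kinases; {overlap.n_overlap} of the "
        f"{overlap.n_drm_enriched} DRM-enriched proteins are in the "
        f"high-confidence S-acylated set ({payload['drm']['overlap_percent']}%)."
    )


if __name__ == "__main__":
    main()
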