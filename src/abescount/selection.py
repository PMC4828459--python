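"""Replicate-aware selection and confidence-tiering of S-acylated candidates.

For each biological replicate a protein *qualifies* when it is identified
only in the +Hyd member of the pair, or when its +Hyd/-Hyd normalized
spectral-count ratio exceeds the threshold (a -Hyd normalized count of
zero counts as exceeding any threshold).  With q the number of qualifying
replicates and t the number of distinct unique peptides observed in +Hyd
runs overall, proteins are classified by an ordered decision table:

    R1  on the exclusion list              -> EXCLUDED
    R2  q == 0                             -> NOT_CANDIDATE
    R3  q == 1 and t == 1                  -> REMOVED_SINGLETON
    R4  q == 1 and t >= 2                  -> MEDIUM
    R5  q >= 2 and t == 1                  -> MEDIUM
    R6  q >= 2 and t >= 2                  -> HIGH

HIGH proteins are subtyped PLUS_ONLY when never identified in any -Hyd
run, else RATIO.  Requiring t >= 2 for HIGH is what makes the high tier
("two or more replicates") and the medium tier ("two replicates on a
single peptide") disjoint and exhaustive.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .psm_io import Condition, ExclusionEntry, ExclusionReason, ValidationError
from .spectral_counting import (
    CountingConfig,
    RatioKind,
    RatioValue,
    RunCounts,
    compute_ratio,
)

__all__ = [
    "Category",
    "HighSubtype",
    "EvidenceRecord",
    "ClassificationResult",
    "ConfigurationError",
    "build_evidence",
    "classify_protein",
    "classify_all",
    "tally_results",
    "write_classification_table",
    "read_classification_table",
    "write_summary_json",
]


class ConfigurationError(Exception):
    """The set of runs handed to the selection stage is incoherent."""


class Category(Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    REMOVED_SINGLETON = "REMOVED_SINGLETON"
    EXCLUDED = "EXCLUDED"
    NOT_CANDIDATE = "NOT_CANDIDATE"


class HighSubtype(Enum):
    PLUS_ONLY = "PLUS_ONLY"
    RATIO = "RATIO"
    NONE = "NONE"


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-protein digest of identification evidence across replicate pairs.

    ``ratios`` carries an entry for every replicate in which the protein was
    identified in at least one run of the pair.  ``q`` counts qualifying
    replicates, ``t`` the distinct unique peptides seen in +Hyd runs.
    """

    protein_id: str
    replicates: tuple[int, ...]
    identified_plus: Mapping[int, bool]
    identified_minus: Mapping[int, bool]
    unique_peptides_plus: Mapping[int, frozenset[str]]
    ratios: Mapping[int, RatioValue]
    qualifying: Mapping[int, bool]
    q: int
    t: int
    ever_in_minus: bool


@dataclass(frozen=True)
class ClassificationResult:
    protein_id: str
    category: Category
    subtype: HighSubtype
    exclusion_reason: ExclusionReason | None
    rule_trace: tuple[str, ...]
    q: int
    t: int
    ever_in_minus: bool


def build_evidence(
    counts: Iterable[RunCounts], cfg: CountingConfig
) -> dict[str, EvidenceRecord]:
    """Assemble per-protein evidence from the per-run count digests.

    Requires at most one run per (replicate, condition) and a +Hyd run for
    every replicate that has a -Hyd run.  Produces one record per protein
    identified in at least one run.
    """
    by_key: dict[tuple[int, Condition], RunCounts] = {}
    for rc in counts:
        key = (rc.run.replicate, rc.run.condition)
        if key in by_key:
            raise ConfigurationError(f"duplicate run for {rc.run}")
        by_key[key] = rc
    if not by_key:
        raise ConfigurationError("no runs supplied")
    replicates = sorted({rep for rep, _ in by_key})
    for rep in replicates:
        if (rep, Condition.PLUS_HYD) not in by_key and (rep, Condition.MINUS_HYD) in by_key:
            raise ConfigurationError(
                f"replicate {rep} has a -Hyd run but no +Hyd run"
            )

    universe: set[str] = set()
    for rc in by_key.values():
        universe.update(rc.identified)

    evidence: dict[str, EvidenceRecord] = {}
    for protein in sorted(universe):
        idp: dict[int, bool] = {}
        idm: dict[int, bool] = {}
        peps: dict[int, frozenset[str]] = {}
        ratios: dict[int, RatioValue] = {}
        qualifying: dict[int, bool] = {}
        for rep in replicates:
            plus = by_key.get((rep, Condition.PLUS_HYD))
            minus = by_key.get((rep, Condition.MINUS_HYD))
            in_plus = plus is not None and protein in plus.identified
            in_minus = minus is not None and protein in minus.identified
            idp[rep] = in_plus
            idm[rep] = in_minus
            peps[rep] = plus.unique_peptides.get(protein, frozenset()) if plus else frozenset()
            if in_plus or in_minus:
                if minus is None:
                    ratio = RatioValue(RatioKind.ONLY_PLUS)
                else:
                    ratio = compute_ratio(protein, plus, minus)
                ratios[rep] = ratio
                qualifying[rep] = (in_plus and not in_minus) or ratio.exceeds(
                    cfg.ratio_threshold
                )
            else:
                qualifying[rep] = False
        all_peps: set[str] = set()
        for s in peps.values():
            all_peps.update(s)
        evidence[protein] = EvidenceRecord(
            protein_id=protein,
            replicates=tuple(replicates),
            identified_plus=idp,
            identified_minus=idm,
            unique_peptides_plus=peps,
            ratios=ratios,
            qualifying=qualifying,
            q=sum(qualifying.values()),
            t=len(all_peps),
            ever_in_minus=any(idm.values()),
        )
    return evidence


def classify_protein(
    e: EvidenceRecord,
    exclusions: Mapping[str, ExclusionReason],
) -> ClassificationResult:
    """Apply the ordered decision table to one protein's evidence.

    ``rule_trace`` lists the rules evaluated in order; the last entry is the
    rule that fired.
    """
    trace: list[str] = []

    def result(category: Category, subtype: HighSubtype = HighSubtype.NONE,
               reason: ExclusionReason | None = None) -> ClassificationResult:
        return ClassificationResult(
            protein_id=e.protein_id,
            category=category,
            subtype=subtype,
            exclusion_reason=reason,
            rule_trace=tuple(trace),
            q=e.q,
            t=e.t,
            ever_in_minus=e.ever_in_minus,
        )

    trace.append("R1")
    if e.protein_id in exclusions:
        return result(Category.EXCLUDED, reason=exclusions[e.protein_id])
    trace.append("R2")
    if e.q == 0:
        return result(Category.NOT_CANDIDATE)
    trace.append("R3")
    if e.q == 1 and e.t == 1:
        return result(Category.REMOVED_SINGLETON)
    trace.append("R4")
    if e.q == 1:
        return result(Category.MEDIUM)
    trace.append("R5")
    if e.t == 1:
        return result(Category.MEDIUM)
    trace.append("R6")
    subtype = HighSubtype.RATIO if e.ever_in_minus else HighSubtype.PLUS_ONLY
    return result(Category.HIGH, subtype=subtype)


def _exclusion_mapping(
    exclusions: Iterable[ExclusionEntry] | Mapping[str, ExclusionReason],
) -> Mapping[str, ExclusionReason]:
    if isinstance(exclusions, Mapping):
        return exclusions
    return {e.protein_id: e.reason for e in exclusions}


def classify_all(
    evidence: Mapping[str, EvidenceRecord],
    exclusions: Iterable[ExclusionEntry] | Mapping[str, ExclusionReason] = (),
) -> tuple[list[ClassificationResult], dict]:
    """Classify every protein with evidence; return results and a tally.

    Results are sorted by protein_id.  The tally maps each category to a
    count and splits HIGH by subtype; categories partition the universe, so
    the counts sum to ``len(evidence)``.
    """
    mapping = _exclusion_mapping(exclusions)
    results = [
        classify_protein(evidence[p], mapping) for p in sorted(evidence)
    ]
    return results, tally_results(results)


def tally_results(results: Sequence[ClassificationResult]) -> dict:
    counts = Counter(r.category.value for r in results)
    subtypes = Counter(
        r.subtype.value for r in results if r.category is Category.HIGH
    )
    return {
        "n_proteins": len(results),
        "by_category": {c.value: counts.get(c.value, 0) for c in Category},
        "high_subtypes": {
            s.value: subtypes.get(s.value, 0)
            for s in (HighSubtype.PLUS_ONLY, HighSubtype.RATIO)
        },
    }


_CLASSIFICATION_COLUMNS = (
    "protein_id",
    "category",
    "subtype",
    "q",
    "t",
    "ever_in_minus",
    "exclusion_reason",
    "rule_trace",
)


def write_classification_table(
    results: Sequence[ClassificationResult], path: Path | str
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(_CLASSIFICATION_COLUMNS) + "\n")
        for r in sorted(results, key=lambda x: x.protein_id):
            handle.write(
                "\t".join(
                    (
                        r.protein_id,
                        r.category.value,
                        r.subtype.value,
                        str(r.q),
                        str(r.t),
                        "true" if r.ever_in_minus else "false",
                        r.exclusion_reason.value if r.exclusion_reason else "",
                        ",".join(r.rule_trace),
                    )
                )
                + "\n"
            )


def read_classification_table(path: Path | str) -> list[ClassificationResult]:
    """Re-read a classification table written by :func:`write_classification_table`."""
    path = Path(path)
    results: list[ClassificationResult] = []
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if header != "\t".join(_CLASSIFICATION_COLUMNS):
            raise ValidationError(f"{path}: unexpected classification header")
        for row, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_CLASSIFICATION_COLUMNS):
                raise ValidationError(f"{path} row {row}: wrong field count")
            pid, cat, sub, q_s, t_s, ever, reason_s, trace_s = fields
            results.append(
                ClassificationResult(
                    protein_id=pid,
                    category=Category(cat),
                    subtype=HighSubtype(sub),
                    exclusion_reason=ExclusionReason(reason_s) if reason_s else None,
                    rule_trace=tuple(trace_s.split(",")) if trace_s else (),
                    q=int(q_s),
                    t=int(t_s),
                    ever_in_minus=ever == "true",
                )
            )
    return results


def write_summary_json(
    tally: dict, cfg: CountingConfig, path: Path | str, extra: Mapping | None = None
) -> None:
    """Write the run summary with the thresholds echoed for provenance."""
    payload = dict(tally)
    payload["thresholds"] = {
        "protein_prob_cutoff": cfg.protein_prob_cutoff,
        "peptide_prob_cutoff": cfg.peptide_prob_cutoff,
        "spectrum_prob_cutoff": cfg.spectrum_prob_cutoff,
        "ratio_threshold": cfg.ratio_threshold,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
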