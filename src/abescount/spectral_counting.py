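"""Label-free spectral counting with +Hyd/-Hyd enrichment ratios.

The counting model: peptide-spectrum matches are first filtered on protein
and peptide posterior probabilities (inclusive cutoffs, default 0.95).
Peptides mapping to two or more proteins anywhere in the dataset are shared
and contribute to no protein; proteins left without unique peptides are
dropped.  Within each run, spectra strictly above the spectrum-probability
cutoff (default 0.5) are indexed per protein, and counts are normalized to
the total number of spectra counted in that run (NSC).  The +Hyd/-Hyd NSC
ratio is finite only for proteins identified in both members of a replicate
pair; one-sided identifications are carried as categorical outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .psm_io import Condition, PSMRecord, RunLabel

__all__ = [
    "CountingConfig",
    "RunCounts",
    "RatioKind",
    "RatioValue",
    "ContractError",
    "filter_confident",
    "unique_peptide_map",
    "count_run",
    "compute_ratio",
    "split_runs",
    "write_count_matrix",
]


class ContractError(Exception):
    """A caller violated an operation's precondition."""


@dataclass(frozen=True)
class CountingConfig:
    """Cutoffs and threshold governing counting and candidate selection.

    protein_prob_cutoff, peptide_prob_cutoff
        Inclusive lower bounds on the ProteinProphet / PeptideProphet-style
        posteriors a match must carry to count as confident (default 0.95).
    spectrum_prob_cutoff
        Exclusive lower bound on the spectrum-level probability for a
        spectrum to be indexed (default 0.5: strictly *above*).
    ratio_threshold
        Strict lower bound on the +Hyd/-Hyd normalized-count ratio for a
        replicate to qualify a protein (default 4).
    """

    protein_prob_cutoff: float = 0.95
    peptide_prob_cutoff: float = 0.95
    spectrum_prob_cutoff: float = 0.5
    ratio_threshold: float = 4.0

    def __post_init__(self) -> None:
        for name in ("protein_prob_cutoff", "peptide_prob_cutoff", "spectrum_prob_cutoff"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.ratio_threshold <= 0:
            raise ValueError(f"ratio_threshold must be > 0, got {self.ratio_threshold!r}")


@dataclass(frozen=True)
class RunCounts:
    """Per-run spectral-count digest.

    ``identified`` holds every protein with at least one confident unique
    peptide in the run, whether or not any of its spectra cleared the
    spectrum-probability cutoff; ``raw`` maps each identified protein to its
    indexed spectrum count (possibly 0) and ``normalized`` to raw/total
    (empty when total == 0).
    """

    run: RunLabel
    raw: Mapping[str, int]
    total: int
    normalized: Mapping[str, float]
    identified: frozenset[str]
    unique_peptides: Mapping[str, frozenset[str]]


def filter_confident(records: Sequence[PSMRecord], cfg: CountingConfig) -> list[PSMRecord]:
    """Keep matches whose protein AND peptide probabilities meet the cutoffs."""
    return [
        r
        for r in records
        if r.protein_probability >= cfg.protein_prob_cutoff
        and r.peptide_probability >= cfg.peptide_prob_cutoff
    ]


def unique_peptide_map(
    records: Sequence[PSMRecord],
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Map each protein to its unique peptides; report proteins left with none.

    Uniqueness is assessed dataset-wide: a peptide sequence associated with
    two or more distinct proteins anywhere in ``records`` (including within
    a single multi-accession record) is shared and contributes to no
    protein.  Returns ``(protein -> unique peptide set, dropped proteins)``
    where the dropped set holds proteins observed in the records but
    identified by shared peptides only.
    """
    owners: dict[str, set[str]] = {}
    all_proteins: set[str] = set()
    for r in records:
        all_proteins.update(r.protein_ids)
        owners.setdefault(r.peptide_sequence, set()).update(r.protein_ids)
    unique: dict[str, set[str]] = {}
    for peptide, prots in owners.items():
        if len(prots) == 1:
            (p,) = prots
            unique.setdefault(p, set()).add(peptide)
    frozen = {p: frozenset(peps) for p, peps in unique.items()}
    dropped = frozenset(all_proteins - frozen.keys())
    return frozen, dropped


def split_runs(records: Iterable[PSMRecord]) -> dict[RunLabel, list[PSMRecord]]:
    """Group records by run, preserving input order within each run."""
    by_run: dict[RunLabel, list[PSMRecord]] = {}
    for r in records:
        by_run.setdefault(r.run, []).append(r)
    return by_run


def count_run(
    records: Sequence[PSMRecord],
    unique_map: Mapping[str, frozenset[str]],
    cfg: CountingConfig,
) -> RunCounts:
    """Index confident spectra for one run and normalize to the run total.

    ``records`` must be confident records from a single run; ``unique_map``
    is the dataset-wide unique-peptide map.  A record contributes to
    protein ``p`` iff its peptide is a unique peptide of ``p`` and its
    spectrum probability is strictly above the cutoff.  A protein counts as
    identified in the run if it has at least one confident unique-peptide
    record, regardless of spectrum-level probability.
    """
    if not records:
        raise ContractError("count_run requires at least one record to define the run")
    run = records[0].run
    if any(r.run != run for r in records):
        raise ContractError("count_run received records from more than one run")

    peptide_owner = {
        pep: p for p, peps in unique_map.items() for pep in peps
    }
    raw: dict[str, int] = {}
    unique_seen: dict[str, set[str]] = {}
    for r in records:
        owner = peptide_owner.get(r.peptide_sequence)
        if owner is None:
            continue
        unique_seen.setdefault(owner, set()).add(r.peptide_sequence)
        raw.setdefault(owner, 0)
        if r.psm_probability > cfg.spectrum_prob_cutoff:
            raw[owner] += 1
    total = sum(raw.values())
    normalized = (
        {p: c / total for p, c in raw.items()} if total > 0 else {}
    )
    return RunCounts(
        run=run,
        raw=raw,
        total=total,
        normalized=normalized,
        identified=frozenset(unique_seen),
        unique_peptides={p: frozenset(s) for p, s in unique_seen.items()},
    )


class RatioKind(Enum):
    FINITE = "FINITE"
    ONLY_PLUS = "ONLY_PLUS"
    ONLY_MINUS = "ONLY_MINUS"
    PLUS_OVER_ZERO = "PLUS_OVER_ZERO"


@dataclass(frozen=True)
class RatioValue:
    """Outcome of the +Hyd/-Hyd normalized-count comparison for one protein.

    ``value`` is present (non-negative) iff ``kind`` is FINITE.  A protein
    identified in both runs whose -Hyd normalized count is zero gets
    PLUS_OVER_ZERO, which downstream treats as exceeding any threshold.
    """

    kind: RatioKind
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind is RatioKind.FINITE:
            if self.value is None or self.value < 0:
                raise ValueError("FINITE ratio requires a non-negative value")
        elif self.value is not None:
            raise ValueError(f"{self.kind.value} ratio must not carry a value")

    def exceeds(self, threshold: float) -> bool:
        """True if this outcome counts as 'ratio > threshold'."""
        if self.kind is RatioKind.FINITE:
            return self.value > threshold
        return self.kind is RatioKind.PLUS_OVER_ZERO


def compute_ratio(protein_id: str, plus: RunCounts, minus: RunCounts) -> RatioValue:
    """Compare one protein's normalized counts across a replicate pair.

    ``plus`` and ``minus`` must be the +Hyd and -Hyd runs of the same
    replicate; the protein must be identified in at least one of them.
    """
    if plus.run.condition is not Condition.PLUS_HYD or minus.run.condition is not Condition.MINUS_HYD:
        raise ContractError("compute_ratio expects (+Hyd, -Hyd) runs in that order")
    if plus.run.replicate != minus.run.replicate:
        raise ContractError(
            f"runs are from different replicates: {plus.run} vs {minus.run}"
        )
    in_plus = protein_id in plus.identified
    in_minus = protein_id in minus.identified
    if not in_plus and not in_minus:
        raise ContractError(
            f"protein {protein_id!r} identified in neither run of replicate "
            f"{plus.run.replicate}"
        )
    if in_plus and not in_minus:
        return RatioValue(RatioKind.ONLY_PLUS)
    if in_minus and not in_plus:
        return RatioValue(RatioKind.ONLY_MINUS)
    norm_minus = minus.normalized.get(protein_id, 0.0)
    if norm_minus == 0.0:
        return RatioValue(RatioKind.PLUS_OVER_ZERO)
    norm_plus = plus.normalized.get(protein_id, 0.0)
    return RatioValue(RatioKind.FINITE, norm_plus / norm_minus)


def write_count_matrix(counts: Iterable[RunCounts], path: Path | str) -> None:
    """Write the per-run count matrix, rows sorted for reproducible diffs."""
    path = Path(path)
    header = (
        "protein_id",
        "replicate",
        "condition",
        "raw_count",
        "normalized_count",
        "n_unique_peptides",
        "identified",
    )
    rows = []
    for rc in counts:
        for p in sorted(rc.identified):
            rows.append(
                (
                    p,
                    str(rc.run.replicate),
                    rc.run.condition.value,
                    str(rc.raw.get(p, 0)),
                    repr(rc.normalized.get(p, 0.0)),
                    str(len(rc.unique_peptides.get(p, ()))),
                    "true",
                )
            )
    rows.sort()
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")
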