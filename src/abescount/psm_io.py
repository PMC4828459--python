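"""Reading, validation and writing of the flat PSM interchange tables.

Every downstream stage of the pipeline consumes the types defined here.  The
interchange format is a bespoke tab-separated table (one row per
peptide-spectrum match) rather than pepXML/protXML: the three posterior
probabilities attached to each match are the only fields the selection
procedure needs, and a flat table keeps fixtures and the synthetic generator
trivial.  ``;`` is the reserved separator inside the ``protein_ids`` column,
so accessions may not contain it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Condition",
    "RunLabel",
    "PSMRecord",
    "ExclusionReason",
    "ExclusionEntry",
    "AnnotationRow",
    "TableFormatError",
    "ValidationError",
    "PSM_COLUMNS",
    "EXCLUSION_COLUMNS",
    "ANNOTATION_COLUMNS",
    "read_psm_table",
    "write_psm_table",
    "read_exclusions",
    "write_exclusion_table",
    "read_annotations",
    "write_annotation_table",
]


class TableFormatError(Exception):
    """Structural problem with a table file (header, column count)."""


class ValidationError(Exception):
    """A row or field violates the interchange contract."""


class Condition(enum.Enum):
    """Hydroxylamine treatment arm of a run.

    ``PLUS_HYD`` is the experimental sample (thioesters cleaved, formerly
    S-acylated cysteines biotinylated); ``MINUS_HYD`` is the untreated
    control capturing nonspecific background.
    """

    PLUS_HYD = "PLUS"
    MINUS_HYD = "MINUS"

    @classmethod
    def parse(cls, token: str) -> "Condition":
        for member in cls:
            if member.value == token:
                return member
        raise ValidationError(
            f"unknown condition {token!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


@dataclass(frozen=True, order=True)
class RunLabel:
    """Identity of one LC-MS/MS run: biological replicate x condition."""

    replicate: int
    condition: Condition = field(compare=True)

    def __post_init__(self) -> None:
        if not isinstance(self.replicate, int) or self.replicate < 1:
            raise ValidationError(
                f"replicate must be a positive integer, got {self.replicate!r}"
            )
        if not isinstance(self.condition, Condition):
            raise ValidationError(f"invalid condition {self.condition!r}")

    def __str__(self) -> str:
        sign = "+" if self.condition is Condition.PLUS_HYD else "-"
        return f"{sign}Hyd_{self.replicate}"


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {value!r}")


def _check_accession(acc: str) -> None:
    if not acc:
        raise ValidationError("empty protein accession")
    if ";" in acc:
        raise ValidationError(
            f"accession {acc!r} contains the reserved separator ';'"
        )
    if "\t" in acc or "\n" in acc:
        raise ValidationError(f"accession {acc!r} contains whitespace control characters")


@dataclass(frozen=True)
class PSMRecord:
    """One spectrum-to-peptide match with its three posterior probabilities.

    ``protein_ids`` is the ordered, duplicate-free tuple of accessions the
    peptide maps to; more than one accession marks a shared peptide.
    Peptide identity is the bare sequence string -- variable modifications
    are not part of identity, matching a peptide-sequence-level export.
    """

    run: RunLabel
    spectrum_id: str
    peptide_sequence: str
    protein_ids: tuple[str, ...]
    psm_probability: float
    peptide_probability: float
    protein_probability: float

    def __post_init__(self) -> None:
        if not self.spectrum_id:
            raise ValidationError("spectrum_id must be non-empty")
        seq = self.peptide_sequence
        if not seq or not all("A" <= c <= "Z" for c in seq):
            raise ValidationError(
                f"peptide_sequence must match ^[A-Z]+$, got {seq!r}"
            )
        if not self.protein_ids:
            raise ValidationError("protein_ids must be non-empty")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError(
                f"duplicate accessions in protein_ids {self.protein_ids!r}"
            )
        for acc in self.protein_ids:
            _check_accession(acc)
        _check_probability("psm_probability", self.psm_probability)
        _check_probability("peptide_probability", self.peptide_probability)
        _check_probability("protein_probability", self.protein_probability)

    @property
    def is_shared(self) -> bool:
        """True if the peptide maps to more than one protein in this record."""
        return len(self.protein_ids) > 1


class ExclusionReason(enum.Enum):
    """Why a protein is struck from the candidate list regardless of evidence."""

    RIBOSOMAL = "RIBOSOMAL"
    THIOESTER = "THIOESTER"

    @classmethod
    def parse(cls, token: str) -> "ExclusionReason":
        for member in cls:
            if member.value == token:
                return member
        raise ValidationError(
            f"unknown exclusion reason {token!r}; allowed: "
            f"{[m.value for m in cls]}"
        )


@dataclass(frozen=True)
class ExclusionEntry:
    protein_id: str
    reason: ExclusionReason

    def __post_init__(self) -> None:
        _check_accession(self.protein_id)
        if not isinstance(self.reason, ExclusionReason):
            raise ValidationError(f"invalid reason {self.reason!r}")


@dataclass(frozen=True)
class AnnotationRow:
    """Per-protein external predictions and category labels.

    These fields are consumed as inputs for cross-tabulation only; the
    underlying predictions (TMD topology, palmitoylation / myristoylation /
    prenylation sites, kinase classification) come from external programs
    and are never computed here.  ``None`` encodes a missing value.
    """

    protein_id: str
    functional_class: str = ""
    kinase_family: str = ""
    kinase_class: int | None = None
    tmd_count: int | None = None
    palm_site_count: int | None = None
    myristoylated: bool | None = None
    prenylated: bool | None = None
    drm_enriched: bool | None = None

    def __post_init__(self) -> None:
        _check_accession(self.protein_id)
        for name in ("tmd_count", "palm_site_count"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value!r}")


PSM_COLUMNS = (
    "replicate",
    "condition",
    "spectrum_id",
    "peptide_sequence",
    "protein_ids",
    "psm_probability",
    "peptide_probability",
    "protein_probability",
)
EXCLUSION_COLUMNS = ("protein_id", "reason")
ANNOTATION_COLUMNS = (
    "protein_id",
    "functional_class",
    "kinase_family",
    "kinase_class",
    "tmd_count",
    "palm_site_count",
    "myristoylated",
    "prenylated",
    "drm_enriched",
)


def _read_rows(path: Path | str, columns: Sequence[str]) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        expected = "\t".join(columns)
        if header != expected:
            got = header.split("\t")
            missing = [c for c in columns if c not in got]
            detail = f"missing or misnamed column(s): {missing}" if missing else "wrong column order"
            raise TableFormatError(
                f"{path}: bad header ({detail}); expected {expected!r}"
            )
        for row_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise TableFormatError(
                    f"{path} row {row_number}: expected {len(columns)} fields, "
                    f"got {len(fields)}"
                )
            yield row_number, fields


def _parse_float(path: Path | str, row: int, name: str, token: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValidationError(
            f"{path} row {row}: {name} is not a number: {token!r}"
        ) from None


def read_psm_table(path: Path | str) -> list[PSMRecord]:
    """Read a PSM table, validating every row.

    Raises :class:`TableFormatError` for structural problems and
    :class:`ValidationError` (citing the 1-based data row) for field-level
    violations, including duplicate spectrum identifiers within a run.
    Accessions listed in ``protein_ids`` are split on ``;`` with order
    preserved and duplicates collapsed.
    """
    records: list[PSMRecord] = []
    seen: set[tuple[RunLabel, str]] = set()
    for row, fields in _read_rows(path, PSM_COLUMNS):
        (rep_s, cond_s, spectrum_id, peptide, prot_s, psm_s, pep_s, protp_s) = fields
        try:
            try:
                replicate = int(rep_s)
            except ValueError:
                raise ValidationError(f"replicate is not an integer: {rep_s!r}") from None
            run = RunLabel(replicate, Condition.parse(cond_s))
            protein_ids = tuple(dict.fromkeys(p for p in prot_s.split(";")))
            record = PSMRecord(
                run=run,
                spectrum_id=spectrum_id,
                peptide_sequence=peptide,
                protein_ids=protein_ids,
                psm_probability=_parse_float(path, row, "psm_probability", psm_s),
                peptide_probability=_parse_float(path, row, "peptide_probability", pep_s),
                protein_probability=_parse_float(path, row, "protein_probability", protp_s),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {row}: {exc}") from None
        key = (run, spectrum_id)
        if key in seen:
            raise ValidationError(
                f"{path} row {row}: duplicate spectrum_id {spectrum_id!r} in run {run}"
            )
        seen.add(key)
        records.append(record)
    return records


def write_psm_table(records: Iterable[PSMRecord], path: Path | str) -> None:
    """Write records in the PSM interchange format.

    Floats are written with ``repr`` so that read(write(X)) == X exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(PSM_COLUMNS) + "\n")
        for r in records:
            handle.write(
                "\t".join(
                    (
                        str(r.run.replicate),
                        r.run.condition.value,
                        r.spectrum_id,
                        r.peptide_sequence,
                        ";".join(r.protein_ids),
                        repr(r.psm_probability),
                        repr(r.peptide_probability),
                        repr(r.protein_probability),
                    )
                )
                + "\n"
            )


def read_exclusions(path: Path | str) -> list[ExclusionEntry]:
    """Read the two-column exclusion table.

    A protein listed twice with conflicting reasons is an error; exact
    duplicates are collapsed.
    """
    entries: list[ExclusionEntry] = []
    reasons: dict[str, ExclusionReason] = {}
    for row, (protein_id, reason_s) in _read_rows(path, EXCLUSION_COLUMNS):
        try:
            entry = ExclusionEntry(protein_id, ExclusionReason.parse(reason_s))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {row}: {exc}") from None
        previous = reasons.get(protein_id)
        if previous is not None:
            if previous is not entry.reason:
                raise ValidationError(
                    f"{path} row {row}: protein {protein_id!r} listed with "
                    f"conflicting reasons {previous.value} and {entry.reason.value}"
                )
            continue
        reasons[protein_id] = entry.reason
        entries.append(entry)
    return entries


def write_exclusion_table(entries: Iterable[ExclusionEntry], path: Path | str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(EXCLUSION_COLUMNS) + "\n")
        for e in entries:
            handle.write(f"{e.protein_id}\t{e.reason.value}\n")


_BOOL_TOKENS: Mapping[str, bool] = {
    "true": True, "false": False, "1": True, "0": False,
}


def _parse_optional_int(path, row, name, token: str) -> int | None:
    if token == "":
        return None
    try:
        return int(token)
    except ValueError:
        raise ValidationError(f"{path} row {row}: {name} is not an integer: {token!r}") from None


def _parse_optional_bool(path, row, name, token: str) -> bool | None:
    if token == "":
        return None
    try:
        return _BOOL_TOKENS[token.lower()]
    except KeyError:
        raise ValidationError(
            f"{path} row {row}: {name} must be true/false/1/0 or empty, got {token!r}"
        ) from None


def read_annotations(path: Path | str) -> list[AnnotationRow]:
    """Read an annotation table; empty strings encode missing values."""
    rows: list[AnnotationRow] = []
    seen: set[str] = set()
    for row, fields in _read_rows(path, ANNOTATION_COLUMNS):
        (pid, fclass, kfam, kclass_s, tmd_s, palm_s, myr_s, pre_s, drm_s) = fields
        if pid in seen:
            raise ValidationError(f"{path} row {row}: duplicate protein_id {pid!r}")
        seen.add(pid)
        try:
            rows.append(
                AnnotationRow(
                    protein_id=pid,
                    functional_class=fclass,
                    kinase_family=kfam,
                    kinase_class=_parse_optional_int(path, row, "kinase_class", kclass_s),
                    tmd_count=_parse_optional_int(path, row, "tmd_count", tmd_s),
                    palm_site_count=_parse_optional_int(path, row, "palm_site_count", palm_s),
                    myristoylated=_parse_optional_bool(path, row, "myristoylated", myr_s),
                    prenylated=_parse_optional_bool(path, row, "prenylated", pre_s),
                    drm_enriched=_parse_optional_bool(path, row, "drm_enriched", drm_s),
                )
            )
        except ValidationError as exc:
            msg = str(exc)
            raise ValidationError(
                msg if str(path) in msg else f"{path} row {row}: {exc}"
            ) from None
    return rows


def _fmt_optional(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_annotation_table(rows: Iterable[AnnotationRow], path: Path | str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in rows:
            handle.write(
                "\t".join(
                    (
                        a.protein_id,
                        a.functional_class,
                        a.kinase_family,
                        _fmt_optional(a.kinase_class),
                        _fmt_optional(a.tmd_count),
                        _fmt_optional(a.palm_site_count),
                        _fmt_optional(a.myristoylated),
                        _fmt_optional(a.prenylated),
                        _fmt_optional(a.drm_enriched),
                    )
                )
                + "\n"
            )
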