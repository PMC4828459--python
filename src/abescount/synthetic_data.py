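"""Seeded synthetic PSM experiments with planted protein classes.

The generator emulates the computational input of a paired ABE enrichment
study: three biological replicates, each with a +Hyd (experimental) and
-Hyd (control) run, emitted as flat PSM tables.  Proteins are planted in
five classes:

* ``TRUE_ACYL_EXCLUSIVE``  -- S-acylated, absent from every control run.
* ``TRUE_ACYL_ENRICHED``   -- S-acylated but leaky: present in controls at
  an abundance several-fold below the +Hyd level.
* ``NONSPECIFIC``          -- background binders, equal abundance in both arms.
* ``CONTAMINANT_RIBOSOMAL``-- abundant ribosomal background, equal in both
  arms, always emitted on the exclusion list.
* ``LOW_EVIDENCE``         -- a single unique peptide in a single +Hyd run,
  the singleton pattern the selection step removes.

Spectrum counts per (protein, run) are Poisson with a class- and
condition-specific mean, optionally jittered per replicate; spectra are
spread uniformly over the protein's peptides; a configurable fraction of
peptides is shared between two proteins.  Posterior probabilities come
from Beta distributions -- concentrated near 1 for planted-real matches
and near 0 for injected noise -- so the 0.95/0.95/0.5 cutoffs are
exercised.  Identical config and seed give byte-identical tables.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .psm_io import (
    Condition,
    ExclusionEntry,
    ExclusionReason,
    PSMRecord,
    RunLabel,
    ValidationError,
    write_exclusion_table,
    write_psm_table,
)
from .selection import Category, ClassificationResult

__all__ = [
    "ProteinClass",
    "GeneratorConfig",
    "SyntheticExperiment",
    "RecoveryReport",
    "generate_experiment",
    "write_experiment",
    "read_truth",
    "write_truth",
    "evaluate_recovery",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ProteinClass(enum.Enum):
    TRUE_ACYL_EXCLUSIVE = "TRUE_ACYL_EXCLUSIVE"
    TRUE_ACYL_ENRICHED = "TRUE_ACYL_ENRICHED"
    NONSPECIFIC = "NONSPECIFIC"
    CONTAMINANT_RIBOSOMAL = "CONTAMINANT_RIBOSOMAL"
    LOW_EVIDENCE = "LOW_EVIDENCE"


_CLASS_PREFIX = {
    ProteinClass.TRUE_ACYL_EXCLUSIVE: "ACYLX",
    ProteinClass.TRUE_ACYL_ENRICHED: "ACYLE",
    ProteinClass.NONSPECIFIC: "NSPEC",
    ProteinClass.CONTAMINANT_RIBOSOMAL: "RIBOS",
    ProteinClass.LOW_EVIDENCE: "LOWEV",
}

_DEFAULT_COUNTS = {
    ProteinClass.TRUE_ACYL_EXCLUSIVE: 50,
    ProteinClass.TRUE_ACYL_ENRICHED: 50,
    ProteinClass.NONSPECIFIC: 50,
    ProteinClass.CONTAMINANT_RIBOSOMAL: 50,
    ProteinClass.LOW_EVIDENCE: 50,
}

# (lambda_plus, lambda_minus): mean spectra per protein per run.  The
# acylated classes sit at 20 spectra in +Hyd; the leaky class carries an
# 8-fold raw enrichment; nonspecific binders are condition-balanced; the
# ribosomal contaminant is the classic high-abundance background of
# affinity purifications, equally present in both arms.
_DEFAULT_LAMBDA = {
    ProteinClass.TRUE_ACYL_EXCLUSIVE: (20.0, 0.0),
    ProteinClass.TRUE_ACYL_ENRICHED: (20.0, 2.5),
    ProteinClass.NONSPECIFIC: (10.0, 10.0),
    ProteinClass.CONTAMINANT_RIBOSOMAL: (40.0, 40.0),
    ProteinClass.LOW_EVIDENCE: (3.0, 0.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for one simulated experiment.

    ``class_lambda`` maps each class to (mean +Hyd spectra, mean -Hyd
    spectra) per protein per run.  ``true_score_shape`` parameterizes the
    Beta law for peptide- and protein-level posteriors of planted-real
    matches, ``true_psm_shape`` the spectrum-level posterior, and
    ``decoy_score_shape`` all three posteriors of injected noise records.
    ``replicate_jitter_sigma`` is the log-normal sigma of the per
    (protein, replicate, condition) multiplicative abundance jitter, which
    is what makes sub-threshold replicate evidence (q < 3) arise naturally.
    """

    n_replicates: int = 3
    class_counts: Mapping[ProteinClass, int] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTS)
    )
    class_lambda: Mapping[ProteinClass, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LAMBDA)
    )
    peptides_per_protein: int = 5
    shared_peptide_fraction: float = 0.10
    true_score_shape: tuple[float, float] = (80.0, 1.0)
    true_psm_shape: tuple[float, float] = (4.0, 1.0)
    decoy_score_shape: tuple[float, float] = (1.0, 12.0)
    replicate_jitter_sigma: float = 0.3
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        counts = {c: int(self.class_counts.get(c, 0)) for c in ProteinClass}
        if any(v < 0 for v in counts.values()):
            raise ValueError("class counts must be non-negative")
        if all(v == 0 for v in counts.values()):
            raise ValueError("empty experiment: all class counts are zero")
        for c in ProteinClass:
            lp, lm = self.class_lambda.get(c, _DEFAULT_LAMBDA[c])
            if lp < 0 or lm < 0:
                raise ValueError(f"negative Poisson mean for {c.value}")
        if not (0.0 <= self.shared_peptide_fraction < 1.0):
            raise ValueError("shared_peptide_fraction must be in [0, 1)")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        if self.replicate_jitter_sigma < 0:
            raise ValueError("replicate_jitter_sigma must be >= 0")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")

    @classmethod
    def from_json(cls, path: Path | str) -> "GeneratorConfig":
        """Load a config from JSON, with enum keys given by class name."""
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        kwargs = dict(raw)
        if "class_counts" in kwargs:
            kwargs["class_counts"] = {
                ProteinClass(k): int(v) for k, v in kwargs["class_counts"].items()
            }
        if "class_lambda" in kwargs:
            kwargs["class_lambda"] = {
                ProteinClass(k): (float(v[0]), float(v[1]))
                for k, v in kwargs["class_lambda"].items()
            }
        for name in ("true_score_shape", "true_psm_shape", "decoy_score_shape"):
            if name in kwargs:
                kwargs[name] = tuple(float(x) for x in kwargs[name])
        return cls(**kwargs)


@dataclass(frozen=True)
class SyntheticExperiment:
    """A generated experiment: PSM tables per run, truth labels, exclusions."""

    records_by_run: Mapping[RunLabel, tuple[PSMRecord, ...]]
    truth: Mapping[str, ProteinClass]
    exclusions: tuple[ExclusionEntry, ...]

    @property
    def all_records(self) -> list[PSMRecord]:
        out: list[PSMRecord] = []
        for run in sorted(self.records_by_run, key=lambda r: (r.replicate, r.condition.value)):
            out.extend(self.records_by_run[run])
        return out


def _random_peptide(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        length = int(rng.integers(9, 15))
        pep = "".join(rng.choice(_AMINO_ACIDS, size=length))
        if pep not in taken:
            taken.add(pep)
            return pep


def generate_experiment(cfg: GeneratorConfig) -> SyntheticExperiment:
    """Generate one seeded experiment.

    Deterministic: a fixed draw order over proteins, replicates and
    conditions means identical config+seed reproduce the experiment
    byte-for-byte once written.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- protein universe -------------------------------------------------
    proteins: list[str] = []
    truth: dict[str, ProteinClass] = {}
    for pclass in ProteinClass:
        n = int(cfg.class_counts.get(pclass, 0))
        for i in range(n):
            pid = f"{_CLASS_PREFIX[pclass]}{i:04d}"
            proteins.append(pid)
            truth[pid] = pclass

    # --- peptide assignment ------------------------------------------------
    taken: set[str] = set()
    peptides: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    for pid in proteins:
        n_pep = 1 if truth[pid] is ProteinClass.LOW_EVIDENCE else cfg.peptides_per_protein
        plist: list[tuple[str, tuple[str, ...]]] = []
        for _ in range(n_pep):
            pep = _random_peptide(rng, taken)
            owners: tuple[str, ...] = (pid,)
            if (
                truth[pid] is not ProteinClass.LOW_EVIDENCE
                and len(proteins) > 1
                and rng.random() < cfg.shared_peptide_fraction
            ):
                partner = pid
                while partner == pid:
                    partner = proteins[int(rng.integers(len(proteins)))]
                owners = (pid, partner)
            plist.append((pep, owners))
        peptides[pid] = plist

    # home run for each LOW_EVIDENCE protein: one +Hyd run only
    low_home = {
        pid: 1 + int(rng.integers(cfg.n_replicates))
        for pid in proteins
        if truth[pid] is ProteinClass.LOW_EVIDENCE
    }

    # --- spectra ------------------------------------------------------------
    a_true, b_true = cfg.true_score_shape
    a_psm, b_psm = cfg.true_psm_shape
    a_dec, b_dec = cfg.decoy_score_shape
    sigma = cfg.replicate_jitter_sigma
    records_by_run: dict[RunLabel, list[PSMRecord]] = {}
    for rep in range(1, cfg.n_replicates + 1):
        for condition in (Condition.PLUS_HYD, Condition.MINUS_HYD):
            run = RunLabel(rep, condition)
            records: list[PSMRecord] = []
            counter = 0
            for pid in proteins:
                pclass = truth[pid]
                lam_plus, lam_minus = cfg.class_lambda.get(pclass, _DEFAULT_LAMBDA[pclass])
                lam = lam_plus if condition is Condition.PLUS_HYD else lam_minus
                if pclass is ProteinClass.LOW_EVIDENCE:
                    if condition is Condition.MINUS_HYD or rep != low_home[pid]:
                        continue
                    count = 1 + int(rng.poisson(max(lam - 1.0, 0.0)))
                else:
                    if lam == 0.0:
                        continue
                    if sigma > 0:
                        lam = lam * float(rng.lognormal(0.0, sigma))
                    count = int(rng.poisson(lam))
                if count == 0:
                    continue
                plist = peptides[pid]
                choices = rng.integers(len(plist), size=count)
                for j in choices:
                    pep, owners = plist[int(j)]
                    counter += 1
                    records.append(
                        PSMRecord(
                            run=run,
                            spectrum_id=f"{run.condition.value}{rep}_{counter:06d}",
                            peptide_sequence=pep,
                            protein_ids=owners,
                            psm_probability=float(rng.beta(a_psm, b_psm)),
                            peptide_probability=float(rng.beta(a_true, b_true)),
                            protein_probability=float(rng.beta(a_true, b_true)),
                        )
                    )
            # injected noise: random low-probability matches
            n_noise = int(rng.poisson(cfg.noise_rate * len(records)))
            for _ in range(n_noise):
                pid = proteins[int(rng.integers(len(proteins)))]
                pep = _random_peptide(rng, taken)
                counter += 1
                records.append(
                    PSMRecord(
                        run=run,
                        spectrum_id=f"{run.condition.value}{rep}_{counter:06d}",
                        peptide_sequence=pep,
                        protein_ids=(pid,),
                        psm_probability=float(rng.beta(a_dec, b_dec)),
                        peptide_probability=float(rng.beta(a_dec, b_dec)),
                        protein_probability=float(rng.beta(a_dec, b_dec)),
                    )
                )
            records_by_run[run] = records

    exclusions = tuple(
        ExclusionEntry(pid, ExclusionReason.RIBOSOMAL)
        for pid in proteins
        if truth[pid] is ProteinClass.CONTAMINANT_RIBOSOMAL
    )
    return SyntheticExperiment(
        records_by_run={k: tuple(v) for k, v in records_by_run.items()},
        truth=truth,
        exclusions=exclusions,
    )


def write_experiment(experiment: SyntheticExperiment, out_dir: Path | str) -> list[Path]:
    """Write PSM tables (one per run), truth.tsv and exclusions.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for run in sorted(
        experiment.records_by_run, key=lambda r: (r.replicate, r.condition.value)
    ):
        tag = "plus" if run.condition is Condition.PLUS_HYD else "minus"
        path = out_dir / f"BR{run.replicate}_{tag}.tsv"
        write_psm_table(experiment.records_by_run[run], path)
        written.append(path)
    truth_path = out_dir / "truth.tsv"
    write_truth(experiment.truth, truth_path)
    written.append(truth_path)
    excl_path = out_dir / "exclusions.tsv"
    write_exclusion_table(experiment.exclusions, excl_path)
    written.append(excl_path)
    return written


def write_truth(truth: Mapping[str, ProteinClass], path: Path | str) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("protein_id\tplanted_class\n")
        for pid in sorted(truth):
            handle.write(f"{pid}\t{truth[pid].value}\n")


def read_truth(path: Path | str) -> dict[str, ProteinClass]:
    truth: dict[str, ProteinClass] = {}
    with Path(path).open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if header != "protein_id\tplanted_class":
            raise ValidationError(f"{path}: unexpected truth-table header")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, label = line.split("\t")
            truth[pid] = ProteinClass(label)
    return truth


_TRUE_CLASSES = frozenset(
    {ProteinClass.TRUE_ACYL_EXCLUSIVE, ProteinClass.TRUE_ACYL_ENRICHED}
)
_FALSE_CLASSES = frozenset(
    {ProteinClass.NONSPECIFIC, ProteinClass.CONTAMINANT_RIBOSOMAL}
)


@dataclass(frozen=True)
class RecoveryReport:
    """Recovery of the planted classes by the selection procedure.

    ``sensitivity`` is the fraction of planted S-acylated proteins
    (exclusive + enriched) landing in HIGH or MEDIUM;
    ``false_discovery_proportion`` the fraction of HIGH u MEDIUM that is
    nonspecific or contaminant.  ``confusion`` maps
    (planted class, category) to a protein count over the classified set.
    """

    sensitivity: float
    false_discovery_proportion: float
    confusion: Mapping[tuple[ProteinClass, Category], int]
    n_true: int
    n_selected: int

    def confusion_count(self, pclass: ProteinClass, category: Category) -> int:
        return self.confusion.get((pclass, category), 0)


def evaluate_recovery(
    classification: Sequence[ClassificationResult],
    truth: Mapping[str, ProteinClass],
) -> RecoveryReport:
    """Score a classification against the planted truth.

    Every classified protein must carry a truth label; unknown accessions
    are an error.  Planted proteins with no classification at all (never
    identified in any run) count against sensitivity.
    """
    unknown = sorted(
        {r.protein_id for r in classification} - set(truth)
    )
    if unknown:
        raise ValidationError(
            f"classified proteins missing from truth: {unknown[:10]}"
            + ("..." if len(unknown) > 10 else "")
        )
    category_by_id = {r.protein_id: r.category for r in classification}
    confusion: dict[tuple[ProteinClass, Category], int] = {}
    for pid, category in category_by_id.items():
        key = (truth[pid], category)
        confusion[key] = confusion.get(key, 0) + 1

    selected = {
        pid
        for pid, cat in category_by_id.items()
        if cat in (Category.HIGH, Category.MEDIUM)
    }
    true_ids = {pid for pid, c in truth.items() if c in _TRUE_CLASSES}
    n_true = len(true_ids)
    sensitivity = (
        len(true_ids & selected) / n_true if n_true else float("nan")
    )
    n_selected = len(selected)
    n_false = sum(1 for pid in selected if truth[pid] in _FALSE_CLASSES)
    fdp = n_false / n_selected if n_selected else 0.0
    return RecoveryReport(
        sensitivity=sensitivity,
        false_discovery_proportion=fdp,
        confusion=confusion,
        n_true=n_true,
        n_selected=n_selected,
    )
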