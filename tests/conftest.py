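"""Shared fixtures: record factories, random small datasets, and an
independent brute-force oracle for counting, evidence and classification.

The oracle is written directly from the selection rules as stated, with no
code shared with the package path it checks: plain loops over (peptide,
protein) pairs and an if/elif chain over the decision rules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pytest

from abescount.psm_io import Condition, PSMRecord, RunLabel
from abescount.spectral_counting import CountingConfig

PLUS = Condition.PLUS_HYD
MINUS = Condition.MINUS_HYD

_counter = itertools.count()


def make_record(
    replicate=1,
    condition=PLUS,
    peptide="ACDEFKK",
    proteins=("P1",),
    psm=0.9,
    pep=0.99,
    prot=0.99,
    spectrum_id=None,
) -> PSMRecord:
    if spectrum_id is None:
        spectrum_id = f"s{next(_counter):06d}"
    return PSMRecord(
        run=RunLabel(replicate, condition),
        spectrum_id=spectrum_id,
        peptide_sequence=peptide,
        protein_ids=tuple(proteins),
        psm_probability=psm,
        peptide_probability=pep,
        protein_probability=prot,
    )


@pytest.fixture
def cfg() -> CountingConfig:
    return CountingConfig()


def random_small_dataset(seed: int) -> list[PSMRecord]:
    """Up to 10 proteins and 50 spectra over 3 replicate pairs.

    Probabilities are drawn from a palette that includes the exact cutoff
    values 0.95 and 0.5 so boundary behaviour is exercised.
    """
    rng = np.random.default_rng(seed)
    n_prot = int(rng.integers(2, 11))
    proteins = [f"P{i}" for i in range(n_prot)]
    n_pep = int(rng.integers(n_prot, 3 * n_prot + 1))
    peptides = []
    for j in range(n_pep):
        owner = proteins[int(rng.integers(n_prot))]
        owners = (owner,)
        if n_prot > 1 and rng.random() < 0.2:  # shared peptide
            other = owner
            while other == owner:
                other = proteins[int(rng.integers(n_prot))]
            owners = (owner, other)
        suffix = chr(65 + j // 26) + chr(65 + j % 26)
        peptides.append((f"{'ACDEFGHIKLMNPQRSTVWY'[j % 20] * 3}PEP{suffix}", owners))
    palette = [0.0, 0.3, 0.5, 0.51, 0.9, 0.949, 0.95, 0.96, 0.99, 1.0]
    # every replicate gets one confident +Hyd anchor record so that a
    # -Hyd-only replicate (a configuration error by contract) cannot arise
    records = [
        make_record(
            replicate=rep,
            condition=PLUS,
            peptide=f"ANCHORPEPTIDE{'ABC'[rep - 1]}",
            proteins=("PANCHOR",),
            psm=0.9,
            pep=0.99,
            prot=0.99,
            spectrum_id=f"anchor{seed}_{rep}",
        )
        for rep in (1, 2, 3)
    ]
    n_spec = int(rng.integers(5, 51))
    for i in range(n_spec):
        rep = int(rng.integers(1, 4))
        cond = PLUS if rng.random() < 0.6 else MINUS
        pep, owners = peptides[int(rng.integers(n_pep))]
        records.append(
            make_record(
                replicate=rep,
                condition=cond,
                peptide=pep,
                proteins=owners,
                psm=float(rng.choice(palette)),
                pep=float(rng.choice(palette)),
                prot=float(rng.choice(palette)),
                spectrum_id=f"r{seed}_{i:04d}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleRun:
    raw: dict = field(default_factory=dict)
    total: int = 0
    normalized: dict = field(default_factory=dict)
    identified: set = field(default_factory=set)
    unique_peptides: dict = field(default_factory=dict)


def oracle_counts(records, cfg: CountingConfig):
    """Recompute per-run counts from first principles.

    Returns {(replicate, condition): OracleRun} plus the dataset-wide
    unique-peptide map and dropped-protein set.
    """
    confident = []
    for r in records:
        if r.protein_probability >= cfg.protein_prob_cutoff and \
                r.peptide_probability >= cfg.peptide_prob_cutoff:
            confident.append(r)

    peptide_proteins: dict[str, set[str]] = {}
    every_protein: set[str] = set()
    for r in confident:
        for p in r.protein_ids:
            peptide_proteins.setdefault(r.peptide_sequence, set()).add(p)
            every_protein.add(p)
    unique_of: dict[str, set[str]] = {}
    for pep, prots in peptide_proteins.items():
        if len(prots) == 1:
            unique_of.setdefault(next(iter(prots)), set()).add(pep)
    dropped = every_protein - set(unique_of)

    runs: dict[tuple[int, Condition], OracleRun] = {}
    run_keys = {(r.run.replicate, r.run.condition) for r in confident}
    for key in run_keys:
        orun = OracleRun()
        run_records = [
            r for r in confident
            if (r.run.replicate, r.run.condition) == key
        ]
        for protein, peps in unique_of.items():
            n_ided = [r for r in run_records if r.peptide_sequence in peps]
            if n_ided:
                orun.identified.add(protein)
                orun.unique_peptides[protein] = {
                    r.peptide_sequence for r in n_ided
                }
                orun.raw[protein] = sum(
                    1 for r in n_ided if r.psm_probability > cfg.spectrum_prob_cutoff
                )
        orun.total = sum(orun.raw.values())
        if orun.total > 0:
            orun.normalized = {p: c / orun.total for p, c in orun.raw.items()}
        runs[key] = orun
    return runs, unique_of, dropped


def oracle_classify(records, cfg: CountingConfig, exclusions: dict):
    """Re-derive the final category of every protein with evidence.

    ``exclusions`` maps protein_id to a reason.  Returns
    {protein: (category name, q, t)}.
    """
    runs, unique_of, _ = oracle_counts(records, cfg)
    replicates = sorted({rep for rep, _ in runs})
    universe = set()
    for orun in runs.values():
        universe |= orun.identified

    out = {}
    for protein in universe:
        q = 0
        peptides_plus = set()
        ever_in_minus = False
        for rep in replicates:
            plus = runs.get((rep, PLUS), OracleRun())
            minus = runs.get((rep, MINUS), OracleRun())
            in_plus = protein in plus.identified
            in_minus = protein in minus.identified
            peptides_plus |= plus.unique_peptides.get(protein, set())
            if in_minus:
                ever_in_minus = True
            qualifies = False
            if in_plus and not in_minus:
                qualifies = True
            elif in_plus and in_minus:
                nm = minus.normalized.get(protein, 0.0)
                if nm == 0.0:
                    qualifies = True  # +Hyd over zero exceeds any threshold
                else:
                    np_ = plus.normalized.get(protein, 0.0)
                    if np_ / nm > cfg.ratio_threshold:
                        qualifies = True
            if qualifies:
                q += 1
        t = len(peptides_plus)
        if protein in exclusions:
            category = "EXCLUDED"
        elif q == 0:
            category = "NOT_CANDIDATE"
        elif q == 1 and t == 1:
            category = "REMOVED_SINGLETON"
        elif q == 1 and t >= 2:
            category = "MEDIUM"
        elif q >= 2 and t == 1:
            category = "MEDIUM"
        else:
            category = "HIGH"
        out[protein] = (category, q, t, ever_in_minus)
    return out
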