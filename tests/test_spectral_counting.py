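"""Probability filtering, unique-peptide counting, normalization and ratios."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abescount.spectral_counting import (
    ContractError,
    CountingConfig,
    RatioKind,
    compute_ratio,
    count_run,
    filter_confident,
    split_runs,
    unique_peptide_map,
)

from conftest import MINUS, PLUS, make_record, oracle_counts, random_small_dataset


class TestFilterConfident:
    def test_cutoffs_are_inclusive(self, cfg):
        r = make_record(pep=0.95, prot=0.95)
        assert filter_confident([r], cfg) == [r]

    def test_just_below_cutoff_dropped(self, cfg):
        assert filter_confident([make_record(pep=0.949, prot=0.99)], cfg) == []
        assert filter_confident([make_record(pep=0.99, prot=0.949)], cfg) == []

    def test_mixed_fixture_keeps_four_in_order(self, cfg):
        records = [
            make_record(pep=0.99, prot=0.99),   # keep
            make_record(pep=0.95, prot=0.95),   # keep (boundary)
            make_record(pep=0.90, prot=0.99),   # drop: peptide
            make_record(pep=0.99, prot=0.90),   # drop: protein
            make_record(pep=1.0, prot=1.0),     # keep
            make_record(pep=0.96, prot=0.97),   # keep
        ]
        kept = filter_confident(records, cfg)
        assert kept == [records[0], records[1], records[4], records[5]]

    def test_psm_probability_is_ignored_here(self, cfg):
        assert filter_confident([make_record(psm=0.0)], cfg)


class TestUniquePeptideMap:
    def test_shared_peptide_contributes_to_no_protein(self):
        records = [
            make_record(peptide="AAAK", proteins=("P1",)),
            make_record(peptide="CCCK", proteins=("P1", "P2")),
        ]
        unique, dropped = unique_peptide_map(records)
        assert unique == {"P1": frozenset({"AAAK"})}
        assert dropped == frozenset({"P2"})

    def test_sharing_across_records_detected(self):
        # same peptide claimed by two proteins in separate single-accession rows
        records = [
            make_record(peptide="AAAK", proteins=("P1",)),
            make_record(peptide="AAAK", proteins=("P2",), replicate=2),
            make_record(peptide="DDDK", proteins=("P2",)),
        ]
        unique, dropped = unique_peptide_map(records)
        assert unique == {"P2": frozenset({"DDDK"})}
        assert dropped == frozenset({"P1"})

    def test_all_shared_drops_everything(self):
        records = [make_record(peptide="AAAK", proteins=("P1", "P2"))]
        unique, dropped = unique_peptide_map(records)
        assert unique == {}
        assert dropped == frozenset({"P1", "P2"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_datasets(self, seed, cfg):
        records = filter_confident(random_small_dataset(seed), cfg)
        unique, dropped = unique_peptide_map(records)
        _, oracle_unique, oracle_dropped = oracle_counts(records, cfg)
        assert {p: set(s) for p, s in unique.items()} == oracle_unique
        assert set(dropped) == oracle_dropped


class TestCountRun:
    def test_spectrum_at_exactly_half_not_counted(self, cfg):
        records = [make_record(peptide="AAAK", psm=0.5)]
        unique, _ = unique_peptide_map(records)
        rc = count_run(records, unique, cfg)
        assert rc.raw == {"P1": 0}
        assert rc.identified == {"P1"}
        assert rc.normalized == {}  # total is zero

    def test_normalization_is_fraction_of_total(self, cfg):
        records = [
            make_record(peptide="AAAK", proteins=("P1",)) for _ in range(8)
        ] + [make_record(peptide="CCCK", proteins=("P2",)) for _ in range(2)]
        unique, _ = unique_peptide_map(records)
        rc = count_run(records, unique, cfg)
        assert rc.raw == {"P1": 8, "P2": 2}
        assert rc.total == 10
        assert rc.normalized == {"P1": 0.8, "P2": 0.2}

    def test_mixed_runs_rejected(self, cfg):
        records = [make_record(replicate=1), make_record(replicate=2)]
        unique, _ = unique_peptide_map(records)
        with pytest.raises(ContractError):
            count_run(records, unique, cfg)

    @pytest.mark.parametrize("seed", range(10))
    def test_raw_counts_equal_bruteforce_tally(self, seed, cfg):
        records = filter_confident(random_small_dataset(seed), cfg)
        unique, _ = unique_peptide_map(records)
        oracle_runs, _, _ = oracle_counts(records, cfg)
        for run, run_records in split_runs(records).items():
            rc = count_run(run_records, unique, cfg)
            orun = oracle_runs[(run.replicate, run.condition)]
            assert dict(rc.raw) == orun.raw
            assert rc.identified == orun.identified
            assert rc.total == orun.total


def _pair(plus_counts: dict, minus_counts: dict, cfg, rep=1):
    """Build a (+Hyd, -Hyd) RunCounts pair from peptide->protein count specs."""
    runs = []
    for cond, spec in ((PLUS, plus_counts), (MINUS, minus_counts)):
        records = []
        for i, (protein, (n_spectra, psm)) in enumerate(sorted(spec.items())):
            for j in range(n_spectra):
                records.append(
                    make_record(
                        replicate=rep,
                        condition=cond,
                        peptide="PEPTIDE" + protein.translate(
                            str.maketrans("0123456789", "ABCDEFGHIJ")
                        ),
                        proteins=(protein,),
                        psm=psm,
                    )
                )
        runs.append(records)
    all_records = runs[0] + runs[1]
    unique, _ = unique_peptide_map(all_records)
    plus = count_run(runs[0], unique, cfg) if runs[0] else None
    minus = count_run(runs[1], unique, cfg) if runs[1] else None
    return plus, minus


class TestComputeRatio:
    def test_finite_ratio_arithmetic(self, cfg):
        # +Hyd: P1 8 of 100, -Hyd: P1 2 of 100 -> 0.08/0.02 = 4.0
        plus, minus = _pair(
            {"P1": (8, 0.9), "PX": (92, 0.9)},
            {"P1": (2, 0.9), "PX": (98, 0.9)},
            cfg,
        )
        ratio = compute_ratio("P1", plus, minus)
        assert ratio.kind is RatioKind.FINITE
        assert ratio.value == pytest.approx(4.0)
        assert not ratio.exceeds(4.0)  # strict threshold

    def test_only_plus(self, cfg):
        plus, minus = _pair({"P1": (5, 0.9)}, {"PX": (5, 0.9)}, cfg)
        assert compute_ratio("P1", plus, minus).kind is RatioKind.ONLY_PLUS

    def test_only_minus(self, cfg):
        plus, minus = _pair({"PX": (5, 0.9)}, {"P1": (5, 0.9)}, cfg)
        assert compute_ratio("P1", plus, minus).kind is RatioKind.ONLY_MINUS

    def test_identified_in_minus_with_zero_count_is_plus_over_zero(self, cfg):
        # P1 identified in -Hyd (confident peptide) but its spectrum is at 0.5
        plus, minus = _pair(
            {"P1": (5, 0.9)}, {"P1": (1, 0.5), "PX": (5, 0.9)}, cfg
        )
        ratio = compute_ratio("P1", plus, minus)
        assert ratio.kind is RatioKind.PLUS_OVER_ZERO
        assert ratio.exceeds(1e9)

    def test_neither_run_is_contract_violation(self, cfg):
        plus, minus = _pair({"PX": (5, 0.9)}, {"PX": (5, 0.9)}, cfg)
        with pytest.raises(ContractError):
            compute_ratio("P1", plus, minus)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_normalized_counts_sum_to_one(self, seed, cfg):
        records = filter_confident(random_small_dataset(seed), cfg)
        unique, _ = unique_peptide_map(records)
        for run_records in split_runs(records).values():
            rc = count_run(run_records, unique, cfg)
            if rc.total > 0:
                assert sum(rc.normalized.values()) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 5])
    def test_duplicating_spectra_preserves_normalization_and_ratios(self, k, cfg):
        records = random_small_dataset(3)
        confident = filter_confident(records, cfg)
        duplicated = []
        for copy in range(k):
            for r in confident:
                duplicated.append(
                    make_record(
                        replicate=r.run.replicate,
                        condition=r.run.condition,
                        peptide=r.peptide_sequence,
                        proteins=r.protein_ids,
                        psm=r.psm_probability,
                        pep=r.peptide_probability,
                        prot=r.protein_probability,
                        spectrum_id=f"dup{copy}_{r.spectrum_id}",
                    )
                )
        unique1, _ = unique_peptide_map(confident)
        uniquek, _ = unique_peptide_map(duplicated)
        assert unique1 == uniquek
        for run, run_records in split_runs(confident).items():
            rc1 = count_run(run_records, unique1, cfg)
            rck = count_run(
                [r for r in duplicated if r.run == run], uniquek, cfg
            )
            assert rck.total == k * rc1.total
            for p in rc1.normalized:
                assert rck.normalized[p] == pytest.approx(rc1.normalized[p])

    @given(st.integers(0, 1000), st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_raising_spectrum_cutoff_never_increases_counts(self, seed, cutoff):
        base = CountingConfig()
        higher = CountingConfig(spectrum_prob_cutoff=max(cutoff, base.spectrum_prob_cutoff))
        records = filter_confident(random_small_dataset(seed % 50), base)
        if not records:
            return
        unique, _ = unique_peptide_map(records)
        for run_records in split_runs(records).values():
            low = count_run(run_records, unique, base)
            high = count_run(run_records, unique, higher)
            for p, c in high.raw.items():
                assert c <= low.raw[p]
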