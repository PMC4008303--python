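"""Verdicts, swap decomposition, contamination estimation and combinatorics."""

import numpy as np
import pandas as pd
import pytest

from sasiseq.report import (
    SampleSheet,
    SampleSheetRow,
    build_pair_registry,
    classify_misattribution,
    decode_combinatorial,
    detect_swaps,
    estimate_contamination,
    pair_capacity,
    verify_samples,
)
from sasiseq.screen import AssuranceMatrix
from sasiseq.simulate import ContaminationEvent, count_level_simulate


def matrix_from(rows: dict[str, dict[int, int]]) -> AssuranceMatrix:
    cols = sorted({b for r in rows.values() for b in r})
    table = pd.DataFrame(0, index=list(rows), columns=cols, dtype=np.int64)
    for sid, counts in rows.items():
        for b, n in counts.items():
            table.loc[sid, b] = n
    return AssuranceMatrix(table)


def sheet_for(n: int, dose: float = 0.001) -> SampleSheet:
    return SampleSheet(
        [SampleSheetRow(f"S{i + 1}", i + 1, (i + 1,), dose) for i in range(n)]
    )


def matrix_for_replicate(counts: pd.DataFrame, rep: int, plex: int) -> AssuranceMatrix:
    sub = counts[counts.replicate == rep]
    table = sub.pivot_table(index="sample", columns="sasi_barcode", values="count",
                            fill_value=0, aggfunc="sum")
    table = table.reindex([f"S{i + 1}" for i in range(plex)], fill_value=0)
    return AssuranceMatrix(table.astype(np.int64))


class TestVerify:
    def test_diagonal_all_confirmed(self):
        m = matrix_from({f"S{i}": {i: 500} for i in range(1, 5)})
        verdicts = verify_samples(m, sheet_for(4))
        assert [v.status for v in verdicts] == ["confirmed"] * 4

    def test_low_evidence_below_floor(self):
        m = matrix_from({"S1": {1: 2}, "S2": {2: 400}})
        verdicts = verify_samples(m, sheet_for(2), min_reads=10)
        assert verdicts[0].status == "low_evidence"
        assert verdicts[1].status == "confirmed"

    def test_swapped_and_unidentified(self):
        m = matrix_from({"S1": {2: 300}, "S2": {1: 280}, "S3": {77: 250}})
        verdicts = verify_samples(m, sheet_for(3))
        assert [v.status for v in verdicts] == ["swapped", "swapped", "unidentified"]

    def test_contaminated_when_foreign_fraction_high(self):
        m = matrix_from({"S1": {1: 900, 2: 100}, "S2": {2: 1000}})
        verdicts = verify_samples(m, sheet_for(2))
        assert verdicts[0].status == "contaminated"
        assert verdicts[1].status == "confirmed"

    def test_row_scaling_invariance(self):
        rows = {"S1": {1: 900, 2: 100}, "S2": {2: 1000}, "S3": {3: 40, 1: 1}}
        base = [v.status for v in verify_samples(matrix_from(rows), sheet_for(3))]
        scaled = {
            sid: {b: n * 7 for b, n in counts.items()} for sid, counts in rows.items()
        }
        assert [v.status for v in verify_samples(matrix_from(scaled), sheet_for(3))] == base

    def test_missing_sample_rejected(self):
        m = matrix_from({"S1": {1: 100}})
        with pytest.raises(ValueError):
            verify_samples(m, sheet_for(2))


class TestSwaps:
    def test_identity_reports_nothing(self):
        m = matrix_from({f"S{i}": {i: 300} for i in range(1, 5)})
        assert detect_swaps(m, sheet_for(4)) == []

    def test_single_transposition(self):
        m = matrix_from({"S1": {1: 300}, "S2": {3: 310}, "S3": {2: 290}, "S4": {4: 305}})
        cycles = detect_swaps(m, sheet_for(4))
        assert len(cycles) == 1
        assert set(cycles[0]) == {"S2", "S3"}

    def test_three_cycle_decomposition(self):
        # material rotated S1->S2->S3->S1: S1's row shows S3's barcode etc.
        m = matrix_from({"S1": {2: 300}, "S2": {3: 310}, "S3": {1: 290}, "S4": {4: 300}})
        cycles = detect_swaps(m, sheet_for(4))
        assert len(cycles) == 1
        assert set(cycles[0]) == {"S1", "S2", "S3"}
        assert len(cycles[0]) == 3

    def test_applying_reported_swaps_restores_confirmation(self):
        """Involution consistency: relabelling the sheet by the reported
        2-cycles makes every sample verify as confirmed."""
        m = matrix_from({"S1": {2: 300}, "S2": {1: 310}, "S3": {3: 290}})
        sheet = sheet_for(3)
        cycles = detect_swaps(m, sheet)
        assert len(cycles) == 1 and len(cycles[0]) == 2
        a, b = cycles[0]
        remap = {a: b, b: a}
        fixed = SampleSheet(
            [
                SampleSheetRow(
                    remap.get(r.sample_id, r.sample_id),
                    r.library_barcode_id,
                    r.expected_sasi_ids,
                    r.dose,
                )
                for r in sheet
            ]
        )
        # rows keep their names; expectations move with the material
        fixed = SampleSheet(sorted(fixed.rows, key=lambda r: r.sample_id))
        verdicts = verify_samples(m, SampleSheet([
            SampleSheetRow(r.sample_id, r.library_barcode_id,
                           sheet.row(remap.get(r.sample_id, r.sample_id)).expected_sasi_ids,
                           r.dose)
            for r in sheet
        ]))
        assert all(v.status == "confirmed" for v in verdicts)


class TestContamination:
    def test_fraction_estimator_definition(self):
        m = matrix_from({"S1": {1: 990, 2: 10}, "S2": {2: 1000}})
        ests = estimate_contamination(m, sheet_for(2))
        assert len(ests) == 1
        e = ests[0]
        assert (e.sample_id, e.foreign_sasi_id, e.foreign_reads) == ("S1", 2, 10)
        assert e.estimated_fraction == pytest.approx(0.01)
        assert e.above_background

    def test_no_foreign_reads_empty(self):
        m = matrix_from({"S1": {1: 500}, "S2": {2: 400}})
        assert estimate_contamination(m, sheet_for(2)) == []

    def test_dose_ratio_rescaling(self):
        sheet = SampleSheet([
            SampleSheetRow("S1", 1, (1,), dose=0.001),
            SampleSheetRow("S2", 2, (2,), dose=0.004),  # source dosed 4x higher
        ])
        m = matrix_from({"S1": {1: 1000, 2: 40}, "S2": {2: 4000}})
        e = estimate_contamination(m, sheet)[0]
        # 40/1040 scaled by 0.001/0.004
        assert e.estimated_fraction == pytest.approx(40 / 1040 / 4)

    def test_titration_detects_down_to_one_percent(self):
        """Triplicate count-level titration at ~1000 own reads/sample: 10%
        and 1% contamination flagged in every replicate, 0.1% not reliably."""
        plex = 8
        events = [
            ContaminationEvent("S1", "S8", 0.10),
            ContaminationEvent("S2", "S8", 0.01),
            ContaminationEvent("S3", "S8", 0.001),
        ]
        counts = count_level_simulate(plex, 1_000_000, 0.001, events, replicates=3, seed=1)
        flags = {0.10: [], 0.01: [], 0.001: []}
        for rep in (1, 2, 3):
            matrix = matrix_for_replicate(counts, rep, plex)
            ests = estimate_contamination(matrix, sheet_for(plex))
            flagged = {(e.sample_id, e.foreign_sasi_id) for e in ests if e.above_background}
            flags[0.10].append(("S1", 8) in flagged)
            flags[0.01].append(("S2", 8) in flagged)
            flags[0.001].append(("S3", 8) in flagged)
        assert all(flags[0.10])
        assert all(flags[0.01])
        assert not all(flags[0.001])

    def test_parameter_recovery_over_seeds(self):
        """Mean estimated fraction over 20 seeded runs sits near truth:
        within 2 points absolute at 10%, within 0.5 at 1%."""
        plex = 4
        events = [
            ContaminationEvent("S1", "S4", 0.10),
            ContaminationEvent("S2", "S4", 0.01),
        ]
        est10, est1 = [], []
        for seed in range(1, 21):
            counts = count_level_simulate(plex, 1_000_000, 0.001, events, seed=seed)
            matrix = matrix_for_replicate(counts, 1, plex)
            for e in estimate_contamination(matrix, sheet_for(plex)):
                if e.sample_id == "S1" and e.foreign_sasi_id == 4:
                    est10.append(e.estimated_fraction)
                if e.sample_id == "S2" and e.foreign_sasi_id == 4:
                    est1.append(e.estimated_fraction)
        assert abs(np.mean(est10) - 0.10) <= 0.02
        assert abs(np.mean(est1) - 0.01) <= 0.005


class TestMisattribution:
    @pytest.mark.parametrize(
        "perfect,corrected,call",
        [(50, 3, "contamination"), (2, 40, "drift"), (0, 0, "inconclusive"),
         (5, 5, "inconclusive"), (4, 3, "inconclusive")],
    )
    def test_calls(self, perfect, corrected, call):
        assert classify_misattribution(perfect, corrected, min_total=10).call == call

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_misattribution(-1, 0)


class TestCombinatorial:
    def test_pair_capacities(self):
        assert pair_capacity(96) == 4560
        assert pair_capacity(384) == 73_536

    def test_exact_pair_resolves(self):
        reg = build_pair_registry([("X", (3, 17)), ("Y", (4, 17))])
        assert decode_combinatorial({17, 3}, reg).sample_id == "X"

    def test_incomplete_and_superset_fail_with_offenders(self):
        reg = build_pair_registry([("X", (3, 17))])
        r1 = decode_combinatorial({17}, reg)
        assert not r1.ok and r1.offending_ids == (17,)
        r2 = decode_combinatorial({3, 17, 99}, reg)
        assert not r2.ok and 99 in r2.offending_ids
        r3 = decode_combinatorial({4, 5}, reg)
        assert not r3.ok

    def test_registry_collision_rejected(self):
        with pytest.raises(ValueError):
            build_pair_registry([("X", (1, 2)), ("Y", (2, 1))])


def test_sample_sheet_csv_round_trip(tmp_path):
    sheet = SampleSheet([
        SampleSheetRow("A", 1, (1,), 0.001),
        SampleSheetRow("B", 2, (2, 9), 0.004),
    ])
    path = tmp_path / "sheet.csv"
    sheet.to_csv(path)
    back = SampleSheet.from_csv(path)
    assert back.rows == sheet.rows
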