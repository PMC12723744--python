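"""Outcome analytics: matching, gel/sequencing fusion, hit rate, decile
binning, frequency tables, and the colony-checking probability."""

from datetime import date, timedelta

import numpy as np
import pytest

from clonecoord.analytics import (
    ALL_CORRECT,
    ALL_INCORRECT,
    AMBIGUOUS,
    LIKELY_CORRECT,
    LIKELY_INCORRECT,
    SOME_CORRECT,
    UNCLASSIFIED,
    assembly_outcome,
    classify_gel,
    compute_decile_bins,
    empirical_hit_rate,
    match_miniprep_to_transformation,
    operations_timeline,
    prob_correct_clone,
    reconcile_sequencing,
    sequencing_outcome_table,
    storage_time_table,
)
from clonecoord.core_model import (
    AssemblyRecord,
    ConstructRecord,
    DsDNARecord,
    Instance,
    MiniprepRecord,
    SequencingRecord,
    Settings,
    TransformationRecord,
)

D0 = date(2024, 5, 1)


def build_assembly_instance(gels, reads=(), colony="10-50"):
    """One assembly with one miniprep per gel code; ``reads`` maps miniprep
    index -> list of interpretations (serials increase in order)."""
    inst = Instance(settings=Settings())
    inst.dsdna = [DsDNARecord("d1", source="external", length_kb=1.0, conc_ng_ul=10.0)]
    inst.registry = [ConstructRecord("c1", queued_date=D0)]
    inst.assemblies = [AssemblyRecord("a1", type="USER", part_ids=["d1"],
                                      construct_id="c1", date=D0)]
    inst.transformations = [
        TransformationRecord("t1", assembly_id="a1", date=D0 + timedelta(days=1),
                             colony_category=colony)
    ]
    for i, gel in enumerate(gels, start=1):
        inst.minipreps.append(
            MiniprepRecord(f"m{i}", assembly_id="a1",
                           inoculation_date=D0 + timedelta(days=2),
                           gel_code=gel)
        )
    serial = 1
    for idx, interps in dict(reads).items():
        for interp in interps:
            inst.sequencing.append(
                SequencingRecord(f"s{serial}", miniprep_id=f"m{idx + 1}",
                                 submission_date=D0 + timedelta(days=4),
                                 interpretation=interp)
            )
            serial += 1
    return inst


class TestTransformationMatching:
    def _instance(self, inoculation, dates_serials, explicit=None):
        inst = Instance(settings=Settings())
        inst.dsdna = [DsDNARecord("d1", source="external", conc_ng_ul=1.0,
                                  length_kb=1.0)]
        inst.assemblies = [AssemblyRecord("a1", type="USER", part_ids=["d1"],
                                          date=D0)]
        for serial, offset in dates_serials:
            inst.transformations.append(
                TransformationRecord(f"t{serial}", assembly_id="a1",
                                     date=D0 + timedelta(days=offset))
            )
        inst.minipreps = [
            MiniprepRecord("m1", assembly_id="a1", transformation_id=explicit,
                           inoculation_date=D0 + timedelta(days=inoculation))
        ]
        return inst

    def test_largest_serial_on_or_before_inoculation(self):
        # t5 three days before, t9 one day before, t12 one day after
        inst = self._instance(3, [(5, 0), (9, 2), (12, 4)])
        assert match_miniprep_to_transformation("m1", inst) == "t9"

    def test_explicit_reference_wins_regardless_of_dates(self):
        inst = self._instance(3, [(5, 0), (9, 2), (12, 4)], explicit="t12")
        assert match_miniprep_to_transformation("m1", inst) == "t12"

    def test_all_transformations_too_late_is_unmatched(self):
        inst = self._instance(1, [(5, 2), (9, 3)])
        assert match_miniprep_to_transformation("m1", inst) is None

    def test_same_day_counts_as_before(self):
        inst = self._instance(2, [(5, 2)])
        assert match_miniprep_to_transformation("m1", inst) == "t5"

    def test_oracle_equivalence(self, generated_campaign):
        inst = generated_campaign
        for m in inst.minipreps:
            got = match_miniprep_to_transformation(m.id, inst)
            if m.transformation_id is not None:
                assert got == m.transformation_id
                continue
            best = None
            for t in inst.transformations:
                if (t.assembly_id == m.assembly_id and t.date is not None
                        and m.inoculation_date is not None
                        and t.date <= m.inoculation_date):
                    if best is None or int(t.id[1:]) > int(best.id[1:]):
                        best = t
            assert got == (best.id if best else None)


class TestClassifyGel:
    @pytest.mark.parametrize(
        "code,expected",
        [("single_band_expected_size", LIKELY_CORRECT),
         ("supercoiled_plus_relaxed", LIKELY_CORRECT),
         ("band_absent", LIKELY_INCORRECT),
         ("smear", LIKELY_INCORRECT),
         ("wrong_size", LIKELY_INCORRECT),
         ("multiple_bands", LIKELY_INCORRECT),
         ("not_run", AMBIGUOUS),
         (None, AMBIGUOUS)],
    )
    def test_quality_classes(self, code, expected):
        assert classify_gel(code, Settings()) == expected


class TestReconcileSequencing:
    def run(self, inst):
        return reconcile_sequencing(inst.minipreps, inst)

    def test_defect_read_demotes_gel_based_set_members(self):
        # m1 gel-correct but sequencing shows a primer dimer: the gel call is
        # refuted, so unsequenced gel-correct m2 is demoted too
        inst = build_assembly_instance(
            ["single_band_expected_size", "single_band_expected_size"],
            reads={0: ["primer_dimer_in_place_of_part"]},
        )
        classes = self.run(inst)
        assert classes == {"m1": LIKELY_INCORRECT, "m2": LIKELY_INCORRECT}

    def test_verification_does_not_propagate(self):
        inst = build_assembly_instance(
            ["single_band_expected_size", "single_band_expected_size"],
            reads={0: ["all_parts_verified"]},
        )
        classes = self.run(inst)
        assert classes == {"m1": LIKELY_CORRECT, "m2": LIKELY_CORRECT}

    def test_read_failure_keeps_gel_class(self):
        inst = build_assembly_instance(
            ["single_band_expected_size"], reads={0: ["poor_read_quality"]}
        )
        assert self.run(inst) == {"m1": LIKELY_CORRECT}

    def test_latest_serial_governs(self):
        inst = build_assembly_instance(
            ["single_band_expected_size"],
            reads={0: ["primer_dimer_in_place_of_part", "all_parts_verified"]},
        )
        assert self.run(inst) == {"m1": LIKELY_CORRECT}

    def test_defect_confirming_bad_gel_leaves_others_alone(self):
        # sequencing a gel-failed clone confirms the gel; nothing is refuted
        inst = build_assembly_instance(
            ["wrong_size", "single_band_expected_size"],
            reads={0: ["template_surviving"]},
        )
        classes = self.run(inst)
        assert classes == {"m1": LIKELY_INCORRECT, "m2": LIKELY_CORRECT}


class TestAssemblyOutcome:
    @pytest.mark.parametrize(
        "gels,reads,expected",
        [
            (["single_band_expected_size"] * 3, {}, ALL_CORRECT),
            (["single_band_expected_size", "wrong_size", "band_absent"], {},
             SOME_CORRECT),
            (["wrong_size", "band_absent"], {}, ALL_INCORRECT),
            (["not_run", "single_band_expected_size"], {}, UNCLASSIFIED),
            (["not_run", "single_band_expected_size", "wrong_size"], {},
             SOME_CORRECT),
        ],
    )
    def test_rollup(self, gels, reads, expected):
        inst = build_assembly_instance(gels, reads)
        assert assembly_outcome("a1", inst) == expected

    def test_zero_minipreps_is_error(self):
        inst = build_assembly_instance(["single_band_expected_size"])
        inst.minipreps = []
        with pytest.raises(ValueError):
            assembly_outcome("a1", inst)


class TestEmpiricalHitRate:
    def test_max_of_presumed_and_verified(self):
        inst = build_assembly_instance(
            ["single_band_expected_size", "single_band_expected_size",
             "wrong_size", "band_absent"],
            reads={0: ["all_parts_verified"]},
        )
        # 2 presumed correct, 1 verified -> max(2,1)/4
        assert empirical_hit_rate("a1", inst) == pytest.approx(50.0)

    def test_ambiguous_gel_undefines_the_rate(self):
        inst = build_assembly_instance(
            ["single_band_expected_size", "not_run", "wrong_size"]
        )
        assert empirical_hit_rate("a1", inst) is None

    def test_all_verified_is_100(self):
        inst = build_assembly_instance(
            ["single_band_expected_size", "single_band_expected_size"],
            reads={0: ["all_parts_verified"], 1: ["all_parts_verified"]},
        )
        assert empirical_hit_rate("a1", inst) == pytest.approx(100.0)

    def test_verified_can_exceed_presumed(self):
        # gel said wrong size but sequencing verified the clone: the max rule
        inst = build_assembly_instance(
            ["wrong_size", "band_absent"], reads={0: ["all_parts_verified"]}
        )
        assert empirical_hit_rate("a1", inst) == pytest.approx(50.0)

    def test_within_bounds_whenever_defined(self, generated_campaign):
        for asm in generated_campaign.assemblies:
            if not any(m.assembly_id == asm.id for m in generated_campaign.minipreps):
                continue
            rate = empirical_hit_rate(asm.id, generated_campaign)
            if rate is not None:
                assert 0.0 <= rate <= 100.0


def percentile_oracle(values, q):
    """Sort-based linear-interpolation percentile, written independently."""
    xs = sorted(values)
    if len(xs) == 1:
        return float(xs[0])
    rank = (len(xs) - 1) * q / 100.0
    lo = int(rank)
    frac = rank - lo
    if lo + 1 < len(xs):
        return xs[lo] + frac * (xs[lo + 1] - xs[lo])
    return float(xs[-1])


class TestDecileBins:
    def test_degenerate_all_zero(self):
        bins, assignment = compute_decile_bins([0, 0, 0, 0])
        assert bins.labels == ["0"]
        assert assignment == [0, 0, 0, 0]

    def test_overflow_label_is_cutoff_plus_one(self):
        values = list(range(20))  # 90th pct = 17.1 -> floor 17; overflow 18+
        bins, assignment = compute_decile_bins(values)
        assert bins.labels[-1].endswith("+")
        top_cut = bins.cutoffs[-1]
        assert bins.labels[-1] == f"{top_cut + 1}+"
        assert all(assignment[i] == len(bins.cutoffs)
                   for i, v in enumerate(values) if v > top_cut)

    def test_oracle_equivalence(self, generated_campaign):
        """Bin counts match an independent sort-based percentile/frequency
        recomputation."""
        inst = generated_campaign
        elapsed = []
        for asm in inst.assemblies:
            cands = [t for t in inst.transformations if t.assembly_id == asm.id]
            if not cands or asm.date is None:
                continue
            recent = max(cands, key=lambda t: (t.date, int(t.id[1:])))
            elapsed.append((recent.date - asm.date).days)
        assert elapsed, "fixture must produce dated assemblies"

        bins, assignment = compute_decile_bins(elapsed)

        # oracle: floored deduplicated decile cutoffs + first-fit binning
        cuts = []
        for q in range(10, 100, 10):
            c = int(np.floor(percentile_oracle(elapsed, q)))
            if not cuts or c > cuts[-1]:
                cuts.append(c)
        assert cuts == bins.cutoffs

        oracle_counts = [0] * (len(cuts) + 1)
        for v in elapsed:
            for i, c in enumerate(cuts):
                if v <= c:
                    oracle_counts[i] += 1
                    break
            else:
                oracle_counts[-1] += 1

        got_counts = [0] * (len(cuts) + 1)
        for b in assignment:
            got_counts[b] += 1
        assert got_counts == oracle_counts
        assert (oracle_counts[-1] > 0) == bins.has_overflow


class TestStorageTimeTable:
    def test_counts_match_nested_loop_oracle(self, generated_campaign):
        inst = generated_campaign
        bins, table = storage_time_table(inst, assembly_type="USER")
        assert table is not None
        # oracle: direct nested loop over assemblies
        rows = {label: dict.fromkeys(table.col_labels, 0)
                for label in table.row_labels}
        verified_n = dict.fromkeys(table.row_labels, 0)
        totals = dict.fromkeys(table.row_labels, 0)
        for asm in inst.assemblies:
            if asm.type != "USER" or asm.date is None:
                continue
            cands = [t for t in inst.transformations if t.assembly_id == asm.id]
            if not cands:
                continue
            recent = max(cands, key=lambda t: (t.date, int(t.id[1:])))
            days = (recent.date - asm.date).days
            label = table.row_labels[bins.bin_of(days)]
            totals[label] += 1
            if recent.colony_category in rows[label]:
                rows[label][recent.colony_category] += 1
            is_verified = False
            for m in inst.minipreps:
                if m.assembly_id != asm.id:
                    continue
                reads = [s for s in inst.sequencing if s.miniprep_id == m.id]
                if reads and max(reads, key=lambda s: int(s.id[1:])).interpretation \
                        == "all_parts_verified":
                    is_verified = True
            if is_verified:
                verified_n[label] += 1

        df = table.to_dataframe()
        for label in table.row_labels:
            for col in table.col_labels:
                assert df.loc[label, col] == rows[label][col]
            assert df.loc[label, "n"] == totals[label]
            if totals[label]:
                expected_pct = 100.0 * verified_n[label] / totals[label]
                assert df.loc[label, "percent_verified"] == pytest.approx(expected_pct)

    def test_normalized_rows_sum_to_one(self, generated_campaign):
        _, table = storage_time_table(generated_campaign)
        norm = table.normalized()
        occupied = table.counts.sum(axis=1) > 0
        assert np.allclose(norm[occupied].sum(axis=1), 1.0)

    def test_no_qualifying_assemblies(self):
        bins, table = storage_time_table(Instance())
        assert bins is None and table is None


class TestSequencingOutcomeTable:
    def test_sorted_by_low_colony_fraction_and_min_observations(self):
        inst = build_assembly_instance(["single_band_expected_size"])
        # craft reads across two extra transformations with different colony
        # categories: "verified" reads mostly >100, "dimer" reads mostly <=100
        inst.transformations.append(
            TransformationRecord("t2", assembly_id="a1",
                                 date=D0 + timedelta(days=1),
                                 colony_category="101-500")
        )
        serial = 1
        mk = 1

        def add_reads(interp, n, t_id):
            nonlocal serial, mk
            for _ in range(n):
                mk += 1
                inst.minipreps.append(
                    MiniprepRecord(f"m{mk}", assembly_id="a1",
                                   transformation_id=t_id,
                                   inoculation_date=D0 + timedelta(days=2),
                                   gel_code="single_band_expected_size")
                )
                inst.sequencing.append(
                    SequencingRecord(f"s{serial}", miniprep_id=f"m{mk}",
                                     submission_date=D0 + timedelta(days=3),
                                     interpretation=interp)
                )
                serial += 1

        add_reads("all_parts_verified", 4, "t1")   # 10-50 colonies
        add_reads("all_parts_verified", 8, "t2")   # 101-500
        add_reads("primer_dimer_in_place_of_part", 9, "t1")
        add_reads("primer_dimer_in_place_of_part", 1, "t2")
        add_reads("template_surviving", 9, "t1")   # only 9: suppressed

        table = sequencing_outcome_table(inst, min_observations=10)
        assert table.row_labels == ["All", "primer_dimer_in_place_of_part",
                                    "all_parts_verified"]
        # All row unions only the displayed categories
        df = table.to_dataframe()
        assert df.loc["All", "n"] == 22
        assert df.loc["primer_dimer_in_place_of_part", "n"] == 10
        # fractions <=100: dimer 0.9 > verified 4/12
        assert df.loc["All", "10-50"] == 13

    def test_empty_when_everything_suppressed(self, mini_campaign):
        table = sequencing_outcome_table(mini_campaign, min_observations=10)
        assert table.row_labels == []


class TestProbCorrectClone:
    @pytest.mark.parametrize("h,k,expected", [(47, 3, 85), (47, 4, 92),
                                              (100, 1, 100), (0, 5, 0)])
    def test_reported_values(self, h, k, expected):
        assert prob_correct_clone(h, k) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            prob_correct_clone(101, 3)
        with pytest.raises(ValueError):
            prob_correct_clone(50, 0)


class TestOperationsTimeline:
    def test_cumulative_series_nondecreasing(self, generated_campaign):
        result = operations_timeline(generated_campaign,
                                     ["assemble", "transform", "sequence"])
        for series in result["cumulative"].values():
            assert all(a <= b for a, b in zip(series, series[1:]))

    def test_counts_match_date_scan(self, generated_campaign):
        result = operations_timeline(generated_campaign, ["transform"])
        dates = result["dates"]
        series = result["cumulative"]["transform"]
        for cutoff, value in zip(dates, series):
            expected = sum(
                1 for t in generated_campaign.transformations
                if t.date is not None and t.date <= cutoff
            )
            assert value == expected

    def test_days_to_completion_nonnegative(self, generated_campaign):
        result = operations_timeline(generated_campaign, ["assemble"])
        assert all(v >= 0 for v in result["days_to_completion"].values())

    def test_too_many_tasks_rejected(self, generated_campaign):
        with pytest.raises(ValueError):
            operations_timeline(
                generated_campaign,
                ["assemble", "transform", "sequence", "miniprep", "purify",
                 "inoculate"],
            )

    def test_empty_instance(self):
        result = operations_timeline(Instance(), ["assemble"])
        assert result["dates"] == [] and result["cumulative"]["assemble"] == []
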