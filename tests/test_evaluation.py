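"""Distances, optimal matching, thresholded tallies, and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from llpsminer.evaluation import (
    FieldTally,
    Metrics,
    MetricsTable,
    aggregate_metrics,
    build_cost_matrix,
    classify_and_tally,
    compare_methods_wilcoxon,
    compute_field_ranges,
    compute_prf,
    evaluate_record_sets,
    match_records,
    numeric_field_distance,
    phase_field_distance,
    record_cost,
    solve_assignment,
    text_field_distance,
    threshold_sweep,
)
from llpsminer.records import Quantity, RecordSet
from llpsminer.synthetic import CorruptionConfig, GeneratorConfig, make_scenario

from conftest import (
    brute_force_assignment_cost,
    exact_signed_rank_p,
    make_record,
    make_set,
    ro_similarity,
)


class TestNumericDistance:
    def test_formula_arithmetic(self):
        assert numeric_field_distance(30, 25, 20, 40) == pytest.approx(0.25)
        assert numeric_field_distance(7.0, 7.5, 6.0, 8.0) == pytest.approx(0.25)

    def test_identity_is_zero(self):
        assert numeric_field_distance(25, 25, 20, 40) == 0.0

    def test_out_of_range_prediction_clamped_to_one(self):
        assert numeric_field_distance(1000, 25, 20, 40) == 1.0

    def test_degenerate_range_keeps_exact_match_semantics(self):
        assert numeric_field_distance(7.4, 7.4, 7.4, 7.4) == 0.0
        assert numeric_field_distance(7.0, 7.4, 7.4, 7.4) == 1.0

    def test_symmetry(self):
        assert numeric_field_distance(30, 25, 20, 40) == numeric_field_distance(25, 30, 20, 40)


class TestTextDistance:
    def test_exact_match_is_zero(self):
        assert text_field_distance("FUS", "FUS") == 0.0

    def test_gestalt_ratio_example(self):
        # "abc" vs "abd": matching block "ab", M=2, s=4/6
        assert text_field_distance("abc", "abd") == pytest.approx(1 - 4 / 6)

    def test_empty_string_is_maximal(self):
        assert text_field_distance("polyU", "") == 1.0

    def test_agrees_with_brute_force_ratcliff_obershelp(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("abcd"))
        for _ in range(200):
            a = "".join(rng.choice(alphabet, size=rng.integers(0, 9)))
            b = "".join(rng.choice(alphabet, size=rng.integers(0, 9)))
            x, y = sorted([a, b])  # the distance orders its arguments canonically
            assert text_field_distance(a, b) == pytest.approx(
                1.0 - ro_similarity(x, y), abs=1e-12
            ), (a, b)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(1)
        alphabet = np.array(list("abcxyz"))
        for _ in range(50):
            a = "".join(rng.choice(alphabet, size=6))
            b = "".join(rng.choice(alphabet, size=6))
            assert text_field_distance(a, b) == pytest.approx(text_field_distance(b, a))


class TestPhaseDistance:
    @pytest.mark.parametrize("a, b, d", [(1, 1, 0.0), (0, 0, 0.0), (1, 0, 1.0), (0, 1, 1.0)])
    def test_binary_indicator(self, a, b, d):
        assert phase_field_distance(a, b) == d


class TestRecordCost:
    def test_identical_records_cost_zero(self, grid_labels):
        ranges = compute_field_ranges(grid_labels)
        rec = grid_labels.records[0]
        assert record_cost(rec, rec, ranges) == 0.0

    def test_single_field_difference_is_one_sixth_weighted(self):
        labels = [
            make_record(pc=1, rc=1, ph=7, temp=20, phase=1),
            make_record(pc=1, rc=1, ph=7, temp=40, phase=1),
        ]
        ranges = compute_field_ranges(labels)
        probe = make_record(pc=1, rc=1, ph=7, temp=30, phase=1)
        # temperature off by half the [20, 40] label range -> 0.5 / 6
        assert record_cost(probe, labels[0], ranges) == pytest.approx(0.5 / 6)

    def test_missing_versus_present_counts_one(self, grid_labels):
        ranges = compute_field_ranges(grid_labels)
        full = grid_labels.records[0]
        partial = full.replace(rna_conc=None)
        assert record_cost(partial, full, ranges) == pytest.approx(1 / 6)

    def test_unit_conserved_after_rescaling(self, grid_labels):
        # 0.1 mM normalized must equal 100 µM exactly: distance 0 to the label
        from llpsminer.normalization import normalize_record

        ranges = compute_field_ranges(grid_labels)
        target = grid_labels.records[2]  # pc = 100 µM
        probe = normalize_record(target.replace(protein_conc=Quantity(0.1, "mM", True)))
        probe = probe.replace(protein_name=target.protein_name)  # isolate the unit effect
        # float rounding in 0.1 mM * 1000 leaves ~1e-16 of residual distance
        assert record_cost(probe, target, ranges) == pytest.approx(0.0, abs=1e-12)

    def test_incompatible_units_score_maximal(self, grid_labels):
        ranges = compute_field_ranges(grid_labels)
        target = grid_labels.records[0]
        probe = target.replace(protein_conc=Quantity(1.0, "mg/mL", False))
        assert record_cost(probe, target, ranges) == pytest.approx(1 / 6)


class TestAssignment:
    def test_two_by_two_diagonal(self):
        result = solve_assignment(np.array([[0.1, 0.9], [0.8, 0.2]]))
        assert [(p.extracted_index, p.label_index) for p in result.pairs] == [(0, 0), (1, 1)]
        assert result.total_cost == pytest.approx(0.3)

    def test_rectangular_single_row(self):
        result = solve_assignment(np.array([[0.6, 0.2]]))
        assert [(p.extracted_index, p.label_index) for p in result.pairs] == [(0, 1)]
        assert result.unmatched_labels == (0,)

    def test_ties_break_lexicographically(self):
        result = solve_assignment(np.full((2, 2), 0.5))
        assert [(p.extracted_index, p.label_index) for p in result.pairs] == [(0, 0), (1, 1)]

    def test_empty_sides_yield_no_pairs(self):
        result = solve_assignment(np.zeros((0, 3)))
        assert result.pairs == () and result.unmatched_labels == (0, 1, 2)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        m=st.integers(1, 7), n=st.integers(1, 7),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_total_cost_matches_exhaustive_enumeration(self, m, n, seed):
        C = np.random.default_rng(seed).random((m, n))
        result = solve_assignment(C)
        assert len(result.pairs) == min(m, n)
        assert result.total_cost == pytest.approx(brute_force_assignment_cost(C), abs=1e-9)

    def test_cost_matrix_entries_clamped_to_unit_interval(self, grid_labels):
        probes = [
            make_record(pc=1e6, rc=1e6, ph=1.0, temp=95, phase=0),
            make_record(name="", pc=None, rc=None, ph=None, temp=None, phase=1),
        ]
        C = build_cost_matrix(probes, list(grid_labels))
        assert C.shape == (2, 4)
        assert np.all((C >= 0) & (C <= 1))


class TestClassifyAndTally:
    def test_perfect_match_all_true_positives(self, grid_labels):
        ev = evaluate_record_sets(
            RecordSet("P01", "Fig1", grid_labels.records, origin="extracted"), grid_labels
        )
        for f in ("protein_name", "protein_conc", "rna_conc", "ph", "temperature", "phase_status"):
            assert (ev.tally.tp[f], ev.tally.fp[f], ev.tally.fn[f]) == (4, 0, 0)

    def test_above_threshold_matched_field_is_false_positive_only(self):
        labels = [
            make_record(pc=1, rc=1, ph=7, temp=20, phase=1),
            make_record(pc=1, rc=1, ph=7, temp=40, phase=1),
        ]
        extracted = [labels[0].replace(temperature=Quantity(30.0, "°C", True)), labels[1]]
        match, _ = match_records(extracted, labels)
        tally = classify_and_tally(match, extracted, labels, threshold=0.2)
        assert (tally.tp["temperature"], tally.fp["temperature"], tally.fn["temperature"]) == (1, 1, 0)
        assert tally.tp["ph"] == 2

    def test_strict_recall_also_counts_false_negative(self):
        labels = [make_record(pc=1, rc=1, ph=7, temp=20, phase=1),
                  make_record(pc=1, rc=1, ph=7, temp=40, phase=1)]
        extracted = [labels[0].replace(temperature=Quantity(30.0, "°C", True)), labels[1]]
        match, _ = match_records(extracted, labels)
        tally = classify_and_tally(match, extracted, labels, 0.2, strict_recall=True)
        assert tally.fn["temperature"] == 1

    def test_unmatched_labels_become_false_negatives(self, grid_labels):
        extracted = list(grid_labels.records[:2])
        match, _ = match_records(extracted, list(grid_labels))
        tally = classify_and_tally(match, extracted, list(grid_labels), 0.2)
        for f in ("protein_name", "ph", "phase_status"):
            assert (tally.tp[f], tally.fp[f], tally.fn[f]) == (2, 0, 2)

    def test_conservation_tp_plus_fp_equals_extracted_presence(self, grid_labels):
        rng = np.random.default_rng(5)
        extracted = [
            rec.replace(rna_conc=None if rng.random() < 0.5 else rec.rna_conc)
            for rec in grid_labels.records[:3]
        ] + [make_record(name="XXXX", pc=7.7, phase=0)]
        match, _ = match_records(extracted, list(grid_labels))
        tally = classify_and_tally(match, extracted, list(grid_labels), 0.2)
        for f in tally.tp:
            n_present = sum(1 for r in extracted if getattr(r, f) is not None)
            assert tally.tp[f] + tally.fp[f] == n_present


class TestMetrics:
    def test_precision_recall_f1_arithmetic(self):
        tally = FieldTally()
        tally.tp["ph"], tally.fp["ph"], tally.fn["ph"] = 3, 1, 2
        m = compute_prf(tally)["ph"]
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_zero_denominators_are_undefined(self):
        m = compute_prf(FieldTally())["ph"]
        assert m.precision is None and m.recall is None and m.f1 is None

    def test_perfect_counts_score_one(self):
        tally = FieldTally()
        tally.tp["ph"] = 5
        m = compute_prf(tally)["ph"]
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_single_scope_aggregate_equals_row_with_zero_std(self):
        row = {f: Metrics(1.0, 1.0, 1.0) for f in FieldTally().tp}
        agg = aggregate_metrics(MetricsTable({("P01", "Fig1"): row}))
        assert agg["average_f1"] == 1.0
        assert agg["fields"]["ph"]["f1_std"] == 0.0
        assert agg["average_f1_std_across_scopes"] == 0.0

    def test_two_scope_mean_and_population_std(self):
        rows = {
            ("P01", "Fig1"): {f: Metrics(1.0, 1.0, 1.0) for f in FieldTally().tp},
            ("P01", "Fig2"): {f: Metrics(0.5, 0.5, 0.5) for f in FieldTally().tp},
        }
        agg = aggregate_metrics(MetricsTable(rows))
        assert agg["fields"]["ph"]["f1_mean"] == pytest.approx(0.75)
        assert agg["fields"]["ph"]["f1_std"] == pytest.approx(np.std([1.0, 0.5]))
        assert agg["average_f1"] == pytest.approx(0.75)

    def test_undefined_fields_excluded_from_aggregation(self):
        # three scopes; 'ph' undefined in the second -> its mean over {1.0, 0.4}
        base = {f: Metrics(1.0, 1.0, 1.0) for f in FieldTally().tp}
        rows = {
            ("P01", "Fig1"): dict(base),
            ("P01", "Fig2"): {**base, "ph": Metrics(None, None, None)},
            ("P01", "Fig3"): {**base, "ph": Metrics(0.4, 0.4, 0.4)},
        }
        agg = aggregate_metrics(MetricsTable(rows))
        assert agg["fields"]["ph"]["f1_mean"] == pytest.approx((1.0 + 0.4) / 2)
        assert agg["fields"]["ph"]["f1_n_defined"] == 2
        assert agg["fields"]["temperature"]["f1_mean"] == 1.0


class TestThresholdSweep:
    @pytest.fixture
    def scenario(self):
        gcfg = GeneratorConfig(seed=21, n_figures=3)
        ccfg = CorruptionConfig(seed=22, miss_field_rate=0.1, drop_record_rate=0.1,
                                typo_rate=0.2, numeric_noise_sd=0.08,
                                spurious_record_rate=0.0)
        return make_scenario(gcfg, ccfg, 0.2)

    def test_f1_nondecreasing_in_threshold(self, scenario):
        taus = [0.0, 0.05, 0.1, 0.2, 0.5, 1.0]
        tables = threshold_sweep(list(scenario.extracted), list(scenario.labels), taus)
        for f in FieldTally().tp:
            series = [
                tables[t].aggregate()["fields"][f]["f1_mean"] for t in taus
            ]
            defined = [v for v in series if v is not None]
            assert all(a <= b + 1e-12 for a, b in zip(defined, defined[1:])), f

    def test_zero_threshold_demotes_any_nonzero_distance(self, scenario):
        ext, lab = list(scenario.extracted[0]), list(scenario.labels[0])
        match, _ = match_records(ext, lab)
        tally = classify_and_tally(match, ext, lab, 0.0)
        # strict "below": even an exact match (distance 0) is not < 0
        assert all(tally.tp[f] == 0 for f in tally.tp)

    def test_unsorted_thresholds_rejected(self, scenario):
        with pytest.raises(ValueError, match="ascending"):
            threshold_sweep(list(scenario.extracted), list(scenario.labels), [0.5, 0.2])


class TestWilcoxon:
    def test_identical_methods_give_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            result = compare_methods_wilcoxon([0.5] * 8, [0.5] * 8)
        assert result.p_value == 1.0 and not result.significant

    def test_constant_shift_flagged_significant(self):
        b = [0.5, 0.6, 0.7, 0.4, 0.55, 0.65, 0.45, 0.52, 0.58, 0.62]
        a = [x + 0.1 for x in b]
        result = compare_methods_wilcoxon(a, b)
        oracle_p = exact_signed_rank_p(np.asarray(a) - np.asarray(b))
        assert oracle_p == pytest.approx(2 / 1024)
        assert result.significant and result.p_value < 0.05

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(12), rng.random(12)
        assert compare_methods_wilcoxon(a, b).p_value == pytest.approx(
            compare_methods_wilcoxon(b, a).p_value
        )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_methods_wilcoxon([1.0], [1.0, 2.0])
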