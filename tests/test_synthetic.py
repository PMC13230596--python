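"""Scenario generation: structure, determinism, and exact bookkeeping."""

import json

import numpy as np
import pytest

from llpsminer.evaluation import evaluate_paired
from llpsminer.orchestration import parse_model_output
from llpsminer.records import TARGET_FIELDS
from llpsminer.synthetic import (
    CorruptionConfig,
    GeneratorConfig,
    corrupt,
    generate_labels,
    make_scenario,
    scenario_as_mock_script,
    scenario_rules,
)


def quiet_corruption(seed, **overrides):
    base = dict(
        numeric_noise_sd=0.0, miss_field_rate=0.0, drop_record_rate=0.0,
        typo_rate=0.0, spurious_record_rate=0.0, unit_jitter_rate=0.0,
    )
    base.update(overrides)
    return CorruptionConfig(seed=seed, **base)


class TestGenerateLabels:
    def test_same_seed_reproduces_identical_sets(self):
        cfg = GeneratorConfig(seed=13, n_figures=6)
        assert generate_labels(cfg) == generate_labels(cfg)

    def test_figures_have_grid_size_and_complete_records(self):
        sets = generate_labels(GeneratorConfig(seed=2, n_figures=10))
        for rs in sets:
            assert 3 <= len(rs) <= 40
            for rec in rs:
                assert rec.present_fields() == TARGET_FIELDS

    def test_both_phase_outcomes_in_each_figure(self):
        sets = generate_labels(GeneratorConfig(seed=4, n_figures=10))
        for rs in sets:
            phases = {r.phase_status for r in rs}
            assert phases == {0, 1}, rs.figure_id

    def test_phase_rule_is_monotone_in_concentration_product(self):
        for rs in generate_labels(GeneratorConfig(seed=6, n_figures=5)):
            recs = sorted(rs, key=lambda r: r.protein_conc.value * r.rna_conc.value)
            phases = [r.phase_status for r in recs]
            assert phases == sorted(phases), rs.figure_id

    def test_default_scale_mirrors_corpus_structure(self):
        # 49 figures over 20 papers, on the order of 18 experiments/figure
        sets = generate_labels(GeneratorConfig(seed=0))
        assert len(sets) == 49
        assert len({rs.paper_id for rs in sets}) == 20
        total = sum(len(rs) for rs in sets)
        assert 700 <= total <= 1050  # expectation ~880

    def test_one_protein_ph_temperature_per_figure(self):
        for rs in generate_labels(GeneratorConfig(seed=8, n_figures=5)):
            assert len({r.protein_name for r in rs}) == 1
            assert len({r.ph for r in rs}) == 1
            assert len({r.temperature.value for r in rs}) == 1


class TestCorrupt:
    def test_identity_corruption_reproduces_labels_up_to_order(self):
        labels = generate_labels(GeneratorConfig(seed=31, n_figures=4))
        s = corrupt(labels, quiet_corruption(5), 0.2)
        for lab, ext in zip(s.labels, s.extracted):
            assert sorted(map(repr, lab.records)) == sorted(map(repr, ext.records))
        for scope, tally in s.expected_tallies.items():
            n = len(next(rs for rs in labels if rs.scope == scope))
            for f in TARGET_FIELDS:
                assert (tally.tp[f], tally.fp[f], tally.fn[f]) == (n, 0, 0)

    def test_scenario_is_pure_function_of_configs(self):
        gcfg = GeneratorConfig(seed=7, n_figures=3)
        ccfg = CorruptionConfig(seed=8, miss_field_rate=0.1, drop_record_rate=0.1,
                                typo_rate=0.1, spurious_record_rate=1.0)
        a, b = make_scenario(gcfg, ccfg, 0.2), make_scenario(gcfg, ccfg, 0.2)
        assert a.extracted == b.extracted
        assert a.raw_responses == b.raw_responses
        assert all(a.expected_tallies[k] == b.expected_tallies[k] for k in a.expected_tallies)

    def test_dropped_records_become_false_negatives(self):
        labels = generate_labels(GeneratorConfig(seed=41, n_figures=3))
        s = corrupt(labels, quiet_corruption(6, drop_record_rate=0.3), 0.2)
        for lab, ext in zip(s.labels, s.extracted):
            n_dropped = len(lab) - len(ext)
            tally = s.expected_tallies[lab.scope]
            for f in TARGET_FIELDS:
                assert tally.fn[f] == n_dropped
                assert tally.tp[f] == len(ext)

    def test_spurious_records_become_false_positives(self):
        labels = generate_labels(GeneratorConfig(seed=43, n_figures=3))
        s = corrupt(labels, quiet_corruption(7, spurious_record_rate=2.0), 0.2)
        for lab, ext in zip(s.labels, s.extracted):
            n_spurious = len(ext) - len(lab)
            tally = s.expected_tallies[lab.scope]
            # spurious records carry a protein name; with no drops they all
            # stay unmatched, so each contributes one name false positive
            assert tally.fp["protein_name"] == n_spurious
            assert tally.fn["protein_name"] == 0

    def test_evaluator_reproduces_expected_tallies(self):
        for i in range(10):
            rate = (0.0, 0.05, 0.2)[i % 3]
            s = make_scenario(
                GeneratorConfig(seed=100 + i, n_figures=3),
                CorruptionConfig(seed=200 + i, miss_field_rate=rate,
                                 drop_record_rate=rate, typo_rate=rate,
                                 numeric_noise_sd=rate / 4,
                                 spurious_record_rate=2 * rate),
                0.2,
            )
            report = evaluate_paired(list(s.extracted), list(s.labels), 0.2)
            for ev in report.scope_evaluations:
                assert ev.tally == s.expected_tallies[ev.scope], ev.scope

    def test_vanishing_corruption_gives_perfect_f1(self):
        s = make_scenario(GeneratorConfig(seed=51, n_figures=4), quiet_corruption(9), 0.2)
        report = evaluate_paired(list(s.extracted), list(s.labels), 0.2)
        assert report.aggregate["average_f1"] == 1.0


class TestMockScript:
    def test_round_trip_through_parser_and_normalizer(self):
        gcfg = GeneratorConfig(seed=61, n_figures=3)
        ccfg = CorruptionConfig(seed=62, miss_field_rate=0.1, drop_record_rate=0.1,
                                typo_rate=0.1, numeric_noise_sd=0.05,
                                spurious_record_rate=1.0, unit_jitter_rate=0.5)
        s = make_scenario(gcfg, ccfg, 0.2)
        script = scenario_as_mock_script(s)
        rules = scenario_rules(sorted({r.protein_name for rs in s.labels for r in rs}))
        for ext in s.extracted:
            parsed = parse_model_output(
                script[ext.figure_id], ext.paper_id, ext.figure_id, rules
            )
            assert parsed.records == ext.records, ext.figure_id

    def test_unit_jitter_appears_in_raw_form_only(self):
        gcfg = GeneratorConfig(seed=71, n_figures=2)
        ccfg = quiet_corruption(10, unit_jitter_rate=1.0)
        s = make_scenario(gcfg, ccfg, 0.2)
        joined = "\n".join(s.raw_responses.values())
        assert " mM" in joined or " nM" in joined
        for ext in s.extracted:
            for rec in ext:
                assert rec.protein_conc.unit == "µM"  # canonical after pipeline

    def test_empty_figure_yields_empty_json_array(self):
        labels = generate_labels(GeneratorConfig(seed=81, n_figures=1))
        s = corrupt(labels, quiet_corruption(11, drop_record_rate=1.0), 0.2)
        assert json.loads(s.raw_responses[labels[0].figure_id]) == []
        tally = s.expected_tallies[labels[0].scope]
        assert all(tally.fn[f] == len(labels[0]) for f in TARGET_FIELDS)
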