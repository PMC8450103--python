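"""Pseudogene rule and the three-stage high-confidence filter."""

import warnings

import pytest

from cloverscan.config import FilterConfig
from cloverscan.filters import (
    annotate_consistency,
    classify_pseudogene,
    high_confidence_filter,
    secondary_filter,
    tertiary_filter,
)
from cloverscan.records import TRNAPrediction


def P(overall=80.0, primary=60.0, secondary=20.0, iso=90.0,
      anticodon="TGC", flags=(), n=[0]):
    n[0] += 1
    return TRNAPrediction(
        seq_id="c", begin=n[0] * 200, end=n[0] * 200 + 72, strand="+",
        overall_bits=overall, primary_bits=primary, secondary_bits=secondary,
        anticodon=anticodon, isotype_by_anticodon="Ala",
        isotype_by_model="Ala",
        isotype_scores={"Ala-TGC": iso}, flags=set(flags))


class TestPseudogene:
    @pytest.mark.parametrize("overall,primary,secondary,expected", [
        (54, 9, 20, True),     # low overall and low primary
        (54, 15, 4, True),     # low overall and low secondary
        (56, 0, 0, False),     # overall at/above 55 blocks the call
        (54, 15, 8, False),    # neither branch condition met
        (55, 9, 4, False),     # boundary: 'below 55' is strict
        (54.9, 10, 5, False),  # boundaries on the inner thresholds too
    ])
    def test_rule(self, overall, primary, secondary, expected):
        assert classify_pseudogene(P(overall, primary, secondary)) == expected


class TestSecondary:
    @pytest.mark.parametrize("iso,overall,secondary,kept", [
        (80, 60, 15, True),
        (69.9, 100, 30, False),   # isotype score below 70
        (100, 49.9, 30, False),   # overall below 50
        (100, 100, 9.9, False),   # secondary below 10
        (70, 50, 10, True),       # boundary values retained
    ])
    def test_rule(self, iso, overall, secondary, kept):
        passed, removed = secondary_filter(
            [P(overall=overall, secondary=secondary, iso=iso)])
        assert (len(passed) == 1) == kept

    def test_missing_isotype_score_removed_with_warning(self):
        p = P()
        p.isotype_scores = {}
        with pytest.warns(UserWarning):
            passed, removed = secondary_filter([p])
        assert passed == [] and removed == [p]


class TestTertiary:
    def test_dynamic_threshold_stops_at_forty(self):
        preds = [P(overall=71.5 + k, anticodon="AGC") for k in range(60)]
        passed, removed = tertiary_filter(preds)
        assert len(passed) == 40
        assert min(p.overall_bits for p in passed) == pytest.approx(91.5)

    def test_small_groups_untouched(self):
        preds = [P(overall=30.0 + k, anticodon="AGC") for k in range(10)]
        passed, removed = tertiary_filter(preds)
        assert len(passed) == 10 and removed == []

    def test_threshold_saturates_at_95(self):
        preds = [P(overall=96.0 + 0.01 * k, anticodon="AGC")
                 for k in range(100)]
        passed, removed = tertiary_filter(preds)
        assert len(passed) == 100   # nothing scores below the 95-bit cap

    def test_order_independent(self):
        preds = [P(overall=71.5 + k, anticodon="AGC") for k in range(60)]
        a, _ = tertiary_filter(preds)
        b, _ = tertiary_filter(list(reversed(preds)))
        assert {id(p) for p in a} == {id(p) for p in b}


class TestConsistency:
    def test_disallowed_anticodon_flagged(self, euk_table):
        p = annotate_consistency(P(anticodon="GGG"), euk_table)
        assert "unexpected_anticodon" in p.flags

    def test_expected_anticodon_clean(self, euk_table):
        p = annotate_consistency(P(anticodon="TGC"), euk_table)
        assert "unexpected_anticodon" not in p.flags


class TestHighConfidence:
    def _constructed_set(self):
        preds = []
        preds += [P(overall=40, primary=5, secondary=20) for _ in range(30)]
        preds += [P(iso=60.0) for _ in range(20)]          # stage-2 failures
        preds += [P(overall=71.5 + k, anticodon="AGC") for k in range(60)]
        preds += [P() for _ in range(20)]
        return preds

    def test_stage_counts(self, euk_table):
        report = high_confidence_filter(self._constructed_set(),
                                        table=euk_table)
        assert report.input_count == 130
        assert report.removed_pseudo == 30
        assert report.removed_stage2 == 20
        assert report.removed_stage3 == 20
        assert len(report.high_confidence) == 60
        assert report.flagged == 0

    def test_inclusion_chain(self, euk_table):
        preds = self._constructed_set()
        report = high_confidence_filter(preds, table=euk_table)
        hc = set(map(id, report.high_confidence))
        assert hc <= set(map(id, preds))
        total = (report.removed_pseudo + report.removed_stage2
                 + report.removed_stage3 + report.flagged
                 + len(report.high_confidence))
        assert total == report.input_count

    def test_empty_input(self, euk_table):
        report = high_confidence_filter([], table=euk_table)
        assert report.input_count == 0
        assert report.high_confidence == []

    def test_all_passing_untouched(self, euk_table):
        preds = [P() for _ in range(5)]
        report = high_confidence_filter(preds, table=euk_table)
        assert report.high_confidence == preds

    def test_flagged_excluded_but_reported(self, euk_table):
        preds = [P(), P(anticodon="ATC"), P(flags={"IPD"})]
        report = high_confidence_filter(preds, table=euk_table)
        assert len(report.high_confidence) == 1
        assert report.flagged == 2

    def test_non_eukaryote_warns(self, euk_table):
        with pytest.warns(UserWarning):
            high_confidence_filter([P()], table=euk_table, domain="bacteria")

    def test_pseudo_flag_written(self, euk_table):
        p = P(overall=40, primary=5)
        high_confidence_filter([p], table=euk_table)
        assert "pseudo" in p.flags
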