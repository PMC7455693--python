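import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fmtrack import (
    EndpointTable,
    SubjectRecord,
    bonferroni,
    derive_endpoint_tables,
    endpoint_analysis,
    fisher_exact_two_sided,
    format_p_value,
    grade_from_symptoms,
    sample_size_two_proportions,
)

from oracles import fisher_two_sided_oracle


class TestGradeFromSymptoms:
    @pytest.mark.parametrize(
        "increase,kwargs,expected",
        [
            (0, {}, 0),
            (2, {}, 1),
            (5, {}, 2),
            (2, {"nocturnal_stools": True}, 2),
            (7, {}, 3),
            (9, {}, 3),
            (1, {"incontinence_or_parenteral": True}, 3),
            (0, {"intensive_care": True}, 4),
            (9, {"intensive_care": True}, 4),
        ],
    )
    def test_ctc_grading_rules(self, increase, kwargs, expected):
        assert grade_from_symptoms(increase, **kwargs) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            grade_from_symptoms(-1)

    def test_highest_satisfied_grade_wins(self):
        # nocturnal stools (grade-2 clause) never downgrades a grade-3 count
        assert grade_from_symptoms(8, nocturnal_stools=True) == 3


class TestEndpointTables:
    def test_trial_wk4_tables(self, trial_subjects):
        resolution, le_g1 = derive_endpoint_tables(trial_subjects, "wk4")
        assert resolution.counts == [[7, 3], [0, 10]]
        assert le_g1.counts == [[10, 0], [2, 8]]

    def test_row_sums_equal_arm_sizes(self, trial_subjects):
        for visit in ("wk1", "wk2", "wk4", "wk8"):
            for table in derive_endpoint_tables(trial_subjects, visit):
                assert table.arm_sizes == (10, 10)

    def test_le_g1_success_dominates_resolution(self, trial_subjects):
        for visit in ("wk1", "wk2", "wk4", "wk8"):
            resolution, le_g1 = derive_endpoint_tables(trial_subjects, visit)
            for arm in (0, 1):
                assert le_g1.counts[arm][0] >= resolution.counts[arm][0]

    def test_saturated_cohort(self):
        subjects = [
            SubjectRecord(f"d{i}", "DFMT", {"baseline": 2, "wk4": 0}, donor_id="DA")
            for i in range(10)
        ] + [
            SubjectRecord(f"p{i}", "PFMT", {"baseline": 2, "wk4": 0})
            for i in range(10)
        ]
        resolution, le_g1 = derive_endpoint_tables(subjects, "wk4")
        assert resolution.counts == [[10, 0], [10, 0]]
        assert le_g1.counts == [[10, 0], [10, 0]]

    def test_degenerate_single_subject(self):
        subjects = [SubjectRecord("d1", "DFMT", {"baseline": 2, "wk4": 2}, donor_id="DA")]
        resolution, _ = derive_endpoint_tables(subjects, "wk4")
        assert resolution.counts == [[0, 1], [0, 0]]

    def test_missing_grade_counts_as_failure(self):
        subjects = [
            SubjectRecord("d1", "DFMT", {"baseline": 2, "wk4": None}, donor_id="DA"),
            SubjectRecord("p1", "PFMT", {"baseline": 2, "wk4": 0}),
        ]
        resolution, le_g1 = derive_endpoint_tables(subjects, "wk4")
        assert resolution.counts == [[0, 1], [1, 0]]
        assert le_g1.counts == [[0, 1], [1, 0]]

    def test_errors(self, trial_subjects):
        with pytest.raises(ValueError):
            derive_endpoint_tables([], "wk4")
        with pytest.raises(ValueError):
            derive_endpoint_tables(trial_subjects, "wk6")

    def test_subject_validation(self):
        with pytest.raises(ValueError):
            SubjectRecord("x", "DFMT", {"baseline": 2})  # no donor link
        with pytest.raises(ValueError):
            SubjectRecord("x", "PFMT", {"baseline": 2}, donor_id="DA")
        with pytest.raises(ValueError):
            SubjectRecord("x", "PFMT", {"baseline": 1})  # ineligible baseline


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[7, 3], [0, 10]], 0.0031),
            ([[5, 5], [5, 5]], 1.0),
            ([[10, 0], [3, 7]], 0.0031),
            ([[3, 7], [0, 10]], 0.2105),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_exact_two_sided(table) == pytest.approx(expected, abs=5e-5)

    @given(
        st.tuples(
            st.integers(0, 12), st.integers(0, 12),
            st.integers(0, 12), st.integers(0, 12),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        assert fisher_exact_two_sided(table) == pytest.approx(
            float(fisher_two_sided_oracle(table)), abs=1e-9
        )

    @given(
        st.tuples(
            st.integers(0, 10), st.integers(0, 10),
            st.integers(0, 10), st.integers(0, 10),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_row_and_column_swap_invariance(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_sided([[a, b], [c, d]])
        assert fisher_exact_two_sided([[d, c], [b, a]]) == pytest.approx(p, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[1, -1], [0, 0]])


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.0031, 7, 0.0217), (0.2105, 7, 1.0), (0.5, 1, 0.5)],
    )
    def test_examples(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(1e-9, 1.0), st.integers(1, 50), st.integers(1, 50))
    def test_monotone_in_m_and_capped(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        assert bonferroni(p, lo) <= bonferroni(p, hi) <= 1.0
        assert bonferroni(p, lo) >= p

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 3)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestSampleSize:
    def test_trial_design_value(self):
        assert sample_size_two_proportions(0.80, 0.20, 0.05, 0.80) == 10

    def test_hand_evaluated_high_power(self):
        # independent evaluation of the pooled-variance z-formula at power 0.99
        from scipy.stats import norm

        z_a, z_p = norm.isf(0.025), norm.ppf(0.99)
        num = z_a * math.sqrt(2 * 0.5 * 0.5) + z_p * math.sqrt(2 * 0.8 * 0.2)
        expected = math.ceil((num / 0.6) ** 2)
        assert sample_size_two_proportions(0.80, 0.20, 0.05, 0.99) == expected

    @given(
        st.floats(0.05, 0.95), st.floats(0.05, 0.95), st.floats(0.5, 0.99)
    )
    def test_symmetry_and_power_monotonicity(self, a, b, power):
        if abs(a - b) < 0.05:
            return
        p1, p2 = max(a, b), min(a, b)
        n = sample_size_two_proportions(p1, p2, 0.05, power)
        assert sample_size_two_proportions(1 - p2, 1 - p1, 0.05, power) == n
        assert sample_size_two_proportions(p1, p2, 0.05, min(power + 0.009, 0.999)) >= n

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_proportions(0.5, 0.5)


class TestEndpointAnalysis:
    def test_primary_unadjusted_secondaries_adjusted(self, trial_subjects):
        results = endpoint_analysis(trial_subjects, m=7)
        by_key = {(r.visit, r.endpoint): r for r in results}
        primary = by_key[("wk4", "resolution")]
        assert primary.is_primary and primary.test.m == 1
        assert primary.test.p_adjusted == primary.test.p_raw
        secondary = by_key[("wk1", "resolution")]
        assert secondary.test.m == 7
        assert secondary.test.p_adjusted == pytest.approx(
            min(1.0, 7 * secondary.test.p_raw)
        )

    def test_printed_style_rounding(self):
        assert format_p_value(0.0031) == "0.003"
        assert format_p_value(0.0217) == "0.02"
        assert format_p_value(0.0007144) == "0.0007"
        assert format_p_value(1.0) == "1"
        assert format_p_value(0.038) == "0.04"


def test_endpoint_table_validation():
    with pytest.raises(ValueError):
        EndpointTable("wk4", "resolution", [[1, -1], [0, 0]])
    with pytest.raises(ValueError):
        EndpointTable("wk4", "resolution", [[1, 2, 3]])
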