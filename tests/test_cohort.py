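"""Cohort IO, completion, prevalence and the positive-count histogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpmburden import (
    Cohort,
    PatientRecord,
    complete_cohort,
    positive_count_histogram,
    prevalence,
    read_cohort,
)
from mpmburden.cohort import CohortSchemaError, CohortValidationError, write_cohort


def make_cohort(counts, taken=None):
    taken = taken or [13] * len(counts)
    return Cohort(
        records=tuple(
            PatientRecord(patient_id=f"P{i}", n_biopsies_taken=t, n_positive=c)
            for i, (c, t) in enumerate(zip(counts, taken))
        )
    )


# a cohort as a list of (n_taken, n_positive) pairs with 0 <= pos <= taken <= 13
cohort_strategy = st.lists(
    st.integers(1, 13).flatmap(lambda t: st.tuples(st.just(t), st.integers(0, t))),
    min_size=1,
    max_size=40,
).map(lambda pairs: make_cohort([p for _, p in pairs], [t for t, _ in pairs]))


class TestReadCohort:
    def test_reads_reference_cohort(self, ref_cohort):
        assert len(ref_cohort) == 26
        assert ref_cohort.total_positives() == 15

    def test_roundtrip_preserves_rows(self, ref_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(ref_cohort, path)
        again = read_cohort(path)
        assert [r.patient_id for r in again] == [r.patient_id for r in ref_cohort]
        assert [r.n_positive for r in again] == [r.n_positive for r in ref_cohort]

    def test_empty_file_gives_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("patient_id,n_biopsies_taken,n_positive\n")
        assert len(read_cohort(path)) == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,n_biopsies_taken\nA,3\n")
        with pytest.raises(CohortSchemaError, match="n_positive"):
            read_cohort(path)

    def test_positive_exceeding_taken_names_the_patient(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,n_biopsies_taken,n_positive\nA,3,5\n")
        with pytest.raises(CohortValidationError, match="'A'"):
            read_cohort(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_cohort(tmp_path / "nope.csv")

    def test_duplicate_patient_ids_rejected(self):
        rec = PatientRecord(patient_id="X", n_biopsies_taken=3, n_positive=0)
        with pytest.raises(CohortValidationError, match="duplicate"):
            Cohort(records=(rec, rec))


class TestCompletion:
    def test_pads_to_target(self):
        cohort = make_cohort([2], taken=[6])
        done = complete_cohort(cohort, target_n=13)
        assert done.records[0].n_biopsies_taken == 13
        assert done.records[0].n_positive == 2
        assert done.completed

    def test_already_complete_is_identity(self, ref_cohort):
        done = complete_cohort(ref_cohort, target_n=13)
        assert [r.n_positive for r in done] == [r.n_positive for r in ref_cohort]
        assert all(r.n_biopsies_taken == 13 for r in done)

    def test_target_below_taken_is_an_error(self):
        with pytest.raises(CohortValidationError):
            complete_cohort(make_cohort([0], taken=[9]), target_n=6)

    @given(cohort_strategy)
    def test_conserves_positives_and_prevalence(self, cohort):
        done = complete_cohort(cohort)
        assert done.total_positives() == cohort.total_positives()
        assert prevalence(done) == prevalence(cohort)


class TestPrevalence:
    def test_reference_cohort_is_7_of_26(self, ref_cohort):
        assert prevalence(ref_cohort) == pytest.approx(7 / 26)
        assert round(100 * prevalence(ref_cohort), 1) == 26.9

    @pytest.mark.parametrize(
        "counts, expected",
        [([0, 0, 0], 0.0), ([1], 1.0), ([0, 2], 0.5)],
    )
    def test_small_cases(self, counts, expected):
        assert prevalence(make_cohort(counts)) == expected

    def test_empty_cohort_is_undefined(self):
        with pytest.raises(CohortValidationError):
            prevalence(Cohort(records=()))


class TestHistogram:
    def test_reference_frequencies(self, ref_cohort):
        hist = positive_count_histogram(complete_cohort(ref_cohort, target_n=13))
        expected = np.zeros(14)
        expected[[0, 1, 2, 7]] = np.array([19, 4, 2, 1]) / 26
        np.testing.assert_allclose(hist.freq, expected)

    def test_requires_completed_cohort(self):
        with pytest.raises(CohortValidationError, match="complete"):
            positive_count_histogram(make_cohort([0], taken=[5]))

    def test_single_patient_all_mass_at_zero(self):
        hist = positive_count_histogram(complete_cohort(make_cohort([0]), target_n=13))
        assert hist.freq[0] == 1.0
        assert hist.freq[1:].sum() == 0.0

    @given(cohort_strategy)
    def test_frequencies_normalised(self, cohort):
        hist = positive_count_histogram(complete_cohort(cohort))
        assert np.all(hist.freq >= 0)
        assert abs(hist.freq.sum() - 1.0) < 1e-12
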