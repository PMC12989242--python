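"""Incident finding, grouping, exclusion cascade, windows and outcomes."""

import datetime as dt

import pandas as pd
import pytest

from psdoc.cohort import (
    CohortParams,
    ExclusionLog,
    apply_exclusions,
    assign_group_hospital,
    build_cohort,
    derive_outcomes,
    find_incident_cases,
    is_cancer_code,
    map_code_to_group,
    window_documents,
)
from psdoc.extract import document_has_ps, extract_document
from psdoc.synth import documents_to_frame

from _oracles import brute_force_cohort

D = dt.date


def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "code", "date", "hospital_id"])


class TestIncident:
    def test_single_code_is_incident(self):
        ev = _events([("p1", "C50.9", D(2019, 6, 1), "H1")])
        assert find_incident_cases(ev) == {"p1": D(2019, 6, 1)}

    def test_prior_code_within_washout_blocks(self):
        """Codes 273 days apart: the later one is not a new diagnosis, and
        the earlier one is outside the study window, so the patient drops."""
        ev = _events([
            ("p1", "C50.9", D(2018, 9, 1), "H1"),
            ("p1", "C50.9", D(2019, 6, 1), "H1"),
        ])
        assert find_incident_cases(ev) == {}

    def test_open_interval_boundary_730_days(self):
        ev = _events([
            ("p1", "C50.9", D(2019, 6, 1) - dt.timedelta(days=730), "H1"),
            ("p1", "C50.9", D(2019, 6, 1), "H1"),
        ])
        assert find_incident_cases(ev) == {"p1": D(2019, 6, 1)}
        ev2 = _events([
            ("p2", "C50.9", D(2019, 6, 1) - dt.timedelta(days=729), "H1"),
            ("p2", "C50.9", D(2019, 6, 1), "H1"),
        ])
        assert find_incident_cases(ev2) == {}

    def test_non_cancer_codes_ignored(self):
        ev = _events([
            ("p1", "I10", D(2018, 9, 1), "H1"),
            ("p1", "C34.1", D(2019, 6, 1), "H1"),
        ])
        assert find_incident_cases(ev) == {"p1": D(2019, 6, 1)}

    def test_index_is_earliest_in_study_window(self):
        ev = _events([
            ("p1", "C34.1", D(2019, 3, 1), "H1"),
            ("p1", "C34.1", D(2020, 3, 1), "H2"),
        ])
        assert find_incident_cases(ev) == {"p1": D(2019, 3, 1)}


class TestGrouping:
    @pytest.mark.parametrize(
        "code, group",
        [
            ("C50.9", "Breast"), ("C18.0", "Colorectal"), ("C20", "Colorectal"),
            ("C34.1", "Lung"), ("C33", "Lung"), ("C61", "Prostate"),
            ("C53.9", "Gynaecological"), ("C56", "Gynaecological"),
            ("C64", "Genitourinary"), ("C67.2", "Genitourinary"),
            ("C43.5", "Skin"), ("C44.3", "Skin"),
            ("C81.9", "Haematological"), ("C90.0", "Haematological"),
            ("C15.3", "OtherGI"), ("C16.0", "OtherGI"), ("C22.0", "OtherGI"),
            ("C25.9", "OtherGI"), ("C71.9", "Other"), ("C73", "Other"),
            ("C32.9", "Other"),
        ],
    )
    def test_mapping_table(self, code, group):
        assert map_code_to_group(code) == group

    def test_unmappable_code_falls_back_to_other(self):
        assert map_code_to_group("ZZZ") == "Other"

    def test_is_cancer_code(self):
        assert is_cancer_code("C97")
        assert is_cancer_code("C00.1")
        assert not is_cancer_code("C98")
        assert not is_cancer_code("I10")
        assert not is_cancer_code("D05.1")
        assert is_cancer_code("D05.1", include_in_situ=True)
        assert is_cancer_code("D40", include_in_situ=True)
        assert not is_cancer_code("D20", include_in_situ=True)

    def test_same_day_tie_breaks_on_code(self):
        ev = _events([
            ("p1", "C61", D(2019, 6, 1), "H2"),
            ("p1", "C34.1", D(2019, 6, 1), "H1"),
        ])
        incident = find_incident_cases(ev)
        assigned = assign_group_hospital(ev, incident)
        row = assigned.iloc[0]
        assert row["index_code"] == "C34.1"  # lexicographically first
        assert row["cancer_group"] == "Lung"
        assert row["hospital_id"] == "H1"

    def test_group_fixed_at_first_code(self):
        """Later codes of a different site never change the group."""
        ev = _events([
            ("p1", "C50.9", D(2019, 6, 1), "H1"),
            ("p1", "C34.1", D(2019, 8, 1), "H1"),
        ])
        incident = find_incident_cases(ev)
        assigned = assign_group_hospital(ev, incident)
        assert assigned.iloc[0]["cancer_group"] == "Breast"


class TestWindow:
    def _docs(self, dates):
        return pd.DataFrame({
            "doc_id": [f"d{i}" for i in range(len(dates))],
            "patient_id": "p1",
            "doc_type": "MDT",
            "date": dates,
        })

    def test_inclusive_bounds(self):
        idx = D(2019, 6, 1)
        docs = self._docs([
            idx - dt.timedelta(days=90),   # kept: lower bound inclusive
            idx - dt.timedelta(days=91),   # dropped
            idx + dt.timedelta(days=365),  # kept: upper bound inclusive
            idx + dt.timedelta(days=366),  # dropped
            idx,                           # kept
        ])
        kept = window_documents(docs, {"p1": idx})
        assert sorted(kept["doc_id"]) == ["d0", "d2", "d4"]

    def test_only_known_patients_and_types_kept(self):
        idx = D(2019, 6, 1)
        docs = pd.DataFrame({
            "doc_id": ["a", "b"],
            "patient_id": ["p1", "p2"],
            "doc_type": ["OTHER", "MDT"],
            "date": [idx, idx],
        })
        kept = window_documents(docs, {"p1": idx})
        assert len(kept) == 0


class TestOutcomes:
    def test_metastatic_window_boundaries(self):
        idx = D(2019, 6, 1)
        ev = _events([("p1", "C78.0", idx + dt.timedelta(days=30), "H1")])
        assert derive_outcomes(idx, ev, None) == (True, False)
        ev = _events([("p1", "C78.0", idx + dt.timedelta(days=90), "H1")])
        assert derive_outcomes(idx, ev, None)[0] is True
        ev = _events([("p1", "C78.0", idx + dt.timedelta(days=91), "H1")])
        assert derive_outcomes(idx, ev, None)[0] is False
        ev = _events([("p1", "C78.0", idx - dt.timedelta(days=1), "H1")])
        assert derive_outcomes(idx, ev, None)[0] is False

    def test_death_boundaries(self):
        idx = D(2019, 6, 1)
        ev = _events([])
        assert derive_outcomes(idx, ev, idx + dt.timedelta(days=365))[1] is True
        assert derive_outcomes(idx, ev, idx + dt.timedelta(days=366))[1] is False

    def test_death_before_index_warns_and_counts(self):
        idx = D(2019, 6, 1)
        with pytest.warns(UserWarning, match="precedes"):
            met, died = derive_outcomes(idx, _events([]), idx - dt.timedelta(days=5))
        assert died is True


class TestExclusions:
    def _fixture(self):
        """20 incident candidates with hand-computable exclusion counts.

        Hospitals: HA x 12, HB x 6, HC x 2 (HC share 10% -> kept; with a
        1%-threshold nobody is small), so the hospital step removes only the
        paediatric flag when configured.  Two minors, one male/gynaecological,
        one female/prostate, three without documents.
        """
        rows = []
        for i in range(20):
            hosp = "HA" if i < 12 else ("HB" if i < 18 else "HC")
            rows.append({
                "patient_id": f"p{i:02d}", "index_date": D(2019, 6, 1),
                "index_code": "C50.9", "cancer_group": "Breast",
                "hospital_id": hosp,
            })
        cand = pd.DataFrame(rows)
        cand.loc[2, "cancer_group"] = "Gynaecological"
        cand.loc[3, "cancer_group"] = "Prostate"
        patients = pd.DataFrame({
            "patient_id": [f"p{i:02d}" for i in range(20)],
            "sex": ["M" if i in (2, 4) else "F" for i in range(20)],
            "birth_date": [
                D(2003, 1, 1) if i in (0, 1) else D(1960, 1, 1) for i in range(20)
            ],
        })
        doc_counts = pd.DataFrame({
            "patient_id": [f"p{i:02d}" for i in range(20)],
            "n_mdt": [0 if i in (5, 6, 7) else 1 for i in range(20)],
            "n_consult": 0,
            "n_hosp": 0,
        })
        return cand, patients, doc_counts

    def test_cascade_counts_match_hand_enumeration(self):
        cand, patients, doc_counts = self._fixture()
        cohort, log = apply_exclusions(cand, patients, doc_counts)
        # p00, p01 minors; p02 M+gynaecological, p03 F+prostate; p05-07 no docs
        assert [(s, r) for s, r, _ in log.steps] == [
            ("incident candidates", 0),
            ("age under 18", 2),
            ("hospital share below threshold or paediatric", 0),
            ("sex and cancer-site mismatch", 2),
            ("no document in window", 3),
        ]
        assert log.steps[-1][2] == len(cohort) == 13
        assert "p04" in set(cohort["patient_id"])  # male breast retained

    def test_paediatric_hospital_flag(self):
        cand, patients, doc_counts = self._fixture()
        params = CohortParams(paediatric_hospitals=("HC",))
        cohort, log = apply_exclusions(cand, patients, doc_counts, params)
        step = dict((s, r) for s, r, _ in log.steps)
        assert step["hospital share below threshold or paediatric"] == 2

    def test_hospital_share_uses_pre_exclusion_denominator(self):
        cand, patients, doc_counts = self._fixture()
        # HC holds 2/20 = 10%: below a 15% threshold even though later steps
        # would change the denominator
        params = CohortParams(hospital_min_share=0.15)
        _, log = apply_exclusions(cand, patients, doc_counts, params)
        step = dict((s, r) for s, r, _ in log.steps)
        assert step["hospital share below threshold or paediatric"] == 2

    def test_exclusion_log_is_monotone(self):
        log = ExclusionLog()
        log.add("a", 0, 10)
        log.add("b", 2, 8)
        with pytest.raises(ValueError):
            log.add("c", 0, 9)


class TestEndToEnd:
    def test_builder_equals_brute_force_oracle(self, small_world):
        """Whole-builder equivalence with an independent re-derivation."""
        _, patients, events, documents = small_world
        doc_frame = documents_to_frame(documents)
        doc_has_ps = {
            d.doc_id: document_has_ps(extract_document(d.doc_id, d.text))
            for d in documents
        }
        cohort, _ = build_cohort(patients, events, doc_frame, doc_has_ps)
        oracle = brute_force_cohort(patients, events, doc_frame, doc_has_ps)
        got = cohort.sort_values("patient_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(got, oracle, check_dtype=False)

    def test_washout_violators_are_excluded(self, small_world):
        _, patients, events, documents = small_world
        incident = find_incident_cases(events)
        violators = set(
            patients.loc[patients["true_washout_violator"], "patient_id"])
        assert violators, "fixture should contain violators"
        assert violators.isdisjoint(incident)
        non_violators = set(patients["patient_id"]) - violators
        assert non_violators <= set(incident)

    def test_rerun_is_deterministic(self, small_world):
        _, patients, events, documents = small_world
        doc_frame = documents_to_frame(documents)
        doc_has_ps = {d.doc_id: d.gold_has_ps for d in documents}
        c1, l1 = build_cohort(patients, events, doc_frame, doc_has_ps)
        c2, l2 = build_cohort(patients, events, doc_frame, doc_has_ps)
        pd.testing.assert_frame_equal(c1, c2)
        assert l1.steps == l2.steps

    def test_cohort_rows_satisfy_invariants(self, small_world):
        _, patients, events, documents = small_world
        doc_frame = documents_to_frame(documents)
        doc_has_ps = {d.doc_id: d.gold_has_ps for d in documents}
        cohort, _ = build_cohort(patients, events, doc_frame, doc_has_ps)
        assert (cohort["age_at_dx"] >= 18).all()
        assert (cohort[["n_mdt", "n_consult", "n_hosp"]].sum(axis=1) >= 1).all()
        assert not ((cohort.sex == "M")
                    & (cohort.cancer_group == "Gynaecological")).any()
        assert not ((cohort.sex == "F") & (cohort.cancer_group == "Prostate")).any()
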