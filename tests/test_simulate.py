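"""Cohort simulation, empirical estimation and the exact enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import binom

from catlr.categories import CategoryNode, FindingModel
from catlr.errors import (
    DegenerateEvidenceError,
    DomainError,
    StratumEmptyError,
)
from catlr.io import DiseaseEntry, DiseaseTable, PatientProfile
from catlr.simulate import (
    Cohort,
    GenerativeModel,
    category_accuracy_table,
    demo_abdominal_model,
    estimate_category_accuracy,
    exact_category_posteriors,
    exact_posterior,
    naive_vs_exact,
    sequential_category_posteriors,
    simulate_cohort,
)

from conftest import make_homogeneous_model, make_random_model


class TestSimulateCohort:
    def test_reproducible_for_fixed_seed(self):
        model = make_random_model(seed=1)
        a = simulate_cohort(model, 500, seed=9)
        b = simulate_cohort(model, 500, seed=9)
        assert np.array_equal(a.disease_idx, b.disease_idx)
        assert np.array_equal(a.X, b.X)
        c = simulate_cohort(model, 500, seed=10)
        assert not np.array_equal(a.X, c.X)

    def test_empty_cohort(self):
        cohort = simulate_cohort(make_random_model(), 0, seed=0)
        assert cohort.n == 0

    def test_negative_n_rejected(self):
        with pytest.raises(DomainError):
            simulate_cohort(make_random_model(), -1, seed=0)

    def test_degenerate_prevalence(self):
        entries = [
            DiseaseEntry("only", "only", 100.0, ("c",)),
            DiseaseEntry("never", "never", 0.0, ("other",)),
        ]
        model = GenerativeModel(
            diseases=DiseaseTable(entries=entries),
            findings=[FindingModel("f", {"only": 0.5, "never": 0.5})],
        )
        cohort = simulate_cohort(model, 200, seed=3)
        assert set(cohort.patient_disease_ids) == {"only"}

    def test_disease_frequencies_within_exact_99pct_binomial_bounds(self):
        model = make_random_model(n_diseases=5, seed=4)
        n = 10_000
        cohort = simulate_cohort(model, n, seed=21)
        for disease_id, p in zip(model.disease_ids, model.prevalence):
            count = int((cohort.patient_disease_ids == disease_id).sum())
            lo, hi = binom.interval(0.99, n, p)
            assert lo <= count <= hi

    def test_csv_round_trip_shape(self, tmp_path):
        import pandas as pd

        model = make_random_model(n_findings=4)
        cohort = simulate_cohort(model, 50, seed=6)
        path = tmp_path / "cohort.csv"
        cohort.write_csv(path)
        df = pd.read_csv(path)
        assert df.shape == (50, 5)
        assert list(df.columns[1:]) == list(model.finding_ids)


class TestEstimateCategoryAccuracy:
    def test_perfectly_separating_finding(self):
        model = make_homogeneous_model(p_in=1.0, p_out=0.0, n_findings=1)
        cohort = simulate_cohort(model, 500, seed=2)
        sens, spec = estimate_category_accuracy(
            cohort, "f0", model.category("inside")
        )
        assert sens.point == 1.0
        assert spec.point == 1.0

    def test_hand_countable_toy_cohort(self):
        """Ten listed patients: estimates must equal the manual 2x2 tally."""
        disease_ids = ("in1", "out1")
        # members: patients 0-3 (findings + + - +) -> sens 3/4
        # non-members: patients 4-9 (findings + - - - + -) -> spec 4/6
        disease_idx = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        X = np.array([[1], [1], [0], [1], [1], [0], [0], [0], [1], [0]], dtype=bool)
        cohort = Cohort(
            disease_ids=disease_ids, finding_ids=("f",),
            disease_idx=disease_idx, X=X, seed=0,
        )
        node = CategoryNode(path=("in",), member_ids=frozenset({"in1"}))
        sens, spec = estimate_category_accuracy(cohort, "f", node)
        assert (sens.point, sens.n_pos, sens.n_neg) == (0.75, 3, 1)
        assert spec.point == pytest.approx(4 / 6)
        assert sens.ci_low <= sens.point <= sens.ci_high

    def test_large_cohort_recovers_homogeneous_accuracy(self):
        model = make_homogeneous_model(p_in=0.9, p_out=0.2)
        cohort = simulate_cohort(model, 200_000, seed=17)
        sens, spec = estimate_category_accuracy(cohort, "f0", model.category("inside"))
        assert abs(sens.point - 0.9) <= 3 * (sens.ci_high - sens.ci_low) / 2
        assert abs(spec.point - 0.8) <= 3 * (spec.ci_high - spec.ci_low) / 2

    def test_empty_stratum_raises(self):
        model = make_random_model()
        cohort = simulate_cohort(model, 100, seed=0)
        ghost = CategoryNode(path=("ghost",), member_ids=frozenset({"nobody"}))
        with pytest.raises(StratumEmptyError):
            estimate_category_accuracy(cohort, "f0", ghost)


class TestExactPosterior:
    def test_empty_profile_returns_prior(self):
        model = make_random_model(seed=8)
        post = exact_posterior(model, PatientProfile())
        np.testing.assert_allclose(
            [post["diseases"][d] for d in model.disease_ids],
            model.prevalence, atol=1e-12,
        )

    def test_uninformative_finding_returns_prior(self):
        model = make_homogeneous_model(p_in=0.3, p_out=0.3, n_findings=1)
        post = exact_posterior(model, PatientProfile(results={"f0": "present"}))
        np.testing.assert_allclose(
            [post["diseases"][d] for d in model.disease_ids],
            model.prevalence, atol=1e-12,
        )

    def test_matches_explicit_joint_table(self):
        """Independent oracle: sum the full n_diseases x 2^n_findings table."""
        model = make_random_model(n_diseases=5, n_findings=3, seed=13)
        profile = PatientProfile(results={"f0": "present", "f2": "absent"})
        prev = model.prevalence
        pm = model.prob_matrix
        joint = {}  # (disease index, finding vector) -> probability
        for i in range(5):
            for vec in itertools.product([0, 1], repeat=3):
                p = prev[i]
                for j, v in enumerate(vec):
                    p *= pm[i, j] if v else (1 - pm[i, j])
                joint[(i, vec)] = p
        # condition on f0 = 1, f2 = 0 (f1 unknown -> marginalized)
        consistent = {
            k: v for k, v in joint.items() if k[1][0] == 1 and k[1][2] == 0
        }
        total = sum(consistent.values())
        expected = [
            sum(v for (i, _), v in consistent.items() if i == d) / total
            for d in range(5)
        ]
        post = exact_posterior(model, profile)
        got = [post["diseases"][f"d{i}"] for i in range(5)]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_normalization_and_category_sums(self):
        model = make_random_model(n_diseases=6, n_findings=3, seed=19)
        profile = PatientProfile(results={"f0": "present", "f1": "absent"})
        post = exact_posterior(model, profile)
        assert sum(post["diseases"].values()) == pytest.approx(1.0, abs=1e-9)
        for path in ("alpha", "beta"):
            members = model.category(path).member_ids
            assert post["categories"][path] == pytest.approx(
                sum(post["diseases"][d] for d in members), abs=1e-12
            )

    def test_impossible_evidence_raises(self):
        model = make_homogeneous_model(p_in=0.0, p_out=0.0, n_findings=1)
        with pytest.raises(DegenerateEvidenceError):
            exact_posterior(model, PatientProfile(results={"f0": "present"}))


class TestNaiveVsExact:
    def test_single_finding_discrepancy_is_zero(self):
        model = make_random_model(n_diseases=6, n_findings=1, seed=23)
        report = naive_vs_exact(
            model, PatientProfile(results={"f0": "present"}), "alpha"
        )
        assert report.abs_diff <= 1e-10

    def test_homogeneous_multi_finding_discrepancy_is_zero(self):
        model = make_homogeneous_model(p_in=0.8, p_out=0.25, n_findings=4)
        profile = PatientProfile(
            results={"f0": "present", "f1": "present", "f2": "absent", "f3": "absent"}
        )
        report = naive_vs_exact(model, profile, "inside")
        assert report.abs_diff <= 1e-10

    def test_heterogeneous_model_reports_nonzero_discrepancy(self):
        entries = [
            DiseaseEntry("h1", "h1", 25.0, ("c",)),
            DiseaseEntry("h2", "h2", 25.0, ("c",)),
            DiseaseEntry("z", "z", 50.0, ("other",)),
        ]
        findings = [
            FindingModel(f"f{j}", {"h1": 0.9, "h2": 0.3, "z": 0.2}) for j in range(3)
        ]
        model = GenerativeModel(diseases=DiseaseTable(entries=entries),
                                findings=findings)
        profile = PatientProfile(
            results={"f0": "present", "f1": "present", "f2": "present"}
        )
        report = naive_vs_exact(model, profile, "c")
        assert report.abs_diff > 1e-4
        assert math.isfinite(report.log_odds_diff)

    def test_vectorized_posteriors_match_scalar_paths(self):
        model = make_random_model(n_diseases=6, n_findings=3, seed=29)
        profile = PatientProfile(
            results={"f0": "present", "f1": "absent", "f2": "present"}
        )
        X = np.array([[True, False, True]])
        report = naive_vs_exact(model, profile, "alpha")
        assert sequential_category_posteriors(model, "alpha", X)[0] == pytest.approx(
            report.sequential_posterior, abs=1e-12
        )
        assert exact_category_posteriors(model, "alpha", X)[0] == pytest.approx(
            report.exact_posterior, abs=1e-12
        )


class TestGenerativeModel:
    def test_json_round_trip(self):
        model = make_random_model(seed=31)
        again = GenerativeModel.from_json(model.to_json())
        assert again == model

    def test_uncovered_disease_rejected(self):
        entries = [
            DiseaseEntry("a", "a", 60.0, ("c",)),
            DiseaseEntry("b", "b", 40.0, ("d",)),
        ]
        with pytest.raises(DomainError):
            GenerativeModel(
                diseases=DiseaseTable(entries=entries),
                findings=[FindingModel("f", {"a": 0.5})],
            )

    def test_prevalence_renormalized(self, diseases):
        model = demo_abdominal_model(heterogeneity=0.0)
        assert model.prevalence.sum() == pytest.approx(1.0, abs=1e-9)


class TestDemoModel:
    def test_zero_heterogeneity_reproduces_bundled_lrs(self, abdominal_table):
        """At zero heterogeneity the analytic category LRs equal the table."""
        model = demo_abdominal_model(heterogeneity=0.0)
        derived = category_accuracy_table(model, "organic")
        for row in abdominal_table:
            got = derived.get(row.finding_id)
            assert got.lr_pos == pytest.approx(row.lr_pos, rel=1e-9)
            assert got.lr_neg == pytest.approx(row.lr_neg, rel=1e-9)

    def test_heterogeneous_demo_stays_near_bundled_lrs(self, abdominal_table):
        model = demo_abdominal_model(heterogeneity=0.15, seed=0)
        derived = category_accuracy_table(model, "organic")
        for row in abdominal_table:
            got = derived.get(row.finding_id)
            assert got.lr_pos == pytest.approx(row.lr_pos, rel=0.25)
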