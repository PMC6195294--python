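"""Published-equation evaluation, geometry terms, refitting and filtering."""

import numpy as np
import pytest
from scipy import stats

from caninebsp.regression import (
    CollinearityError,
    MissingDimensionError,
    MorphometricRecord,
    NonPhysicalWarning,
    build_term,
    equations_for,
    evaluate,
    fit,
    load_dimension_dictionary,
    load_equations,
    predict_all,
    repeatability_filter,
    select_shape,
)
from caninebsp.synthetic_data import (
    CohortSpec,
    generate_cohort_from_equation,
    nominal_dimensions,
)


def full_record(body_mass=36.8, scale=1.0):
    dims = {}
    for seg in ("manus", "antebrachium", "brachium", "pes", "crus", "thigh",
                "head", "neck", "abdomen", "thorax", "tail"):
        dims.update({k: v * scale for k, v in nominal_dimensions(seg).items()})
    return MorphometricRecord(body_mass=body_mass, dimensions=dims)


class TestTranscription:
    def test_cardinality(self):
        eqs = load_equations()
        assert len(eqs) == 44
        assert sum(e.quantity == "mass" for e in eqs) == 11
        assert sum(e.quantity.startswith("I_") for e in eqs) == 33

    def test_every_segment_has_four_equations(self):
        eqs = load_equations()
        for seg in ("manus", "antebrachium", "brachium", "pes", "crus", "thigh",
                    "head", "neck", "abdomen", "thorax", "tail"):
            assert len([e for e in eqs if e.segment == seg]) == 4

    def test_flexion_extension_always_on_yy(self):
        for eq in load_equations():
            if eq.quantity == "I_yy":
                assert eq.anatomical_axis == "flx_ext"

    def test_dimension_keys_defined_in_dictionary(self):
        dd = load_dimension_dictionary()
        for eq in load_equations():
            for key in eq.dimension_keys:
                assert key in dd[eq.segment], (eq.segment, key)

    def test_body_mass_slope_matches_transcribed_coefficient(self):
        # finite difference in body mass with dimensions fixed, all 44 rows
        rec_lo = full_record(35.0)
        rec_hi = full_record(37.0)
        for eq in load_equations():
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v_lo = evaluate(eq, rec_lo).value
                v_hi = evaluate(eq, rec_hi).value
            slope = (v_hi - v_lo) / 2.0
            if eq.geometry_times_mass and eq.term_kind != "mass_only":
                term = build_term(
                    eq.term_kind,
                    [rec_lo.get(f"{eq.segment}.{k}") for k in eq.dimension_keys],
                )
                slope -= eq.term_coef * term
            assert slope == pytest.approx(eq.a_coef, rel=1e-9, abs=1e-12), (
                eq.segment, eq.quantity
            )


class TestEvaluate:
    def test_manus_mass_worked_example(self):
        rec = MorphometricRecord(36.8, {"manus.b": 0.20, "manus.c": 0.14})
        eq = equations_for("manus", "mass")[0]
        assert evaluate(eq, rec).value == pytest.approx(0.2401, abs=1e-4)

    def test_manus_flexion_moi_validity_boundary(self):
        eq = equations_for("manus", "I_yy")[0]
        rec = MorphometricRecord(43.6, {})
        with pytest.warns(NonPhysicalWarning):
            pv = evaluate(eq, rec)
        assert pv.value == pytest.approx(0.0, abs=1e-12)
        assert not pv.physical
        assert not pv.within_calibration

    def test_missing_dimension_names_the_key(self):
        eq = equations_for("tail", "mass")[0]
        with pytest.raises(MissingDimensionError, match="tail.c"):
            evaluate(eq, MorphometricRecord(36.8, {"tail.b": 0.4}))


class TestPredictAll:
    def test_complete_record_yields_all_44(self):
        preds, missing = predict_all(full_record())
        assert missing == []
        masses = [seg for seg, qs in preds.items() if "mass" in qs]
        mois = sum(q.startswith("I_") for qs in preds.values() for q in qs)
        assert len(masses) == 11
        assert mois == 33

    def test_missing_sacrum_circumference_drops_only_tail(self):
        rec = full_record()
        dims = dict(rec.dimensions)
        del dims["tail.c"]  # every tail equation uses the sacrum circumference
        preds, missing = predict_all(MorphometricRecord(rec.body_mass, dims))
        assert len(missing) == 4
        assert all(m.startswith("tail.") for m in missing)
        assert "tail" not in preds
        assert len([s for s in preds if "mass" in preds[s]]) == 10

    def test_predicted_masses_sum_near_body_mass(self):
        # synthetic record at reference proportions: limb masses count twice
        preds, _ = predict_all(full_record())
        total = sum(
            preds[s]["mass"].value * (2.0 if s in
                ("manus", "antebrachium", "brachium", "pes", "crus", "thigh")
                else 1.0)
            for s in preds
        )
        assert total == pytest.approx(36.8, rel=0.15)


class TestBuildTerm:
    def test_transverse_cylinder_identity(self):
        # c = 2*pi (r = 1): 0.076 c^2 ~ 3 r^2
        assert build_term("transverse_cylinder", [2 * np.pi, 0.0]) == pytest.approx(
            3.0, rel=2e-3
        )

    def test_axial_frustum_continuous_at_equal_radii(self):
        limit = build_term("axial_frustum", [1.0, 1.0])
        assert limit == pytest.approx(5.0 / 3.0)
        near = build_term("axial_frustum", [1.0, 1.0 - 1e-7])
        assert near == pytest.approx(limit, rel=1e-6)

    def test_frustum_volume_cylinder_limit(self):
        b, c = 0.1, 0.4
        assert build_term("frustum_volume", [c, b, b]) == pytest.approx(3 * b * b * c)

    def test_transverse_cylinder_nonnegative(self, rng):
        for _ in range(100):
            c, b = rng.uniform(0, 2, size=2)
            assert build_term("transverse_cylinder", [c, b]) >= 0.0

    def test_arity_checked(self):
        with pytest.raises(ValueError):
            build_term("cylinder_volume", [1.0])


class TestFit:
    def _cohort(self, noise_cv, seed=0, n=12):
        eq = equations_for("crus", "I_yy")[0]
        return eq, *generate_cohort_from_equation(
            eq, CohortSpec(n=n, seed=seed), noise_cv=noise_cv
        )

    def test_noise_free_exact_recovery(self):
        eq, cohort, beta = self._cohort(0.0)
        res = fit(cohort, eq.term_kind, eq.dimension_keys, eq.segment, True)
        assert np.allclose(res.coefficients, beta, rtol=1e-7)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_two_standard_errors_typically(self):
        eq = equations_for("crus", "I_yy")[0]
        max_t = []
        for seed in range(9):
            cohort, beta = generate_cohort_from_equation(
                eq, CohortSpec(n=12, seed=seed), noise_cv=0.01
            )
            res = fit(cohort, eq.term_kind, eq.dimension_keys, eq.segment, True)
            max_t.append(np.max(np.abs(res.coefficients - beta) / res.std_errors))
        assert np.median(max_t) <= 2.0

    def test_constant_regressor_collinear(self):
        eq, cohort, _ = self._cohort(0.0)
        # identical body mass and dimensions for every record: the geometry
        # term and intercept columns are proportional, so the design is singular
        frozen = [(MorphometricRecord(36.8, {k: 0.1 for k in r.dimensions}), y)
                  for r, y in cohort]
        with pytest.raises(CollinearityError):
            fit(frozen, eq.term_kind, eq.dimension_keys, eq.segment, True)

    def test_minimum_cohort_size(self):
        eq, cohort, _ = self._cohort(0.0)
        with pytest.raises(ValueError):
            fit(cohort[:3], eq.term_kind, eq.dimension_keys, eq.segment, True)


class TestSelectShape:
    CANDIDATES = [
        ("transverse_cylinder", ("c", "b")),
        ("ellipsoid_sum", ("c", "b")),
        ("axial_circ", ("c",)),
        ("cylinder_volume", ("b", "c")),
    ]

    def test_generating_shape_selected_in_at_least_ninety_percent_of_seeds(self):
        eq = equations_for("crus", "I_yy")[0]
        hits = 0
        for seed in range(50):
            cohort, _ = generate_cohort_from_equation(
                eq, CohortSpec(n=12, seed=seed), noise_cv=0.01
            )
            best, _ = select_shape(cohort, self.CANDIDATES, eq.segment, True)
            hits += best.term_kind == eq.term_kind
        assert hits >= 45

    def test_single_candidate_returned(self):
        eq = equations_for("crus", "I_yy")[0]
        cohort, _ = generate_cohort_from_equation(eq, CohortSpec(n=12, seed=1))
        best, ranking = select_shape(
            cohort, [("transverse_cylinder", ("c", "b"))], "crus", True
        )
        assert best.term_kind == "transverse_cylinder"
        assert len(ranking) == 1

    def test_identical_candidates_tie_break_deterministic(self):
        eq = equations_for("crus", "I_yy")[0]
        cohort, _ = generate_cohort_from_equation(eq, CohortSpec(n=12, seed=1))
        best, ranking = select_shape(
            cohort,
            [("transverse_cylinder", ("c", "b")),
             ("transverse_cylinder", ("c", "b"))],
            "crus", True,
        )
        assert len(ranking) == 2
        assert ranking[0].r_squared == pytest.approx(ranking[1].r_squared)


class TestRepeatabilityFilter:
    def test_identical_sets_included(self):
        include, p = repeatability_filter([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert include and p == 1.0

    def test_systematic_shift_excluded(self, rng):
        base = rng.uniform(1, 2, size=5)
        shifted = base + 1.0 + rng.normal(0, 1e-6, size=5)
        include, p = repeatability_filter(base, shifted)
        assert not include and p < 1e-6

    def test_zero_variance_nonzero_mean(self):
        include, p = repeatability_filter([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert not include and p == 0.0

    def test_matches_independent_statistics_routine(self, rng):
        x1 = rng.normal(10, 1, size=6)
        x2 = x1 + rng.normal(0.2, 0.3, size=6)
        _, p = repeatability_filter(x1, x2)
        assert p == pytest.approx(stats.ttest_rel(x1, x2).pvalue, rel=1e-10)
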