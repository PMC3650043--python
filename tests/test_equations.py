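"""Unit and property tests for the risk-equation engine."""

import io
import math

import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from cvdrisk import (
    EquationConfigError,
    EquationLibrary,
    IncompleteProfileError,
    ReferenceProfileError,
    RiskEquation,
    spline_transform,
)

finite = st.floats(min_value=-500, max_value=500, allow_nan=False)


@pytest.mark.parametrize(
    "x, knot, expected",
    [
        (8.0, 7.0, (7.0, 1.0)),
        (6.5, 7.0, (6.5, 0.0)),
        (7.0, 7.0, (7.0, 0.0)),  # the high piece vanishes exactly at the knot
    ],
)
def test_spline_transform_examples(x, knot, expected):
    assert spline_transform(x, knot) == expected


@given(x=finite, knot=finite)
def test_spline_pieces_sum_to_covariate(x, knot):
    low, high = spline_transform(x, knot)
    assert low + high == pytest.approx(x, abs=1e-9)
    assert high >= 0.0
    assert low <= knot or math.isclose(low, knot)


class TestWorkedExample:
    """The published illustrative patient: a non-smoking 58-year-old male
    diagnosed 10 years ago with HbA1c 8.0, SBP 150, TC/HDL 4.3, LDL 2.0
    and macroalbuminuria."""

    def test_first_ami_linear_predictor(self, library, profile):
        # independent hand sum of the printed terms
        expected = (
            -7.8187 + 0.5719 + 0.0829 * 0.73 + 0.0079 * 9.08
            + 0.1712 * 0.41 + 0.1161 * (-0.77) + 0.0541 * (-8.02)
        )
        lp = library["ami:first"].linear_predictor(profile)
        assert lp == pytest.approx(expected, abs=1e-12)
        assert lp == pytest.approx(-7.5676, abs=5e-4)

    def test_second_ami_linear_predictor(self, library, profile):
        expected = -2.5755 + 0.5478 + 0.1745 * (-0.54) + 0.0254 * (-8.64) + 0.0566 * 0
        lp = library["ami:second"].linear_predictor(profile)
        assert lp == pytest.approx(expected, abs=1e-12)
        assert lp == pytest.approx(-2.3414, abs=5e-4)

    def test_five_year_cumulative_hazard(self, library, profile):
        H = library["ami:first"].cumulative_hazard(profile, 10, 15)
        lp = library["ami:first"].linear_predictor(profile)
        assert H == pytest.approx(math.exp(lp) * (15**2.0537 - 10**2.0537), rel=1e-12)
        assert H == pytest.approx(0.0760, abs=5e-4)

    def test_five_year_risks_match_printed_values(self, library, profile):
        r1 = library["ami:first"].interval_risk(profile, 10, 15)
        r2 = library["ami:second"].interval_risk(profile, 0, 5)
        assert r1 == pytest.approx(0.0732, abs=5e-5)
        assert r2 == pytest.approx(0.2909, abs=5e-4)  # printed value carries rounding


def test_centering_identity(library):
    """A profile sitting exactly at the centering constants with all
    indicators zero reproduces the equation's constant."""
    eq = library["ami:first"]
    prof = {name: 0 for name in eq.required_covariates()}
    prof.update(eq.centering)
    assert eq.linear_predictor(prof) == pytest.approx(eq.constant, abs=1e-12)


def test_missing_covariate_is_named(library, profile):
    p = dict(profile)
    del p["hba1c"]
    with pytest.raises(IncompleteProfileError, match="hba1c"):
        library["ami:first"].linear_predictor(p)


def test_missing_centering_is_a_config_error(library, profile):
    # the shipped first-HF equation has unpublished centering constants
    with pytest.raises(EquationConfigError, match="centering"):
        library["hf:first"].linear_predictor(profile)


def test_interval_validation(library, profile):
    eq = library["ami:first"]
    assert eq.cumulative_hazard(profile, 3.0, 3.0) == 0.0
    with pytest.raises(ValueError):
        eq.cumulative_hazard(profile, 5.0, 4.0)
    with pytest.raises(ValueError):
        eq.cumulative_hazard(profile, -1.0, 4.0)


@given(
    a=st.floats(min_value=0, max_value=30),
    w1=st.floats(min_value=0, max_value=10),
    w2=st.floats(min_value=0, max_value=10),
)
def test_hazard_additivity_and_risk_composition(library, profile, a, w1, w2):
    """ΔH(a,c) = ΔH(a,b) + ΔH(b,c) exactly for closed-form equations, and
    interval risks compose multiplicatively on survival."""
    b, c = a + w1, a + w1 + w2
    for key in ("ami:first", "ami:second"):
        eq = library[key]
        h_ab = eq.cumulative_hazard(profile, a, b)
        h_bc = eq.cumulative_hazard(profile, b, c)
        h_ac = eq.cumulative_hazard(profile, a, c)
        assert h_ac == pytest.approx(h_ab + h_bc, abs=1e-12, rel=1e-12)
        r = eq.interval_risk
        assert 1 - (1 - r(profile, a, b)) * (1 - r(profile, b, c)) == pytest.approx(
            r(profile, a, c), abs=1e-9
        )


def test_step_time_term_piecewise_hazard(full_library, small_cohort):
    """Second-HF gap hazard drops sharply after gap year 1; the closed
    piecewise form must agree with adaptive quadrature of the hazard."""
    eq = full_library["hf:second"]
    prof = small_cohort.iloc[0].to_dict()
    H = eq.cumulative_hazard(prof, 0.0, 2.0)
    ref = quad(lambda t: eq.hazard_rate(prof, t), 1e-12, 2.0, limit=400)[0]
    assert H == pytest.approx(ref, rel=1e-6)
    # additivity across the threshold
    assert H == pytest.approx(
        eq.cumulative_hazard(prof, 0.0, 1.0) + eq.cumulative_hazard(prof, 1.0, 2.0),
        rel=1e-12,
    )


@pytest.mark.parametrize("key", ["hf:first", "hf:second", "stroke:second",
                                 "naihd:first", "naihd:second"])
def test_time_term_equations_match_quadrature(full_library, small_cohort, key):
    """Every equation with covariate-by-time terms: the engine's
    cumulative hazard equals independent adaptive quadrature of the
    instantaneous hazard within 1e-6 relative."""
    eq = full_library[key]
    for i in (0, 1, 7):
        prof = small_cohort.iloc[i].to_dict()
        prof["female"] = 1  # exercise the female-by-time term where present
        prof["smoker"] = 1
        lo = 1e-12 if eq.shape < 1 else 0.0
        for t0, t1 in ((0.0, 2.0), (0.5, 4.5)):
            ref = quad(lambda t: eq.hazard_rate(prof, t), max(t0, lo), t1, limit=400)[0]
            assert eq.cumulative_hazard(prof, t0, t1) == pytest.approx(ref, rel=1e-6)


def test_hazard_rate_shape_monotonicity(full_library, small_cohort):
    """First-event hazards rise with diabetes duration (p>1); second-event
    hazards fall with time since the first event (p<1)."""
    prof = small_cohort.iloc[3].to_dict()
    prof["smoker"] = 0
    prof["female"] = 0
    prof["microalbuminuria"] = 0
    prof["macroalbuminuria"] = 0  # silence time-varying terms
    ts = np.linspace(0.5, 14.5, 40)
    for eq in full_library:
        h = np.array([eq.hazard_rate(prof, t) for t in ts])
        if eq.order == "first":
            assert np.all(np.diff(h) > 0), eq.key
        else:
            # exclude the step discontinuity panels from strictness checks
            mask = np.diff(ts > 1.0) | np.diff(ts > 3.0)
            assert np.all(np.diff(h)[~mask] < 0), eq.key


def test_hazard_rate_integrates_to_cumulative_hazard(library, profile):
    eq = library["ami:first"]
    ref = quad(lambda t: eq.hazard_rate(profile, t), 10, 15, epsabs=1e-12)[0]
    assert eq.cumulative_hazard(profile, 10, 15) == pytest.approx(ref, abs=1e-8)


def test_hazard_rate_domain(library, profile):
    with pytest.raises(ValueError):
        library["ami:second"].hazard_rate(profile, 0.0)  # p < 1: unbounded at 0
    with pytest.raises(ValueError):
        library["ami:first"].hazard_rate(profile, -1.0)
    assert library["ami:first"].hazard_rate(profile, 0.0) == 0.0  # p > 1


class TestHazardRatio:
    def test_plain_terms(self, library):
        assert library["ami:first"].hazard_ratio("female", 1) == pytest.approx(
            math.exp(-0.2318)
        )
        assert library["hf:first"].hazard_ratio("hf_history", 1) == pytest.approx(
            5.5, abs=0.05
        )
        assert library["stroke:first"].hazard_ratio("systolic_bp", 10) == pytest.approx(
            1.065, abs=5e-4
        )

    def test_null_difference(self, library):
        for eq in library:
            cov = sorted(eq.required_covariates())[0]
            assert eq.hazard_ratio(cov, 0) == 1.0

    def test_unknown_covariate(self, library):
        with pytest.raises(KeyError):
            library["ami:first"].hazard_ratio("bmi", 1)

    def test_interaction_requires_reference(self, library):
        with pytest.raises(ReferenceProfileError, match="reference"):
            library["ami:second"].hazard_ratio("female", 1)

    def test_time_term_requires_time(self, library, profile):
        with pytest.raises(ReferenceProfileError, match="t="):
            library["stroke:second"].hazard_ratio("smoker", 1, profile=profile)

    def test_interaction_reference_profile(self, library, profile):
        """Female HR for a second AMI at centred LDL is exp(beta_female);
        one unit above centred LDL multiplies in the interaction."""
        eq = library["ami:second"]
        p0 = dict(profile, ldl=2.54, female=0)
        assert eq.hazard_ratio("female", 1, profile=p0) == pytest.approx(
            math.exp(0.1887), rel=1e-12
        )
        p1 = dict(profile, ldl=3.54, female=0)
        assert eq.hazard_ratio("female", 1, profile=p1) == pytest.approx(
            math.exp(0.1887 - 0.2155), rel=1e-12
        )

    def test_time_interaction_with_reference(self, library, profile):
        eq = library["stroke:second"]
        hr = eq.hazard_ratio("smoker", 1, profile=dict(profile, smoker=0), t=2.0)
        assert hr == pytest.approx(math.exp(0.8806 - 0.2326 * 2.0), rel=1e-12)


class TestLibraryConfig:
    def test_default_library_is_complete(self, library):
        assert len(library) == 8
        library.validate_complete()
        assert library["ami:first"].constant == -7.8187
        assert library["ami:first"].shape == 2.0537
        assert library["naihd:second"].shape == 0.4380

    def test_shape_pattern(self, library):
        for eq in library:
            assert (eq.shape > 1) == (eq.order == "first"), eq.key

    def test_round_trip_is_byte_identical(self, library, tmp_path):
        path = tmp_path / "lib.yaml"
        library.save(path)
        reloaded = EquationLibrary.load(path)
        path2 = tmp_path / "lib2.yaml"
        reloaded.save(path2)
        assert path.read_bytes() == path2.read_bytes()
        assert reloaded.content_hash() == library.content_hash()

    @pytest.mark.parametrize(
        "mutation, message",
        [
            ({"shape": None}, "shape"),
            ({"shape": -2.0}, "shape"),
            ({"terms": {"not_a_covariate": 1.0}}, "unknown covariate"),
            ({"constant": None}, "constant"),
        ],
    )
    def test_schema_errors_carry_field_path(self, library, mutation, message):
        d = library.to_dict()
        d["equations"][0].update(mutation)
        with pytest.raises(EquationConfigError, match=message):
            EquationLibrary.from_dict(d)

    def test_duplicate_equation_rejected(self, library):
        d = library.to_dict()
        d["equations"].append(d["equations"][0])
        with pytest.raises(EquationConfigError, match="duplicate"):
            EquationLibrary.from_dict(d)

    def test_subset(self, library):
        sub = library.subset(["ami:first"])
        assert len(sub) == 1 and "ami:first" in sub and "hf:first" not in sub


def test_cumulative_hazard_curve(library, profile):
    eq = library["ami:first"]
    curve = eq.cumulative_hazard_curve(profile, 10, 15, 0.25)
    assert curve[0, 1] == 0.0
    assert curve[-1, 0] == 15.0
    assert curve[-1, 1] == pytest.approx(eq.cumulative_hazard(profile, 10, 15), rel=1e-12)
    assert np.all(np.diff(curve[:, 1]) >= 0)
    # Weibull curvature: convex in t for p>1, concave for p<1
    assert np.all(np.diff(curve[:, 1], 2) >= -1e-12)
    curve2 = library["ami:second"].cumulative_hazard_curve(profile, 0, 5, 0.25)
    assert np.all(np.diff(curve2[:, 1], 2) <= 1e-12)
    with pytest.raises(ValueError):
        eq.cumulative_hazard_curve(profile, 10, 15, 0.0)


def test_vectorised_evaluation_matches_rowwise(full_library, small_cohort):
    df = small_cohort.head(25)
    for key in ("ami:first", "hf:second"):
        eq = full_library[key]
        vec = np.asarray(eq.interval_risk(df, 0.5, 3.5))
        row = np.array([eq.interval_risk(r.to_dict(), 0.5, 3.5) for _, r in df.iterrows()])
        np.testing.assert_allclose(vec, row, rtol=1e-12)


def test_library_yaml_is_valid_yaml(library):
    parsed = yaml.safe_load(io.StringIO(library.dumps()))
    assert len(parsed["equations"]) == 8
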