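import math

import numpy as np
import pandas as pd
import pytest

import riskport as rp
from riskport import units
from riskport.model_core import (
    MissingFieldError,
    RiskModel,
    TermSpec,
    UnknownInterceptError,
    apply_eligibility_filter,
    define_outcome,
    define_outcomes,
    encode_subject,
    linear_predictor,
    predict_risk,
)


@pytest.mark.parametrize(
    "model,term,value",
    [
        ("ARIC", "fpg", 0.0880),
        ("ARIC", "waist", 0.0273),
        ("ARIC", "height", -0.0326),
        ("ARIC", "hdl", -0.0122),
        ("ARIC", "sbp", 0.0111),
        ("ARIC", "triglyceride", 0.0027),
        ("ARIC", "age", 0.0173),
        ("ARIC", "ethnicity", 0.4433),
        ("ARIC", "family_history", 0.4981),
        ("SAHS", "hdl", -0.039),
        ("SAHS", "age", 0.028),
        ("SAHS", "gender", 0.661),
        ("SAHS", "ethnicity", 0.412),
        ("FRAM", "ifg", 1.98),
        ("FRAM", "bmi_overweight", 0.30),
    ],
)
def test_published_coefficients(published, model, term, value):
    assert published[model].coefficient(term) == pytest.approx(value, abs=1e-12)


def test_published_models_have_no_intercept_and_fram_no_age(published):
    for m in published.values():
        assert m.intercept is None
        assert m.provenance == "published"
    assert "age" not in published["FRAM"].term_names


def test_glucose_unit_conversion_in_encoding(published, subject):
    x = encode_subject(subject, published["ARIC"])
    i = published["ARIC"].term_names.index("fpg")
    assert x[i] == pytest.approx(5.35 * 18.0182, rel=1e-12)
    assert round(x[i], 2) == 96.40


def test_unit_round_trip():
    for factor in units.DEFAULT_FACTORS.values():
        v = 5.35
        back = units.mgdl_to_mmol(units.mmol_to_mgdl(v, factor), factor)
        assert back == pytest.approx(v, rel=1e-9)


def test_reference_levels_and_dichotomizations(published, subject):
    aric = published["ARIC"]
    x = encode_subject(subject, aric)
    assert x[aric.term_names.index("ethnicity")] == 0.0  # Chinese reference
    malay = dict(subject, ethnicity="Malay")
    assert encode_subject(malay, aric)[aric.term_names.index("ethnicity")] == 1.0
    sahs = published["SAHS"]
    assert encode_subject(subject, sahs)[sahs.term_names.index("gender")] == 1.0

    fram = published["FRAM"]
    over = dict(subject, bmi=26.0)
    xf = encode_subject(over, fram)
    assert xf[fram.term_names.index("bmi_overweight")] == 1.0
    assert xf[fram.term_names.index("bmi_obese")] == 0.0
    # sex-specific low-HDL cut: 1.2 mmol/L is low for women, not for men
    woman = dict(subject, hdl=1.2)
    man = dict(subject, hdl=1.2, sex="male")
    assert encode_subject(woman, fram)[fram.term_names.index("hdl_low")] == 1.0
    assert encode_subject(man, fram)[fram.term_names.index("hdl_low")] == 0.0


def test_asian_overweight_option(subject):
    fram = rp.load_published_models(asian_overweight=True)["FRAM"]
    x = encode_subject(dict(subject, bmi=24.0), fram)
    assert x[fram.term_names.index("bmi_overweight")] == 1.0


def test_encoding_is_order_stable(published, subject):
    shuffled = dict(reversed(list(subject.items())))
    a = encode_subject(subject, published["ARIC"])
    b = encode_subject(shuffled, published["ARIC"])
    np.testing.assert_array_equal(a, b)


def test_missing_field_error_names_field_and_subject(published, subject):
    broken = dict(subject)
    broken["hdl"] = np.nan
    with pytest.raises(MissingFieldError, match="hdl.*S1"):
        encode_subject(broken, published["ARIC"])


def test_linear_predictor_closed_forms():
    terms = [TermSpec("a", "a", "linear", {}), TermSpec("b", "b", "linear", {})]
    m = RiskModel("toy", terms, [2.0, -1.0], intercept=0.5)
    assert linear_predictor(m, [1.0, 3.0]) == pytest.approx(-0.5)
    zero = RiskModel("toy0", terms, [2.0, -1.0], intercept=0.0)
    assert linear_predictor(zero, [0.0, 0.0]) == 0.0


def test_linear_predictor_unit_fpg_increase_matches_published_slope(published, subject):
    aric = published["ARIC"]
    x0 = encode_subject(subject, aric)
    x1 = x0.copy()
    x1[aric.term_names.index("fpg")] += 1.0  # +1 mg/dl
    d = float(x1 @ aric.beta - x0 @ aric.beta)
    assert d == pytest.approx(0.0880, abs=1e-12)


def test_unknown_intercept_raises_with_guidance(published, subject):
    with pytest.raises(UnknownInterceptError, match="recalibrate"):
        predict_risk(published["ARIC"], subject)
    x = encode_subject(subject, published["ARIC"])
    score = linear_predictor(published["ARIC"], x, allow_missing_intercept=True)
    assert np.isfinite(score)


def test_predict_risk_logistic_closed_forms(subject):
    terms = [TermSpec("age", "age", "linear", {})]
    m = RiskModel("toy", terms, [0.0], intercept=0.0)
    assert predict_risk(m, subject).probability == pytest.approx(0.5)
    m_ln3 = RiskModel("toy", terms, [0.0], intercept=math.log(3))
    assert predict_risk(m_ln3, subject).probability == pytest.approx(0.75)
    m_hi = RiskModel("toy", terms, [0.0], intercept=40.0)
    assert predict_risk(m_hi, subject).probability == pytest.approx(1.0, abs=1e-12)
    m_lo = RiskModel("toy", terms, [0.0], intercept=-40.0)
    assert predict_risk(m_lo, subject).probability == pytest.approx(0.0, abs=1e-12)


def test_risk_monotone_in_each_covariate_sign(published, subject):
    """Nudging a covariate moves the score in the direction of its sign."""
    aric = published["ARIC"]
    nudge = {"fpg": 0.1, "waist": 1.0, "height": 1.0, "hdl": 0.1, "sbp": 2.0,
             "triglyceride": 0.1, "age": 1.0}
    base = encode_subject(subject, aric) @ aric.beta
    for field, delta in nudge.items():
        bumped = dict(subject)
        bumped[field] = bumped[field] + delta
        score = encode_subject(bumped, aric) @ aric.beta
        beta = aric.coefficient(field if field != "fpg" else "fpg")
        assert np.sign(score - base) == np.sign(beta)


def test_eligibility_filter_rules_and_idempotence(subject):
    rows = [
        dict(subject, id="A", fpg=7.0),                      # boundary: excluded
        dict(subject, id="B", fpg=5.0, two_hpg=11.1),        # OGTT: excluded
        dict(subject, id="C", fpg=5.0, two_hpg=np.nan),      # eligible
        dict(subject, id="D", physician_dx_baseline=1),      # prior diagnosis
    ]
    cohort = pd.DataFrame(rows)
    eligible, excluded = apply_eligibility_filter(cohort)
    assert list(eligible["id"]) == ["C"]
    reasons = dict(zip(excluded["id"], excluded["exclusion_reason"]))
    assert reasons == {"A": "baseline_fpg", "B": "baseline_2hpg",
                       "D": "prior_diagnosis"}
    again, removed = apply_eligibility_filter(eligible)
    assert len(removed) == 0 and len(again) == len(eligible)


def test_outcome_definition():
    assert define_outcome({"followup_fpg": 7.2, "physician_dx_followup": 0}) == 1
    assert define_outcome({"followup_fpg": 5.9, "physician_dx_followup": 1}) == 1
    assert define_outcome({"followup_fpg": 5.9, "physician_dx_followup": 0}) == 0
    assert define_outcome({"followup_fpg": None, "physician_dx_followup": None}) is None
    df = pd.DataFrame({
        "followup_fpg": [7.0, 5.0, np.nan, np.nan],
        "physician_dx_followup": [0, 0, 1, np.nan],
    })
    out = define_outcomes(df)
    assert list(out[:3]) == [1, 0, 1]
    assert pd.isna(out.iloc[3])


def test_model_json_round_trip(tmp_path, published):
    path = tmp_path / "aric.json"
    published["ARIC"].to_json(path)
    back = RiskModel.from_json(path)
    np.testing.assert_allclose(back.beta, published["ARIC"].beta)
    assert back.term_names == published["ARIC"].term_names
    assert back.intercept is None


def test_validate_cohort_flags_violations(cohort_2k):
    df, _ = cohort_2k
    rp.validate_cohort(df)
    bad = df.copy()
    bad.loc[bad.index[0], "age"] = 15.0
    with pytest.raises(ValueError, match="age"):
        rp.validate_cohort(bad)
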