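import numpy as np
import pandas as pd
import pytest

import riskport as rp
from riskport import recalibration as rc
from riskport import validation_metrics as vm
from riskport.model_core import RiskModel, TermSpec, design_matrix, predict_proba
from riskport.recalibration import (
    RecalibrationContext,
    Recalibrator,
    estimate_context,
    recalibrate_probabilities,
    stratified_recalibration_by_age,
    two_step_race_recalibration,
)
from riskport.synthetic_cohort import CohortGeneratorConfig, generate_cohort


def test_subject_at_mean_gets_mean_risk(cohort_2k, published):
    df, _ = cohort_2k
    model = published["ARIC"]
    ctx = estimate_context(df, model)
    X = design_matrix(df, model.terms)
    mean_subject = df.iloc[[0]].copy()
    # a synthetic row whose encoded vector equals m: feed m through directly
    p = 1.0 - ctx.s_m ** np.exp(float((ctx.m - ctx.m) @ model.beta))
    assert p == pytest.approx(1.0 - ctx.s_m)
    assert ctx.s_m == pytest.approx(1.0 - df["outcome_t2dm"].mean())


def test_closed_form_s09_ln2_gives_019():
    ctx = RecalibrationContext(m=np.array([0.0]), s_m=0.9)
    model = RiskModel("toy", [TermSpec("a", "a", "linear", {})], [1.0])
    df = pd.DataFrame({"a": [np.log(2.0)]})
    p = recalibrate_probabilities(model, ctx, df)
    assert p[0] == pytest.approx(1.0 - 0.81)


def test_limits_and_monotonicity_in_relative_score():
    ctx = RecalibrationContext(m=np.array([0.0]), s_m=0.9)
    model = RiskModel("toy", [TermSpec("a", "a", "linear", {})], [1.0])
    a = np.linspace(-4, 4, 101)
    p = recalibrate_probabilities(model, ctx, pd.DataFrame({"a": a}))
    assert ((p >= 0) & (p < 1)).all()
    assert (np.diff(p) > 0).all()
    tails = recalibrate_probabilities(model, ctx, pd.DataFrame({"a": [-30.0, 30.0]}))
    assert tails[0] == pytest.approx(0.0, abs=1e-10)
    assert tails[1] == pytest.approx(1.0, abs=1e-10)


def test_plugin_incidence_gives_survival_complement():
    # 7.8% incidence -> S(m) = 0.922
    model = RiskModel("toy", [TermSpec("a", "a", "linear", {})], [0.5])
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"a": rng.normal(0, 1, 1000)})
    y = np.zeros(1000)
    y[:78] = 1
    ctx = estimate_context(df, model, y=y, method="mean_plugin_incidence")
    assert ctx.s_m == pytest.approx(0.922)


def test_zero_event_stratum_gives_survival_one_and_zero_risk():
    model = RiskModel("toy", [TermSpec("a", "a", "linear", {})], [0.5])
    df = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
    with pytest.warns(UserWarning, match="zero events"):
        ctx = estimate_context(df, model, y=np.zeros(3))
    assert ctx.s_m == 1.0
    assert recalibrate_probabilities(model, ctx, df) == pytest.approx([0, 0, 0])


def test_empty_stratum_errors():
    model = RiskModel("toy", [TermSpec("a", "a", "linear", {})], [0.5])
    with pytest.raises(ValueError, match="empty"):
        estimate_context(pd.DataFrame({"a": []}), model, y=np.array([]))


def _bisect_survival(d, incidence, tol=1e-12):
    lo, hi = 1e-12, 1 - 1e-12
    e = np.exp(d)
    for _ in range(200):
        mid = (lo + hi) / 2
        if np.mean(1 - mid**e) > incidence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def test_intercept_matched_matches_bisection_oracle(cohort_2k, published):
    df, _ = cohort_2k
    model = published["ARIC"]
    ctx = estimate_context(df, model, method="intercept_matched")
    X = design_matrix(df, model.terms)
    d = (X - ctx.m) @ model.beta
    oracle = _bisect_survival(d, df["outcome_t2dm"].mean())
    assert ctx.s_m == pytest.approx(oracle, abs=1e-8)
    p = recalibrate_probabilities(model, ctx, df)
    assert abs(p.mean() - df["outcome_t2dm"].mean()) < 1e-6


def test_invariant_to_external_intercept(cohort_2k, published):
    """Eq-style recalibration never touches the external intercept."""
    df, _ = cohort_2k
    base = published["ARIC"]
    shifted = RiskModel(base.name, base.terms, base.beta.copy(), intercept=3.7)
    ctx = estimate_context(df, base)
    np.testing.assert_allclose(
        recalibrate_probabilities(base, ctx, df),
        recalibrate_probabilities(shifted, estimate_context(df, shifted), df),
    )


def test_two_step_single_ethnicity_equals_plain_race_free_recalibration(published):
    df = generate_cohort(
        CohortGeneratorConfig(
            n=1500, ethnic_proportions={"Chinese": 1.0, "Malay": 0.0, "Indian": 0.0}
        ),
        seed=11,
    )
    model = published["ARIC"]
    two_step = two_step_race_recalibration(model, df)
    race_free = model.drop_terms(["ethnicity"])
    ctx = estimate_context(df, race_free)
    plain = recalibrate_probabilities(race_free, ctx, df)
    np.testing.assert_allclose(two_step["probability"].to_numpy(), plain)


def test_two_step_group_calibration_with_known_generator(published):
    """Each ethnic group's mean recalibrated risk sits within one percentage
    point of that group's true incidence (intercept-matched survival)."""
    df = generate_cohort(
        CohortGeneratorConfig(
            n=10_000, ethnic_proportions={"Chinese": 0.5, "Malay": 0.5, "Indian": 0.0}
        ),
        seed=13,
    )
    out = two_step_race_recalibration(published["ARIC"], df,
                                      method="intercept_matched")
    merged = df.assign(p=out["probability"].to_numpy())
    for eth, grp in merged.groupby("ethnicity", observed=True):
        assert abs(grp["p"].mean() - grp["outcome_t2dm"].mean()) < 0.01


def test_within_group_ranking_follows_relative_linear_predictor(published):
    df = generate_cohort(CohortGeneratorConfig(n=1000), seed=17)
    model = published["ARIC"]
    out = two_step_race_recalibration(model, df)
    race_free = model.drop_terms(["ethnicity"])
    for eth, grp in df.groupby("ethnicity", observed=True):
        d = design_matrix(grp, race_free.terms) @ race_free.beta
        p = out.loc[grp.index, "probability"].to_numpy()
        np.testing.assert_array_equal(np.argsort(d, kind="stable"),
                                      np.argsort(p, kind="stable"))


def test_single_age_band_equals_unstratified(cohort_2k, published):
    df, _ = cohort_2k
    model = published["ARIC"]
    banded = stratified_recalibration_by_age(model, df, [17.9, 100.0])
    ctx = estimate_context(df, model)
    plain = recalibrate_probabilities(model, ctx, df)
    np.testing.assert_allclose(banded["probability"].to_numpy(), plain)


def test_empty_age_band_errors(cohort_2k, published):
    df, _ = cohort_2k
    with pytest.raises(ValueError, match="empty age band"):
        stratified_recalibration_by_age(published["ARIC"], df, [17.9, 98.0, 100.0])


def test_age_band_recalibration_fixes_birth_cohort_effect(published):
    """When older subjects carry extra risk the external model misses,
    band-wise recalibration lowers the lack-of-fit statistic."""
    rng = np.random.default_rng(23)
    df, tm = generate_cohort(CohortGeneratorConfig(n=10_000), seed=29,
                             return_model=True)
    extra = 1.0 * (df["age"] > 45).to_numpy(float)
    lp = np.log(predict_proba(tm, df) / (1 - predict_proba(tm, df))) + extra
    df["outcome_t2dm"] = (rng.random(len(df)) < 1 / (1 + np.exp(-lp))).astype(int)
    y = df["outcome_t2dm"].to_numpy(float)
    ext = RiskModel(tm.name, tm.terms, tm.beta.copy())  # no band effect
    ctx = estimate_context(df, ext, method="intercept_matched")
    hl_flat = vm.hosmer_lemeshow(recalibrate_probabilities(ext, ctx, df), y)
    banded = stratified_recalibration_by_age(ext, df, [17.9, 35, 45, 100],
                                             method="intercept_matched")
    hl_band = vm.hosmer_lemeshow(banded["probability"].to_numpy(), y)
    assert hl_band.statistic < hl_flat.statistic


def test_recalibrator_estimator_api(cohort_2k, published):
    df, _ = cohort_2k
    rec = Recalibrator(model=published["ARIC"], strata="ethnicity",
                       drop_race_terms=True, method="intercept_matched")
    assert rec.get_params()["method"] == "intercept_matched"
    rec.fit(df)
    assert set(rec.contexts_) == set(df["ethnicity"].unique())
    proba = rec.predict_proba(df)
    assert proba.shape == (len(df), 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    frame = rec.predict_frame(df)
    assert frame["recalibrated"].all()
    assert set(frame["stratum"]) == set(df["ethnicity"].unique())
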