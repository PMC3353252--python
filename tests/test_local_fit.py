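import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import riskport as rp
from riskport import local_fit
from riskport.local_fit import FitError, LocalLogisticModel
from riskport.model_core import RiskModel, TermSpec
from riskport.synthetic_cohort import CohortGeneratorConfig, _draw_covariates


def _toy_cohort(n, seed, malay_beta, indian_beta, base=-3.0):
    """Cohort with outcome from fasting glucose + ethnicity log-odds."""
    rng = np.random.default_rng(seed)
    df = _draw_covariates(CohortGeneratorConfig(n=n), rng)
    lp = base + 0.5 * (df["fpg"] - 5.35) / 0.44 + np.where(
        df["ethnicity"] == "Malay", malay_beta,
        np.where(df["ethnicity"] == "Indian", indian_beta, 0.0))
    df["outcome_t2dm"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return df


TOY_TERMS = [
    TermSpec("fpg", "fpg", "linear", {"factor": 18.0182}),
    TermSpec("ethnicity", "ethnicity", "non_chinese", {}),
]


def test_intercept_only_fit_recovers_logit_of_event_rate():
    y = np.zeros(1000)
    y[:300] = 1
    df = pd.DataFrame({"outcome_t2dm": y})
    fit = LocalLogisticModel(terms=[]).fit(df)
    assert fit.intercept_ == pytest.approx(logit(0.3), abs=1e-8)


def test_calibration_in_the_large_is_exact(cohort_2k, published):
    df, _ = cohort_2k
    fit = LocalLogisticModel(terms=list(published["ARIC"].terms)).fit(df)
    p = fit.predict_proba(df)[:, 1]
    assert abs(p.mean() - df["outcome_t2dm"].mean()) < 1e-8


def test_parameter_recovery_within_3_se(cohort_5k):
    df, truth = cohort_5k
    fit = LocalLogisticModel(terms=list(truth.terms)).fit(df)
    z = np.abs(fit.coef_ - truth.beta) / fit.bse_
    assert (z < 3.0).all(), dict(zip(truth.term_names, z.round(2)))


def test_aic_identity_on_refit(cohort_2k, published):
    df, _ = cohort_2k
    terms = list(published["ARIC"].terms)
    a1 = LocalLogisticModel(terms=terms).fit(df).aic_
    a2 = LocalLogisticModel(terms=terms).fit(df).aic_
    assert a1 == pytest.approx(a2, abs=1e-6)
    model = local_fit.fit_logistic(df, terms)
    k = len(terms) + 1
    assert model.fit_metadata["aic"] == pytest.approx(
        2 * k - 2 * model.fit_metadata["log_likelihood"], abs=1e-9)


def test_fit_requires_both_classes_and_full_rank(cohort_2k):
    df, _ = cohort_2k
    allzero = df.copy()
    allzero["outcome_t2dm"] = 0
    with pytest.raises(FitError, match="event"):
        LocalLogisticModel(terms=TOY_TERMS).fit(allzero)
    dup = TOY_TERMS + [TermSpec("fpg_copy", "fpg", "linear", {"factor": 18.0182})]
    with pytest.raises(FitError, match="rank"):
        LocalLogisticModel(terms=dup).fit(df)


def test_race_coding_equal_effects_prefers_combined_dummy():
    combined_wins = 0
    reps = 40
    for rep in range(reps):
        _, aics = local_fit.choose_race_coding(_toy_cohort(800, rep, 0.5, 0.5),
                                               TOY_TERMS)
        combined_wins += aics["combined"] <= aics["separate"]
    assert combined_wins > reps / 2


def test_race_coding_distinct_effects_selects_separate_dummies():
    chosen, aics = local_fit.choose_race_coding(_toy_cohort(4000, 99, 0.0, 1.3),
                                                TOY_TERMS)
    assert aics["separate"] < aics["combined"]
    assert {"malay", "indian"} <= set(chosen.term_names)
    assert set(aics) == {"combined", "separate"}  # both AICs always reported


def test_race_coding_missing_level_falls_back_with_warning():
    df = _toy_cohort(1500, 3, 0.5, 0.5)
    df = df[df["ethnicity"] != "Indian"].reset_index(drop=True)
    with pytest.warns(UserWarning, match="incomplete"):
        chosen, aics = local_fit.choose_race_coding(df, TOY_TERMS)
    assert np.isnan(aics["separate"])
    assert "ethnicity" in chosen.term_names


def test_interaction_screen_keeps_strong_interaction():
    rng = np.random.default_rng(5)
    df = _draw_covariates(CohortGeneratorConfig(n=5000), rng)
    z = (df["fpg"] - 5.35) / 0.44
    nonch = (df["ethnicity"] != "Chinese").astype(float)
    lp = -3.2 + 0.3 * z + 0.4 * nonch + 0.8 * z * nonch
    df["outcome_t2dm"] = (rng.random(5000) < 1 / (1 + np.exp(-lp))).astype(int)
    tests, final = local_fit.screen_ethnicity_interactions(df, TOY_TERMS)
    by_term = {t.term: t for t in tests}
    assert by_term["fpg"].kept and by_term["fpg"].p_value < 0.05
    assert "fpg_x_ethnicity" in final.term_names


def test_interaction_screen_type_i_error_near_nominal():
    """With no true interaction, the 5% LRT screen keeps ~5% of terms."""
    kept = 0
    reps = 500
    for rep in range(reps):
        tests, _ = local_fit.screen_ethnicity_interactions(
            _toy_cohort(800, 10_000 + rep, 0.4, 0.4), TOY_TERMS)
        kept += tests[0].kept
    assert 0.03 <= kept / reps <= 0.08


def _local_with_ci(names, betas, cis):
    terms = [TermSpec(n, "age", "linear", {}) for n in names]
    return RiskModel("local", terms, betas, intercept=0.0, provenance="local",
                     fit_metadata={"conf_int_95": cis, "log_likelihood": 0.0,
                                   "aic": 0.0, "se": [0.1] * len(names)})


def test_compare_coefficients_flags_published_outside_ci():
    local = _local_with_ci(["fpg", "ethnicity"], [0.120, 0.677],
                           [[0.090, 0.149], [0.214, 1.140]])
    terms = [TermSpec("fpg", "age", "linear", {}),
             TermSpec("ethnicity", "age", "linear", {})]
    published = RiskModel("pub", terms, [0.0880, 0.4433])
    table = local_fit.compare_coefficients(local, published).set_index("term")
    assert bool(table.loc["fpg", "outside_ci"]) is True
    assert bool(table.loc["ethnicity", "outside_ci"]) is False


def test_compare_coefficients_point_equal_not_flagged_and_mismatch_errors():
    local = _local_with_ci(["fpg"], [0.1], [[0.05, 0.15]])
    published = RiskModel("pub", [TermSpec("fpg", "age", "linear", {})], [0.1])
    table = local_fit.compare_coefficients(local, published)
    assert not table["outside_ci"].any()
    other = RiskModel("pub", [TermSpec("waist", "age", "linear", {})], [0.1])
    with pytest.raises(ValueError, match="mismatch"):
        local_fit.compare_coefficients(local, other)
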