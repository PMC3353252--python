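"""End-to-end study pipeline on a synthetic cohort.

Reproduces the shape of the full model-transport comparison: local refits of
each published model structure (with the race-coding choice and the
ethnicity-interaction screen), discrimination tables (pairwise DeLong AUC
comparisons, NRI between the two best published models), and calibration
tables (Hosmer-Lemeshow and predicted incidence, before and after
recalibration, overall and by sex).

Because published intercepts are unknown, "uncalibrated published"
predictions are produced by deriving each published structure in a synthetic
external population (shifted covariate means, shifted baseline risk), which
yields a known intercept; recalibrated predictions need no intercept at all.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import local_fit, model_core, recalibration, validation_metrics as vm
from .synthetic_cohort import (
    CohortGeneratorConfig,
    generate_cohort,
    generate_external_population,
)

#: default shifts making the external derivation populations differ from the
#: local cohort (older, heavier, higher baseline risk)
EXTERNAL_MEAN_SHIFTS = {"age": 8.0, "bmi": 2.5, "fpg": 0.15, "waist": 6.0}
EXTERNAL_INTERCEPT_SHIFT = math.log(2.0)


def _local_terms_for(name: str, published: model_core.RiskModel):
    return list(published.terms)


def run_full_study(
    n: int = 1401,
    seed: int = 0,
    *,
    external_n: int = 4000,
    method: str = "mean_plugin_incidence",
    config: CohortGeneratorConfig | None = None,
) -> dict:
    """Run the complete published-vs-local comparison on synthetic data.

    Returns a dict of DataFrames: ``coefficients`` (local vs published per
    model), ``aic`` (race-coding choice), ``interactions``, ``auc`` (pairwise
    DeLong comparisons), ``calibration`` (HL + predicted incidence),
    ``calibration_by_sex``, plus the ``nri`` result and the cohort itself.
    """
    rng = np.random.default_rng(seed)
    config = config or CohortGeneratorConfig()
    config = replace(config, n=n)
    cohort, true_model = generate_cohort(config, seed=int(rng.integers(2**31)),
                                         return_model=True)
    cohort, excluded = model_core.apply_eligibility_filter(cohort)
    y = cohort["outcome_t2dm"].to_numpy(dtype=float)
    published = model_core.load_published_models()

    # --- local fits ------------------------------------------------------
    local_models: dict[str, model_core.RiskModel] = {}
    probs: dict[str, np.ndarray] = {}
    aic_rows, interaction_rows, coef_tables = [], [], {}
    for name, pub in published.items():
        terms = _local_terms_for(name, pub)
        has_race = any(t.encoding == "non_chinese" for t in terms)
        if has_race:
            chosen, aics = local_fit.choose_race_coding(cohort, terms, name=f"{name}-local")
            aic_rows.append({"model": name, **aics,
                             "chosen": "combined" if aics["combined"] <= aics["separate"]
                             else "separate"})
            if chosen.term_names != [t.name for t in terms]:
                # separate coding won; local model keeps it
                terms = list(chosen.terms)
        tests, local = local_fit.screen_ethnicity_interactions(
            cohort, terms, name=f"{name}-local"
        )
        for t in tests:
            interaction_rows.append({"model": name, "term": t.term, "lrt": t.lrt,
                                     "df": t.df, "p": t.p_value, "kept": t.kept})
        local_models[name] = local
        if set(local.term_names) == set(pub.term_names):
            coef_tables[name] = local_fit.compare_coefficients(local, pub)
        probs[f"{name}-local"] = model_core.predict_proba(local, cohort)
    for label, terms in (("FPG-local", model_core.fpg_only_terms()),
                         ("OGTT-local", model_core.ogtt_only_terms())):
        m = local_fit.fit_logistic(cohort, terms, name=label)
        local_models[label] = m
        probs[label] = model_core.predict_proba(m, cohort)

    # --- external (uncalibrated) and recalibrated published models -------
    recalibrated: dict[str, np.ndarray] = {}
    for name, pub in published.items():
        ext_config = replace(config, n=external_n,
                             outcome_model=model_core.RiskModel(
                                 name, pub.terms, pub.beta.copy(), None, "published"))
        _, ext_model = generate_external_population(
            ext_config, intercept_shift=EXTERNAL_INTERCEPT_SHIFT,
            mean_shifts=EXTERNAL_MEAN_SHIFTS, seed=int(rng.integers(2**31)),
        )
        probs[f"{name}-published"] = model_core.predict_proba(ext_model, cohort)
        ctx = recalibration.estimate_context(cohort, pub, method=method)
        recalibrated[name] = recalibration.recalibrate_probabilities(pub, ctx, cohort)
        probs[f"{name}-recalibrated"] = recalibrated[name]

    # --- discrimination ---------------------------------------------------
    auc_rows = []
    pairs = [
        ("SAHS-local", "SAHS-published"), ("ARIC-local", "ARIC-published"),
        ("FRAM-local", "FRAM-published"), ("SAHS-published", "ARIC-published"),
        ("SAHS-published", "FRAM-published"), ("ARIC-published", "FRAM-published"),
    ]
    pairs += [("FPG-local", m) for m in ("SAHS-local", "ARIC-local", "FRAM-local",
                                         "SAHS-published", "ARIC-published",
                                         "FRAM-published")]
    pairs += [("OGTT-local", m) for m in ("SAHS-local", "ARIC-local", "FRAM-local",
                                          "SAHS-published", "ARIC-published",
                                          "FRAM-published")]
    for m1, m2 in pairs:
        res = vm.delong_compare(probs[m1], probs[m2], y)
        a1, a2 = vm.auc(probs[m1], y), vm.auc(probs[m2], y)
        auc_rows.append({
            "model_1": m1, "auc_1": a1.auc, "ci_1": (a1.ci_low, a1.ci_high),
            "model_2": m2, "auc_2": a2.auc, "ci_2": (a2.ci_low, a2.ci_high),
            "p_value": res.p_value,
        })

    nri_result = vm.nri(recalibrated["ARIC"], recalibrated["SAHS"], y)

    # --- calibration ------------------------------------------------------
    cal_rows, sex_rows = [], []
    cal_labels = (
        [f"{m}-local" for m in ("SAHS", "ARIC", "FRAM")]
        + ["FPG-local", "OGTT-local"]
        + [f"{m}-published" for m in ("SAHS", "ARIC", "FRAM")]
        + [f"{m}-recalibrated" for m in ("SAHS", "ARIC", "FRAM")]
    )
    for label in cal_labels:
        hl = vm.hosmer_lemeshow(probs[label], y)
        cal_rows.append({"model": label, "hl_statistic": hl.statistic,
                         "lack_of_fit": hl.significant_lack_of_fit,
                         "predicted_incidence_pct": vm.predicted_incidence(probs[label])})
    for label in ([f"{m}-published" for m in ("SAHS", "ARIC", "FRAM")]
                  + [f"{m}-recalibrated" for m in ("SAHS", "ARIC", "FRAM")]):
        row = {"model": label}
        for sex in ("female", "male"):
            mask = (cohort["sex"] == sex).to_numpy()
            row[sex] = vm.hosmer_lemeshow(probs[label][mask], y[mask]).statistic
        sex_rows.append(row)

    # two-step (race-removed, per-ethnicity) recalibration of SAHS and ARIC
    eth_rows = []
    for name in ("SAHS", "ARIC"):
        two = recalibration.two_step_race_recalibration(
            published[name], cohort, method=method)
        p_two = two["probability"].to_numpy()
        row = {"model": f"{name}-two-step"}
        for eth in cohort["ethnicity"].unique():
            mask = (cohort["ethnicity"] == eth).to_numpy()
            row[eth] = vm.hosmer_lemeshow(p_two[mask], y[mask]).statistic
        eth_rows.append(row)

    return {
        "cohort": cohort,
        "excluded": excluded,
        "true_model": true_model,
        "local_models": local_models,
        "coefficients": coef_tables,
        "aic": pd.DataFrame(aic_rows),
        "interactions": pd.DataFrame(interaction_rows),
        "auc": pd.DataFrame(auc_rows),
        "nri": nri_result,
        "calibration": pd.DataFrame(cal_rows),
        "calibration_by_sex": pd.DataFrame(sex_rows),
        "calibration_by_ethnicity_two_step": pd.DataFrame(eth_rows),
        "observed_incidence_pct": vm.observed_incidence(y),
    }
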