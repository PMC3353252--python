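"""Reproducible validation experiments for the transport methodology.

Each function runs a self-contained simulation study — the worked
reclassification example, oracle cross-checks of the discrimination
statistics, null calibration of the goodness-of-fit test, the
transport/recalibration recovery experiment, logistic parameter recovery,
and the multiple-imputation bias study — and returns a small dict of summary
numbers. They are consumed by the test suite and by the acceptance script.

All randomness flows from a single integer seed per experiment.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from . import validation_metrics as vm
from .local_fit import LocalLogisticModel
from .missing_data import fcs_impute, pool_logistic_fits
from .model_core import load_published_models, predict_proba
from .recalibration import estimate_context, recalibrate_probabilities
from .synthetic_cohort import (
    CohortGeneratorConfig,
    apply_mar_dropout,
    generate_cohort,
    generate_external_population,
)

#: covariate-mean offsets of the synthetic external derivation population
#: (older, heavier, higher fasting glucose than the local cohort)
EXTERNAL_MEAN_SHIFTS = {"age": 8.0, "bmi": 2.5, "fpg": 0.15, "waist": 6.0}

#: default MAR dropout mechanism: returners differ in age, adiposity and
#: family history, with roughly 30% of follow-up glucose missing
DEFAULT_MAR_MECHANISM = {
    "intercept": float(np.log(0.3 / 0.7)),
    "age": 0.5,
    "bmi": 0.3,
    "family_history_t2dm": -0.3,
}


def _sub_seeds(seed: int, k: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=k)


# ---------------------------------------------------------------------------
# worked reclassification example


def nri_worked_example() -> dict:
    """Reproduce the published reclassification comparison from its counts.

    Inputs are the printed reclassification counts for the two best external
    models on the full validation cohort (1,401 subjects at 7.8% incidence,
    hence 109 cases and 1,292 non-cases): 32 cases reclassified up against
    21 down, and 110 non-cases reclassified down against 76 up. Probability
    vectors realizing exactly those category moves are constructed and fed
    through the ``nri`` operation.
    """
    n_cases, case_up, case_down = 109, 32, 21
    n_noncases, non_down, non_up = 1292, 110, 76
    reps = {0: 0.05, 1: 0.15, 2: 0.25}  # representative risks per category

    def build(n, up, down):
        old = np.full(n, reps[1])
        new = old.copy()
        new[:up] = reps[2]
        new[up:up + down] = reps[0]
        return new, old

    new_c, old_c = build(n_cases, case_up, case_down)
    new_n, old_n = build(n_noncases, non_up, non_down)
    p_new = np.concatenate([new_c, new_n])
    p_old = np.concatenate([old_c, old_n])
    y = np.concatenate([np.ones(n_cases), np.zeros(n_noncases)])
    res = vm.nri(p_new, p_old, y)
    return {
        "nri_events": res.nri_events,
        "nri_nonevents": res.nri_nonevents,
        "nri_total": res.nri_total,
        "n": n_cases + n_noncases,
    }


# ---------------------------------------------------------------------------
# brute-force oracles for AUC and NRI


def _auc_bruteforce(p, y) -> float:
    cases, ctrls = p[y == 1], p[y == 0]
    wins = 0.0
    for c in cases:
        for d in ctrls:
            wins += 1.0 if c > d else (0.5 if c == d else 0.0)
    return wins / (len(cases) * len(ctrls))


def _nri_bruteforce(p_new, p_old, y, cuts):
    def cat(p):
        k = 0
        for c in cuts:
            if p > c:
                k += 1
        return k

    eu = ed = nu = nd = 0
    for pn, po, yi in zip(p_new, p_old, y):
        cn, co = cat(pn), cat(po)
        if yi == 1:
            eu += cn > co
            ed += cn < co
        else:
            nu += cn > co
            nd += cn < co
    n_ev = int(sum(y))
    n_ne = len(y) - n_ev
    return (eu - ed) / n_ev, (nd - nu) / n_ne


def oracle_equivalence(seed: int = 0, instances: int = 200) -> dict:
    """AUC and NRI against exhaustive pair/reclassification counting."""
    rng = np.random.default_rng(seed)
    max_auc_err = max_nri_err = 0.0
    for _ in range(instances):
        n = int(rng.integers(10, 51))
        y = np.zeros(n)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        # coarse grid probabilities force plenty of ties
        p1 = rng.integers(0, 11, size=n) / 10.0
        p2 = rng.integers(0, 11, size=n) / 10.0
        max_auc_err = max(max_auc_err, abs(vm.auc(p1, y).auc - _auc_bruteforce(p1, y)))
        res = vm.nri(p1, p2, y)
        bf_e, bf_n = _nri_bruteforce(p1, p2, y, vm.DEFAULT_NRI_CUTPOINTS)
        max_nri_err = max(max_nri_err, abs(res.nri_events - bf_e),
                          abs(res.nri_nonevents - bf_n))
    return {"max_auc_error": max_auc_err, "max_nri_error": max_nri_err,
            "n": instances}


# ---------------------------------------------------------------------------
# DeLong variance vs bootstrap


def _fast_auc(p, y):
    r = rankdata(p)
    n1 = y.sum()
    n0 = len(y) - n1
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def delong_bootstrap_check(seed: int = 0, n: int = 200, n_boot: int = 2000) -> dict:
    """Compare the DeLong variance of an AUC difference with a bootstrap."""
    rng = np.random.default_rng(seed)
    t = rng.normal(0, 1, n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(t - 1)))).astype(float)
    p1 = 1 / (1 + np.exp(-(t + rng.normal(0, 0.8, n))))
    p2 = 1 / (1 + np.exp(-(t + rng.normal(0, 0.8, n))))
    res = vm.delong_compare(p1, p2, y)
    c = res.covariance
    delong_var = c[0, 0] + c[1, 1] - 2 * c[0, 1]
    diffs = []
    while len(diffs) < n_boot:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        diffs.append(_fast_auc(p1[idx], yb) - _fast_auc(p2[idx], yb))
    boot_var = float(np.var(diffs, ddof=1))
    self_p = vm.delong_compare(p1, p1, y).p_value
    return {"delong_variance": float(delong_var), "bootstrap_variance": boot_var,
            "variance_ratio": float(delong_var / boot_var),
            "self_comparison_p": self_p, "n": n}


# ---------------------------------------------------------------------------
# null calibration of the goodness-of-fit test


def hl_null_rejection(seed: int = 0, reps: int = 500, n: int = 1400) -> dict:
    """Rejection rate of the 11.5 cutoff for a correctly specified local fit."""
    rejected = 0
    for s in _sub_seeds(seed, reps):
        df, tm = generate_cohort(CohortGeneratorConfig(n=n), seed=int(s),
                                 return_model=True)
        y = df["outcome_t2dm"].to_numpy(float)
        fit = LocalLogisticModel(terms=list(tm.terms)).fit(df)
        hl = vm.hosmer_lemeshow(fit.predict_proba(df)[:, 1], y)
        rejected += hl.statistic > vm.HL_CUTOFF
    return {"rejection_rate": rejected / reps, "n": reps}


# ---------------------------------------------------------------------------
# transport / recalibration recovery


def transport_recovery(seed: int = 0, reps: int = 200, n_local: int = 5000,
                       n_external: int = 2000,
                       method: str = "intercept_matched") -> dict:
    """External model with doubled baseline odds applied to a local cohort.

    Per replicate: draw a local cohort; derive an external model with the
    same coefficients, covariate means shifted by
    :data:`EXTERNAL_MEAN_SHIFTS` and baseline log-odds shifted by log 2;
    score the local cohort with it raw and after recalibration.
    """
    seeds = _sub_seeds(seed, 2 * reps).reshape(reps, 2)
    uncal_fail = recal_pass = gap_ok = 0
    for s_local, s_ext in seeds:
        df = generate_cohort(CohortGeneratorConfig(n=n_local), seed=int(s_local))
        _, ext = generate_external_population(
            CohortGeneratorConfig(n=n_external), intercept_shift=float(np.log(2)),
            mean_shifts=EXTERNAL_MEAN_SHIFTS, seed=int(s_ext),
        )
        y = df["outcome_t2dm"].to_numpy(float)
        p_unc = predict_proba(ext, df)
        uncal_fail += vm.hosmer_lemeshow(p_unc, y).statistic > vm.HL_CUTOFF
        ctx = estimate_context(df, ext, method=method)
        p_rec = recalibrate_probabilities(ext, ctx, df)
        recal_pass += vm.hosmer_lemeshow(p_rec, y).statistic <= vm.HL_CUTOFF
        gap_ok += abs(float(p_rec.mean()) - float(y.mean())) < 0.01
    return {
        "uncalibrated_fail_rate": uncal_fail / reps,
        "recalibrated_pass_rate": recal_pass / reps,
        "mean_risk_within_1pct_rate": gap_ok / reps,
        "n": reps,
    }


# ---------------------------------------------------------------------------
# parameter recovery


def coverage_experiment(seed: int = 0, reps: int = 200, n: int = 2000) -> dict:
    """95% Wald CI coverage of local fits under the generating model."""
    cover = None
    names = None
    for s in _sub_seeds(seed, reps):
        df, tm = generate_cohort(CohortGeneratorConfig(n=n), seed=int(s),
                                 return_model=True)
        fit = LocalLogisticModel(terms=list(tm.terms)).fit(df)
        hit = (fit.conf_int_[:, 0] <= tm.beta) & (tm.beta <= fit.conf_int_[:, 1])
        cover = hit.astype(int) if cover is None else cover + hit
        names = tm.term_names
    coverage = {name: c / reps for name, c in zip(names, cover)}
    return {"coverage": coverage, "min_coverage": min(coverage.values()),
            "max_coverage": max(coverage.values()), "n": reps}


# ---------------------------------------------------------------------------
# multiple imputation


def mi_bias_experiment(seed: int = 0, reps: int = 100, n: int = 2000,
                       m: int = 20) -> dict:
    """Pooled coefficient bias under 30% MAR dropout of follow-up glucose.

    Follow-up glucose is deleted by :data:`DEFAULT_MAR_MECHANISM`, imputed by
    chained equations with predictive-mean matching for the continuous
    conditional (the case/non-case mixture around the diagnostic threshold
    makes a plain normal draw misplace probability mass), and the local
    model refitted on each completed dataset and pooled. Bias is reported
    for the dominant fasting-glucose coefficient against its generating
    value.
    """
    pub = load_published_models()["ARIC"]
    true_fpg = pub.coefficient("fpg")
    seeds = _sub_seeds(seed, 3 * reps).reshape(reps, 3)
    pooled_fpg = []
    for s_gen, s_drop, s_imp in seeds:
        df = generate_cohort(CohortGeneratorConfig(n=n), seed=int(s_gen))
        dropped = apply_mar_dropout(df, DEFAULT_MAR_MECHANISM, seed=int(s_drop))
        work = dropped.drop(columns=["followup_fpg_true", "outcome_t2dm_true",
                                     "outcome_t2dm"])
        res = fcs_impute(work, m=m, seed=int(s_imp), pmm=True)
        pooled = pool_logistic_fits(res.datasets, pub.terms)
        pooled_fpg.append(pooled.pooled.loc["fpg", "estimate"])
    mean_est = float(np.mean(pooled_fpg))
    return {
        "true_fpg_coefficient": true_fpg,
        "pooled_fpg_coefficient": mean_est,
        "relative_bias": (mean_est - true_fpg) / true_fpg,
        "n": reps,
    }
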