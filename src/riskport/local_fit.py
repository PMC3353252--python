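"""Maximum-likelihood logistic refits of the published model structures.

The "local" counterpart of a published model keeps its term list but
re-estimates the coefficients (and an intercept) on the cohort at hand.
Estimation is delegated to statsmodels' Newton-Raphson MLE; the module adds
the race-coding choice by AIC, the likelihood-ratio screen for
ethnicity-by-covariate interactions, and the published-vs-local coefficient
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .model_core import RiskModel, TermSpec, design_matrix, _expit

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class FitError(RuntimeError):
    """Logistic MLE failed (separation, rank deficiency, non-convergence)."""


class LocalLogisticModel(BaseEstimator):
    """Logistic regression on a cohort, parameterized by model term specs.

    scikit-learn style estimator: ``fit`` takes the cohort DataFrame (the
    outcome defaults to the ``outcome_t2dm`` column), fitted attributes carry
    a trailing underscore, and ``predict_proba`` returns the usual
    ``(n, 2)`` array of class probabilities.

    Parameters
    ----------
    terms : sequence of TermSpec
        Covariate encodings, in scoring order.
    name : str
        Name recorded on the fitted :class:`~riskport.model_core.RiskModel`.
    maxiter, tol : MLE stopping rule (relative log-likelihood change).
    """

    def __init__(self, terms: Sequence[TermSpec] = (), name: str = "custom",
                 maxiter: int = 100, tol: float = 1e-10):
        self.terms = terms
        self.name = name
        self.maxiter = maxiter
        self.tol = tol

    def fit(self, cohort: pd.DataFrame, y=None) -> "LocalLogisticModel":
        if y is None:
            y = cohort["outcome_t2dm"]
        y = np.asarray(pd.to_numeric(pd.Series(y), errors="coerce"), dtype=float)
        if np.isnan(y).any():
            raise FitError("outcome contains missing values; impute first")
        if y.min() == y.max():
            raise FitError("need at least one event and one non-event")
        X = design_matrix(cohort, list(self.terms))
        Xc = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            raise FitError(
                "design matrix rank deficient after encoding; check terms "
                f"{[t.name for t in self.terms]}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=self.maxiter, tol=self.tol,
                                      method="newton")
            if not res.mle_retvals.get("converged", False):
                # Newton can overshoot with sparse events; quasi-Newton retry
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=10 * self.maxiter,
                                          method="lbfgs")
        if not res.mle_retvals.get("converged", False):
            raise FitError("logistic MLE did not converge (possible separation)")
        slopes = res.params[1:]
        if (slopes.size and np.abs(slopes).max() > 30) or not np.all(
                np.isfinite(res.bse)):
            raise FitError(
                "degenerate fit (huge coefficients / infinite SEs): likely "
                "separation in terms " + str([t.name for t in self.terms])
            )
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.bse_ = np.asarray(res.bse[1:], dtype=float)
        self.intercept_se_ = float(res.bse[0])
        self.llf_ = float(res.llf)
        k = Xc.shape[1]
        self.aic_ = 2 * k - 2 * self.llf_
        self.conf_int_ = np.column_stack(
            [self.coef_ - Z_95 * self.bse_, self.coef_ + Z_95 * self.bse_]
        )
        self.n_obs_ = len(y)
        self.model_ = RiskModel(
            name=self.name,
            terms=list(self.terms),
            beta=self.coef_,
            intercept=self.intercept_,
            provenance="local",
            fit_metadata={
                "log_likelihood": self.llf_,
                "aic": self.aic_,
                "se": self.bse_.tolist(),
                "intercept_se": self.intercept_se_,
                "conf_int_95": self.conf_int_.tolist(),
                "n_obs": self.n_obs_,
            },
        )
        return self

    def decision_function(self, cohort: pd.DataFrame) -> np.ndarray:
        return self.intercept_ + design_matrix(cohort, list(self.terms)) @ self.coef_

    def predict_proba(self, cohort: pd.DataFrame) -> np.ndarray:
        p = _expit(self.decision_function(cohort))
        return np.column_stack([1 - p, p])

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(cohort) > 0).astype(int)


def fit_logistic(cohort: pd.DataFrame, terms: Sequence[TermSpec],
                 name: str = "custom", y=None) -> RiskModel:
    """MLE logistic fit; returns a ``provenance='local'`` RiskModel."""
    return LocalLogisticModel(terms=list(terms), name=name).fit(cohort, y=y).model_


# ---------------------------------------------------------------------------
# race coding


def _split_race_terms(terms: Sequence[TermSpec]):
    race = [t for t in terms if t.encoding == "non_chinese"]
    other = [t for t in terms if t.encoding != "non_chinese"]
    if not race:
        raise ValueError("term list has no ethnicity (non_chinese) term")
    return race[0], other


def choose_race_coding(cohort: pd.DataFrame, terms: Sequence[TermSpec],
                       name: str = "custom") -> tuple[RiskModel, dict[str, float]]:
    """Pick between one combined non-Chinese dummy and separate Malay/Indian
    dummies by AIC (lower wins; the combined coding wins ties).

    Returns ``(chosen model, {"combined": aic, "separate": aic})``. If an
    ethnicity level is absent from the cohort the separate coding is not
    identifiable, so the available combined coding is returned with a warning.
    """
    race_term, other = _split_race_terms(terms)
    levels = set(cohort["ethnicity"].dropna().unique())
    combined = LocalLogisticModel(terms=list(terms), name=name).fit(cohort)
    if not {"Chinese", "Malay", "Indian"} <= levels:
        warnings.warn(
            f"ethnicity levels {sorted(levels)} incomplete; keeping combined race coding"
        )
        return combined.model_, {"combined": combined.aic_, "separate": float("nan")}
    # level dummies are not a generic TermSpec encoding; build them inline
    work = cohort.copy()
    work["is_malay"] = (work["ethnicity"] == "Malay").astype(float)
    work["is_indian"] = (work["ethnicity"] == "Indian").astype(float)
    sep_terms = [t for t in terms if t is not race_term] + [
        TermSpec("malay", "is_malay", "linear", {}),
        TermSpec("indian", "is_indian", "linear", {}),
    ]
    separate = LocalLogisticModel(terms=sep_terms, name=name).fit(work)
    aics = {"combined": combined.aic_, "separate": separate.aic_}
    chosen = combined.model_ if combined.aic_ <= separate.aic_ else separate.model_
    return chosen, aics


# ---------------------------------------------------------------------------
# interaction screening


@dataclass(frozen=True)
class InteractionTest:
    term: str
    lrt: float | None
    df: int
    p_value: float | None
    kept: bool
    testable: bool = True


def screen_ethnicity_interactions(
    cohort: pd.DataFrame,
    base_terms: Sequence[TermSpec],
    alpha: float = 0.05,
    three_level: bool = False,
    name: str = "custom",
) -> tuple[list[InteractionTest], RiskModel]:
    """Likelihood-ratio screen of covariate-by-ethnicity interactions.

    For every non-ethnicity covariate, fits the base model plus the
    covariate times the non-Chinese dummy (or times both Malay and Indian
    dummies when ``three_level``) and keeps the interaction iff the LRT
    p-value is below ``alpha``. Kept interactions are appended to the
    returned local model.
    """
    base_fit = LocalLogisticModel(terms=list(base_terms), name=name).fit(cohort)

    results: list[InteractionTest] = []
    kept_terms: list[TermSpec] = []
    for term in base_terms:
        if term.encoding == "non_chinese":
            continue
        if three_level:
            inter_cols = [
                TermSpec(f"{term.name}_x_{level.lower()}", term.source_field,
                         "product_level", {"inner": term.to_dict(), "level": level})
                for level in ("Malay", "Indian")
            ]
        else:
            inter_cols = [
                TermSpec(f"{term.name}_x_ethnicity", term.source_field,
                         "product_non_chinese", {"inner": term.to_dict()})
            ]
        df = len(inter_cols)
        try:
            full = LocalLogisticModel(
                terms=list(base_terms) + inter_cols, name=name
            ).fit(cohort)
        except FitError:
            results.append(InteractionTest(term.name, None, df, None, False, testable=False))
            continue
        lrt = max(0.0, 2.0 * (full.llf_ - base_fit.llf_))
        p = float(stats.chi2.sf(lrt, df)) if lrt > 0 else 1.0
        kept = p < alpha
        if kept:
            kept_terms.extend(inter_cols)
        results.append(InteractionTest(term.name, lrt, df, p, kept))

    if kept_terms:
        final = LocalLogisticModel(
            terms=list(base_terms) + kept_terms, name=name
        ).fit(cohort).model_
    else:
        final = base_fit.model_
    return results, final


# ---------------------------------------------------------------------------
# published-vs-local comparison


def compare_coefficients(local: RiskModel, published: RiskModel) -> pd.DataFrame:
    """Per-term table: local estimate and 95% CI against the published value.

    ``outside_ci`` flags terms whose published effect size falls outside the
    local Wald interval — the shape of the published-vs-local comparison
    tables.
    """
    if local.fit_metadata is None:
        raise ValueError("local model lacks fit metadata (not an MLE fit?)")
    shared = [n for n in local.term_names if n in published.term_names]
    missing = (set(local.term_names) ^ set(published.term_names)) - set(shared)
    unmatched = [n for n in published.term_names if n not in local.term_names]
    unmatched += [n for n in local.term_names if n not in published.term_names]
    if unmatched:
        raise ValueError(f"term mismatch between models: {sorted(set(unmatched))}")
    ci = np.asarray(local.fit_metadata["conf_int_95"], dtype=float)
    rows = []
    for name in shared:
        i = local.term_names.index(name)
        pub = published.coefficient(name)
        lo, hi = ci[i]
        rows.append(
            {
                "term": name,
                "local": float(local.beta[i]),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "published": pub,
                "outside_ci": bool(pub < lo or pub > hi),
            }
        )
    return pd.DataFrame(rows)
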