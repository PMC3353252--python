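"""Recalibration of externally developed logistic risk models.

An external model's coefficient vector beta transfers across populations far
better than its intercept, which absorbs the derivation cohort's baseline
incidence and covariate means. The recalibration formula maps the external
linear predictor onto local absolute risk using only local quantities:

    p(x) = 1 - S(m) ** exp((x - m) . beta)

where m is the local mean covariate vector on the model's encoding scale and
S(m) the probability that a subject with covariates m stays event-free over
the study period. A subject at the local mean gets exactly the local mean
risk 1 - S(m); everyone else is scaled up or down by their relative risk
exp((x - m) . beta). The external intercept is never used, so recalibrated
risks are invariant to it.

S(m) is not pinned down by a formula; two estimators are provided:

- ``mean_plugin_incidence`` (default): S(m) = 1 - observed incidence,
  reading the event-free probability of the average subject as the
  stratum's overall survival.
- ``intercept_matched``: solves for S(m) so that the mean recalibrated
  probability equals the observed incidence exactly
  (calibration-in-the-large by construction).

The two-step procedure for multi-ethnic populations first removes the race
terms from the model (the relative ordering of risk within an ethnic group
does not need them) and then recalibrates within each ethnic group
separately, absorbing between-group baseline differences into the per-group
S(m). Age-band stratification works the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .model_core import RiskModel, design_matrix


@dataclass
class RecalibrationContext:
    """Local mean covariates m and event-free probability S(m) for a stratum."""

    m: np.ndarray
    s_m: float
    estimation_method: str = "mean_plugin_incidence"
    stratum: Hashable | None = None
    n: int = 0
    incidence: float | None = None

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if not (0.0 < self.s_m <= 1.0):
            raise ValueError(f"S(m) must be in (0, 1], got {self.s_m}")

    def to_dict(self) -> dict:
        return {
            "m": self.m.tolist(),
            "s_m": self.s_m,
            "estimation_method": self.estimation_method,
            "stratum": None if self.stratum is None else str(self.stratum),
            "n": self.n,
            "incidence": self.incidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecalibrationContext":
        return cls(np.asarray(d["m"], dtype=float), d["s_m"],
                   d.get("estimation_method", "mean_plugin_incidence"),
                   d.get("stratum"), d.get("n", 0), d.get("incidence"))


def _outcome_vector(cohort: pd.DataFrame, y=None) -> np.ndarray:
    if y is None:
        y = cohort["outcome_t2dm"]
    y = np.asarray(pd.to_numeric(pd.Series(y), errors="coerce"), dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcomes contain missing values; impute first")
    return y


def estimate_context(
    cohort: pd.DataFrame,
    model: RiskModel,
    *,
    y=None,
    method: str = "mean_plugin_incidence",
    stratum: Hashable | None = None,
) -> RecalibrationContext:
    """Estimate m and S(m) from one cohort (or one stratum of it).

    ``m`` is the per-term arithmetic mean of the encoded covariates, so
    binary terms contribute their prevalence. With zero events S(m) is 1
    (every recalibrated risk becomes 0) and a warning is emitted.
    """
    if len(cohort) == 0:
        raise ValueError(f"empty stratum {stratum!r}")
    X = design_matrix(cohort, model.terms)
    yv = _outcome_vector(cohort, y)
    incidence = float(yv.mean())
    m = X.mean(axis=0)
    if incidence == 0.0:
        warnings.warn(f"stratum {stratum!r} has zero events; S(m) set to 1")
        return RecalibrationContext(m, 1.0, method, stratum, len(cohort), 0.0)
    if method == "mean_plugin_incidence":
        s_m = 1.0 - incidence
    elif method == "intercept_matched":
        d = (X - m) @ model.beta
        s_m = _match_survival(d, incidence)
    else:
        raise ValueError(f"unknown S(m) estimation method {method!r}")
    return RecalibrationContext(m, s_m, method, stratum, len(cohort), incidence)


def _match_survival(relative_lp: np.ndarray, incidence: float) -> float:
    """Solve mean(1 - s**exp(d)) = incidence for s; monotone in s."""
    e = np.exp(np.clip(relative_lp, -700, 700))

    def gap(s):
        return float(np.mean(1.0 - s ** e)) - incidence

    lo, hi = 1e-12, 1.0 - 1e-12
    if gap(hi) > 0:  # incidence below what even s ~ 1 can give (not reachable)
        return hi
    if gap(lo) < 0:
        return lo
    return float(brentq(gap, lo, hi, xtol=1e-14))


def recalibrate_probabilities(
    model: RiskModel, context: RecalibrationContext, cohort: pd.DataFrame
) -> np.ndarray:
    """Vector of recalibrated risks 1 - S(m)^exp((x-m).beta) over a cohort."""
    X = design_matrix(cohort, model.terms)
    d = (X - context.m) @ model.beta
    return 1.0 - context.s_m ** np.exp(np.clip(d, -700, 700))


def recalibrate(model: RiskModel, context: RecalibrationContext, subject) -> "RiskPrediction":
    """Recalibrated risk for a single subject record."""
    from .model_core import RiskPrediction, encode_subject

    x = encode_subject(subject, model)
    d = float((x - context.m) @ model.beta)
    p = 1.0 - context.s_m ** np.exp(d)
    sid = str(subject.get("id", "")) if hasattr(subject, "get") else str(subject["id"])
    return RiskPrediction(sid, d, p, model.name, recalibrated=True)


def _race_term_names(model: RiskModel) -> list[str]:
    return [t.name for t in model.terms if t.encoding == "non_chinese"
            or t.name.lower() in ("ethnicity", "malay", "indian", "race")]


class Recalibrator(BaseEstimator):
    """Fits per-stratum recalibration contexts and predicts absolute risk.

    Parameters
    ----------
    model : RiskModel
        External model supplying beta (its intercept, if any, is ignored).
    method : {"mean_plugin_incidence", "intercept_matched"}
        Estimator for the event-free probability S(m).
    strata : str, callable or None
        ``None`` for a single whole-cohort context; a column name (e.g.
        ``"ethnicity"``) to recalibrate within its groups; or a callable
        mapping the cohort frame to a label Series (e.g. age bands).
    drop_race_terms : bool
        Remove the model's race terms before scoring (step 1 of the
        two-step procedure).
    drop_age_terms : bool
        Remove linear age terms (for age-stratified recalibration).
    """

    def __init__(self, model: RiskModel = None, method: str = "mean_plugin_incidence",
                 strata=None, drop_race_terms: bool = False, drop_age_terms: bool = False):
        self.model = model
        self.method = method
        self.strata = strata
        self.drop_race_terms = drop_race_terms
        self.drop_age_terms = drop_age_terms

    def _working_model(self) -> RiskModel:
        model = self.model
        if self.drop_race_terms:
            names = _race_term_names(model)
            if not names:
                raise ValueError(f"model {model.name!r} has no race terms to remove")
            model = model.drop_terms(names)
        if self.drop_age_terms:
            names = [t.name for t in model.terms
                     if t.source_field == "age" and t.encoding == "linear"]
            if names:
                model = model.drop_terms(names)
        return model

    def _labels(self, cohort: pd.DataFrame) -> pd.Series:
        if self.strata is None:
            return pd.Series("__all__", index=cohort.index)
        if callable(self.strata):
            return pd.Series(self.strata(cohort), index=cohort.index)
        return cohort[self.strata]

    def fit(self, cohort: pd.DataFrame, y=None) -> "Recalibrator":
        if self.model is None:
            raise ValueError("Recalibrator needs a model")
        self.model_ = self._working_model()
        labels = self._labels(cohort)
        if labels.isna().any():
            raise ValueError("stratum labels contain missing values")
        yv = pd.Series(_outcome_vector(cohort, y), index=cohort.index)
        self.contexts_ = {}
        for label, idx in labels.groupby(labels, observed=True).groups.items():
            sub = cohort.loc[idx]
            self.contexts_[label] = estimate_context(
                sub, self.model_, y=yv.loc[idx], method=self.method, stratum=label
            )
        return self

    def predict_proba(self, cohort: pd.DataFrame) -> np.ndarray:
        p = self.predict_risk(cohort)
        return np.column_stack([1 - p, p])

    def predict_risk(self, cohort: pd.DataFrame) -> np.ndarray:
        labels = self._labels(cohort)
        p = np.empty(len(cohort))
        pos = pd.Series(np.arange(len(cohort)), index=cohort.index)
        for label, idx in labels.groupby(labels, observed=True).groups.items():
            if label not in self.contexts_:
                raise KeyError(f"no fitted context for stratum {label!r}")
            rows = pos.loc[idx].to_numpy()
            p[rows] = recalibrate_probabilities(
                self.model_, self.contexts_[label], cohort.loc[idx]
            )
        return p

    def predict_frame(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Per-subject predictions with their stratum labels."""
        return pd.DataFrame(
            {
                "id": cohort["id"] if "id" in cohort else cohort.index.astype(str),
                "stratum": self._labels(cohort).to_numpy(),
                "probability": self.predict_risk(cohort),
                "model": self.model_.name,
                "recalibrated": True,
            },
            index=cohort.index,
        )


def two_step_race_recalibration(
    model: RiskModel,
    cohort: pd.DataFrame,
    *,
    y=None,
    ethnicity_column: str = "ethnicity",
    method: str = "mean_plugin_incidence",
) -> pd.DataFrame:
    """Two-step procedure: drop race terms, then recalibrate per ethnic group.

    Returns a frame with ``id``, ``stratum`` (ethnic group) and
    ``probability`` columns.
    """
    rec = Recalibrator(model=model, method=method, strata=ethnicity_column,
                       drop_race_terms=True)
    rec.fit(cohort, y=y)
    return rec.predict_frame(cohort)


def stratified_recalibration_by_age(
    model: RiskModel,
    cohort: pd.DataFrame,
    age_bands: Sequence[float],
    *,
    y=None,
    drop_age_term: bool = False,
    method: str = "mean_plugin_incidence",
) -> pd.DataFrame:
    """Recalibrate within age bands given by ``age_bands`` bin edges.

    Edges follow :func:`pandas.cut` (right-closed); every subject must fall
    in a band and every band must be non-empty.
    """
    bands = pd.cut(cohort["age"], bins=list(age_bands), include_lowest=True)
    if bands.isna().any():
        raise ValueError("some subjects fall outside the specified age bands")
    if bands.cat.categories.size != bands.nunique():
        empty = set(bands.cat.categories) - set(bands.dropna().unique())
        raise ValueError(f"empty age band(s): {sorted(map(str, empty))}")
    labeler = lambda df: pd.cut(df["age"], bins=list(age_bands), include_lowest=True)
    rec = Recalibrator(model=model, method=method, strata=labeler,
                       drop_age_terms=drop_age_term)
    rec.fit(cohort, y=y)
    out = rec.predict_frame(cohort)
    out["stratum"] = out["stratum"].astype(str)
    return out
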