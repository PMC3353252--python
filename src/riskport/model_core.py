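"""Data model, covariate encodings, eligibility/outcome rules and risk scoring.

A cohort is a :class:`pandas.DataFrame` with one row per subject and the
columns of :data:`SUBJECT_FIELDS` (continuous fields in the units noted
there, glucose/lipids in mmol/L). A :class:`RiskModel` is a named logistic
model: an ordered list of :class:`TermSpec` encodings plus a coefficient
vector, with an optional intercept. Published models (SAHS, ARIC, Framingham)
ship as JSON files; their intercepts were never published, so absolute-risk
use of them goes through recalibration (see :mod:`riskport.recalibration`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import units

#: field -> (dtype kind, unit) for the subject schema
SUBJECT_FIELDS = {
    "id": ("str", None),
    "age": ("float", "years"),
    "sex": ("category", None),  # male / female
    "ethnicity": ("category", None),  # Chinese / Malay / Indian
    "fpg": ("float", "mmol/L"),
    "two_hpg": ("float", "mmol/L"),  # optional
    "sbp": ("float", "mmHg"),
    "hdl": ("float", "mmol/L"),
    "triglyceride": ("float", "mmol/L"),
    "bmi": ("float", "kg/m^2"),
    "waist": ("float", "cm"),
    "height": ("float", "cm"),
    "family_history_t2dm": ("binary", None),
    "physician_dx_baseline": ("binary", None),
    "followup_fpg": ("float", "mmol/L"),  # optional until follow-up
    "physician_dx_followup": ("binary", None),
    "outcome_t2dm": ("binary", None),  # optional until follow-up
}

ETHNICITIES = ("Chinese", "Malay", "Indian")
SEXES = ("male", "female")

#: diagnostic thresholds, mmol/L; inclusive (>=) per the diagnostic convention
FPG_DIABETES_THRESHOLD = 7.0
TWO_HPG_DIABETES_THRESHOLD = 11.1


class MissingFieldError(ValueError):
    """A model term needs a field that is missing for a subject."""


class UnknownInterceptError(ValueError):
    """Absolute risk requested from a model whose intercept is unknown."""

    def __init__(self, name: str):
        super().__init__(
            f"model {name!r} has no published intercept; recalibrate it "
            "against a local cohort, supply an intercept explicitly, or "
            "request an intercept-free (rank-only) score"
        )


# ---------------------------------------------------------------------------
# term specifications


@dataclass(frozen=True)
class TermSpec:
    """One covariate term of a logistic risk model.

    ``encoding`` decides how the raw subject field maps onto the model's
    covariate scale:

    - ``linear``: value times an optional unit conversion ``factor``
    - ``indicator``: the field itself, coerced to 0/1
    - ``female``: 1 for female subjects (SAHS gender coding)
    - ``non_chinese``: 1 for Malay or Indian subjects (Chinese reference)
    - ``ge`` / ``lt``: threshold indicator against ``cutpoint`` (raw units)
    - ``band``: 1 iff ``low <= value < high`` (raw units)
    - ``lt_by_sex``: 1 iff value below a sex-specific cutpoint
      (``male_cut`` / ``female_cut``)
    - ``product_non_chinese``: the encoding of an ``inner`` term spec
      (``params["inner"]``, a TermSpec dict) times the non-Chinese dummy —
      a covariate-by-ethnicity interaction
    """

    name: str
    source_field: str
    encoding: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.encoding in ("ge", "lt") and "cutpoint" not in self.params:
            raise ValueError(f"term {self.name!r}: {self.encoding} needs a cutpoint")
        if self.encoding == "band" and not {"low", "high"} <= set(self.params):
            raise ValueError(f"term {self.name!r}: band needs low and high")
        if self.encoding == "lt_by_sex" and not {"male_cut", "female_cut"} <= set(self.params):
            raise ValueError(f"term {self.name!r}: lt_by_sex needs male_cut and female_cut")

    def encode(self, cohort: pd.DataFrame) -> np.ndarray:
        """Encode this term for every row of ``cohort``; raises on missing data."""
        if self.encoding == "female":
            col = cohort["sex"]
            if col.isna().any():
                _raise_missing(self, cohort, col.isna())
            return (col == "female").to_numpy(dtype=float)
        if self.encoding == "non_chinese":
            col = cohort["ethnicity"]
            if col.isna().any():
                _raise_missing(self, cohort, col.isna())
            return (col != "Chinese").to_numpy(dtype=float)
        if self.encoding == "product_non_chinese":
            inner = TermSpec.from_dict(self.params["inner"])
            dummy = (cohort["ethnicity"] != "Chinese").to_numpy(dtype=float)
            return inner.encode(cohort) * dummy
        if self.encoding == "product_level":
            inner = TermSpec.from_dict(self.params["inner"])
            dummy = (cohort["ethnicity"] == self.params["level"]).to_numpy(dtype=float)
            return inner.encode(cohort) * dummy

        if self.source_field not in cohort.columns:
            raise MissingFieldError(
                f"term {self.name!r} needs field {self.source_field!r}, absent from cohort"
            )
        col = pd.to_numeric(cohort[self.source_field], errors="coerce")
        if col.isna().any():
            _raise_missing(self, cohort, col.isna())
        v = col.to_numpy(dtype=float)

        if self.encoding == "linear":
            return v * float(self.params.get("factor", 1.0))
        if self.encoding == "indicator":
            return (v != 0).astype(float)
        if self.encoding == "ge":
            return (v >= self.params["cutpoint"]).astype(float)
        if self.encoding == "lt":
            return (v < self.params["cutpoint"]).astype(float)
        if self.encoding == "band":
            return ((v >= self.params["low"]) & (v < self.params["high"])).astype(float)
        if self.encoding == "lt_by_sex":
            cuts = np.where(
                cohort["sex"].to_numpy() == "female",
                self.params["female_cut"],
                self.params["male_cut"],
            )
            return (v < cuts).astype(float)
        raise ValueError(f"unknown encoding {self.encoding!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source_field": self.source_field,
            "encoding": self.encoding,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TermSpec":
        return cls(d["name"], d["source_field"], d["encoding"], dict(d.get("params", {})))


def _raise_missing(term: TermSpec, cohort: pd.DataFrame, mask) -> None:
    ids = cohort.loc[mask, "id"].astype(str).tolist() if "id" in cohort else list(
        cohort.index[mask].astype(str)
    )
    shown = ", ".join(ids[:5]) + ("..." if len(ids) > 5 else "")
    raise MissingFieldError(
        f"field {term.source_field!r} required by term {term.name!r} is missing "
        f"for subject(s): {shown}"
    )


# ---------------------------------------------------------------------------
# risk models


@dataclass
class RiskModel:
    """A named logistic risk model: ordered terms, coefficients, intercept."""

    name: str
    terms: Sequence[TermSpec]
    beta: np.ndarray
    intercept: float | None = None
    provenance: str = "published"  # published | local
    fit_metadata: dict | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.terms):
            raise ValueError(
                f"model {self.name!r}: {len(self.beta)} coefficients for "
                f"{len(self.terms)} terms"
            )
        if self.provenance == "published" and self.fit_metadata is not None:
            raise ValueError("published models carry no fit metadata")

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def term(self, name: str) -> TermSpec:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def coefficient(self, name: str) -> float:
        return float(self.beta[self.term_names.index(name)])

    def drop_terms(self, names: Iterable[str]) -> "RiskModel":
        """New model without the named terms (used by the two-step procedure)."""
        drop = set(names)
        keep = [i for i, t in enumerate(self.terms) if t.name not in drop]
        if len(keep) == len(self.terms):
            raise KeyError(f"none of {sorted(drop)} found in model {self.name!r}")
        return RiskModel(
            name=self.name,
            terms=[self.terms[i] for i in keep],
            beta=self.beta[keep],
            intercept=self.intercept,
            provenance=self.provenance,
            fit_metadata=None if self.fit_metadata is None else dict(self.fit_metadata),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "terms": [t.to_dict() for t in self.terms],
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskModel":
        return cls(
            name=d["name"],
            terms=[TermSpec.from_dict(t) for t in d["terms"]],
            beta=np.asarray(d["beta"], dtype=float),
            intercept=d.get("intercept"),
            provenance=d.get("provenance", "published"),
        )

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class RiskPrediction:
    subject_id: str
    linear_predictor: float
    probability: float | None
    model_name: str
    recalibrated: bool = False
    rank_only: bool = False


# ---------------------------------------------------------------------------
# published model definitions

_PUBLISHED_NAMES = ("SAHS", "ARIC", "FRAM")


def load_published_models(asian_overweight: bool = False) -> dict[str, RiskModel]:
    """Load the bundled SAHS, ARIC and Framingham published models.

    Coefficients are the published values; intercepts are unknown (``None``)
    because the source publications' constants were not reproduced here, so
    absolute risks require recalibration or a user-supplied intercept.

    Parameters
    ----------
    asian_overweight : bool
        Use the Asian overweight cutoff (BMI >= 23 instead of >= 25) for the
        Framingham dichotomization.
    """
    models = {}
    for name in _PUBLISHED_NAMES:
        text = resources.files("riskport.published_models").joinpath(
            f"{name.lower()}.json"
        ).read_text()
        models[name] = RiskModel.from_dict(json.loads(text))
    if asian_overweight:
        fram = models["FRAM"]
        terms = []
        for t in fram.terms:
            if t.name == "bmi_overweight":
                terms.append(TermSpec(t.name, t.source_field, "band", {"low": 23.0, "high": 30.0}))
            else:
                terms.append(t)
        models["FRAM"] = RiskModel(fram.name, terms, fram.beta, fram.intercept, fram.provenance)
    return models


def fpg_only_terms(factor: float = units.GLUCOSE_MGDL_PER_MMOL) -> list[TermSpec]:
    """Single-predictor term list: fasting plasma glucose in mg/dl."""
    return [TermSpec("fpg", "fpg", "linear", {"factor": factor})]


def ogtt_only_terms(factor: float = units.GLUCOSE_MGDL_PER_MMOL) -> list[TermSpec]:
    """Single-predictor term list: 2-hour post-challenge glucose in mg/dl."""
    return [TermSpec("two_hpg", "two_hpg", "linear", {"factor": factor})]


# ---------------------------------------------------------------------------
# encoding and scoring


def design_matrix(cohort: pd.DataFrame, terms: Sequence[TermSpec]) -> np.ndarray:
    """Column-stack the encoded terms; shape (n_subjects, n_terms)."""
    if len(terms) == 0:
        return np.empty((len(cohort), 0))
    return np.column_stack([t.encode(cohort) for t in terms])


def encode_subject(subject: Mapping | pd.Series, model: RiskModel) -> np.ndarray:
    """Covariate vector for one subject, aligned with ``model.terms``."""
    row = pd.DataFrame([dict(subject)])
    return design_matrix(row, model.terms)[0]


def linear_predictor(
    model: RiskModel, x: np.ndarray, *, allow_missing_intercept: bool = False
) -> np.ndarray | float:
    """``intercept + x . beta``; intercept-free (rank-only) when allowed."""
    score = np.asarray(x, dtype=float) @ model.beta
    if model.intercept is None:
        if not allow_missing_intercept:
            raise UnknownInterceptError(model.name)
        return score
    return score + model.intercept


def predict_risk(model: RiskModel, subject: Mapping | pd.Series) -> RiskPrediction:
    """Absolute risk ``p = 1 / (1 + exp(-y))`` for one subject."""
    x = encode_subject(subject, model)
    y = float(linear_predictor(model, x))
    sid = str(subject.get("id", "")) if hasattr(subject, "get") else str(subject["id"])
    return RiskPrediction(sid, y, _expit(y), model.name)


def predict_proba(model: RiskModel, cohort: pd.DataFrame) -> np.ndarray:
    """Vector of absolute risks over a cohort (requires a known intercept)."""
    y = linear_predictor(model, design_matrix(cohort, model.terms))
    return _expit(y)


def rank_score(model: RiskModel, cohort: pd.DataFrame) -> np.ndarray:
    """Intercept-free linear predictor ``x . beta`` — valid for ranking only."""
    return design_matrix(cohort, model.terms) @ model.beta


def _expit(y):
    return 1.0 / (1.0 + np.exp(-np.asarray(y, dtype=float)))


# ---------------------------------------------------------------------------
# eligibility and outcome


def apply_eligibility_filter(
    cohort: pd.DataFrame,
    *,
    fpg_threshold: float = FPG_DIABETES_THRESHOLD,
    two_hpg_threshold: float = TWO_HPG_DIABETES_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects with diabetes at baseline.

    Excludes physician-diagnosed diabetes, baseline FPG >= 7.0 mmol/L and
    baseline 2hPG >= 11.1 mmol/L (thresholds inclusive). Returns
    ``(eligible, excluded)``; the excluded frame gains an
    ``exclusion_reason`` column with machine-readable codes
    (``prior_diagnosis`` / ``baseline_fpg`` / ``baseline_2hpg``), the first
    matching reason winning.
    """
    reason = pd.Series(pd.NA, index=cohort.index, dtype="object")
    if "physician_dx_baseline" in cohort:
        dx = cohort["physician_dx_baseline"].fillna(0).astype(float) != 0
        reason[dx] = "prior_diagnosis"
    fpg = pd.to_numeric(cohort["fpg"], errors="coerce")
    reason[reason.isna() & (fpg >= fpg_threshold)] = "baseline_fpg"
    if "two_hpg" in cohort:
        two = pd.to_numeric(cohort["two_hpg"], errors="coerce")
        reason[reason.isna() & (two >= two_hpg_threshold)] = "baseline_2hpg"
    excluded = cohort[reason.notna()].copy()
    excluded["exclusion_reason"] = reason[reason.notna()]
    return cohort[reason.isna()].copy(), excluded


def define_outcome(subject: Mapping | pd.Series) -> int | None:
    """Incident diabetes: follow-up FPG >= 7.0 mmol/L or physician diagnosis.

    Returns ``None`` (outcome unknown, route to imputation) when both the
    follow-up glucose and the diagnosis flag are absent.
    """
    fpg = subject.get("followup_fpg")
    dx = subject.get("physician_dx_followup")
    fpg_known = fpg is not None and not (isinstance(fpg, float) and math.isnan(fpg))
    dx_known = dx is not None and not (isinstance(dx, float) and math.isnan(dx))
    if not fpg_known and not dx_known:
        return None
    if dx_known and dx:
        return 1
    if fpg_known and fpg >= FPG_DIABETES_THRESHOLD:
        return 1
    if not fpg_known:
        # diagnosis known-negative but glucose unmeasured: still unknown
        return None
    return 0


def define_outcomes(cohort: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`define_outcome`; NA where the outcome is unknown."""
    fpg = pd.to_numeric(cohort.get("followup_fpg"), errors="coerce")
    dx = pd.to_numeric(cohort.get("physician_dx_followup"), errors="coerce")
    if fpg is None:
        fpg = pd.Series(np.nan, index=cohort.index)
    if dx is None:
        dx = pd.Series(np.nan, index=cohort.index)
    pos = (dx.fillna(0) != 0) | (fpg >= FPG_DIABETES_THRESHOLD)
    known = fpg.notna() | (dx.notna() & (dx != 0))
    out = pd.Series(pd.NA, index=cohort.index, dtype="object")
    out[known & pos] = 1
    out[known & ~pos] = 0
    return out


def validate_cohort(cohort: pd.DataFrame, *, require_outcome: bool = False) -> None:
    """Check subject-record invariants; raises ``ValueError`` on violation."""
    problems = []
    for col in ("age", "fpg", "sbp", "hdl", "bmi"):
        if col not in cohort:
            problems.append(f"missing column {col!r}")
    if problems:
        raise ValueError("; ".join(problems))
    age = pd.to_numeric(cohort["age"], errors="coerce")
    if ((age < 18) | (age > 100)).any():
        problems.append("age outside [18, 100]")
    for col in ("fpg", "two_hpg", "sbp", "hdl", "triglyceride", "bmi", "waist", "height"):
        if col in cohort:
            v = pd.to_numeric(cohort[col], errors="coerce")
            if (v.dropna() <= 0).any():
                problems.append(f"non-positive values in {col!r}")
    if "ethnicity" in cohort and not cohort["ethnicity"].dropna().isin(ETHNICITIES).all():
        problems.append("ethnicity outside {Chinese, Malay, Indian}")
    if "sex" in cohort and not cohort["sex"].dropna().isin(SEXES).all():
        problems.append("sex outside {male, female}")
    if require_outcome and ("outcome_t2dm" not in cohort or cohort["outcome_t2dm"].isna().any()):
        problems.append("outcome_t2dm missing")
    if problems:
        raise ValueError("cohort invariant violations: " + "; ".join(problems))


def read_cohort(path) -> pd.DataFrame:
    """Read a comma-separated cohort file (header row, empty cells missing)."""
    df = pd.read_csv(path, dtype={"id": str})
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
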