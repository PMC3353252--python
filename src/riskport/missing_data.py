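"""Multiple imputation by fully conditional specification and Rubin pooling.

Missing follow-up glucose (and any incomplete baseline fields) are filled by
chained conditional draws: a normal linear conditional with
posterior-predictive noise for continuous fields, a logistic conditional for
binary fields, each regressed on the remaining imputer fields. M independent
chains with distinct sub-seeds yield M completed datasets; downstream model
coefficients are pooled with Rubin's rules — mean estimate, total variance
T = W + (1 + 1/M) B from the within- (W) and between-imputation (B)
variances.

The default imputer field list is deliberately wider than any risk model
(hip, creatinine, LDL, insulin resistance, waist-hip ratio enter only here):
a more inclusive conditional model makes the missing-at-random assumption
more plausible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .model_core import TermSpec, define_outcomes

#: baseline fields used to predict missing values, when present in the frame
DEFAULT_IMPUTER_FIELDS = (
    "age", "sex", "ethnicity", "sbp", "bmi", "hdl", "ldl", "fpg",
    "family_history_t2dm", "hip", "waist", "waist_hip_ratio", "creatinine",
    "triglyceride", "insulin_resistance", "followup_fpg",
)


@dataclass
class ImputationResult:
    m: int
    datasets: list[pd.DataFrame]
    estimates: np.ndarray | None = None  # (M, k)
    variances: np.ndarray | None = None  # (M, k)
    pooled: pd.DataFrame | None = None


def _is_binary(series: pd.Series) -> bool:
    vals = pd.unique(pd.to_numeric(series.dropna(), errors="coerce"))
    return len(vals) > 0 and np.isin(vals, (0.0, 1.0)).all()


def _predictor_frame(df: pd.DataFrame, fields: Sequence[str], target: str) -> pd.DataFrame:
    """Numeric predictor matrix from the imputer fields, excluding the target."""
    cols = {}
    for f in fields:
        if f == target or f not in df.columns:
            continue
        if f == "sex":
            cols["sex_female"] = (df["sex"] == "female").astype(float)
        elif f == "ethnicity":
            cols["eth_malay"] = (df["ethnicity"] == "Malay").astype(float)
            cols["eth_indian"] = (df["ethnicity"] == "Indian").astype(float)
        else:
            cols[f] = pd.to_numeric(df[f], errors="coerce")
    return pd.DataFrame(cols, index=df.index)


class FCSImputer(BaseEstimator):
    """Chained-equation multiple imputer.

    Parameters
    ----------
    fields : sequence of str or None
        Columns eligible for imputation; ``None`` means every imputer field
        with missing cells.
    imputer_fields : sequence of str
        Predictor pool for the conditional models (only columns actually in
        the frame are used).
    m : int
        Number of imputed datasets (independent chains).
    n_cycles : int
        FCS sweeps over the incomplete fields per chain.
    pmm : bool
        Predictive-mean matching for continuous fields (draw from the
        ``pmm_k`` observed donors closest in predicted mean) instead of the
        normal posterior-predictive draw.
    random_state : int or None
        Seed; the same seed reproduces the completed datasets exactly.
    """

    def __init__(self, fields=None, imputer_fields=DEFAULT_IMPUTER_FIELDS,
                 m: int = 20, n_cycles: int = 10, pmm: bool = False,
                 pmm_k: int = 5, random_state=None):
        self.fields = fields
        self.imputer_fields = imputer_fields
        self.m = m
        self.n_cycles = n_cycles
        self.pmm = pmm
        self.pmm_k = pmm_k
        self.random_state = random_state

    # the imputer is stateless across datasets; fit records the target fields
    def fit(self, cohort: pd.DataFrame, y=None) -> "FCSImputer":
        candidates = self.fields
        if candidates is None:
            candidates = [f for f in self.imputer_fields if f in cohort.columns]
        self.incomplete_fields_ = [
            f for f in candidates if f in cohort.columns and cohort[f].isna().any()
        ]
        return self

    def transform(self, cohort: pd.DataFrame) -> list[pd.DataFrame]:
        root = np.random.default_rng(self.random_state)
        sub_seeds = root.integers(0, 2**31 - 1, size=self.m)
        return [self._run_chain(cohort, int(s)) for s in sub_seeds]

    def fit_transform(self, cohort: pd.DataFrame, y=None) -> list[pd.DataFrame]:
        return self.fit(cohort).transform(cohort)

    def impute(self, cohort: pd.DataFrame) -> ImputationResult:
        datasets = self.fit_transform(cohort)
        return ImputationResult(m=self.m, datasets=datasets)

    # ------------------------------------------------------------------
    def _run_chain(self, cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        df = cohort.copy()
        targets = [f for f in self.incomplete_fields_]
        if not targets:
            return df
        masks = {f: cohort[f].isna().to_numpy() for f in targets}
        # initialize missing cells by resampling observed values
        for f in targets:
            obs = pd.to_numeric(cohort[f].dropna(), errors="coerce").to_numpy()
            if obs.size == 0:
                warnings.warn(f"field {f!r} has no observed values; skipped")
                targets = [t for t in targets if t != f]
                continue
            df.loc[masks[f], f] = rng.choice(obs, size=masks[f].sum(), replace=True)
        for _ in range(self.n_cycles):
            for f in targets:
                self._impute_field(df, cohort, f, masks[f], rng)
        return df

    def _impute_field(self, df, cohort, field, miss, rng):
        pred = _predictor_frame(df, self.imputer_fields, field)
        pred = pred.loc[:, pred.notna().all()]  # predictors must be complete
        if pred.shape[1] == 0:
            warnings.warn(f"no complete predictors for field {field!r}; skipped")
            return
        X = np.column_stack([np.ones(len(df)), pred.to_numpy(dtype=float)])
        yv = pd.to_numeric(df[field], errors="coerce").to_numpy(dtype=float)
        obs = ~miss
        if _is_binary(cohort[field]):
            df.loc[miss, field] = self._draw_binary(X, yv, obs, miss, rng)
        else:
            df.loc[miss, field] = self._draw_continuous(X, yv, obs, miss, rng)

    def _draw_continuous(self, X, y, obs, miss, rng):
        Xo, yo = X[obs], y[obs]
        n, k = Xo.shape
        xtx = Xo.T @ Xo
        xtx_inv = np.linalg.pinv(xtx)
        beta_hat = xtx_inv @ (Xo.T @ yo)
        resid = yo - Xo @ beta_hat
        dof = max(n - k, 1)
        s2 = float(resid @ resid) / dof
        # posterior-predictive draw: sigma^2 from scaled inverse chi-square,
        # beta from its normal posterior, then new observation noise
        sigma2 = s2 * dof / rng.chisquare(dof)
        beta = rng.multivariate_normal(beta_hat, sigma2 * xtx_inv, method="svd")
        mu_miss = X[miss] @ beta
        if self.pmm:
            mu_obs = Xo @ beta
            order = np.argsort(mu_obs, kind="stable")
            mu_sorted, y_sorted = mu_obs[order], yo[order]
            k = min(self.pmm_k, len(y_sorted))
            pos = np.searchsorted(mu_sorted, mu_miss)
            draws = np.empty(len(mu_miss))
            for i, (mval, p0) in enumerate(zip(mu_miss, pos)):
                lo = max(0, p0 - k)
                hi = min(len(mu_sorted), p0 + k)
                window = np.arange(lo, hi)
                near = window[np.argpartition(np.abs(mu_sorted[window] - mval), k - 1)[:k]]
                draws[i] = y_sorted[rng.choice(near)]
            return draws
        return mu_miss + rng.normal(0.0, np.sqrt(sigma2), size=miss.sum())

    def _draw_binary(self, X, y, obs, miss, rng):
        Xo, yo = X[obs], y[obs]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yo, Xo).fit(disp=0, maxiter=50)
            if not res.mle_retvals.get("converged", False):
                raise RuntimeError
            beta = rng.multivariate_normal(res.params, res.cov_params(), method="svd")
            p = 1.0 / (1.0 + np.exp(-(X[miss] @ beta)))
        except Exception:
            # degenerate conditional: fall back to the marginal rate
            p = np.full(miss.sum(), yo.mean())
        return (rng.random(miss.sum()) < p).astype(float)


def fcs_impute(cohort: pd.DataFrame, fields=None, m: int = 20,
               n_cycles: int = 10, seed=None, **kw) -> ImputationResult:
    """Convenience wrapper around :class:`FCSImputer`."""
    imp = FCSImputer(fields=fields, m=m, n_cycles=n_cycles, random_state=seed, **kw)
    return imp.impute(cohort)


# ---------------------------------------------------------------------------
# Rubin's rules


def rubin_pool(estimates, variances) -> pd.DataFrame:
    """Pool M per-imputation estimates and squared SEs with Rubin's rules.

    Returns a frame with columns ``estimate`` (mean across imputations),
    ``within`` (mean variance), ``between`` (sample variance of estimates),
    ``total`` (W + (1 + 1/M) B) and ``se`` (sqrt of total).
    """
    q = np.atleast_2d(np.asarray(estimates, dtype=float))
    u = np.atleast_2d(np.asarray(variances, dtype=float))
    if q.shape != u.shape:
        raise ValueError(f"estimates {q.shape} and variances {u.shape} differ")
    m = q.shape[0]
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    qbar = q.mean(axis=0)
    wbar = u.mean(axis=0)
    b = q.var(axis=0, ddof=1)
    t = wbar + (1.0 + 1.0 / m) * b
    return pd.DataFrame(
        {"estimate": qbar, "within": wbar, "between": b, "total": t,
         "se": np.sqrt(t)}
    )


def pool_logistic_fits(
    datasets: Sequence[pd.DataFrame],
    terms: Sequence[TermSpec],
    *,
    name: str = "custom",
    derive_outcome: bool = True,
) -> ImputationResult:
    """Fit the local logistic model on each completed dataset and pool.

    When ``derive_outcome`` the incident-diabetes outcome is recomputed from
    each dataset's (possibly imputed) follow-up glucose before fitting. The
    pooled frame is indexed by ``intercept`` plus the term names.
    """
    from .local_fit import LocalLogisticModel

    est, var = [], []
    for df in datasets:
        work = df
        if derive_outcome:
            work = df.copy()
            work["outcome_t2dm"] = pd.to_numeric(define_outcomes(df), errors="coerce")
        fit = LocalLogisticModel(terms=list(terms), name=name).fit(work)
        est.append(np.concatenate([[fit.intercept_], fit.coef_]))
        var.append(np.concatenate([[fit.intercept_se_**2], fit.bse_**2]))
    est = np.asarray(est)
    var = np.asarray(var)
    pooled = rubin_pool(est, var)
    pooled.index = ["intercept"] + [t.name for t in terms]
    return ImputationResult(
        m=len(datasets), datasets=list(datasets), estimates=est,
        variances=var, pooled=pooled,
    )
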