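"""Discrimination and calibration statistics for risk predictions.

Discrimination: Mann-Whitney AUC with DeLong structural-component variance,
the DeLong test for two correlated AUCs, and the categorical net
reclassification improvement (NRI) over the six clinical risk bands
0-10%, 10.1-20%, ..., 40.1-50%, >50%.

Calibration: the Hosmer-Lemeshow chi-square over quantile groups of
predicted risk (quintiles by default, df = groups - 2 = 3, with 11.5 as the
P < 0.01 lack-of-fit cutoff) and the predicted incidence 100 * mean(p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

#: default NRI category bounds; p = 0.10 falls in the lowest category
DEFAULT_NRI_CUTPOINTS = (0.10, 0.20, 0.30, 0.40, 0.50)

#: chi-square lack-of-fit cutoff (P < 0.01 at df = 3)
HL_CUTOFF = 11.5


def _check_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if y.ndim != 1 or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be a flat 0/1 vector")
    if y.min() == y.max():
        raise ValueError("need both events and non-events")
    return y


# ---------------------------------------------------------------------------
# AUC / DeLong


def _delong_components(p: np.ndarray, y: np.ndarray):
    """Structural components: V10 per case, V01 per non-case."""
    cases = p[y == 1]
    ctrls = p[y == 0]
    # psi(case, control) = 1 if case > control, 1/2 if tie, 0 otherwise
    cmp = (cases[:, None] > ctrls[None, :]).astype(float)
    cmp += 0.5 * (cases[:, None] == ctrls[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


def auc(probabilities, outcomes, *, alpha: float = 0.05) -> AucResult:
    """Mann-Whitney AUC with a DeLong-variance normal CI.

    Ties between a case and a non-case count one half. Any monotone score
    works; probabilities are not required to be calibrated.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _check_binary(outcomes)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcomes differ in length")
    v10, v01 = _delong_components(p, y)
    a = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return AucResult(a, se, max(0.0, a - z * se), min(1.0, a + z * se), m, n)


@dataclass(frozen=True)
class DeLongResult:
    auc1: float
    auc2: float
    covariance: np.ndarray  # 2x2 covariance of (auc1, auc2)
    z: float
    p_value: float
    significant: bool  # at the 0.05 criterion


def delong_compare(p1, p2, outcomes, *, alpha: float = 0.05) -> DeLongResult:
    """DeLong test for two correlated AUCs measured on the same subjects."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    y = _check_binary(outcomes)
    if p1.shape != y.shape or p2.shape != y.shape:
        raise ValueError("prediction vectors must match the outcome length")
    v10 = np.empty((2, (y == 1).sum()))
    v01 = np.empty((2, (y == 0).sum()))
    aucs = np.empty(2)
    for k, p in enumerate((p1, p2)):
        v10[k], v01[k] = _delong_components(p, y)
        aucs[k] = v10[k].mean()
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if diff == 0:
        z, p = 0.0, 1.0
    return DeLongResult(float(aucs[0]), float(aucs[1]), cov, float(z), p, p < alpha)


# ---------------------------------------------------------------------------
# NRI


@dataclass(frozen=True)
class NriResult:
    cutpoints: tuple
    event_up: int
    event_down: int
    nonevent_up: int
    nonevent_down: int
    n_events: int
    n_nonevents: int
    nri_events: float
    nri_nonevents: float
    nri_total: float
    z_events: float
    p_events: float
    z_nonevents: float
    p_nonevents: float
    z_total: float
    p_total: float


def risk_category(probabilities, cutpoints=DEFAULT_NRI_CUTPOINTS) -> np.ndarray:
    """0-based category index; bounds are half-open (c_low, c_high]."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    cuts = np.asarray(cutpoints, dtype=float)
    return (p[:, None] > cuts[None, :]).sum(axis=1)


def _component_stats(up: int, down: int, n: int):
    nri = (up - down) / n
    var = (up + down) / n**2 - (up - down) ** 2 / n**3
    if var <= 0:
        z = 0.0 if up == down else np.inf * np.sign(up - down)
    else:
        z = nri / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if up == down:
        z, p = 0.0, 1.0
    return nri, var, float(z), p


def nri(p_new, p_old, outcomes, cutpoints=DEFAULT_NRI_CUTPOINTS) -> NriResult:
    """Categorical net reclassification improvement of model *new* over *old*.

    Moving an eventual case up a risk category is an improvement; for
    non-cases moving down is. Component NRIs are net moves over the group
    size; the total is their sum, with its SE from the sum of the component
    variances.
    """
    y = _check_binary(outcomes)
    c_new = risk_category(p_new, cutpoints)
    c_old = risk_category(p_old, cutpoints)
    if len(c_new) != len(y) or len(c_old) != len(y):
        raise ValueError("prediction vectors must match the outcome length")
    ev = y == 1
    event_up = int(((c_new > c_old) & ev).sum())
    event_down = int(((c_new < c_old) & ev).sum())
    nonevent_up = int(((c_new > c_old) & ~ev).sum())
    nonevent_down = int(((c_new < c_old) & ~ev).sum())
    n_ev, n_ne = int(ev.sum()), int((~ev).sum())
    nri_e, var_e, z_e, p_e = _component_stats(event_up, event_down, n_ev)
    nri_n, var_n, z_n, p_n = _component_stats(nonevent_down, nonevent_up, n_ne)
    total = nri_e + nri_n
    var_t = var_e + var_n
    if var_t <= 0:
        z_t, p_t = 0.0, 1.0
    else:
        z_t = total / np.sqrt(var_t)
        p_t = float(2 * stats.norm.sf(abs(z_t)))
    return NriResult(
        tuple(cutpoints), event_up, event_down, nonevent_up, nonevent_down,
        n_ev, n_ne, nri_e, nri_n, total, z_e, p_e, z_n, p_n, float(z_t), p_t,
    )


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class HosmerLemeshowResult:
    groups: int
    group_n: tuple
    observed: tuple
    expected: tuple
    statistic: float
    df: int
    p_value: float
    significant_lack_of_fit: bool
    cutoff: float = HL_CUTOFF


def hosmer_lemeshow(
    probabilities,
    outcomes,
    groups: int = 5,
    *,
    cutoff: float = HL_CUTOFF,
    eps: float = 1e-10,
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow chi-square over quantile groups of predicted risk.

    Subjects are ranked by predicted probability (stable sort, so ties keep
    input order) and split into ``groups`` near-equal bins. The statistic is
    sum (O_g - E_g)^2 / (E_g (1 - E_g/n_g)); degenerate bins (E_g = 0 or
    E_g = n_g) have their variance term floored at ``eps``. ``df`` is
    ``groups - 2``; lack of fit is flagged when the statistic exceeds
    ``cutoff`` (11.5, the P < 0.01 point at df = 3).
    """
    p = np.asarray(probabilities, dtype=float)
    y = _check_binary(outcomes)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcomes differ in length")
    if len(p) < groups:
        raise ValueError("fewer subjects than groups")
    order = np.argsort(p, kind="stable")
    stat = 0.0
    ns, obs, exp = [], [], []
    for chunk in np.array_split(order, groups):
        n_g = len(chunk)
        o_g = float(y[chunk].sum())
        e_g = float(p[chunk].sum())
        denom = e_g * (1.0 - e_g / n_g)
        if denom <= 0:
            denom = eps
        stat += (o_g - e_g) ** 2 / denom
        ns.append(n_g)
        obs.append(o_g)
        exp.append(e_g)
    df = groups - 2
    p_value = float(stats.chi2.sf(stat, df))
    return HosmerLemeshowResult(
        groups, tuple(ns), tuple(obs), tuple(exp), float(stat), df, p_value,
        stat > cutoff, cutoff,
    )


def predicted_incidence(probabilities) -> float:
    """Mean predicted risk as a percentage."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("no probabilities supplied")
    return float(100.0 * p.mean())


def observed_incidence(outcomes) -> float:
    """Observed event rate as a percentage."""
    y = np.asarray(outcomes, dtype=float)
    if y.size == 0:
        raise ValueError("no outcomes supplied")
    return float(100.0 * y.mean())
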