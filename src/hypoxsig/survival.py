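"""Kaplan-Meier estimation, the two-group log-rank test, Cox proportional-
hazards fitting and the treatment-interaction test.

Kaplan-Meier and Cox fits are delegated to lifelines (Efron tie
correction, 95% Wald confidence intervals); the log-rank statistic is
computed here so the per-group observed/expected event counts and the
hypergeometric variance are available, and it agrees with lifelines'
``logrank_test`` to numerical precision. Subjects censored at an event
time remain in the risk set for that event (events precede censorings at
ties). Deaths from other causes enter as censored observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

__all__ = [
    "KaplanMeierCurve",
    "LogRankResult",
    "CoxFit",
    "kaplan_meier",
    "logrank_test",
    "fit_cox",
    "test_interaction",
]


def _as_surv_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("no survival records")
    if time.shape != event.shape:
        raise ValueError("time and event have different lengths")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and > 0")
    ev = np.unique(event)
    if not set(ev.tolist()) <= {0, 1, False, True}:
        raise ValueError("event indicators must be 0/1")
    return time, event.astype(int)


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit survival estimate: right-continuous, non-increasing,
    S(0) = 1. ``times`` are the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return float(s) if s.ndim == 0 else s


def kaplan_meier(time, event) -> KaplanMeierCurve:
    time, event = _as_surv_arrays(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_["KM_estimate"]
    event_times = np.unique(time[event == 1])
    surv = sf.reindex(event_times, method="ffill").to_numpy(float)
    return KaplanMeierCurve(times=event_times, survival=surv,
                            n=len(time), n_events=int(event.sum()))


@dataclass(frozen=True)
class LogRankResult:
    """Mantel-Haenszel log-rank comparison of two groups (1 df)."""

    observed: tuple[float, float]   # events in (group 0, group 1)
    expected: tuple[float, float]
    variance: float
    chi_square: float
    df: int
    p_value: float


def logrank_test(time, event, group) -> LogRankResult:
    """Two-sided log-rank test. ``group`` is a binary membership vector;
    at each distinct event time a 2x2 table contributes observed-minus-
    expected events under the hypergeometric null."""
    time, event = _as_surv_arrays(time, event)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    if event.sum() == 0:
        raise ValueError("no events; log-rank test undefined")
    in_g1 = group == levels[1]

    et = np.unique(time[event == 1])
    ts_all = np.sort(time)
    ts_g1 = np.sort(time[in_g1])
    n_at = len(time) - np.searchsorted(ts_all, et, side="left")
    n1_at = int(in_g1.sum()) - np.searchsorted(ts_g1, et, side="left")
    evt_all = np.sort(time[event == 1])
    evt_g1 = np.sort(time[(event == 1) & in_g1])
    d = (np.searchsorted(evt_all, et, side="right")
         - np.searchsorted(evt_all, et, side="left"))
    d1 = (np.searchsorted(evt_g1, et, side="right")
          - np.searchsorted(evt_g1, et, side="left"))

    frac1 = n1_at / n_at
    e1 = d * frac1
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * frac1 * (1.0 - frac1) * (n_at - d) / (n_at - 1.0)
    v = np.where(n_at > 1, v, 0.0)

    o1, e1_tot, var = float(d1.sum()), float(e1.sum()), float(v.sum())
    total = float(d.sum())
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = (o1 - e1_tot) ** 2 / var
    p = float(stats.chi2.sf(chi2, 1)) if var > 0 else 1.0
    return LogRankResult(
        observed=(total - o1, o1),
        expected=(total - e1_tot, e1_tot),
        variance=var, chi_square=float(chi2), df=1, p_value=p,
    )


@dataclass(frozen=True)
class CoxFit:
    """A fitted proportional-hazards model. ``summary`` is indexed by
    covariate with columns coef, se, hr, hr_lower, hr_upper, z, p
    (hazard ratios with 95% Wald intervals)."""

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool
    n: int
    n_events: int


def fit_cox(time, event, covariates: pd.DataFrame) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron ties) over all covariates
    entered simultaneously. A constant covariate or a non-converging /
    monotone likelihood is an error."""
    time, event = _as_surv_arrays(time, event)
    covariates = pd.DataFrame(covariates).astype(float)
    if covariates.shape[0] != len(time):
        raise ValueError("covariate rows do not match survival records")
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise ValueError(f"constant covariate {col!r}")
    n_events = int(event.sum())
    if n_events < covariates.shape[1] + 1:
        raise ValueError(
            f"{n_events} event(s) cannot support {covariates.shape[1]} covariate(s)"
        )
    df = covariates.copy()
    df["_time"], df["_event"] = time, event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "z": s["z"],
            "p": s["p"],
        }
    )
    return CoxFit(summary=summary,
                  log_likelihood=float(cph.log_likelihood_),
                  converged=True, n=len(time), n_events=n_events)


INTERACTION_TERM = "score_high_x_treatment"


def test_interaction(time, event, score_high, treatment,
                     adjusters: pd.DataFrame | None = None) -> CoxFit:
    """Test whether a treatment modifies the prognostic effect of the
    signature-high group: fits score_high + treatment + their product
    (+ adjusters); the interaction row is ``score_high_x_treatment``."""
    score_high = np.asarray(score_high).astype(int)
    treatment = np.asarray(treatment).astype(int)
    if len(np.unique(treatment)) < 2:
        raise ValueError("treatment does not vary")
    if len(np.unique(score_high)) < 2:
        raise ValueError("score_high does not vary")
    product = score_high * treatment
    if len(np.unique(product)) < 2:
        raise ValueError("interaction term is constant")
    if np.array_equal(product, score_high) or np.array_equal(product, treatment):
        raise ValueError("interaction term is collinear with a main effect")
    cols = pd.DataFrame({
        "score_high": score_high,
        "treatment": treatment,
        INTERACTION_TERM: product,
    })
    if adjusters is not None:
        adjusters = pd.DataFrame(adjusters).reset_index(drop=True)
        cols = pd.concat([cols, adjusters], axis=1)
    return fit_cox(time, event, cols)
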