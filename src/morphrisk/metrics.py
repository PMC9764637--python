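"""Outcome statistics: Harrell's C, Kaplan–Meier, log-rank, Cox HR, and
horizon-based confusion metrics.

Conventions used throughout the package:

* a *risk score* is oriented so that **higher score = higher risk** (shorter
  expected time to event);
* Harrell's C is the fraction of comparable pairs (orderable under right
  censoring) in which the higher-scored patient fails earlier, with score
  ties counting 1/2 — 0.5 is chance, 1.0 perfect;
* the 2x2 table at a horizon calls a patient *positive* if an event occurred
  at or before the horizon and *negative* if followed event-free to the
  horizon; patients censored earlier are excluded (and counted), which is
  the standard way to keep censoring from diluting sensitivity/specificity.
  An unadjusted mode that counts early-censored patients as negatives is
  available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance

from ._util import as_1d_float


def concordance_index(scores, time, event) -> float:
    """Harrell's concordance index of a risk score against censored outcomes.

    Higher scores are expected to go with shorter event times.
    """
    scores = as_1d_float(scores, "scores")
    time = as_1d_float(time, "time")
    ev = np.asarray(event, dtype=int).ravel()
    if not (len(scores) == len(time) == len(ev)):
        raise ValueError("scores, time and event must be aligned")
    if ev.sum() == 0:
        raise ValueError("no comparable pairs: no events observed")
    try:
        # lifelines orients predictions as survival-like (higher = later)
        return float(_ll_concordance(time, -scores, ev))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs under censoring") from exc


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(time, event) -> KMEstimate:
    """Product-limit survival estimate with Greenwood-based CI band."""
    time = as_1d_float(time, "time")
    if (time < 0).any():
        raise ValueError("negative survival times")
    ev = np.asarray(event, dtype=int).ravel()
    kmf = KaplanMeierFitter()
    kmf.fit(time, ev)
    sf = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    ev_table = kmf.event_table.reindex(sf.index)
    return KMEstimate(
        times=sf.index.to_numpy(float),
        survival=sf.to_numpy(float),
        at_risk=ev_table["at_risk"].to_numpy(float),
        ci_lower=ci.iloc[:, 0].to_numpy(float),
        ci_upper=ci.iloc[:, 1].to_numpy(float),
    )


def logrank_test(groups, time, event) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p-value."""
    g = np.asarray(groups).ravel()
    time = as_1d_float(time, "time")
    ev = np.asarray(event, dtype=int).ravel()
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 nonempty groups, got {len(labels)}")
    mask = g == labels[0]
    res = _ll_logrank(time[mask], time[~mask], ev[mask], ev[~mask])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxHR:
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    stable: bool = True


def cox_hr_binary(stratum, time, event) -> CoxHR:
    """Univariate Cox PH hazard ratio for a binary stratum (Efron ties).

    ``stratum`` is 1 for high risk; HR > 1 means the high stratum fails
    faster. Flagged unstable when a stratum has no events.
    """
    s = np.asarray(stratum, dtype=int).ravel()
    time = as_1d_float(time, "time")
    ev = np.asarray(event, dtype=int).ravel()
    if set(np.unique(s)) - {0, 1}:
        raise ValueError("stratum must be binary 0/1")
    stable = all(ev[s == v].sum() > 0 for v in (0, 1)) and len(np.unique(s)) == 2
    df = pd.DataFrame({"time": time, "event": ev, "high": s})
    cph = CoxPHFitter()
    try:
        cph.fit(
            df, duration_col="time", event_col="event",
            fit_options={"precision": 1e-9},
        )
    except Exception as exc:
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    summary = cph.summary.loc["high"]
    with np.errstate(over="ignore"):  # unstable strata can push a CI bound to inf
        return CoxHR(
            hr=float(np.exp(summary["coef"])),
            ci_lower=float(np.exp(summary["coef lower 95%"])),
            ci_upper=float(np.exp(summary["coef upper 95%"])),
            p_value=float(summary["p"]),
            stable=stable,
        )


@dataclass
class HorizonConfusion:
    horizon: float
    tp: int
    fp: int
    tn: int
    fn: int
    excluded: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.excluded

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "excluded": self.excluded,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def horizon_labels(
    time, event, horizon: float, censored_as_negative: bool = False
) -> np.ndarray:
    """Per-patient horizon label: 1 positive, 0 negative, -1 excluded."""
    time = as_1d_float(time, "time")
    ev = np.asarray(event, dtype=int).ravel()
    pos = (ev == 1) & (time <= horizon)
    neg = ~pos & (time >= horizon)
    lab = np.where(pos, 1, np.where(neg, 0, -1))
    if censored_as_negative:
        lab = np.where(lab == -1, 0, lab)
    return lab


def horizon_confusion(
    scores,
    threshold: float,
    time,
    event,
    horizon: float,
    censored_as_negative: bool = False,
) -> HorizonConfusion:
    """2x2 table of (score >= threshold) against event-by-horizon labels."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    scores = as_1d_float(scores, "scores")
    lab = horizon_labels(time, event, horizon, censored_as_negative)
    if (lab == -1).all():
        raise ValueError("all patients censored before the horizon")
    pred = scores >= threshold
    return HorizonConfusion(
        horizon=float(horizon),
        tp=int(np.sum(pred & (lab == 1))),
        fp=int(np.sum(pred & (lab == 0))),
        tn=int(np.sum(~pred & (lab == 0))),
        fn=int(np.sum(~pred & (lab == 1))),
        excluded=int(np.sum(lab == -1)),
    )
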