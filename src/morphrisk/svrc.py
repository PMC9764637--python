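"""Censored-data support vector regression (linear kernel) with 0-100 risk
scaling, sensitivity+specificity threshold selection, and PSO tuning.

The model regresses time-to-event (months) on standardized features with an
asymmetric ε-insensitive loss: every patient carries an *over-prediction*
penalty pair (C⁺, ε⁺) and an *under-prediction* pair (C⁻, ε⁻), drawn from
the event set or the censored set according to their event flag,

    minimize  ½‖w‖² + Σᵢ [Cᵢ⁺ max(0, rᵢ − εᵢ⁺) + Cᵢ⁻ max(0, −rᵢ − εᵢ⁻)],
    rᵢ = (w·xᵢ + b) − yᵢ,

so censoring is handled by economics rather than by deletion: predicting a
*later* time than a censored follow-up (over-prediction) is cheap, since the
true event time really is later, while predicting *earlier* than a censored
time is penalised like an ordinary miss. With all patients uncensored and a
single (C, ε) the problem is exactly classical ε-SVR.

The raw output is a survival-time surrogate (higher = later event); risk is
reported on a 0-100 scale by reversing and min-max scaling against the
training prediction range, then dichotomised at the threshold maximising
sensitivity + specificity at the clinical horizon.

Solver: the slack variables are eliminated, leaving a (d+1)-dimensional
convex piecewise-quadratic problem minimised by L-BFGS over a Huber-smoothed
hinge with a decreasing smoothing parameter, followed by an exact
active-set/KKT polish (the support-vector structure pins the solution); the
polish is accepted only when it verifiably lowers the true objective and
satisfies the box conditions on the kink multipliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold

from ._util import as_1d_float, check_nonnegative, check_positive, derive_seed, round_half_up
from .metrics import concordance_index, horizon_confusion, horizon_labels
from .pso import pso_minimize


class OptimizationError(RuntimeError):
    """Raised when the SVRc problem cannot be solved."""


@dataclass(frozen=True)
class SVRcHyperparams:
    """Asymmetric penalty weights and margins for event vs censored patients."""

    C_event_over: float = 1.0
    C_event_under: float = 1.0
    C_cens_over: float = 0.1
    C_cens_under: float = 1.0
    eps_event_over: float = 2.0
    eps_event_under: float = 2.0
    eps_cens_over: float = 6.0
    eps_cens_under: float = 2.0

    def __post_init__(self) -> None:
        for name in ("C_event_over", "C_event_under", "C_cens_over", "C_cens_under"):
            check_positive(name, getattr(self, name))
        for name in ("eps_event_over", "eps_event_under", "eps_cens_over", "eps_cens_under"):
            check_nonnegative(name, getattr(self, name))

    def per_patient(self, delta: np.ndarray):
        """(C_over, C_under, eps_over, eps_under) arrays by event flag."""
        delta = np.asarray(delta, dtype=bool)
        pick = lambda ev, ce: np.where(delta, ev, ce)
        return (
            pick(self.C_event_over, self.C_cens_over),
            pick(self.C_event_under, self.C_cens_under),
            pick(self.eps_event_over, self.eps_cens_over),
            pick(self.eps_event_under, self.eps_cens_under),
        )


# ---------------------------------------------------------------------------
# Reduced-primal solver
# ---------------------------------------------------------------------------


def _huber_hinge(t: np.ndarray, mu: float) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed max(0, t): value and derivative."""
    val = np.where(t <= 0, 0.0, np.where(t < mu, t * t / (2 * mu), t - mu / 2))
    grad = np.clip(t / mu, 0.0, 1.0)
    return val, grad


def _true_objective(theta, X, y, Co, Cu, eo, eu) -> float:
    w, b = theta[:-1], theta[-1]
    r = X @ w + b - y
    return 0.5 * w @ w + float(
        np.sum(Co * np.maximum(0.0, r - eo) + Cu * np.maximum(0.0, -r - eu))
    )


def _smoothed_minimize(theta0, X, y, Co, Cu, eo, eu, mu: float, maxiter: int):
    def fg(theta):
        w, b = theta[:-1], theta[-1]
        r = X @ w + b - y
        v_o, g_o = _huber_hinge(r - eo, mu)
        v_u, g_u = _huber_hinge(-r - eu, mu)
        g_r = Co * g_o - Cu * g_u
        f = 0.5 * w @ w + np.sum(Co * v_o + Cu * v_u)
        grad = np.empty_like(theta)
        grad[:-1] = w + X.T @ g_r
        grad[-1] = g_r.sum()
        return f, grad

    res = minimize(
        fg, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x


def _active_set_polish(theta, X, y, Co, Cu, eo, eu, tol: float):
    """Exact KKT solve given the support-vector classification at ``theta``.

    Returns a polished theta or None when the classification is infeasible.
    """
    w, b = theta[:-1], theta[-1]
    r = X @ w + b - y
    at_up = np.abs(r - eo) <= tol
    at_lo = np.abs(r + eu) <= tol
    up = (r > eo) & ~at_up
    lo = (r < -eu) & ~at_lo
    kink = at_up | at_lo

    c_vec = Co[up] @ X[up] - Cu[lo] @ X[lo]
    kappa = float(Co[up].sum() - Cu[lo].sum())
    idx = np.flatnonzero(kink)
    m = len(idx)
    if m == 0:
        if abs(kappa) > 1e-9 * (1 + np.abs(Co).max()):
            return None
        w_new = -c_vec
        return np.concatenate([w_new, [b]])

    Xf = X[idx]
    # kink residual target and multiplier box per kink point
    k_target = np.where(at_up[idx], eo[idx], -eu[idx])
    s_lo = np.where(at_lo[idx], -Cu[idx], 0.0)
    s_hi = np.where(at_up[idx], Co[idx], 0.0)

    G = Xf @ Xf.T
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = -G
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    rhs = np.concatenate([y[idx] + k_target + Xf @ c_vec, [-kappa]])
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    s, b_new = sol[:m], sol[m]
    box_tol = 1e-8 * (1.0 + max(np.abs(Co).max(), np.abs(Cu).max()))
    if np.any(s < s_lo - box_tol) or np.any(s > s_hi + box_tol):
        return None
    w_new = -(c_vec + s @ Xf)
    return np.concatenate([w_new, [b_new]])


def solve_svrc(
    X: np.ndarray,
    y: np.ndarray,
    Co: np.ndarray,
    Cu: np.ndarray,
    eo: np.ndarray,
    eu: np.ndarray,
    mode: str = "exact",
) -> tuple[np.ndarray, float, dict]:
    """Minimise the reduced SVRc primal; returns (w, b, info)."""
    n, d = X.shape
    scale = float(max(1.0, np.std(y)))
    # ridge warm start
    A = X.T @ X + np.eye(d)
    w0 = np.linalg.solve(A, X.T @ (y - y.mean()))
    theta = np.concatenate([w0, [y.mean()]])

    mus = [1e-2 * scale] if mode == "fast" else [1e-1 * scale, 1e-3 * scale, 1e-6 * scale]
    maxiter = 200 if mode == "fast" else 500
    for mu in mus:
        theta = _smoothed_minimize(theta, X, y, Co, Cu, eo, eu, mu, maxiter)
    info = {"mode": mode, "polished": False}
    if mode == "exact":
        f_smooth = _true_objective(theta, X, y, Co, Cu, eo, eu)
        for tol in (1e-5 * scale, 1e-3 * scale):
            cand = _active_set_polish(theta, X, y, Co, Cu, eo, eu, tol)
            if cand is not None and _true_objective(
                cand, X, y, Co, Cu, eo, eu
            ) <= f_smooth + 1e-9 * (1 + abs(f_smooth)):
                theta = cand
                info["polished"] = True
                break
    info["objective"] = _true_objective(theta, X, y, Co, Cu, eo, eu)
    if not np.isfinite(info["objective"]):
        raise OptimizationError("SVRc solve diverged (non-finite objective)")
    return theta[:-1], float(theta[-1]), info


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------


@dataclass
class SVRcModel:
    feature_names: list[str]
    weights: np.ndarray  # on standardized-feature scale
    bias: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    train_min: float
    train_max: float
    hyperparams: SVRcHyperparams
    threshold_raw: Optional[float] = None
    threshold_reported: Optional[int] = None
    solver_info: dict = field(default_factory=dict)

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"feature-name mismatch; missing {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return (X - self.feature_mean) / self.feature_sd

    def predict_raw(self, X) -> np.ndarray:
        """Survival-time surrogate (higher = later predicted event)."""
        return self._matrix(X) @ self.weights + self.bias

    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "train_min": self.train_min,
            "train_max": self.train_max,
            "hyperparams": asdict(self.hyperparams),
            "threshold_raw": self.threshold_raw,
            "threshold_reported": self.threshold_reported,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SVRcModel":
        d = json.loads(text)
        return cls(
            feature_names=list(d["feature_names"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_sd=np.asarray(d["feature_sd"], dtype=float),
            train_min=float(d["train_min"]),
            train_max=float(d["train_max"]),
            hyperparams=SVRcHyperparams(**d["hyperparams"]),
            threshold_raw=d.get("threshold_raw"),
            threshold_reported=d.get("threshold_reported"),
        )


@dataclass
class RiskScore:
    score: np.ndarray  # 0-100, higher = higher risk
    stratum: Optional[np.ndarray] = None  # "low"/"high" once a threshold exists


def fit_svrc(
    X,
    y,
    delta,
    hp: Optional[SVRcHyperparams] = None,
    feature_names: Optional[Sequence[str]] = None,
    mode: str = "exact",
    log_time: bool = False,
) -> SVRcModel:
    """Fit the censored SVR on raw (unstandardized) features.

    Standardization parameters are estimated here and stored on the model so
    prediction uses the training-set scaling. With ``log_time`` the target
    is log1p(months); the risk score is a min-max rescaling of the raw
    output, so its meaning is unchanged, but the ε margins then live on the
    log scale.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = as_1d_float(y, "y")
    if log_time:
        if (y < 0).any():
            raise ValueError("log_time requires non-negative times")
        y = np.log1p(y)
    delta = np.asarray(delta, dtype=int).ravel()
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if len(y) < 2:
        raise ValueError("need at least 2 patients")
    if delta.sum() < 1:
        raise ValueError("need at least 1 observed event")
    hp = hp or SVRcHyperparams()
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    Co, Cu, eo, eu = hp.per_patient(delta)
    w, b, info = solve_svrc(Xs, y, Co, Cu, eo, eu, mode=mode)
    raw = Xs @ w + b
    lo, hi = float(raw.min()), float(raw.max())
    if not hi > lo:
        raise OptimizationError("degenerate fit: constant predictions on training data")
    return SVRcModel(
        feature_names=list(feature_names),
        weights=w,
        bias=b,
        feature_mean=mean,
        feature_sd=sd,
        train_min=lo,
        train_max=hi,
        hyperparams=hp,
        solver_info=info,
    )


def raw_to_score(model: SVRcModel, raw: np.ndarray) -> np.ndarray:
    """Map the survival-time surrogate onto the 0-100 risk scale (reversed:
    the training-range maximum maps to risk 0, the minimum to 100)."""
    span = model.train_max - model.train_min
    return np.clip(100.0 * (model.train_max - raw) / span, 0.0, 100.0)


def predict_risk(model: SVRcModel, X) -> RiskScore:
    score = raw_to_score(model, model.predict_raw(X))
    stratum = None
    if model.threshold_reported is not None:
        stratum = np.where(score >= model.threshold_reported, "high", "low")
    return RiskScore(score=score, stratum=stratum)


def select_threshold(
    scores, time, event, horizon: float, censored_as_negative: bool = False
) -> tuple[float, int]:
    """Scan observed scores for the cut maximising sensitivity + specificity
    at the horizon; ties break toward the lowest threshold. Returns the raw
    threshold and its half-up integer reporting value."""
    scores = as_1d_float(scores, "scores")
    lab = horizon_labels(time, event, horizon, censored_as_negative)
    if not ((lab == 1).any() and (lab == 0).any()):
        raise ValueError("need at least one positive and one negative at the horizon")
    best: tuple[float, float] | None = None
    for t in np.unique(scores):
        c = horizon_confusion(scores, t, time, event, horizon, censored_as_negative)
        j = c.sensitivity + c.specificity
        if best is None or j > best[1] + 1e-12:
            best = (float(t), j)
    thr = best[0]
    return thr, round_half_up(thr)


# ---------------------------------------------------------------------------
# Cross-validation + PSO tuning
# ---------------------------------------------------------------------------


def cv_concordance(
    X, y, delta, hp: SVRcHyperparams, cv_folds: int = 5, seed: int = 0,
    mode: str = "fast",
) -> float:
    """Mean out-of-fold Harrell C of the risk score (event-stratified folds)."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = as_1d_float(y, "y")
    delta = np.asarray(delta, dtype=int).ravel()
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=derive_seed(seed, 5))
    scores, failures = [], []
    for tr, te in skf.split(X, delta):
        try:
            m = fit_svrc(X[tr], y[tr], delta[tr], hp, mode=mode)
            risk = -m.predict_raw(X[te])
            scores.append(concordance_index(risk, y[te], delta[te]))
        except (ValueError, OptimizationError) as exc:
            failures.append(str(exc))
    if not scores:
        raise OptimizationError(
            "all cross-validation folds failed: " + "; ".join(failures[:3])
        )
    return float(np.mean(scores))


DEFAULT_PSO_BOUNDS = {
    "log10_C_event_over": (-3.0, 3.0),
    "log10_C_event_under": (-3.0, 3.0),
    "log10_C_cens_over": (-3.0, 3.0),
    "log10_C_cens_under": (-3.0, 3.0),
    "eps_event_over": (0.0, 24.0),
    "eps_event_under": (0.0, 24.0),
    "eps_cens_over": (0.0, 24.0),
    "eps_cens_under": (0.0, 24.0),
}


def _decode_particle(v: np.ndarray) -> SVRcHyperparams:
    C = 10.0 ** v[:4]
    # soft constraint: censored over-prediction never costs more than an
    # event over-prediction (censored "late" predictions may be correct)
    C_cens_over = min(C[2], C[0])
    return SVRcHyperparams(
        C_event_over=C[0],
        C_event_under=C[1],
        C_cens_over=C_cens_over,
        C_cens_under=C[3],
        eps_event_over=v[4],
        eps_event_under=v[5],
        eps_cens_over=v[6],
        eps_cens_under=v[7],
    )


def pso_optimize(
    X,
    y,
    delta,
    bounds: Optional[dict] = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_particles: int = 20,
    n_iter: int = 50,
    return_result: bool = False,
):
    """Tune SVRc hyperparameters by PSO on mean cross-validated C-index."""
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    bounds = {**DEFAULT_PSO_BOUNDS, **(bounds or {})}
    keys = list(DEFAULT_PSO_BOUNDS)
    barr = np.array([bounds[k] for k in keys], dtype=float)

    def objective(v: np.ndarray) -> float:
        try:
            return -cv_concordance(X, y, delta, _decode_particle(v), cv_folds, seed)
        except OptimizationError:
            return np.inf

    res = pso_minimize(
        objective, barr, n_particles=n_particles, n_iter=n_iter,
        seed=derive_seed(seed, 11),
    )
    if not np.isfinite(res.fun):
        raise OptimizationError("every candidate hyperparameter setting failed")
    hp = _decode_particle(res.x)
    return (hp, res) if return_result else hp
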