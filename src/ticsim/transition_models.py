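"""Transition models: ordered probit for next-wave TICS27, probit for death.

The cognition model is a latent-index ordered probit.  With design row x,
coefficients beta and strictly increasing cutpoints kappa_0 < ... < kappa_{K-2},

    P(S = j | x) = Phi(kappa_j - x'beta) - Phi(kappa_{j-1} - x'beta),

with kappa_{-1} = -inf and kappa_{K-1} = +inf.  There is no free intercept
(it is absorbed by the cutpoints).  Two-year mortality is a probit
P(death | x) = Phi(c + x'gamma) with an explicit intercept c.

Covariates follow the published FEM TICS27 / mortality specification:
two- and four-year lagged scores, demographics (race/ethnicity and
education dummies with non-Hispanic white / high school as reference),
piecewise-linear age splines (knots 65, 75 for cognition; 65, 75, 85 for
mortality), chronic-disease indicators, behavioural covariates, a
verified-ADOD/MCI-ever flag, the deviation of the interview gap from two
years (delta_age), and a lagged log-BMI spline with a knot at BMI 30.

Estimation is unweighted maximum likelihood.  Cutpoint monotonicity is
enforced by optimizing the first cutpoint plus log-increments; standard
errors come from the inverse observed information in the natural
(beta, kappa) parametrization.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from . import cognition_states as cs
from .errors import DomainError, EstimationError

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "DEFAULT_SPEC",
    "OrderedProbitParams",
    "ProbitParams",
    "FitResult",
    "age_spline_basis",
    "bmi_spline_basis",
    "build_design_matrix",
    "build_design_row",
    "build_estimation_frame",
    "op_category_probabilities",
    "op_loglik",
    "probit_loglik",
    "fit_ordered_probit",
    "fit_probit",
    "fit_tics_model",
    "fit_mortality_model",
    "average_marginal_effects",
    "REFERENCE_TICS_COEFFICIENTS",
    "REFERENCE_MORTALITY_COEFFICIENTS",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _norm_pdf(z):
    with np.errstate(over="ignore"):
        return np.exp(-0.5 * np.square(z)) / _SQRT_2PI


# ---------------------------------------------------------------------------
# Design specification
# ---------------------------------------------------------------------------

TICS_COLUMNS = (
    "lag_tics",
    "lag4_tics",
    "nh_black",
    "hispanic",
    "lt_hs",
    "some_college",
    "male",
    "age_spline_lt65",
    "age_spline_65_75",
    "age_spline_75p",
    "heart_ever",
    "stroke_ever",
    "cancer_ever",
    "hypertension_ever",
    "diabetes_ever",
    "lung_ever",
    "heart_attack_2yr",
    "working",
    "widowed",
    "smoke_ever",
    "verified_ever",
    "delta_age",
    "lag_log_bmi_lt30",
    "lag_log_bmi_gt30",
)

MORTALITY_COLUMNS = (
    "nh_black",
    "hispanic",
    "lt_hs",
    "some_college",
    "male",
    "age_spline_lt65",
    "age_spline_65_75",
    "age_spline_75_85",
    "age_spline_85p",
    "heart_ever",
    "stroke_ever",
    "cancer_ever",
    "hypertension_ever",
    "diabetes_ever",
    "lung_ever",
    "heart_attack_2yr",
    "widowed",
    "iadl_1",
    "iadl_2p",
    "adl_1",
    "adl_2",
    "adl_3p",
    "smoke_current",
    "heart50",
    "stroke50",
    "cancer50",
    "hypertension50",
    "diabetes50",
    "lung50",
    "smoke_ever50",
    "smoke_current50",
    "chf_ever",
)


@dataclass(frozen=True)
class DesignSpec:
    """Covariate lists and spline knots for the two transition models."""

    tics_columns: tuple[str, ...] = TICS_COLUMNS
    mortality_columns: tuple[str, ...] = MORTALITY_COLUMNS
    tics_age_knots: tuple[float, ...] = (65.0, 75.0)
    mortality_age_knots: tuple[float, ...] = (65.0, 75.0, 85.0)
    bmi_knot: float = 30.0

    def __post_init__(self):
        for knots in (self.tics_age_knots, self.mortality_age_knots):
            if np.any(np.diff(knots) <= 0):
                raise DomainError(f"age spline knots must be strictly increasing: {knots}")
        for cols in (self.tics_columns, self.mortality_columns):
            if len(set(cols)) != len(cols):
                raise DomainError("design columns must be unique")

    def columns(self, model: str) -> tuple[str, ...]:
        if model == "tics":
            return self.tics_columns
        if model == "mortality":
            return self.mortality_columns
        raise DomainError(f"unknown model {model!r}; expected 'tics' or 'mortality'")


DEFAULT_SPEC = DesignSpec()


# ---------------------------------------------------------------------------
# Published FEM coefficient estimates (used as synthetic-truth seeds)
# ---------------------------------------------------------------------------

#: FEM TICS27 transition model latent-index coefficients (US 51+ biennial panel).
REFERENCE_TICS_COEFFICIENTS: dict[str, float] = {
    "lag_tics": 0.0915,
    "lag4_tics": 0.0955,
    "nh_black": -0.2343,
    "hispanic": -0.1502,
    "lt_hs": -0.1361,
    "some_college": 0.1967,
    "male": -0.0884,
    "age_spline_lt65": -0.0009,
    "age_spline_65_75": -0.0173,
    "age_spline_75p": -0.0353,
    "heart_ever": -0.0126,
    "stroke_ever": -0.1288,
    "cancer_ever": 0.0008,
    "hypertension_ever": -0.0355,
    "diabetes_ever": -0.0693,
    "lung_ever": -0.0430,
    "heart_attack_2yr": -0.0750,
    "working": 0.0943,
    "widowed": -0.0298,
    "smoke_ever": -0.0426,
    "verified_ever": -0.7105,
    "delta_age": -0.1374,
    "lag_log_bmi_lt30": 0.1314,
    "lag_log_bmi_gt30": -0.0090,
}

#: FEM two-year mortality probit index coefficients (no intercept printed).
REFERENCE_MORTALITY_COEFFICIENTS: dict[str, float] = {
    "nh_black": 0.0028,
    "hispanic": -0.0094,
    "lt_hs": -0.0002,
    "some_college": -0.0072,
    "male": 0.0177,
    "age_spline_lt65": 0.0025,
    "age_spline_65_75": 0.0029,
    "age_spline_75_85": 0.0040,
    "age_spline_85p": 0.0067,
    "heart_ever": 0.0131,
    "stroke_ever": 0.0110,
    "cancer_ever": 0.0334,
    "hypertension_ever": 0.0097,
    "diabetes_ever": 0.0155,
    "lung_ever": 0.0294,
    "heart_attack_2yr": 0.0049,
    "widowed": 0.0055,
    "iadl_1": 0.0162,
    "iadl_2p": 0.0483,
    "adl_1": 0.0222,
    "adl_2": 0.0342,
    "adl_3p": 0.0603,
    "smoke_current": 0.0187,
    "heart50": 0.0051,
    "stroke50": -0.0107,
    "cancer50": -0.0083,
    "hypertension50": 0.0027,
    "diabetes50": 0.0142,
    "lung50": -0.0278,
    "smoke_ever50": 0.0061,
    "smoke_current50": 0.0174,
    "chf_ever": 0.0259,
}


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


def _check_kappa(kappa: np.ndarray) -> None:
    if kappa.ndim != 1 or len(kappa) < 1 or np.any(np.diff(kappa) <= 0):
        raise DomainError("cutpoints must be a strictly increasing 1-D vector")


@dataclass
class OrderedProbitParams:
    """Named latent-index coefficients plus strictly increasing cutpoints."""

    beta: np.ndarray
    names: tuple[str, ...]
    kappa: np.ndarray
    levels: np.ndarray | None = None  # score values the categories map to

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)
        self.kappa = np.asarray(self.kappa, float)
        self.names = tuple(self.names)
        _check_kappa(self.kappa)
        if len(self.beta) != len(self.names):
            raise DomainError("beta and names must have equal length")
        if self.levels is None:
            self.levels = np.arange(len(self.kappa) + 1)
        else:
            self.levels = np.asarray(self.levels, int)
            if len(self.levels) != len(self.kappa) + 1:
                raise DomainError("levels must have one entry per category")

    @property
    def n_categories(self) -> int:
        return len(self.kappa) + 1

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "ordered_probit",
                "beta": dict(zip(self.names, self.beta.tolist())),
                "kappa": self.kappa.tolist(),
                "levels": self.levels.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "OrderedProbitParams":
        d = json.loads(text)
        return cls(
            beta=np.array(list(d["beta"].values()), float),
            names=tuple(d["beta"].keys()),
            kappa=np.array(d["kappa"], float),
            levels=np.array(d["levels"], int) if d.get("levels") else None,
        )


@dataclass
class ProbitParams:
    """Named probit index coefficients with an explicit intercept."""

    gamma: np.ndarray
    names: tuple[str, ...]
    intercept: float = 0.0

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, float)
        self.names = tuple(self.names)
        if len(self.gamma) != len(self.names):
            raise DomainError("gamma and names must have equal length")

    def coef(self, name: str) -> float:
        return float(self.gamma[self.names.index(name)])

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "probit",
                "intercept": self.intercept,
                "gamma": dict(zip(self.names, self.gamma.tolist())),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProbitParams":
        d = json.loads(text)
        return cls(
            gamma=np.array(list(d["gamma"].values()), float),
            names=tuple(d["gamma"].keys()),
            intercept=float(d["intercept"]),
        )


@dataclass
class FitResult:
    """Maximum-likelihood fit: parameters, SEs, log-likelihood, diagnostics."""

    params: OrderedProbitParams | ProbitParams
    standard_errors: pd.Series
    log_likelihood: float
    converged: bool
    n_obs: int
    extras: dict = field(default_factory=dict)

    def se(self, name: str) -> float:
        return float(self.standard_errors[name])

    def to_frame(self) -> pd.DataFrame:
        """(name, estimate, std_err) table, cutpoints/intercept included."""
        if isinstance(self.params, OrderedProbitParams):
            names = list(self.params.names) + [
                f"kappa_{j}" for j in range(len(self.params.kappa))
            ]
            est = np.concatenate([self.params.beta, self.params.kappa])
        else:
            names = ["intercept"] + list(self.params.names)
            est = np.concatenate([[self.params.intercept], self.params.gamma])
        se = [self.standard_errors.get(n, np.nan) for n in names]
        return pd.DataFrame({"name": names, "estimate": est, "std_err": se})


# ---------------------------------------------------------------------------
# Spline bases and design assembly
# ---------------------------------------------------------------------------


def age_spline_basis(age, knots: Sequence[float]) -> np.ndarray:
    """Piecewise-linear age basis: (min(a,k1), clamped segments, max(a-k_last,0)).

    Returns shape ``(..., len(knots)+1)``; each column's slope coefficient is
    the marginal age effect inside that segment.
    """
    a = np.asarray(age, float)
    k = np.asarray(knots, float)
    if k.ndim != 1 or len(k) < 1 or np.any(np.diff(k) <= 0):
        raise DomainError(f"knots must be strictly increasing, got {knots}")
    cols = [np.minimum(a, k[0])]
    for i in range(len(k) - 1):
        cols.append(np.clip(a - k[i], 0.0, k[i + 1] - k[i]))
    cols.append(np.maximum(a - k[-1], 0.0))
    return np.stack(cols, axis=-1)


def bmi_spline_basis(log_bmi, knot: float = 30.0) -> np.ndarray:
    """Two-piece log-BMI basis with a knot at BMI ``knot``: (min, excess)."""
    lb = np.asarray(log_bmi, float)
    lk = math.log(knot)
    return np.stack([np.minimum(lb, lk), np.maximum(lb - lk, 0.0)], axis=-1)


_RACE_DUMMIES = {"nh_black": "nh_black", "hispanic": "hispanic"}
_EDU_DUMMIES = {"lt_hs": "lt_hs", "some_college": "some_college"}


def _column(frame, name, n):
    """Fetch a design input column from a DataFrame or mapping of arrays."""
    if isinstance(frame, pd.DataFrame):
        if name in frame.columns:
            return frame[name].to_numpy(float)
    else:
        if name in frame:
            return np.broadcast_to(np.asarray(frame[name], float), (n,)).astype(float)
    # derived encodings
    if name in _RACE_DUMMIES and _has(frame, "race_ethnicity"):
        return (np.asarray(_raw(frame, "race_ethnicity")) == name).astype(float)
    if name in _EDU_DUMMIES and _has(frame, "education"):
        return (np.asarray(_raw(frame, "education")) == name).astype(float)
    if name in ("adl_1", "adl_2", "adl_3p") and _has(frame, "adl_count"):
        c = np.asarray(_raw(frame, "adl_count"), float)
        return {"adl_1": c == 1, "adl_2": c == 2, "adl_3p": c >= 3}[name].astype(float)
    if name in ("iadl_1", "iadl_2p") and _has(frame, "iadl_count"):
        c = np.asarray(_raw(frame, "iadl_count"), float)
        return {"iadl_1": c == 1, "iadl_2p": c >= 2}[name].astype(float)
    raise EstimationError(f"missing covariate column {name!r}")


def _has(frame, name):
    return name in (frame.columns if isinstance(frame, pd.DataFrame) else frame)


def _raw(frame, name):
    return frame[name] if not isinstance(frame, pd.DataFrame) else frame[name].to_numpy()


def build_design_matrix(frame, model: str, spec: DesignSpec = DEFAULT_SPEC):
    """Assemble the (n, p) design matrix for ``model`` from predictor-wave data.

    ``frame`` is a DataFrame or mapping of equal-length arrays holding the
    predictor-wave fields (``lag_tics``, ``age``, flags, ``lag_log_bmi``,
    ...).  Race/education categoricals and ADL/IADL counts are expanded to
    dummies when dummy columns are not supplied directly.

    Returns ``(X, names)``.
    """
    cols = spec.columns(model)
    if isinstance(frame, pd.DataFrame):
        n = len(frame)
    else:
        n = max(np.size(v) for v in frame.values())
    knots = spec.tics_age_knots if model == "tics" else spec.mortality_age_knots
    age = _column(frame, "age", n)
    age_basis = age_spline_basis(age, knots)
    age_names = [c for c in cols if c.startswith("age_spline")]
    if len(age_names) != age_basis.shape[-1]:
        raise DomainError("age spline columns inconsistent with knots")
    parts = {nm: age_basis[..., i] for i, nm in enumerate(age_names)}
    if model == "tics":
        bmi = bmi_spline_basis(_column(frame, "lag_log_bmi", n), spec.bmi_knot)
        parts["lag_log_bmi_lt30"] = bmi[..., 0]
        parts["lag_log_bmi_gt30"] = bmi[..., 1]
    X = np.empty((n, len(cols)), float)
    for i, c in enumerate(cols):
        X[:, i] = parts[c] if c in parts else _column(frame, c, n)
    if not np.all(np.isfinite(X)):
        bad = [cols[i] for i in np.unique(np.where(~np.isfinite(X))[1])]
        raise EstimationError(f"non-finite design values in columns {bad}")
    return X, list(cols)


def build_design_row(person_state: Mapping, model: str, spec: DesignSpec = DEFAULT_SPEC) -> pd.Series:
    """Single-row named design vector for one person-wave state."""
    frame = {k: np.atleast_1d(v) for k, v in dict(person_state).items()}
    X, names = build_design_matrix(frame, model, spec)
    return pd.Series(X[0], index=names)


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

_PROB_FLOOR = 1e-300


def op_category_probabilities(params: OrderedProbitParams, x) -> np.ndarray:
    """Category probabilities P(S = level_j | x) for one row or a matrix."""
    _check_kappa(params.kappa)
    x = np.asarray(x, float)
    one_row = x.ndim == 1
    eta = np.atleast_1d(x @ params.beta)
    cum = ndtr(params.kappa[None, :] - eta[:, None])
    probs = np.diff(
        np.concatenate(
            [np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))], axis=1
        ),
        axis=1,
    )
    probs = np.clip(probs, 0.0, 1.0)
    return probs[0] if one_row else probs


def _level_index(params: OrderedProbitParams, y) -> np.ndarray:
    y = np.asarray(y)
    idx = np.searchsorted(params.levels, y)
    valid = (idx < len(params.levels)) & (params.levels[np.minimum(idx, len(params.levels) - 1)] == y)
    if not np.all(valid):
        raise DomainError("outcome contains score levels not covered by the model")
    return idx


def op_loglik(params: OrderedProbitParams, X, y) -> float:
    """Ordered-probit log-likelihood of observed score levels ``y``."""
    X = np.asarray(X, float)
    if X.size == 0:
        return 0.0
    idx = _level_index(params, y)
    probs = op_category_probabilities(params, X)
    p = probs[np.arange(len(idx)), idx]
    return float(np.sum(np.log(np.clip(p, _PROB_FLOOR, None))))


def probit_loglik(params: ProbitParams, X, y) -> float:
    """Probit log-likelihood of binary outcomes ``y``."""
    X = np.asarray(X, float)
    if X.size == 0:
        return 0.0
    y = np.asarray(y, float)
    eta = params.intercept + X @ params.gamma
    p = np.where(y > 0.5, ndtr(eta), ndtr(-eta))
    return float(np.sum(np.log(np.clip(p, _PROB_FLOOR, None))))


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

#: converged when max |score| / n_obs falls below this
_GRAD_TOL_PER_OBS = 1e-5


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    # QR with column pivoting via diag of R from numpy's (unpivoted) QR is a
    # good-enough collinearity screen for reporting purposes
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.max() > 0 else 0.0
    bad = [names[i] for i in np.where(d <= tol)[0]]
    if bad:
        raise EstimationError(f"design matrix is rank deficient; collinear columns: {bad}")


def _op_nll_grad_transformed(theta, X, yidx, K):
    p = X.shape[1]
    beta = theta[:p]
    a = theta[p]
    incr = np.exp(theta[p + 1 :])
    kappa = a + np.concatenate([[0.0], np.cumsum(incr)])
    nll, g_beta, g_kappa = _op_nll_grad_natural(beta, kappa, X, yidx, K)
    g_a = g_kappa.sum()
    # d kappa_j / d theta_m = incr_{m} for j >= m (m = 1..K-2)
    rc = np.cumsum(g_kappa[::-1])[::-1]
    g_incr = rc[1:] * incr
    return nll, np.concatenate([g_beta, [g_a], g_incr])


def _op_nll_grad_natural(beta, kappa, X, yidx, K):
    """Negative log-lik and its gradient w.r.t. (beta, kappa)."""
    eta = X @ beta
    hi = np.where(yidx == K - 1, np.inf, kappa[np.minimum(yidx, K - 2)] - eta)
    lo = np.where(yidx == 0, -np.inf, kappa[np.maximum(yidx - 1, 0)] - eta)
    pu = ndtr(hi)
    pl = ndtr(lo)
    pr = np.clip(pu - pl, _PROB_FLOOR, None)
    nll = -np.sum(np.log(pr))
    du = _norm_pdf(hi)
    dl = _norm_pdf(lo)
    inv = 1.0 / pr
    g_eta = (du - dl) * inv  # d nll / d eta
    g_beta = X.T @ g_eta
    w_hi = du * inv
    w_lo = dl * inv
    mask_hi = yidx <= K - 2
    mask_lo = yidx >= 1
    g_kappa = -(
        np.bincount(yidx[mask_hi], weights=w_hi[mask_hi], minlength=K - 1)
        - np.bincount(yidx[mask_lo] - 1, weights=w_lo[mask_lo], minlength=K - 1)
    )
    return nll, g_beta, g_kappa


def _fd_hessian(grad_fn, x0, rel_step=1e-5):
    n = len(x0)
    H = np.empty((n, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(x0[i]))
        xp = x0.copy()
        xp[i] += h
        xm = x0.copy()
        xm[i] -= h
        H[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2 * h)
    return 0.5 * (H + H.T)


def _se_from_hessian(grad_fn, x0, names):
    H = _fd_hessian(grad_fn, x0)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        se = np.sqrt(diag)
        ok = True
    except np.linalg.LinAlgError:
        logger.warning("observed information not invertible; standard errors set to NaN")
        se = np.full(len(x0), np.nan)
        ok = False
    return pd.Series(se, index=names), ok


def fit_ordered_probit(
    X,
    y,
    names: Sequence[str] | None = None,
    compute_se: bool = True,
    maxiter: int = 2000,
) -> FitResult:
    """Unweighted MLE of the ordered probit on integer score outcomes.

    Score levels absent from ``y`` are dropped from the category set (the
    fitted model then cannot emit them); a warning is logged when the
    outcome looks like a 0–27 score with missing levels.  Cutpoint
    monotonicity is enforced through a log-increment transform; reported
    standard errors come from the finite-difference observed information
    in the natural (beta, kappa) space.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise EstimationError("X must be (n, p) with one outcome per row")
    if len(y) == 0:
        raise EstimationError("no observations")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    _check_full_rank(X, names)

    levels, yidx = np.unique(y.astype(int), return_inverse=True)
    K = len(levels)
    if K < 2:
        raise EstimationError("outcome is constant; ordered probit undefined (separation)")
    if levels.min() >= 0 and levels.max() <= cs.MAX_SCORE and K < cs.MAX_SCORE + 1:
        logger.warning(
            "%d of 28 score levels unobserved; merging them out of the category set",
            cs.MAX_SCORE + 1 - K,
        )

    counts = np.bincount(yidx, minlength=K)
    cum = np.cumsum(counts)[:-1] / len(y)
    kappa0 = ndtri(np.clip(cum, 1e-6, 1 - 1e-6))
    kappa0 = np.maximum.accumulate(kappa0 + 1e-8 * np.arange(K - 1))
    p = X.shape[1]
    theta0 = np.concatenate([np.zeros(p), [kappa0[0]], np.log(np.maximum(np.diff(kappa0), 1e-6))])

    res = minimize(
        _op_nll_grad_transformed,
        theta0,
        args=(X, yidx, K),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 4 * maxiter, "ftol": 1e-13, "gtol": 1e-9},
    )
    beta = res.x[:p]
    kappa = res.x[p] + np.concatenate([[0.0], np.cumsum(np.exp(res.x[p + 1 :]))])

    def nat_grad(v):
        _, gb, gk = _op_nll_grad_natural(v[:p], v[p:], X, yidx, K)
        return np.concatenate([gb, gk])

    # Newton polish in the natural space to tighten the optimum
    v = np.concatenate([beta, kappa])
    nll = res.fun
    for _ in range(5):
        g = nat_grad(v)
        if np.max(np.abs(g)) / len(y) < _GRAD_TOL_PER_OBS / 10:
            break
        H = _fd_hessian(nat_grad, v)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        v_new = v - step
        if np.any(np.diff(v_new[p:]) <= 0):
            break
        nll_new, _, _ = _op_nll_grad_natural(v_new[:p], v_new[p:], X, yidx, K)
        if not np.isfinite(nll_new) or nll_new > nll + 1e-9:
            break
        v, nll = v_new, nll_new
    beta, kappa = v[:p], v[p:]

    grad_norm = float(np.max(np.abs(nat_grad(v))))
    converged = bool(res.success or grad_norm / len(y) < _GRAD_TOL_PER_OBS)
    params = OrderedProbitParams(beta=beta, names=names, kappa=kappa, levels=levels)
    se_names = names + [f"kappa_{j}" for j in range(K - 1)]
    if compute_se:
        se, ok = _se_from_hessian(nat_grad, v, se_names)
        converged = converged and ok
    else:
        se = pd.Series(np.full(len(v), np.nan), index=se_names)
    return FitResult(
        params=params,
        standard_errors=se,
        log_likelihood=-nll,
        converged=converged,
        n_obs=len(y),
        extras={"grad_norm": grad_norm, "n_categories": K},
    )


def _probit_nll_grad(theta, X, y):
    c = theta[0]
    gamma = theta[1:]
    eta = c + X @ gamma
    q = np.where(y > 0.5, 1.0, -1.0)
    z = q * eta
    p = np.clip(ndtr(z), _PROB_FLOOR, None)
    nll = -np.sum(np.log(p))
    lam = q * _norm_pdf(z) / p  # d loglik / d eta
    g = -np.concatenate([[lam.sum()], X.T @ lam])
    return nll, g


def fit_probit(
    X,
    y,
    names: Sequence[str] | None = None,
    compute_se: bool = True,
    maxiter: int = 1000,
) -> FitResult:
    """Unweighted MLE of the binary probit with a free intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y):
        raise EstimationError("X must be (n, p) with one outcome per row")
    if len(y) == 0:
        raise EstimationError("no observations")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise EstimationError("probit outcome must be binary 0/1")
    if y.min() == y.max():
        raise EstimationError("outcome is constant (complete separation)")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    _check_full_rank(np.column_stack([np.ones(len(y)), X]), ["intercept"] + names)

    theta0 = np.concatenate([[ndtri(np.clip(y.mean(), 1e-6, 1 - 1e-6))], np.zeros(X.shape[1])])
    res = minimize(
        _probit_nll_grad,
        theta0,
        args=(X, y),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
    )

    def nat_grad(v):
        return _probit_nll_grad(v, X, y)[1]

    v = res.x
    nll = res.fun
    for _ in range(5):
        g = nat_grad(v)
        if np.max(np.abs(g)) / len(y) < _GRAD_TOL_PER_OBS / 10:
            break
        H = _fd_hessian(nat_grad, v)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        nll_new = _probit_nll_grad(v - step, X, y)[0]
        if not np.isfinite(nll_new) or nll_new > nll + 1e-9:
            break
        v, nll = v - step, nll_new

    grad_norm = float(np.max(np.abs(nat_grad(v))))
    converged = bool(res.success or grad_norm / len(y) < _GRAD_TOL_PER_OBS)
    params = ProbitParams(gamma=v[1:], names=names, intercept=float(v[0]))
    se_names = ["intercept"] + names
    if compute_se:
        se, ok = _se_from_hessian(nat_grad, v, se_names)
        converged = converged and ok
    else:
        se = pd.Series(np.full(len(v), np.nan), index=se_names)
    return FitResult(
        params=params,
        standard_errors=se,
        log_likelihood=-nll,
        converged=converged,
        n_obs=len(y),
        extras={"grad_norm": grad_norm},
    )


# ---------------------------------------------------------------------------
# Average marginal effects
# ---------------------------------------------------------------------------


def _is_binary(col: np.ndarray) -> bool:
    return np.all(np.isin(col, (0.0, 1.0)))


def average_marginal_effects(fit: FitResult, X, names: Sequence[str] | None = None) -> pd.Series:
    """Sample-average marginal effects of each covariate.

    Probit: effect on the event probability.  Ordered probit: effect on the
    expected score E[S | x] = sum_j level_j P(j | x).  Binary covariates use
    the discrete 0→1 difference averaged over rows; continuous covariates
    use the analytic derivative averaged over rows.
    """
    if not fit.converged:
        raise EstimationError("marginal effects require a converged fit")
    X = np.asarray(X, float)
    params = fit.params
    names = list(names) if names is not None else list(params.names)
    out = {}
    if isinstance(params, ProbitParams):
        eta = params.intercept + X @ params.gamma
        phi_bar = _norm_pdf(eta)
        for k, nm in enumerate(names):
            if _is_binary(X[:, k]):
                e1 = eta + (1.0 - X[:, k]) * params.gamma[k]
                e0 = eta - X[:, k] * params.gamma[k]
                out[nm] = float(np.mean(ndtr(e1) - ndtr(e0)))
            else:
                out[nm] = float(np.mean(phi_bar) * params.gamma[k])
    else:
        levels = params.levels.astype(float)
        eta = X @ params.beta

        def mean_expected(e):
            cum = ndtr(params.kappa[None, :] - e[:, None])
            probs = np.diff(
                np.concatenate([np.zeros((len(e), 1)), cum, np.ones((len(e), 1))], axis=1),
                axis=1,
            )
            return probs @ levels

        # dE/deta = sum_j level_j * (pdf(kappa_{j-1}-eta) - pdf(kappa_j-eta))
        pdfs = _norm_pdf(params.kappa[None, :] - eta[:, None])
        padded = np.concatenate([np.zeros((len(eta), 1)), pdfs, np.zeros((len(eta), 1))], axis=1)
        dE_deta = (padded[:, :-1] - padded[:, 1:]) @ levels
        for k, nm in enumerate(names):
            if _is_binary(X[:, k]):
                e1 = eta + (1.0 - X[:, k]) * params.beta[k]
                e0 = eta - X[:, k] * params.beta[k]
                out[nm] = float(np.mean(mean_expected(e1) - mean_expected(e0)))
            else:
                out[nm] = float(np.mean(dE_deta) * params.beta[k])
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Estimation frames from a long panel
# ---------------------------------------------------------------------------

_LAGGED_FLAGS = (
    "heart_ever",
    "stroke_ever",
    "cancer_ever",
    "hypertension_ever",
    "diabetes_ever",
    "lung_ever",
    "chf_ever",
    "heart_attack_2yr",
    "working",
    "widowed",
    "smoke_ever",
    "smoke_current",
    "adl_count",
    "iadl_count",
)

_STATIC_COLS = (
    "male",
    "race_ethnicity",
    "education",
    "heart50",
    "stroke50",
    "cancer50",
    "hypertension50",
    "diabetes50",
    "lung50",
    "smoke_ever50",
    "smoke_current50",
)


def build_estimation_frame(
    panel: pd.DataFrame, model: str, spec: DesignSpec = DEFAULT_SPEC
):
    """Extract (predictor frame, outcome vector) transition rows from a panel.

    Cognition rows require the outcome score and both lagged scores observed
    at three consecutive waves with the person alive at the outcome wave.
    Mortality rows require a live interview at the previous wave; the
    outcome is death (``alive == 0``) at the current wave.  Because entry
    into the panel conditions on being alive at baseline, transitions into
    the two entry waves are left-truncated and carry no mortality
    information; mortality outcomes therefore start at the first
    post-baseline wave.  All covariates are taken at the predictor
    (previous) wave; the verified-ever flag uses statuses whose confirming
    observation lies at or before that wave.
    """
    if model not in ("tics", "mortality"):
        raise DomainError(f"unknown model {model!r}")
    df = cs.add_status_columns(panel)
    grp = df.groupby("person_id", sort=False)

    lag1_ok = (df["wave"] - grp["wave"].shift(1)).to_numpy() == 1
    lag2_ok = lag1_ok & ((df["wave"] - grp["wave"].shift(2)).to_numpy() == 2)

    frame = pd.DataFrame(index=df.index)
    for c in _STATIC_COLS:
        frame[c] = df[c].to_numpy()
    for c in _LAGGED_FLAGS:
        frame[c] = grp[c].shift(1).to_numpy()
    frame["age"] = grp["age"].shift(1).to_numpy()
    frame["weight"] = df["weight"].to_numpy()
    frame["person_id"] = df["person_id"].to_numpy()
    frame["wave"] = df["wave"].to_numpy()

    if model == "tics":
        frame["lag_tics"] = grp["tics27"].shift(1).to_numpy()
        frame["lag4_tics"] = grp["tics27"].shift(2).to_numpy()
        frame["lag_log_bmi"] = grp["log_bmi"].shift(1).to_numpy()
        frame["verified_ever"] = (grp["verified_status"].shift(1).to_numpy() > 0).astype(float)
        frame["delta_age"] = df["interview_gap_years"].to_numpy(float) - 2.0
        y = df["tics27"].to_numpy(float)
        keep = (
            lag2_ok
            & (df["alive"].to_numpy() == 1)
            & ~np.isnan(y)
            & ~np.isnan(frame["lag_tics"].to_numpy(float))
            & ~np.isnan(frame["lag4_tics"].to_numpy(float))
        )
        return frame.loc[keep].reset_index(drop=True), y[keep].astype(int)

    prev_alive = grp["alive"].shift(1).to_numpy()
    y = (df["alive"].to_numpy() == 0).astype(float)
    waves = np.sort(df["wave"].unique())
    post_entry = df["wave"].to_numpy() > waves[1] if len(waves) > 1 else np.ones(len(df), bool)
    keep = lag1_ok & (prev_alive == 1) & post_entry
    return frame.loc[keep].reset_index(drop=True), y[keep]


def fit_tics_model(panel: pd.DataFrame, spec: DesignSpec = DEFAULT_SPEC, **kwargs) -> FitResult:
    """Build cognition transition rows from a panel and fit the ordered probit."""
    frame, y = build_estimation_frame(panel, "tics", spec)
    X, names = build_design_matrix(frame, "tics", spec)
    return fit_ordered_probit(X, y, names=names, **kwargs)


def fit_mortality_model(panel: pd.DataFrame, spec: DesignSpec = DEFAULT_SPEC, **kwargs) -> FitResult:
    """Build mortality transition rows from a panel and fit the probit."""
    frame, y = build_estimation_frame(panel, "mortality", spec)
    X, names = build_design_matrix(frame, "mortality", spec)
    return fit_probit(X, y, names=names, **kwargs)
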