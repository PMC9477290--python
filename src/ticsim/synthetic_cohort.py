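"""Survey-like synthetic cohorts for the cognition microsimulation.

Emulates the structure of a biennial ageing survey: a baseline cohort aged
53+ with demographics, chronic-condition histories, behavioural covariates
and mean-one log-normal sample weights; a pre-baseline wave so the
four-year lag score exists at the first transition; forward evolution of
waves by the *true* transition models (probit death, ordered-probit score);
and missing-not-at-random masking of the cognitive score for proxy
respondents, where lower true scores are more likely to be masked.

The forward process reuses the simulation engine's step function, so the
data-generating dynamics and the projection dynamics are one code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from . import microsim_engine as engine
from .errors import ConfigurationError
from .transition_models import (
    DEFAULT_SPEC,
    REFERENCE_MORTALITY_COEFFICIENTS,
    REFERENCE_TICS_COEFFICIENTS,
    DesignSpec,
    OrderedProbitParams,
    ProbitParams,
    build_design_matrix,
)

__all__ = [
    "ProxyMissingnessParams",
    "CohortConfig",
    "default_covariate_prevalences",
    "generate_baseline",
    "generate_panel",
    "apply_proxy_missingness",
    "default_true_models",
    "single_transition_dataset",
    "mortality_transition_dataset",
    "read_panel",
    "write_panel",
]

#: baseline score distribution: discretized normal centered near the
#: published 2006 mean (15.57), dispersion declining in education and
#: increasing in age
_BASE_SCORE_CENTER = 15.6
_BASE_SCORE_SD = 4.3
_PREBASE_DRIFT = 0.3  # mean two-year score gain looking backward
_PREBASE_SD = 1.6


def default_covariate_prevalences() -> dict[str, float]:
    """Baseline prevalences emulating a 2006 US 53+ cohort (survey means)."""
    return {
        "male": 0.45,
        "nh_black": 0.091,
        "hispanic": 0.073,
        "lt_hs": 0.181,
        "some_college": 0.472,
        "heart_ever": 0.215,
        "stroke_ever": 0.075,
        "cancer_ever": 0.131,
        "hypertension_ever": 0.517,
        "diabetes_ever": 0.179,
        "lung_ever": 0.083,
        "chf_ever": 0.048,
        "heart_attack_2yr": 0.017,
        "working": 0.429,
        "widowed": 0.177,
        "smoke_ever": 0.571,
        "smoke_current": 0.135,
        "adl_1": 0.07,
        "adl_2": 0.04,
        "adl_3p": 0.04,
        "iadl_1": 0.07,
        "iadl_2p": 0.05,
        "heart50": 0.05,
        "stroke50": 0.01,
        "cancer50": 0.02,
        "hypertension50": 0.10,
        "diabetes50": 0.035,
        "lung50": 0.02,
        "smoke_ever50": 0.50,
        "smoke_current50": 0.25,
    }


@dataclass
class ProxyMissingnessParams:
    """Logit model for proxy-respondent score masking (MNAR by construction).

    P(missing | true score s) = logistic(intercept + slope * s) outside a
    never-missing share of persons.  A negative slope makes low scorers
    more likely to be masked.

    Defaults emulate observed proxy-interview patterns: roughly 4-5% of
    live interviews use a proxy, with impaired-range scorers about 4-5x
    more likely to be masked than normal-range scorers, so that about half
    of proxies come from the impaired bands.
    """

    intercept: float = -0.7
    slope_per_score_point: float = -0.15
    share_never_missing: float = 0.25

    def missing_probability(self, score) -> np.ndarray:
        return expit(self.intercept + self.slope_per_score_point * np.asarray(score, float))

    def validate(self) -> None:
        if not 0.0 <= self.share_never_missing <= 1.0:
            raise ConfigurationError(
                f"share_never_missing must be in [0, 1], got {self.share_never_missing}"
            )
        p = self.missing_probability(np.arange(28))
        if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
            raise ConfigurationError("proxy missingness probabilities outside [0, 1]")


@dataclass
class CohortConfig:
    """Settings for the synthetic cohort generator."""

    n_individuals: int = 1000
    n_waves: int = 6  # baseline + 5 transitions, i.e. a 2006-2016 panel
    seed: int = 0
    age_range: tuple[float, float] = (53.0, 90.0)
    covariate_prevalences: dict[str, float] = field(default_factory=default_covariate_prevalences)
    incidence_rates: dict[str, float] = field(default_factory=engine.default_incidence_rates)
    weight_dispersion: float = 0.5
    proxy_missingness: ProxyMissingnessParams = field(default_factory=ProxyMissingnessParams)
    true_models: Optional[tuple[OrderedProbitParams, ProbitParams]] = None

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be positive")
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be >= 2")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")
        if self.age_range[0] < 51 or self.age_range[1] <= self.age_range[0]:
            raise ConfigurationError(f"invalid age_range {self.age_range} (min must be >= 51)")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"covariate_prevalences[{name!r}] = {p} not in [0, 1]")
        for name, p in self.incidence_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"incidence_rates[{name!r}] = {p} not in [0, 1]")
        if self.weight_dispersion <= 0:
            raise ConfigurationError("weight_dispersion must be positive")
        self.proxy_missingness.validate()


_FLAG_COLS = (
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
    "heart50",
    "stroke50",
    "cancer50",
    "hypertension50",
    "diabetes50",
    "lung50",
    "smoke_ever50",
    "smoke_current50",
)

BASE_CALENDAR_YEAR = 2006


def generate_baseline(config: CohortConfig) -> pd.DataFrame:
    """Generate waves -1 and 0 of a cohort (pre-baseline wave supplies lag-4).

    Baseline TICS27 is a discretized normal on 0-27 centered near 15.6 with
    dispersion declining in education and increasing in age; weights are
    log-normal normalized to mean one.
    """
    config.validate()
    rng = np.random.Generator(np.random.Philox(key=config.seed, counter=[0, 0, 0, 1]))
    n = config.n_individuals
    prev = config.covariate_prevalences

    age = rng.uniform(config.age_range[0], config.age_range[1], n)
    male = (rng.random(n) < prev.get("male", 0.0)).astype(float)
    u = rng.random(n)
    p_black = prev.get("nh_black", 0.0)
    p_hisp = prev.get("hispanic", 0.0)
    race = np.where(u < p_black, "nh_black", np.where(u < p_black + p_hisp, "hispanic", "nh_white"))
    u = rng.random(n)
    p_lt = prev.get("lt_hs", 0.0)
    p_sc = prev.get("some_college", 0.0)
    education = np.where(u < p_lt, "lt_hs", np.where(u < p_lt + p_sc, "some_college", "hs"))

    flags = {c: (rng.random(n) < prev.get(c, 0.0)).astype(float) for c in _FLAG_COLS}
    # by-age-50 histories imply the corresponding ever flag
    for f50, fev in (
        ("heart50", "heart_ever"),
        ("stroke50", "stroke_ever"),
        ("cancer50", "cancer_ever"),
        ("hypertension50", "hypertension_ever"),
        ("diabetes50", "diabetes_ever"),
        ("lung50", "lung_ever"),
        ("smoke_ever50", "smoke_ever"),
    ):
        flags[fev] = np.maximum(flags[fev], flags[f50])
    flags["smoke_current50"] = np.minimum(flags["smoke_current50"], flags["smoke_ever50"])
    flags["smoke_current"] = np.minimum(
        np.maximum(flags["smoke_current"], 0.0), flags["smoke_ever"]
    )

    u = rng.random(n)
    adl = np.zeros(n)
    p1, p2, p3 = prev.get("adl_1", 0.0), prev.get("adl_2", 0.0), prev.get("adl_3p", 0.0)
    adl[u < p1 + p2 + p3] = 1
    adl[u < p2 + p3] = 2
    adl[u < p3] = 3
    u = rng.random(n)
    iadl = np.zeros(n)
    q1, q2 = prev.get("iadl_1", 0.0), prev.get("iadl_2p", 0.0)
    iadl[u < q1 + q2] = 1
    iadl[u < q2] = 2

    log_bmi = rng.normal(math.log(27.5), 0.17, n)
    weight = rng.lognormal(mean=0.0, sigma=config.weight_dispersion, size=n)
    weight = weight / weight.mean()

    sd = np.clip(
        _BASE_SCORE_SD
        + 0.5 * (education == "lt_hs")
        - 0.5 * (education == "some_college")
        + 0.04 * (age - 66.0),
        1.0,
        None,
    )
    score0 = np.clip(np.rint(rng.normal(_BASE_SCORE_CENTER, sd)), 0, 27).astype(int)
    score_prev = np.clip(
        np.rint(score0 + rng.normal(_PREBASE_DRIFT, _PREBASE_SD, n)), 0, 27
    ).astype(int)

    rows = []
    for wave, scores, ages in ((-1, score_prev, age - 2.0), (0, score0, age)):
        rows.append(
            pd.DataFrame(
                {
                    "person_id": np.arange(n),
                    "wave": wave,
                    "calendar_year": BASE_CALENDAR_YEAR + 2 * wave,
                    "age": ages,
                    "male": male,
                    "race_ethnicity": race,
                    "education": education,
                    "tics27": scores.astype(float),
                    "proxy": 0,
                    "alive": 1,
                    "weight": weight,
                    **flags,
                    "log_bmi": log_bmi,
                    "adl_count": adl,
                    "iadl_count": iadl,
                    "interview_gap_years": 2.0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(["person_id", "wave"]).reset_index(drop=True)


def generate_panel(config: CohortConfig, spec: DesignSpec = DEFAULT_SPEC) -> pd.DataFrame:
    """Generate a full multi-wave panel by evolving the baseline forward.

    Requires ``config.true_models``; waves 1..n_waves-1 are produced by the
    engine's step (probit death draw, ordered-probit score draw, exogenous
    covariate updates).  A death is recorded as a final row with
    ``alive=0`` and a missing score; later rows are absent.
    """
    config.validate()
    if config.true_models is None:
        raise ConfigurationError("generate_panel requires config.true_models")
    tics_params, mort_params = config.true_models
    baseline = generate_baseline(config)
    pop = engine.init_population(baseline, spec)

    rows = [baseline]
    for wave in range(1, config.n_waves - 1 + 1):
        pre_alive = pop["alive"].copy()
        rec = engine.step(
            pop,
            tics_params,
            mort_params,
            wave=wave,
            base_seed=config.seed,
            rep=0,
            spec=spec,
            covariate_process="synthetic",
            incidence_rates=config.incidence_rates,
        )
        present = pre_alive  # survivors get a live row, the newly dead a death row
        alive_now = rec["alive"]
        df = pd.DataFrame(
            {
                "person_id": pop["person_id"],
                "wave": wave,
                "calendar_year": BASE_CALENDAR_YEAR + 2 * wave,
                "age": pop["age"],
                "male": pop["male"],
                "race_ethnicity": np.where(
                    pop["nh_black"] > 0, "nh_black", np.where(pop["hispanic"] > 0, "hispanic", "nh_white")
                ),
                "education": np.where(
                    pop["lt_hs"] > 0, "lt_hs", np.where(pop["some_college"] > 0, "some_college", "hs")
                ),
                "tics27": np.where(alive_now, pop["tics_cur"].astype(float), np.nan),
                "proxy": 0,
                "alive": alive_now.astype(int),
                "weight": pop["weight"],
                **{c: pop[c] for c in _FLAG_COLS},
                "log_bmi": pop["log_bmi"],
                "adl_count": pop["adl_count"],
                "iadl_count": pop["iadl_count"],
                "interview_gap_years": rec["gap"],
            }
        )
        rows.append(df[present].reset_index(drop=True))
    panel = pd.concat(rows, ignore_index=True).sort_values(["person_id", "wave"]).reset_index(drop=True)
    return panel


def apply_proxy_missingness(
    panel: pd.DataFrame, params: ProxyMissingnessParams, seed: int
) -> pd.DataFrame:
    """Mask scores for proxy respondents; returns a copy, input untouched.

    Persons outside a never-missing share have each live score masked with
    probability logistic(intercept + slope * true score); masked rows get
    ``proxy = 1`` and a missing score.
    """
    params.validate()
    if panel.loc[panel["alive"] == 1, "tics27"].isna().any():
        raise ConfigurationError(
            "apply_proxy_missingness expects scores observed for all live rows"
        )
    out = panel.copy()
    rng = np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, 2]))
    persons = np.unique(out["person_id"].to_numpy())
    never = persons[rng.random(len(persons)) < params.share_never_missing]
    eligible = ~out["person_id"].isin(never).to_numpy() & (out["alive"].to_numpy() == 1)
    p = params.missing_probability(out["tics27"].to_numpy(float))
    u = rng.random(len(out))
    mask = eligible & (u < p)
    out.loc[mask, "proxy"] = 1
    out.loc[mask, "tics27"] = np.nan
    return out


# ---------------------------------------------------------------------------
# True-model construction (synthetic data-generating process)
# ---------------------------------------------------------------------------


def default_true_models(
    config: CohortConfig,
    spec: DesignSpec = DEFAULT_SPEC,
    target_death_rate: float = 0.07,
) -> tuple[OrderedProbitParams, ProbitParams]:
    """Reference-coefficient transition models calibrated to the cohort.

    The latent-index coefficients are the published FEM estimates.  The
    cognition cutpoints (not printed) are set by quantile matching so the
    one-step score distribution approximately reproduces the baseline
    score distribution (near-stationarity); the mortality intercept (also
    not printed) is chosen so the mean per-wave death probability equals
    ``target_death_rate`` on the baseline cohort.
    """
    calib = replace(config, n_individuals=max(config.n_individuals, 5000), true_models=None)
    baseline = generate_baseline(calib)
    b0 = baseline[baseline["wave"] == 0].reset_index(drop=True)
    bp = baseline[baseline["wave"] == -1].reset_index(drop=True)

    names = list(spec.tics_columns)
    beta = np.array([REFERENCE_TICS_COEFFICIENTS[c] for c in names])
    design = {
        "lag_tics": b0["tics27"].to_numpy(float),
        "lag4_tics": bp["tics27"].to_numpy(float),
        "lag_log_bmi": b0["log_bmi"].to_numpy(float),
        "verified_ever": np.zeros(len(b0)),
        "delta_age": np.zeros(len(b0)),
        "age": b0["age"].to_numpy(float),
        "male": b0["male"].to_numpy(float),
        "race_ethnicity": b0["race_ethnicity"].to_numpy(),
        "education": b0["education"].to_numpy(),
        **{c: b0[c].to_numpy(float) for c in _FLAG_COLS},
        "adl_count": b0["adl_count"].to_numpy(float),
        "iadl_count": b0["iadl_count"].to_numpy(float),
    }
    Xt, _ = build_design_matrix(design, "tics", spec)
    eta = Xt @ beta
    m, s = float(eta.mean()), float(math.sqrt(eta.var() + 1.0))
    scores = b0["tics27"].to_numpy(int)
    counts = np.bincount(scores, minlength=28).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    kappa = m + s * ndtri(np.clip(cum, 1e-5, 1 - 1e-5))
    kappa = np.maximum.accumulate(kappa + 1e-6 * np.arange(27))
    tics_params = OrderedProbitParams(beta=beta, names=names, kappa=kappa)

    mnames = list(spec.mortality_columns)
    gamma = np.array([REFERENCE_MORTALITY_COEFFICIENTS[c] for c in mnames])
    Xm, _ = build_design_matrix(design, "mortality", spec)
    etam = Xm @ gamma

    def mean_rate(c):
        return float(ndtr(etam + c).mean()) - target_death_rate

    intercept = brentq(mean_rate, -30.0, 30.0)
    mort_params = ProbitParams(gamma=gamma, names=mnames, intercept=float(intercept))
    return tics_params, mort_params


# ---------------------------------------------------------------------------
# Single-transition recovery datasets (design rows drawn at generator defaults)
# ---------------------------------------------------------------------------


def single_transition_dataset(n: int, seed: int, spec: DesignSpec = DEFAULT_SPEC):
    """Synthetic single-transition cognition dataset with known truth.

    Covariates at generator defaults: lag scores uniform integers on 0-27,
    binaries Bernoulli at default prevalences, race multinomial
    (0.81 reference / 0.09 / 0.07), verified-ever Bernoulli(0.1), age
    uniform on 53-95 through the (65, 75) spline, interview-gap jitter
    +-0.5y, log BMI normal around log 27.5.  The latent index uses the
    reference coefficients, centered at its sample mean; cutpoints are
    kappa_j = (j - 13.5) / 4; standard-normal noise is thresholded into
    scores 0-27.

    Returns ``(X, names, y, true_params)``.
    """
    rng = np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, 3]))
    prev = default_covariate_prevalences()
    u = rng.random(n)
    frame = {
        "lag_tics": rng.integers(0, 28, n).astype(float),
        "lag4_tics": rng.integers(0, 28, n).astype(float),
        "nh_black": (u < 0.09).astype(float),
        "hispanic": ((u >= 0.09) & (u < 0.16)).astype(float),
        "lt_hs": None,
        "some_college": None,
        "male": (rng.random(n) < prev["male"]).astype(float),
        "age": rng.uniform(53.0, 95.0, n),
        "verified_ever": (rng.random(n) < 0.1).astype(float),
        "delta_age": rng.uniform(-0.5, 0.5, n),
        "lag_log_bmi": rng.normal(math.log(27.5), 0.17, n),
    }
    ue = rng.random(n)
    frame["lt_hs"] = (ue < prev["lt_hs"]).astype(float)
    frame["some_college"] = ((ue >= prev["lt_hs"]) & (ue < prev["lt_hs"] + prev["some_college"])).astype(float)
    for c in (
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
    ):
        frame[c] = (rng.random(n) < prev[c]).astype(float)
    X, names = build_design_matrix(frame, "tics", spec)
    beta = np.array([REFERENCE_TICS_COEFFICIENTS[c] for c in names])
    eta = X @ beta
    offset = eta.mean()
    kappa = (np.arange(27) - 13.5) / 4.0
    z = (eta - offset) + rng.standard_normal(n)
    y = np.searchsorted(kappa, z, side="left")
    # on the uncentered index the equivalent true cutpoints absorb the offset
    true_params = OrderedProbitParams(beta=beta, names=names, kappa=kappa + offset)
    return X, names, y, true_params


def mortality_transition_dataset(
    n: int, seed: int, spec: DesignSpec = DEFAULT_SPEC, target_death_rate: float = 0.1
):
    """Synthetic mortality dataset with known truth (reference coefficients).

    Binaries at generator defaults (CHF-ever Bernoulli(0.1)); ADL/IADL
    multinomial at default category shares; age uniform on 53-95 through
    the (65, 75, 85) spline.  The intercept is chosen so the mean death
    probability equals ``target_death_rate``; deaths are Bernoulli(Phi).

    Returns ``(X, names, y, true_params)``.
    """
    rng = np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, 4]))
    prev = default_covariate_prevalences()
    u = rng.random(n)
    frame: dict[str, np.ndarray] = {
        "nh_black": (u < 0.09).astype(float),
        "hispanic": ((u >= 0.09) & (u < 0.16)).astype(float),
        "age": rng.uniform(53.0, 95.0, n),
    }
    ue = rng.random(n)
    frame["lt_hs"] = (ue < prev["lt_hs"]).astype(float)
    frame["some_college"] = ((ue >= prev["lt_hs"]) & (ue < prev["lt_hs"] + prev["some_college"])).astype(float)
    for c in (
        "male",
        "heart_ever",
        "stroke_ever",
        "cancer_ever",
        "hypertension_ever",
        "diabetes_ever",
        "lung_ever",
        "heart_attack_2yr",
        "widowed",
        "smoke_current",
        "heart50",
        "stroke50",
        "cancer50",
        "hypertension50",
        "diabetes50",
        "lung50",
        "smoke_ever50",
        "smoke_current50",
    ):
        frame[c] = (rng.random(n) < prev[c]).astype(float)
    frame["chf_ever"] = (rng.random(n) < 0.1).astype(float)
    ua = rng.random(n)
    adl = np.zeros(n)
    adl[ua < prev["adl_1"] + prev["adl_2"] + prev["adl_3p"]] = 1
    adl[ua < prev["adl_2"] + prev["adl_3p"]] = 2
    adl[ua < prev["adl_3p"]] = 3
    frame["adl_count"] = adl
    ui = rng.random(n)
    iadl = np.zeros(n)
    iadl[ui < prev["iadl_1"] + prev["iadl_2p"]] = 1
    iadl[ui < prev["iadl_2p"]] = 2
    frame["iadl_count"] = iadl

    X, names = build_design_matrix(frame, "mortality", spec)
    gamma = np.array([REFERENCE_MORTALITY_COEFFICIENTS[c] for c in names])
    eta = X @ gamma

    def mean_rate(c):
        return float(ndtr(eta + c).mean()) - target_death_rate

    intercept = brentq(mean_rate, -30.0, 30.0)
    y = (rng.random(n) < ndtr(eta + intercept)).astype(float)
    true_params = ProbitParams(gamma=gamma, names=names, intercept=float(intercept))
    return X, names, y, true_params


# ---------------------------------------------------------------------------
# Panel CSV round-trip
# ---------------------------------------------------------------------------


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel as CSV; missing scores become empty fields."""
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    """Read a panel CSV written by :func:`write_panel`."""
    df = pd.read_csv(path)
    df["tics27"] = pd.to_numeric(df["tics27"], errors="coerce")
    return df.sort_values(["person_id", "wave"]).reset_index(drop=True)
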