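"""Monte Carlo projection of a cohort in two-year steps.

Each step, in fixed person order: (1) a mortality draw from the probit
using start-of-step covariates — a death freezes the state and records the
cognitive status at death, with death confirming a still-provisional
category; (2) survivors draw the next TICS27 score by inverse CDF over the
ordered-probit category probabilities; (3) the verified status is updated
on the fly by the two-wave confirmation rule; (4) lags shift, age advances
by the drawn interview gap, and exogenous covariates evolve (or stay
frozen).

Randomness is counter-based: every (draw kind, wave, replicate) triple owns
a Philox substream keyed by the base seed, and within a stream person i
consumes draw i.  Appending persons to a cohort therefore never perturbs
the draws of existing persons, and runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import cognition_states as cs
from .errors import ConfigurationError, DomainError, SimulationError
from .transition_models import (
    DEFAULT_SPEC,
    DesignSpec,
    OrderedProbitParams,
    ProbitParams,
    build_design_matrix,
)

__all__ = [
    "SimulationConfig",
    "Population",
    "ReplicateOutcomes",
    "init_population",
    "step",
    "simulate",
    "risk_fraction",
    "RISK_PREDICATES",
    "default_incidence_rates",
]

# draw-kind indices for the Philox counter
_DRAW_MORTALITY = 0
_DRAW_SCORE = 1
_DRAW_GAP = 2
_DRAW_COVARIATES = 3


def _stream(base_seed: int, rep: int, wave: int, kind: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(key=int(base_seed), counter=[0, int(kind), int(wave), int(rep)])
    )


def default_incidence_rates() -> dict[str, float]:
    """Per-wave incidence of the absorbing conditions in the exogenous process."""
    return {
        "heart_ever": 0.025,
        "stroke_ever": 0.012,
        "cancer_ever": 0.018,
        "hypertension_ever": 0.035,
        "diabetes_ever": 0.020,
        "lung_ever": 0.010,
        "chf_ever": 0.012,
        "widowed": 0.020,
        "heart_attack_2yr": 0.017,
    }


@dataclass
class SimulationConfig:
    """Monte Carlo projection settings (defaults: 10-year horizon, 500 reps)."""

    horizon_waves: int = 5
    replicates: int = 500
    base_seed: int = 0
    covariate_process: str = "synthetic"  # or "frozen"
    incidence_rates: dict = field(default_factory=default_incidence_rates)

    def __post_init__(self):
        if self.horizon_waves < 1:
            raise ConfigurationError("horizon_waves must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.covariate_process not in ("synthetic", "frozen"):
            raise ConfigurationError(
                f"unknown covariate_process {self.covariate_process!r}"
            )


#: columns carried in the simulation state
_STATE_COLS = (
    "person_id",
    "weight",
    "alive",
    "age",
    "male",
    "nh_black",
    "hispanic",
    "lt_hs",
    "some_college",
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
    "log_bmi",
    "adl_count",
    "iadl_count",
    "heart50",
    "stroke50",
    "cancer50",
    "hypertension50",
    "diabetes50",
    "lung50",
    "smoke_ever50",
    "smoke_current50",
    "tics_cur",
    "tics_prev",
    "verified",
    "status_at_death",
    "died_wave",
    "baseline_tics",
)


class Population:
    """Column-array simulation state for a cohort, in fixed person_id order."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays
        self.n = len(arrays["person_id"])

    def __getitem__(self, key):
        return self.arrays[key]

    def __setitem__(self, key, value):
        self.arrays[key] = value

    def copy(self) -> "Population":
        return Population({k: v.copy() for k, v in self.arrays.items()})


_ABSORBING_CONDITIONS = (
    "heart_ever",
    "stroke_ever",
    "cancer_ever",
    "hypertension_ever",
    "diabetes_ever",
    "lung_ever",
    "chf_ever",
    "widowed",
)


def init_population(baseline: pd.DataFrame, spec: DesignSpec = DEFAULT_SPEC) -> Population:
    """Build the simulation state from the two earliest waves of a panel.

    The earlier wave supplies the four-year lag score; the later wave is
    the simulation baseline.  Baseline verified status is derived from the
    two observed waves (pair completed by baseline).
    """
    waves = np.sort(baseline["wave"].unique())
    if len(waves) < 2:
        raise SimulationError("baseline panel must contain two waves to supply both lags")
    w_prev, w0 = waves[-2], waves[-1]
    b0 = baseline[baseline["wave"] == w0].sort_values("person_id").reset_index(drop=True)
    bp = baseline[baseline["wave"] == w_prev].sort_values("person_id").reset_index(drop=True)
    if not np.array_equal(b0["person_id"].to_numpy(), bp["person_id"].to_numpy()):
        raise SimulationError("baseline waves must cover the same persons")
    if b0["tics27"].isna().any() or bp["tics27"].isna().any():
        raise SimulationError("baseline scores must be complete (impute before simulating)")

    arr: dict[str, np.ndarray] = {}
    arr["person_id"] = b0["person_id"].to_numpy()
    arr["weight"] = b0["weight"].to_numpy(float)
    arr["alive"] = np.ones(len(b0), bool)
    arr["age"] = b0["age"].to_numpy(float)
    arr["male"] = b0["male"].to_numpy(float)
    race = b0["race_ethnicity"].to_numpy() if "race_ethnicity" in b0 else None
    arr["nh_black"] = (
        (race == "nh_black").astype(float) if race is not None else b0["nh_black"].to_numpy(float)
    )
    arr["hispanic"] = (
        (race == "hispanic").astype(float) if race is not None else b0["hispanic"].to_numpy(float)
    )
    edu = b0["education"].to_numpy() if "education" in b0 else None
    arr["lt_hs"] = (
        (edu == "lt_hs").astype(float) if edu is not None else b0["lt_hs"].to_numpy(float)
    )
    arr["some_college"] = (
        (edu == "some_college").astype(float)
        if edu is not None
        else b0["some_college"].to_numpy(float)
    )
    for c in _STATE_COLS:
        if c in arr or c in (
            "tics_cur",
            "tics_prev",
            "verified",
            "status_at_death",
            "died_wave",
            "baseline_tics",
        ):
            continue
        arr[c] = b0[c].to_numpy(float)
    arr["tics_cur"] = b0["tics27"].to_numpy(float).astype(np.int64)
    arr["tics_prev"] = bp["tics27"].to_numpy(float).astype(np.int64)
    arr["baseline_tics"] = arr["tics_cur"].copy()

    cat0 = cs.classify_scores(arr["tics_cur"])
    catp = cs.classify_scores(arr["tics_prev"])
    dem, mci = int(cs.CognitiveCategory.DEMENTIA), int(cs.CognitiveCategory.MCI)
    verified = np.zeros(len(b0), np.int64)
    verified[(catp == dem) & (cat0 == dem)] = 2
    conf_mci = ((catp == mci) & ((cat0 == mci) | (cat0 == dem))) | (
        (catp == dem) & (cat0 == mci)
    )
    verified[conf_mci & (verified < 1)] = 1
    arr["verified"] = verified
    arr["status_at_death"] = np.full(len(b0), -1, np.int64)
    arr["died_wave"] = np.full(len(b0), -1, np.int64)
    return Population(arr)


def _confirmed_level(cat: np.ndarray) -> np.ndarray:
    """Verified level a terminal event (death) confirms for category ``cat``."""
    return np.where(
        cat == int(cs.CognitiveCategory.DEMENTIA),
        2,
        np.where(cat == int(cs.CognitiveCategory.MCI), 1, 0),
    )


def exogenous_covariate_update(
    pop: Population, substream, rates: dict[str, float], active: np.ndarray
) -> None:
    """Default exogenous covariate evolution (shared by the cohort generator).

    Absorbing conditions arrive at per-wave incidence rates; a fresh
    two-year heart-attack indicator is drawn; current smokers may quit;
    work stops with an age-increasing probability; ADL/IADL limitation
    counts drift upward; log BMI follows a Gaussian random walk (sd 0.02).
    ``substream(j)`` must return an independent generator for field j, so
    each field's draw for person i sits at a fixed stream position and
    adding persons never perturbs existing persons' draws.
    """
    n = pop.n
    for j, cond in enumerate(_ABSORBING_CONDITIONS):
        u = substream(j).random(n)
        rate = rates.get(cond, 0.0)
        pop[cond] = np.where(active & (u < rate), 1.0, pop[cond])
    u = substream(8).random(n)
    pop["heart_attack_2yr"] = np.where(
        active, (u < rates.get("heart_attack_2yr", 0.0)).astype(float), pop["heart_attack_2yr"]
    )
    u = substream(9).random(n)
    quit_smoking = active & (pop["smoke_current"] > 0) & (u < 0.08)
    pop["smoke_current"] = np.where(quit_smoking, 0.0, pop["smoke_current"])
    u = substream(10).random(n)
    p_retire = np.clip(0.02 + 0.005 * (pop["age"] - 53.0), 0.0, 1.0)
    stop_work = active & (pop["working"] > 0) & (u < p_retire)
    pop["working"] = np.where(stop_work, 0.0, pop["working"])
    u = substream(11).random(n)
    pop["adl_count"] = np.where(active & (u < 0.06), np.minimum(pop["adl_count"] + 1, 3), pop["adl_count"])
    u = substream(12).random(n)
    pop["iadl_count"] = np.where(active & (u < 0.06), np.minimum(pop["iadl_count"] + 1, 2), pop["iadl_count"])
    z = substream(13).standard_normal(n)
    pop["log_bmi"] = np.where(active, pop["log_bmi"] + 0.02 * z, pop["log_bmi"])


def step(
    pop: Population,
    tics_params: OrderedProbitParams,
    mort_params: ProbitParams,
    wave: int,
    base_seed: int,
    rep: int = 0,
    spec: DesignSpec = DEFAULT_SPEC,
    covariate_process: str = "synthetic",
    incidence_rates: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Advance the population one two-year wave in place.

    Returns per-person records for the new wave: ``alive``, ``tics``
    (-1 when dead), ``verified`` (frozen at the status at death), and
    ``died_now``.
    """
    n = pop.n
    alive = pop["alive"].copy()

    # (1) mortality, using start-of-step covariates
    try:
        Xm, _ = build_design_matrix(pop.arrays, "mortality", spec)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise SimulationError(f"mortality design failed at wave {wave}: {exc}") from exc
    p_die = ndtr(mort_params.intercept + Xm @ mort_params.gamma)
    u = _stream(base_seed, rep, wave, _DRAW_MORTALITY).random(n)
    died_now = alive & (u < p_die)
    cat_cur = cs.classify_scores(pop["tics_cur"])
    sad = np.maximum(pop["verified"], _confirmed_level(cat_cur))
    pop["status_at_death"] = np.where(died_now, sad, pop["status_at_death"])
    pop["died_wave"] = np.where(died_now, wave, pop["died_wave"])
    pop["verified"] = np.where(died_now, sad, pop["verified"])
    survivors = alive & ~died_now

    # (2) interview gap and next score for survivors
    gap = 2.0 + (_stream(base_seed, rep, wave, _DRAW_GAP).random(n) - 0.5)
    design = dict(pop.arrays)
    design["lag_tics"] = pop["tics_cur"].astype(float)
    design["lag4_tics"] = pop["tics_prev"].astype(float)
    design["lag_log_bmi"] = pop["log_bmi"]
    design["verified_ever"] = (pop["verified"] > 0).astype(float)
    design["delta_age"] = gap - 2.0
    try:
        Xt, _ = build_design_matrix(design, "tics", spec)
    except Exception as exc:  # noqa: BLE001
        raise SimulationError(f"cognition design failed at wave {wave}: {exc}") from exc
    eta = Xt @ tics_params.beta
    cum = ndtr(tics_params.kappa[None, :] - eta[:, None])
    u2 = _stream(base_seed, rep, wave, _DRAW_SCORE).random(n)
    cat_idx = np.sum(u2[:, None] > cum, axis=1)
    new_score = tics_params.levels[cat_idx]

    # (3) on-the-fly verification from the (previous, new) category pair
    new_cat = cs.classify_scores(new_score)
    dem, mci = int(cs.CognitiveCategory.DEMENTIA), int(cs.CognitiveCategory.MCI)
    conf_dem = (cat_cur == dem) & (new_cat == dem)
    conf_mci = ((cat_cur == mci) & ((new_cat == mci) | (new_cat == dem))) | (
        (cat_cur == dem) & (new_cat == mci)
    )
    new_verified = np.maximum(
        pop["verified"], np.where(conf_dem, 2, np.where(conf_mci, 1, 0))
    )

    # (4) shift lags, advance age, update exogenous covariates
    pop["tics_prev"] = np.where(survivors, pop["tics_cur"], pop["tics_prev"])
    pop["tics_cur"] = np.where(survivors, new_score, pop["tics_cur"])
    pop["verified"] = np.where(survivors, new_verified, pop["verified"])
    pop["age"] = np.where(survivors, pop["age"] + gap, pop["age"])
    pop["alive"] = survivors
    if covariate_process == "synthetic":
        exogenous_covariate_update(
            pop,
            lambda j: _stream(base_seed, rep, wave, _DRAW_COVARIATES + j),
            default_incidence_rates() if incidence_rates is None else incidence_rates,
            survivors,
        )
    elif covariate_process != "frozen":
        raise ConfigurationError(f"unknown covariate_process {covariate_process!r}")

    return {
        "alive": survivors.copy(),
        "tics": np.where(survivors, pop["tics_cur"], -1).astype(np.int16),
        "verified": pop["verified"].astype(np.int8).copy(),
        "died_now": died_now.copy(),
        "gap": gap,
    }


@dataclass
class ReplicateOutcomes:
    """Per-(replicate, person, wave) simulated outcomes.

    ``verified`` is frozen at the status at death once a person dies, so
    "dementia or dead with dementia by wave w" is simply ``verified == 2``
    at wave w.  Waves are 1-based post-baseline indices.
    """

    person_id: np.ndarray
    weight: np.ndarray
    baseline_tics: np.ndarray
    baseline_verified: np.ndarray
    alive: np.ndarray  # (R, N, W) bool
    tics: np.ndarray  # (R, N, W) int16, -1 when dead
    verified: np.ndarray  # (R, N, W) int8
    status_at_death: np.ndarray  # (R, N) int8, -1 while alive
    died_wave: np.ndarray  # (R, N) int16, -1 while alive

    @property
    def n_replicates(self) -> int:
        return self.alive.shape[0]

    @property
    def horizon_waves(self) -> int:
        return self.alive.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (replicate, person_id, wave, alive, tics, verified)."""
        R, N, W = self.alive.shape
        rep, per, wav = np.meshgrid(
            np.arange(R), np.arange(N), np.arange(1, W + 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                "replicate": rep.ravel(),
                "person_id": self.person_id[per.ravel()],
                "wave": wav.ravel(),
                "alive": self.alive.ravel().astype(int),
                "tics27": self.tics.ravel(),
                "verified_status": self.verified.ravel(),
            }
        )


def simulate(
    baseline: pd.DataFrame,
    tics_params: OrderedProbitParams,
    mort_params: ProbitParams,
    config: SimulationConfig,
    spec: DesignSpec = DEFAULT_SPEC,
) -> ReplicateOutcomes:
    """Run the Monte Carlo projection from a two-wave baseline panel."""
    pop0 = init_population(baseline, spec)
    R, W, N = config.replicates, config.horizon_waves, pop0.n
    alive = np.empty((R, N, W), bool)
    tics = np.empty((R, N, W), np.int16)
    verified = np.empty((R, N, W), np.int8)
    sad = np.empty((R, N), np.int8)
    dwave = np.empty((R, N), np.int16)
    for r in range(R):
        pop = pop0.copy()
        for w in range(1, W + 1):
            rec = step(
                pop,
                tics_params,
                mort_params,
                wave=w,
                base_seed=config.base_seed,
                rep=r,
                spec=spec,
                covariate_process=config.covariate_process,
                incidence_rates=config.incidence_rates,
            )
            alive[r, :, w - 1] = rec["alive"]
            tics[r, :, w - 1] = rec["tics"]
            verified[r, :, w - 1] = rec["verified"]
        sad[r] = pop["status_at_death"]
        dwave[r] = pop["died_wave"]
    return ReplicateOutcomes(
        person_id=pop0["person_id"],
        weight=pop0["weight"],
        baseline_tics=pop0["baseline_tics"],
        baseline_verified=pop0["verified"],
        alive=alive,
        tics=tics,
        verified=verified,
        status_at_death=sad,
        died_wave=dwave,
    )


RISK_PREDICATES = (
    "dementia_or_dead_with_dementia",
    "dementia_given_alive",
    "mci_or_worse_or_dead_with_mci_or_worse",
    "mci_or_worse_given_alive",
    "significant_decline_2yr",
)


def risk_fraction(outcomes: ReplicateOutcomes, predicate: str, wave: int) -> np.ndarray:
    """Per-person replicate fraction of an outcome at a 1-based wave.

    Conditional predicates divide by the fraction of replicates in which
    the person is alive at that wave (NaN when alive in none).
    """
    if predicate not in RISK_PREDICATES:
        raise DomainError(f"unknown predicate {predicate!r}; choose from {RISK_PREDICATES}")
    if not 1 <= wave <= outcomes.horizon_waves:
        raise DomainError(f"wave must be in [1, {outcomes.horizon_waves}]")
    w = wave - 1
    v = outcomes.verified[:, :, w].astype(int)
    a = outcomes.alive[:, :, w]
    R = outcomes.n_replicates
    if predicate == "dementia_or_dead_with_dementia":
        return (v == 2).sum(axis=0) / R
    if predicate == "mci_or_worse_or_dead_with_mci_or_worse":
        return (v >= 1).sum(axis=0) / R
    if predicate in ("dementia_given_alive", "mci_or_worse_given_alive"):
        lvl = 2 if predicate.startswith("dementia") else 1
        num = (a & (v >= lvl)).sum(axis=0).astype(float)
        den = a.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[den == 0] = np.nan
        return out
    decline = a & (
        outcomes.baseline_tics[None, :] - outcomes.tics[:, :, w] >= cs.SIGNIFICANT_DECLINE_POINTS
    )
    return decline.sum(axis=0) / R
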