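"""Validation framework: k-fold cross-validated simulation, weighted
distribution comparison, 10-year cognitive/mortality transition matrices,
and ROC/AUROC on replicate-fraction risk scores.

The headline design: partition persons into k folds; for each fold fit
both transition models on the other k-1 folds and simulate the held-out
fold from its baseline, so every person is simulated exactly once by a
model that never saw them.  Per-person risks are the fraction of Monte
Carlo replicates in which an outcome occurs; ranking those risks against
the observed outcomes yields ROC curves, overall and by subgroup and
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cognition_states as cs
from . import microsim_engine as engine
from .errors import DomainError, EstimationError
from .imputation import ImputationConfig, impute, pooled_fit
from .microsim_engine import ReplicateOutcomes, SimulationConfig, risk_fraction
from .transition_models import (
    DEFAULT_SPEC,
    DesignSpec,
    FitResult,
    fit_mortality_model,
    fit_tics_model,
)

__all__ = [
    "kfold_split",
    "cross_validated_simulate",
    "weighted_percentiles",
    "DistributionSummary",
    "transition_matrix",
    "roc_auc",
    "ROCResult",
    "full_followup_ids",
    "observed_outcomes",
    "evaluate",
    "ValidationReport",
    "PERCENTILE_PROBS",
]

PERCENTILE_PROBS = (0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99)

TRANSITION_ROWS = ("normal", "mci", "dementia")
TRANSITION_COLS = ("normal", "mci", "dementia", "dead_without_dementia", "dead_with_dementia")


def kfold_split(person_ids, k: int, seed: int) -> pd.Series:
    """Uniform random partition of ids into k folds with sizes differing <= 1."""
    ids = np.asarray(person_ids)
    if len(np.unique(ids)) != len(ids):
        raise DomainError("person_ids must be unique")
    if not 2 <= k <= len(ids):
        raise DomainError(f"k must be in [2, {len(ids)}], got {k}")
    rng = np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, 6]))
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), int)
    folds[perm] = np.arange(len(ids)) % k
    return pd.Series(folds, index=ids, name="fold")


@dataclass
class DistributionSummary:
    """Weighted score percentiles and mean, with an optional baseline diff."""

    percentiles: pd.Series  # indexed by probability
    mean: float
    mean_diff: float | None = None

    def as_row(self) -> dict:
        row = {f"p{int(100 * p)}": v for p, v in self.percentiles.items()}
        row["mean"] = self.mean
        row["mean_diff"] = self.mean_diff
        return row


def weighted_percentiles(
    values, weights, probs: Sequence[float] = PERCENTILE_PROBS
) -> DistributionSummary:
    """Left-continuous inverse of the weighted empirical CDF at ``probs``.

    With uniform weights this reduces to type-1 empirical quantiles;
    integer inputs yield integer outputs.
    """
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if v.size == 0:
        raise DomainError("weighted_percentiles requires at least one value")
    if np.any(w <= 0):
        raise DomainError("weights must be positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w) / w.sum()
    idx = np.searchsorted(cw, np.asarray(probs, float), side="left")
    idx = np.minimum(idx, len(v) - 1)
    pct = pd.Series(v[idx], index=list(probs))
    mean = float(np.average(v, weights=w))
    return DistributionSummary(percentiles=pct, mean=mean)


def transition_matrix(baseline_status, final_outcome, weights) -> pd.DataFrame:
    """Weighted percent-of-total 3x5 cognitive/mortality transition table.

    Rows: baseline verified status (normal / mci / dementia).  Columns add
    the two death states, split by status at death (dead with dementia =
    verified dementia at death; an MCI death counts as dead without
    dementia).  Absorbing-status rules make some cells structurally zero;
    populated structural zeros raise a domain error.
    """
    b = np.asarray(baseline_status, int)
    f = np.asarray(final_outcome, int)
    w = np.asarray(weights, float)
    if not (len(b) == len(f) == len(w)):
        raise DomainError("inputs must have equal length")
    if np.any((b < 0) | (b > 2)) or np.any((f < 0) | (f > 4)):
        raise DomainError("invalid status codes")
    # structural zeros: mci cannot revert to normal; verified dementia can
    # only remain dementia or die with dementia
    if np.any((b == 1) & (f == 0)):
        raise DomainError("inconsistent sequence: baseline MCI with final normal status")
    if np.any((b == 2) & np.isin(f, (0, 1, 3))):
        raise DomainError("inconsistent sequence: baseline dementia with non-dementia final status")
    mat = np.zeros((3, 5))
    np.add.at(mat, (b, f), w)
    mat = 100.0 * mat / w.sum()
    return pd.DataFrame(mat, index=list(TRANSITION_ROWS), columns=list(TRANSITION_COLS))


@dataclass
class ROCResult:
    """ROC curve points and trapezoidal AUROC with case/control counts."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    n_cases: int
    n_controls: int


def roc_auc(risks, outcomes) -> ROCResult:
    """ROC curve by threshold sweep; AUROC = (concordant + 0.5 ties) / pairs."""
    r = np.asarray(risks, float)
    y = np.asarray(outcomes)
    if np.any(np.isnan(r)):
        raise DomainError("risks contain NaN; filter undefined risks first")
    if not np.all(np.isin(y, (0, 1))):
        raise DomainError("outcomes must be binary 0/1")
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise DomainError("AUROC undefined without at least one case and one control")
    order = np.argsort(-r, kind="stable")
    r_s, y_s = r[order], y[order]
    # group tied risk values so the curve steps once per distinct threshold
    boundary = np.r_[np.diff(r_s) != 0, True]
    tp = np.cumsum(y_s)[boundary]
    fp = np.cumsum(1 - y_s)[boundary]
    tpr = np.r_[0.0, tp / n_cases]
    fpr = np.r_[0.0, fp / n_controls]
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auroc=auroc, n_cases=n_cases, n_controls=n_controls)


# ---------------------------------------------------------------------------
# Cross-validated simulation
# ---------------------------------------------------------------------------


def _baseline_waves(panel: pd.DataFrame) -> pd.DataFrame:
    waves = np.sort(panel["wave"].unique())
    return panel[panel["wave"].isin(waves[:2])]


def cross_validated_simulate(
    panel: pd.DataFrame,
    k: int,
    sim_config: SimulationConfig,
    spec: DesignSpec = DEFAULT_SPEC,
    seed: int = 0,
    imputation: ImputationConfig | None = None,
    compute_se: bool = False,
) -> tuple[ReplicateOutcomes, list[tuple[FitResult, FitResult]]]:
    """Five-fold-style held-out simulation: fit on k-1 folds, simulate the rest.

    Returns pooled outcomes (each person simulated exactly once, by models
    that never saw them, persons in sorted person_id order) and the per-fold
    (cognition fit, mortality fit) pairs.  With ``imputation`` set, masked
    scores in the training folds are multiply imputed and the fits pooled;
    the simulated baselines must be fully observed either way.
    """
    ids = np.sort(panel["person_id"].unique())
    folds = kfold_split(ids, k, seed)
    fold_of = panel["person_id"].map(folds)
    results: list[tuple[FitResult, FitResult]] = []
    pieces: list[ReplicateOutcomes] = []
    for f in range(k):
        train = panel[fold_of != f]
        test = panel[fold_of == f]
        try:
            if imputation is not None and train["tics27"].isna().any():
                completed = impute(train, imputation)
                tics_fit = pooled_fit(completed, "tics", spec, compute_se=compute_se)
                mort_fit = pooled_fit(completed, "mortality", spec, compute_se=compute_se)
            else:
                tics_fit = fit_tics_model(train, spec, compute_se=compute_se)
                mort_fit = fit_mortality_model(train, spec, compute_se=compute_se)
        except Exception as exc:
            raise EstimationError(f"estimation failed for fold {f}: {exc}") from exc
        results.append((tics_fit, mort_fit))
        fold_cfg = SimulationConfig(
            horizon_waves=sim_config.horizon_waves,
            replicates=sim_config.replicates,
            base_seed=sim_config.base_seed + f,
            covariate_process=sim_config.covariate_process,
            incidence_rates=sim_config.incidence_rates,
        )
        pieces.append(
            engine.simulate(
                _baseline_waves(test), tics_fit.params, mort_fit.params, fold_cfg, spec
            )
        )
    # pool the held-out pieces back into sorted person order
    all_ids = np.concatenate([p.person_id for p in pieces])
    order = np.argsort(all_ids)

    def cat2(a):
        return np.concatenate(a, axis=1)[:, order]

    pooled = ReplicateOutcomes(
        person_id=all_ids[order],
        weight=np.concatenate([p.weight for p in pieces])[order],
        baseline_tics=np.concatenate([p.baseline_tics for p in pieces])[order],
        baseline_verified=np.concatenate([p.baseline_verified for p in pieces])[order],
        alive=cat2([p.alive for p in pieces]),
        tics=cat2([p.tics for p in pieces]),
        verified=cat2([p.verified for p in pieces]),
        status_at_death=np.concatenate([p.status_at_death for p in pieces], axis=1)[:, order],
        died_wave=np.concatenate([p.died_wave for p in pieces], axis=1)[:, order],
    )
    return pooled, results


# ---------------------------------------------------------------------------
# Observed-truth extraction
# ---------------------------------------------------------------------------


def full_followup_ids(panel: pd.DataFrame, horizon_wave: int) -> np.ndarray:
    """Persons observed at every wave from baseline to the horizon or death."""
    waves = np.sort(panel["wave"].unique())
    w0 = waves[waves >= 0].min()
    keep = []
    for pid, g in panel[panel["wave"] >= w0].groupby("person_id"):
        ws = g["wave"].to_numpy()
        alive = g["alive"].to_numpy()
        dead_wave = ws[alive == 0].min() if np.any(alive == 0) else None
        last_needed = horizon_wave if dead_wave is None else min(horizon_wave, dead_wave)
        expected = np.arange(w0, last_needed + 1)
        if np.all(np.isin(expected, ws)):
            keep.append(pid)
    return np.asarray(keep)


def observed_outcomes(panel: pd.DataFrame, horizon_wave: int) -> pd.DataFrame:
    """Per-person observed state at a horizon wave.

    Returns a frame indexed by person_id with ``alive``, ``verified``
    (information-set status, frozen at the death-confirmed status for the
    dead), ``score`` (NaN if dead or missing), baseline ``verified0``,
    ``score0``, ``weight``, ``age0`` and demographic columns.
    """
    df = cs.add_status_columns(panel)
    waves = np.sort(df["wave"].unique())
    w0 = waves[waves >= 0].min()
    if horizon_wave not in waves:
        raise DomainError(f"horizon wave {horizon_wave} not present in panel")
    base = df[df["wave"] == w0].set_index("person_id")
    out = pd.DataFrame(index=base.index)
    out["weight"] = base["weight"]
    out["score0"] = base["tics27"]
    out["verified0"] = base["verified_status"]
    out["age0"] = base["age"]
    for c in ("race_ethnicity", "education", "male"):
        out[c] = base[c]
    for c in ("heart_ever", "stroke_ever", "hypertension_ever", "diabetes_ever"):
        if c in base:
            out[f"{c}0"] = base[c]

    upto = df[(df["wave"] > w0) & (df["wave"] <= horizon_wave)]
    died = upto[upto["alive"] == 0].groupby("person_id")[["verified_status"]].max()
    at_h = df[df["wave"] == horizon_wave].set_index("person_id")
    alive_h = at_h["alive"].reindex(out.index)
    # last known verified status up to the horizon (absorbing)
    vmax = (
        df[(df["wave"] >= w0) & (df["wave"] <= horizon_wave)]
        .groupby("person_id")["verified_status"]
        .max()
        .reindex(out.index)
    )
    out["alive"] = (alive_h == 1).astype(float).where(alive_h.notna())
    out.loc[died.index, "alive"] = 0.0
    # persons never observed again and never recorded dead: unknown
    out["verified"] = vmax
    out["score"] = at_h["tics27"].reindex(out.index).where(out["alive"] == 1)
    return out


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def _sim_final_outcome(outcomes: ReplicateOutcomes, wave: int):
    """(R, N) final-status codes 0..4 at a 1-based wave."""
    w = wave - 1
    v = outcomes.verified[:, :, w].astype(int)
    a = outcomes.alive[:, :, w]
    return np.where(a, v, np.where(v == 2, 4, 3))


def _truth_final_outcome(obs: pd.DataFrame) -> np.ndarray:
    v = obs["verified"].to_numpy(int)
    a = obs["alive"].to_numpy(float)
    return np.where(a == 1, v, np.where(v == 2, 4, 3))


@dataclass
class ValidationReport:
    """Percentile tables, transition matrices and AUROC results."""

    distribution: pd.DataFrame
    transition_truth: pd.DataFrame
    transition_sim: pd.DataFrame
    auroc: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.distribution.to_csv(d / "distribution.csv")
        self.transition_truth.to_csv(d / "transition_matrix_observed.csv")
        self.transition_sim.to_csv(d / "transition_matrix_simulated.csv")
        self.auroc.to_csv(d / "auroc.csv", index=False)
        (d / "manifest.json").write_text(json.dumps(self.meta, indent=2, default=str))


def default_subgroups(obs: pd.DataFrame) -> dict[str, np.ndarray]:
    """Subgroup masks over the baseline frame (mirrors the report layout)."""
    g = {
        "full_sample": np.ones(len(obs), bool),
        "verified_mci_baseline": (obs["verified0"].to_numpy(int) == 1),
        "age_65_plus": (obs["age0"].to_numpy(float) >= 65),
        "nh_white": (obs["race_ethnicity"].to_numpy() == "nh_white"),
        "nh_black": (obs["race_ethnicity"].to_numpy() == "nh_black"),
        "hispanic": (obs["race_ethnicity"].to_numpy() == "hispanic"),
        "lt_hs": (obs["education"].to_numpy() == "lt_hs"),
        "hs": (obs["education"].to_numpy() == "hs"),
        "some_college": (obs["education"].to_numpy() == "some_college"),
    }
    for c in ("heart_ever0", "stroke_ever0", "hypertension_ever0", "diabetes_ever0"):
        if c in obs:
            g[c.replace("0", "")] = obs[c].to_numpy(float) == 1
    return g


def evaluate(
    panel_truth: pd.DataFrame,
    outcomes: ReplicateOutcomes,
    horizons: Sequence[int] | None = None,
    predicates: Sequence[str] = (
        "dementia_or_dead_with_dementia",
        "dementia_given_alive",
        "mci_or_worse_or_dead_with_mci_or_worse",
        "mci_or_worse_given_alive",
    ),
    subgroups: Mapping[str, np.ndarray] | None = None,
    age_restriction: float = 65.0,
) -> ValidationReport:
    """Assemble the population- and individual-level validation report.

    Individual-level AUROCs use the full-follow-up subsample (observed at
    every wave until the horizon or death).  Conditional predicates are
    evaluated among persons observed alive at the horizon, with the
    conditional replicate-fraction risk.  The significant-decline AUROC
    (wave 1, baseline-MCI persons) is included when that predicate's
    inputs exist.
    """
    W = outcomes.horizon_waves
    horizons = list(horizons) if horizons is not None else list(range(1, W + 1))
    if max(horizons) > W:
        raise DomainError(f"horizon {max(horizons)} beyond simulated waves ({W})")
    final_wave = max(horizons)

    ids = outcomes.person_id
    ffu = full_followup_ids(panel_truth, final_wave)
    obs_final = observed_outcomes(panel_truth, final_wave).reindex(ids)

    # --- population-level: weighted score distributions -------------------
    dist_rows = {}
    w_truth = obs_final["weight"].to_numpy(float)
    base_scores = obs_final["score0"].to_numpy(float)
    bmask = ~np.isnan(base_scores)
    for label, amin in (("all", None), (f"age_{int(age_restriction)}_plus", age_restriction)):
        sel = bmask.copy()
        if amin is not None:
            sel &= obs_final["age0"].to_numpy(float) >= amin
        d0 = weighted_percentiles(base_scores[sel], w_truth[sel])
        truth_alive = (obs_final["alive"].to_numpy(float) == 1) & sel
        t_scores = obs_final["score"].to_numpy(float)
        tmask = truth_alive & ~np.isnan(t_scores)
        d_truth = weighted_percentiles(t_scores[tmask], w_truth[tmask])
        d_truth.mean_diff = d_truth.mean - d0.mean
        sim_scores = outcomes.tics[:, :, final_wave - 1].astype(float)
        sim_alive = outcomes.alive[:, :, final_wave - 1]
        smask = sim_alive & sel[None, :]
        d_sim = weighted_percentiles(
            sim_scores[smask], np.broadcast_to(w_truth, sim_scores.shape)[smask]
        )
        d_sim.mean_diff = d_sim.mean - d0.mean
        dist_rows[(label, "baseline")] = d0.as_row()
        dist_rows[(label, "final_observed")] = d_truth.as_row()
        dist_rows[(label, "final_simulated")] = d_sim.as_row()
    distribution = pd.DataFrame(dist_rows).T

    # --- population-level: transition matrices (full-follow-up sample) ----
    in_ffu = np.isin(ids, ffu)
    obs_ffu = obs_final[in_ffu & obs_final["alive"].notna().to_numpy()]
    b_status = obs_ffu["verified0"].to_numpy(int)
    t_final = _truth_final_outcome(obs_ffu)
    t_weights = obs_ffu["weight"].to_numpy(float)
    trans_truth = transition_matrix(b_status, t_final, t_weights)

    sim_final = _sim_final_outcome(outcomes, final_wave)  # (R, N)
    R = outcomes.n_replicates
    sel = in_ffu & obs_final["alive"].notna().to_numpy()
    b_rep = np.broadcast_to(outcomes.baseline_verified[sel], (R, sel.sum())).ravel()
    f_rep = sim_final[:, sel].ravel()
    w_rep = np.broadcast_to(outcomes.weight[sel] / R, (R, sel.sum())).ravel()
    trans_sim = transition_matrix(b_rep, f_rep, w_rep)

    # --- individual-level: AUROC tables ------------------------------------
    groups = dict(subgroups) if subgroups is not None else default_subgroups(obs_final)
    rows = []
    for h in horizons:
        obs_h = observed_outcomes(panel_truth, h).reindex(ids)
        known = obs_h["alive"].notna().to_numpy() & in_ffu
        truth_v = obs_h["verified"].to_numpy(float)
        truth_alive = obs_h["alive"].to_numpy(float) == 1
        for pred in predicates:
            risks = risk_fraction(outcomes, pred, h)
            if pred == "dementia_or_dead_with_dementia":
                y = (truth_v == 2).astype(int)
                sel_p = known
            elif pred == "mci_or_worse_or_dead_with_mci_or_worse":
                y = (truth_v >= 1).astype(int)
                sel_p = known
            elif pred == "dementia_given_alive":
                y = (truth_v == 2).astype(int)
                sel_p = known & truth_alive & ~np.isnan(risks)
            elif pred == "mci_or_worse_given_alive":
                y = (truth_v >= 1).astype(int)
                sel_p = known & truth_alive & ~np.isnan(risks)
            elif pred == "significant_decline_2yr":
                t_score = obs_h["score"].to_numpy(float)
                b_score = obs_h["score0"].to_numpy(float)
                y = ((b_score - t_score) >= cs.SIGNIFICANT_DECLINE_POINTS).astype(int)
                sel_p = known & truth_alive & ~np.isnan(t_score) & ~np.isnan(risks)
            else:
                raise DomainError(f"unknown predicate {pred!r}")
            for gname, gmask in groups.items():
                m = sel_p & gmask
                try:
                    res = roc_auc(risks[m], y[m])
                except DomainError:
                    continue
                rows.append(
                    {
                        "subgroup": gname,
                        "predicate": pred,
                        "horizon_wave": h,
                        "auroc": res.auroc,
                        "n_cases": res.n_cases,
                        "n_controls": res.n_controls,
                    }
                )
    auroc = pd.DataFrame(rows)
    return ValidationReport(
        distribution=distribution,
        transition_truth=trans_truth,
        transition_sim=trans_sim,
        auroc=auroc,
        meta={
            "horizons": horizons,
            "n_persons": len(ids),
            "n_full_followup": int(len(ffu)),
            "replicates": R,
        },
    )
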