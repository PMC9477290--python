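"""Sequential-regression multiple imputation of MNAR-masked TICS27 scores.

Proxy respondents have the cognitive score missing, and the missingness is
informative (lower true scores are masked more often).  Missing scores are
filled wave by wave, earliest first: a linear regression of the observed
scores on demographics, health and economic covariates plus prior-wave
cognition (score, category band, proxy flag) is fitted for the wave;
regression parameters are drawn from their approximate posterior (scaled
inverse-chi-square variance, normal coefficients); missing rows are filled
by predictive mean matching against the ``donor_count`` observed rows with
the nearest predictions, so imputed values are always observed integers in
0-27.  Later waves see already-imputed earlier scores.

After the initial forward pass, further chained-equation sweeps re-impute
each wave conditioning on the two prior waves' and the next wave's
(imputed) cognition.  Both prior waves matter because the analysis model
carries two- and four-year lags: omitting the twice-prior score would let
the imputation model overstate the one-wave persistence and distort how
the fitted transition model splits persistence across its two lags.  The extra conditioning matters under informative missingness:
selection on the true score tilts the residual around the regression
prediction, and the tilt is proportional to the residual variance, so the
tighter two-sided conditioning materially reduces the bias of imputed
cells — most visibly in the earliest wave, which has no prior-wave
predictor at all.  The procedure is repeated m times with independent
sub-seeds.

Non-responding waves (absent rows) are never imputed, matching the survey
convention; only proxy-masked scores among live interviews are filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cognition_states as cs
from .errors import ImputationError
from .transition_models import DEFAULT_SPEC, DesignSpec, FitResult

__all__ = ["ImputationConfig", "impute", "pooled_fit"]

#: diagonal ridge factor on the scaled normal equations (mice-style)
_RIDGE = 1e-4

_DEFAULT_PREDICTORS = (
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
    "working",
    "widowed",
    "smoke_ever",
    "smoke_current",
    "log_bmi",
    "adl_count",
    "iadl_count",
    "weight",
)


@dataclass
class ImputationConfig:
    """Settings for sequential-regression multiple imputation."""

    m: int = 5
    seed: int = 0
    donor_count: int = 5
    n_sweeps: int = 3
    predictors: Sequence[str] = _DEFAULT_PREDICTORS

    def validate(self) -> None:
        if self.m < 2:
            raise ImputationError("m must be >= 2")
        if self.donor_count < 1:
            raise ImputationError("donor_count must be >= 1")
        if self.n_sweeps < 1:
            raise ImputationError("n_sweeps must be >= 1")


def _cognition_block(neighbor: pd.DataFrame | None, n: int) -> list[np.ndarray]:
    """Score, category dummies, proxy flag of an adjacent wave, zero-filled.

    An availability dummy absorbs the level shift for rows whose neighbor
    wave is absent (first/last wave, or dead next wave), so the score slope
    applies only where the neighbor exists.
    """
    if neighbor is None:
        return [np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n)]
    s = neighbor["tics27"].to_numpy(float)
    has = ~np.isnan(s)
    sf = np.where(has, s, 0.0)
    cat = np.where(has, cs.classify_scores(np.where(has, s, 0).astype(int)), -1)
    return [
        has.astype(float),
        sf,
        (cat == int(cs.CognitiveCategory.MCI)).astype(float),
        (cat == int(cs.CognitiveCategory.DEMENTIA)).astype(float),
        np.where(has, neighbor["proxy"].to_numpy(float), 0.0),
    ]


def _design_for_wave(
    df_w: pd.DataFrame,
    prior: pd.DataFrame | None,
    prior2: pd.DataFrame | None,
    nxt: pd.DataFrame | None,
    predictors,
) -> np.ndarray:
    n = len(df_w)
    cols = [np.ones(n)]
    for c in predictors:
        if c in ("nh_black", "hispanic") and c not in df_w:
            cols.append((df_w["race_ethnicity"].to_numpy() == c).astype(float))
            continue
        if c in ("lt_hs", "some_college") and c not in df_w:
            cols.append((df_w["education"].to_numpy() == c).astype(float))
            continue
        if c not in df_w:
            raise ImputationError(f"predictor column {c!r} missing from panel")
        v = df_w[c].to_numpy(float)
        if np.any(np.isnan(v)):
            raise ImputationError(f"predictor column {c!r} has missing values")
        cols.append(v)
    cols.extend(_cognition_block(prior, n))
    cols.extend(_cognition_block(prior2, n))
    cols.extend(_cognition_block(nxt, n))
    return np.column_stack(cols)


def _neighbor_frame(df: pd.DataFrame, waves, wi: int, offset: int, person_ids):
    wj = wi + offset
    if wj < 0 or wj >= len(waves):
        return None
    nb = df[df["wave"] == waves[wj]].set_index("person_id")
    return nb.reindex(person_ids)


def impute(panel: pd.DataFrame, config: ImputationConfig) -> list[pd.DataFrame]:
    """Return m completed copies of the panel (observed cells untouched)."""
    config.validate()
    base = panel.sort_values(["person_id", "wave"]).reset_index(drop=True)
    waves = np.sort(base["wave"].unique())
    miss_any = (base["tics27"].isna() & (base["alive"] == 1)).to_numpy()
    completed = []
    for i in range(config.m):
        rng = np.random.Generator(np.random.Philox(key=config.seed, counter=[0, 0, i, 5]))
        df = base.copy()
        for sweep in range(config.n_sweeps):
            for wi, w in enumerate(waves):
                sel = (df["wave"] == w) & (df["alive"] == 1)
                df_w = df.loc[sel]
                miss = miss_any[sel.to_numpy()]
                if not miss.any():
                    continue
                if (~miss).sum() == 0:
                    raise ImputationError(f"all scores missing in wave {w}; cannot impute")
                pids = df_w["person_id"].to_numpy()
                prior = _neighbor_frame(df, waves, wi, -1, pids)
                prior2 = _neighbor_frame(df, waves, wi, -2, pids)
                # the next wave is usable from the second sweep on (its
                # missing cells are filled by then); the first sweep runs
                # forward with prior-wave information only
                nxt = _neighbor_frame(df, waves, wi, +1, pids) if sweep > 0 else None
                Xw = _design_for_wave(df_w, prior, prior2, nxt, config.predictors)
                y = df_w["tics27"].to_numpy(float)
                obs = ~miss
                Xo, yo = Xw[obs], y[obs]
                # ridge-stabilized normal equations: adjacent-wave score
                # blocks are highly correlated, and an unregularized
                # posterior draw has exploding variance along near-null
                # directions, which sweep feedback then amplifies
                XtX = Xo.T @ Xo
                d = np.diag(XtX).copy()
                d[d == 0] = 1.0
                R = XtX + _RIDGE * np.diag(d)
                coef = np.linalg.solve(R, Xo.T @ yo)
                resid = yo - Xo @ coef
                dof = max(len(yo) - Xo.shape[1], 1)
                sigma2 = float(resid @ resid) / rng.chisquare(dof)
                cov = sigma2 * np.linalg.inv(R)
                try:
                    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(coef)))
                except np.linalg.LinAlgError:
                    L = np.diag(np.sqrt(np.clip(np.diag(cov), 0, None)))
                coef_draw = coef + L @ rng.standard_normal(len(coef))
                pred_obs = Xo @ coef
                pred_mis = Xw[miss] @ coef_draw
                # predictive mean matching among donor_count nearest predictions
                k = min(config.donor_count, int(obs.sum()))
                dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
                nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
                pick = nearest[np.arange(len(pred_mis)), rng.integers(0, k, len(pred_mis))]
                df.loc[df_w.index[miss], "tics27"] = yo[pick]
        completed.append(df)
    return completed


def pooled_fit(
    completed: list[pd.DataFrame],
    model: str,
    spec: DesignSpec = DEFAULT_SPEC,
    **fit_kwargs,
) -> FitResult:
    """Fit the transition model on each completed panel and average.

    Point estimates are the equal-weight average of the per-imputation
    coefficient vectors; the between-imputation variance of each
    coefficient is reported as a diagnostic in ``extras`` (Rubin-style
    total variance is logged there, not propagated downstream).
    """
    from .transition_models import fit_mortality_model, fit_tics_model

    fits = []
    for i, df in enumerate(completed):
        try:
            fit = fit_tics_model(df, spec, **fit_kwargs) if model == "tics" else fit_mortality_model(df, spec, **fit_kwargs)
        except Exception as exc:
            raise ImputationError(f"fit failed for imputation {i}: {exc}") from exc
        fits.append(fit)

    params0 = fits[0].params
    if model == "tics":
        betas = np.stack([f.params.beta for f in fits])
        # kappa vectors can differ in length if score levels differ; average
        # only when the category sets agree, else keep the first fit's kappa
        same_levels = all(
            np.array_equal(f.params.levels, params0.levels) for f in fits
        )
        kappas = (
            np.stack([f.params.kappa for f in fits]).mean(axis=0)
            if same_levels
            else params0.kappa
        )
        from .transition_models import OrderedProbitParams

        pooled = OrderedProbitParams(
            beta=betas.mean(axis=0),
            names=params0.names,
            kappa=kappas,
            levels=params0.levels,
        )
        between = betas.var(axis=0, ddof=1)
    else:
        from .transition_models import ProbitParams

        gammas = np.stack([f.params.gamma for f in fits])
        intercepts = np.array([f.params.intercept for f in fits])
        pooled = ProbitParams(
            gamma=gammas.mean(axis=0),
            names=params0.names,
            intercept=float(intercepts.mean()),
        )
        between = gammas.var(axis=0, ddof=1)

    within = np.stack(
        [f.standard_errors.reindex(list(params0.names)).to_numpy() ** 2 for f in fits]
    ).mean(axis=0)
    m = len(fits)
    total = within + (1 + 1 / m) * between
    se = pd.Series(np.sqrt(total), index=list(params0.names))
    return FitResult(
        params=pooled,
        standard_errors=se,
        log_likelihood=float(np.mean([f.log_likelihood for f in fits])),
        converged=all(f.converged for f in fits),
        n_obs=int(np.mean([f.n_obs for f in fits])),
        extras={
            "between_variance": pd.Series(between, index=list(params0.names)),
            "m": m,
        },
    )
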