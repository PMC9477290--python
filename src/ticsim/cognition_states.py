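"""Cognitive-status rules for the 27-point telephone cognitive screen (TICS27).

The score bands follow the Langa–Weir classification: 0–6 dementia (ADOD),
7–11 mild cognitive impairment (MCI), 12–27 cognitively normal.  A single
low score can reflect measurement error rather than true impairment, so a
category only becomes a person's *verified* status once a second adjacent
observation confirms it:

* verified dementia — a dementia-band wave followed by dementia or by death;
* verified MCI — an MCI-band wave followed by MCI, dementia or death, or a
  dementia-band wave followed by an MCI-band wave (the MCI wave confirms);
* everything else counts as cognitively normal.

Verified status is absorbing: once attained it never reverts to a less
severe state, even if later raw scores are in the normal band.  Status at
death is the verified status in the last wave before death, where death
itself may act as the confirming event.

Two timing conventions coexist and are both exposed:

``verify_trajectory``
    labels the status as effective at the *first* wave of the confirming
    pair (retrospective labelling of an observed trajectory).

``verified_known_by_wave``
    counts a status only once its confirming observation has occurred
    (the information available *by* each wave).  This is the convention a
    forward simulation — and the verified-ever regression covariate — must
    use, since the confirming wave may be the very outcome being predicted.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "CognitiveCategory",
    "VerifiedStatus",
    "classify_score",
    "classify_scores",
    "verify_trajectory",
    "verified_known_by_wave",
    "status_at_death",
    "significant_decline",
    "add_status_columns",
    "DEMENTIA_MAX_SCORE",
    "MCI_MAX_SCORE",
    "MAX_SCORE",
]

DEMENTIA_MAX_SCORE = 6
MCI_MAX_SCORE = 11
MAX_SCORE = 27

#: 3-point two-year drop counted as significant decline (MMSE-crosswalk based).
SIGNIFICANT_DECLINE_POINTS = 3


class CognitiveCategory(IntEnum):
    """Score-band category, ordered by severity (normal < mci < dementia)."""

    NORMAL = 0
    MCI = 1
    DEMENTIA = 2


class VerifiedStatus(IntEnum):
    """Absorbing confirmed status, ordered by severity."""

    NORMAL = 0
    VERIFIED_MCI = 1
    VERIFIED_DEMENTIA = 2


def classify_score(score: int) -> CognitiveCategory:
    """Map a TICS27 score to its category (0–6 dementia, 7–11 MCI, 12–27 normal)."""
    if (
        isinstance(score, (bool, np.bool_))
        or not isinstance(score, (int, np.integer, float, np.floating))
        or not float(score).is_integer()
    ):
        raise DomainError(f"TICS27 score must be an integer, got {score!r}")
    score = int(score)
    if not 0 <= score <= MAX_SCORE:
        raise DomainError(f"TICS27 score must be in [0, {MAX_SCORE}], got {score}")
    if score <= DEMENTIA_MAX_SCORE:
        return CognitiveCategory.DEMENTIA
    if score <= MCI_MAX_SCORE:
        return CognitiveCategory.MCI
    return CognitiveCategory.NORMAL


def classify_scores(scores) -> np.ndarray:
    """Vectorized :func:`classify_score`; NaN propagates (float output then)."""
    s = np.asarray(scores)
    if np.issubdtype(s.dtype, np.floating):
        out = np.full(s.shape, np.nan)
        ok = ~np.isnan(s)
        if np.any((s[ok] < 0) | (s[ok] > MAX_SCORE) | (s[ok] != np.floor(s[ok]))):
            raise DomainError("TICS27 scores must be integers in [0, 27] or NaN")
        out[ok] = np.where(
            s[ok] <= DEMENTIA_MAX_SCORE,
            CognitiveCategory.DEMENTIA,
            np.where(s[ok] <= MCI_MAX_SCORE, CognitiveCategory.MCI, CognitiveCategory.NORMAL),
        )
        return out
    if np.any((s < 0) | (s > MAX_SCORE)):
        raise DomainError("TICS27 scores must be integers in [0, 27]")
    return np.where(
        s <= DEMENTIA_MAX_SCORE,
        int(CognitiveCategory.DEMENTIA),
        np.where(s <= MCI_MAX_SCORE, int(CognitiveCategory.MCI), int(CognitiveCategory.NORMAL)),
    ).astype(np.int64)


def _as_categories(traj: Sequence) -> list[CognitiveCategory]:
    out = []
    for c in traj:
        try:
            out.append(CognitiveCategory(int(c)))
        except (ValueError, TypeError) as exc:
            raise DomainError(f"invalid category in trajectory: {c!r}") from exc
    return out


def verify_trajectory(
    categories: Sequence, died: bool = False
) -> list[VerifiedStatus]:
    """Per-wave verified status for an observed category trajectory.

    Parameters
    ----------
    categories
        Per-wave :class:`CognitiveCategory` values (or their integer codes).
    died
        Whether the trajectory ends in death immediately after the last wave;
        death acts as a confirming event for the last wave's category.

    Returns
    -------
    list of :class:`VerifiedStatus`, one per wave.  A status is effective
    from the first wave of its confirming pair (for the dementia→MCI rule,
    from the MCI wave) and is carried forward, never downgraded.
    """
    cats = _as_categories(categories)
    n = len(cats)
    if n == 0:
        raise DomainError("trajectory must contain at least one wave")
    attained = np.zeros(n, dtype=int)
    for t in range(n):
        confirmed_by_death = died and t == n - 1
        nxt = cats[t + 1] if t + 1 < n else None
        if cats[t] == CognitiveCategory.DEMENTIA and (
            nxt == CognitiveCategory.DEMENTIA or confirmed_by_death
        ):
            attained[t] = max(attained[t], int(VerifiedStatus.VERIFIED_DEMENTIA))
        if cats[t] == CognitiveCategory.MCI and (
            nxt in (CognitiveCategory.MCI, CognitiveCategory.DEMENTIA)
            or confirmed_by_death
        ):
            attained[t] = max(attained[t], int(VerifiedStatus.VERIFIED_MCI))
        if (
            cats[t] == CognitiveCategory.MCI
            and t > 0
            and cats[t - 1] == CognitiveCategory.DEMENTIA
        ):
            attained[t] = max(attained[t], int(VerifiedStatus.VERIFIED_MCI))
    return [VerifiedStatus(v) for v in np.maximum.accumulate(attained)]


def verified_known_by_wave(categories: Sequence, died: bool = False) -> list[VerifiedStatus]:
    """Verified status using only information available by each wave.

    A confirming pair (s, s+1) contributes from wave s+1 onward.  With
    ``died=True`` the returned list gains no extra element; use
    :func:`status_at_death` for the death-confirmed terminal status.
    """
    cats = _as_categories(categories)
    if not cats:
        raise DomainError("trajectory must contain at least one wave")
    level = 0
    out = []
    for t, c in enumerate(cats):
        if t > 0:
            p = cats[t - 1]
            if p == CognitiveCategory.DEMENTIA and c == CognitiveCategory.DEMENTIA:
                level = max(level, int(VerifiedStatus.VERIFIED_DEMENTIA))
            if (
                p == CognitiveCategory.MCI
                and c in (CognitiveCategory.MCI, CognitiveCategory.DEMENTIA)
            ) or (p == CognitiveCategory.DEMENTIA and c == CognitiveCategory.MCI):
                level = max(level, int(VerifiedStatus.VERIFIED_MCI))
        out.append(VerifiedStatus(level))
    return out


def status_at_death(categories: Sequence) -> VerifiedStatus:
    """Verified status effective in the last wave before death.

    The trajectory is taken to end in death immediately after its last
    wave; death confirms a still-provisional category in that wave.
    """
    statuses = verify_trajectory(categories, died=True)
    return statuses[-1]


def significant_decline(score_t: int, score_next: int) -> bool:
    """True iff the score dropped by 3 or more points between two waves."""
    for s in (score_t, score_next):
        if (
            isinstance(s, (bool, np.bool_))
            or not isinstance(s, (int, np.integer, float, np.floating))
            or not float(s).is_integer()
        ):
            raise DomainError(f"scores must be integers, got {s!r}")
        if not 0 <= int(s) <= MAX_SCORE:
            raise DomainError(f"scores must be in [0, {MAX_SCORE}], got {s}")
    return int(score_t) - int(score_next) >= SIGNIFICANT_DECLINE_POINTS


def add_status_columns(panel: pd.DataFrame) -> pd.DataFrame:
    """Annotate a long panel with ``category`` and ``verified_status`` columns.

    ``category`` is the raw per-wave score band (NaN when the score is
    missing).  ``verified_status`` uses the information-set convention
    (:func:`verified_known_by_wave`): a status appears once its confirming
    observation — including a death row (``alive == 0``) — has occurred,
    and is carried forward.  Waves with a missing score neither confirm
    nor break an already-attained status.
    """
    df = panel.sort_values(["person_id", "wave"]).copy()
    cat = classify_scores(df["tics27"].to_numpy(float))
    df["category"] = cat

    grp = df.groupby("person_id", sort=False)
    prev_cat = grp["category"].shift(1).to_numpy()
    contiguous = (df["wave"] - grp["wave"].shift(1)).to_numpy() == 1
    dead_row = df["alive"].to_numpy() == 0

    cur = df["category"].to_numpy()
    dem = float(CognitiveCategory.DEMENTIA)
    mci = float(CognitiveCategory.MCI)
    conf_dem = contiguous & (prev_cat == dem) & ((cur == dem) | dead_row)
    conf_mci = contiguous & (
        ((prev_cat == mci) & ((cur == mci) | (cur == dem) | dead_row))
        | ((prev_cat == dem) & (cur == mci))
    )
    event = np.where(conf_dem, 2, np.where(conf_mci, 1, 0))
    df["verified_status"] = (
        pd.Series(event, index=df.index).groupby(df["person_id"], sort=False).cummax()
    )
    return df
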