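"""Fungus patrolling and resource-monopolization comparisons.

Patrolling is the time a female spends *alone* on the fungal resource —
her on-fungus intervals minus her partner's — computed by exact interval
arithmetic from the occupancy log.  Females are then binarized into
patrollers (any positive alone-on-fungus time in any trial) versus
non-patrollers, and the two groups are compared on body size (Welch's
unequal-variance t-test) and on total interactive behavior in each
female's first trial (Mann-Whitney U; behavior counts are not normal).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import intersect, total_length
from .event_log import (BehaviorEvent, FemaleRecord, OccupancyInterval,
                        TrialRecord)


@dataclass
class PatrollingSummary:
    #: seconds alone on fungus, keyed by (female_id, trial_id)
    patrol_seconds: Dict[Tuple[str, str], float]
    #: per-female: ever patrolled (strictly positive alone time)?
    any_patrol: Dict[str, bool]
    n_patrollers: int
    n_nonpatrollers: int
    n_trials_with_patrolling: int

    def per_trial_frame(self) -> pd.DataFrame:
        rows = [{"female_id": f, "trial_id": t, "patrol_s": s}
                for (f, t), s in sorted(self.patrol_seconds.items())]
        return pd.DataFrame(rows, columns=["female_id", "trial_id", "patrol_s"])

    def mean_patrol_minutes(self) -> float:
        """Mean patrolling duration per female-trial, in minutes."""
        vals = list(self.patrol_seconds.values())
        return float(np.mean(vals)) / 60.0 if vals else 0.0


@dataclass
class GroupTestResult:
    statistic: float
    df: Optional[float]  # Welch-Satterthwaite df; None for Mann-Whitney
    p_value: float
    group_ns: Tuple[int, int]
    method: str  # "welch_t" or "mann_whitney_u"


def patrolling_durations(occupancy: Sequence[OccupancyInterval],
                         trials: Sequence[TrialRecord],
                         min_dwell: float = 0.0) -> PatrollingSummary:
    """Alone-on-fungus time for every female in every trial.

    ``min_dwell`` optionally requires more than that many seconds of alone
    time before a female-trial counts as patrolling (default: any positive
    time counts).
    """
    on_fungus: Dict[Tuple[str, str], List[Tuple[float, float]]] = {}
    for iv in occupancy:
        if iv.on_fungus:
            on_fungus.setdefault((iv.trial_id, iv.female_id), []).append((iv.start, iv.stop))
    # non-overlap within a female is an upstream invariant; re-check cheaply
    for key, ivs in on_fungus.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1 - 1e-9:
                raise ValueError(f"overlapping occupancy intervals for {key[1]} in {key[0]}")

    patrol: Dict[Tuple[str, str], float] = {}
    for t in trials:
        fa, fb = t.females
        ia = on_fungus.get((t.trial_id, fa), [])
        ib = on_fungus.get((t.trial_id, fb), [])
        both = total_length(intersect(ia, ib))
        patrol[(fa, t.trial_id)] = total_length(ia) - both
        patrol[(fb, t.trial_id)] = total_length(ib) - both

    any_patrol: Dict[str, bool] = {}
    for (fid, _), sec in patrol.items():
        any_patrol[fid] = any_patrol.get(fid, False) or sec > min_dwell
    trials_with = {tid for (fid, tid), sec in patrol.items() if sec > min_dwell}
    n_pat = sum(any_patrol.values())
    return PatrollingSummary(patrol, any_patrol, n_pat, len(any_patrol) - n_pat,
                             len(trials_with))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        warnings.warn("zero variance in both groups", stacklevel=2)
        if np.mean(x) == np.mean(y):
            return GroupTestResult(0.0, float(len(x) + len(y) - 2), 1.0,
                                   (len(x), len(y)), "welch_t")
        return GroupTestResult(np.inf, float(len(x) + len(y) - 2), 0.0,
                               (len(x), len(y)), "welch_t")
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupTestResult(float(res.statistic), float(res.df), float(res.pvalue),
                           (len(x), len(y)), "welch_t")


def _rank_u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: number of (x, y) pairs with x > y, ties counted half."""
    n1 = len(x)
    allv = np.concatenate([x, y])
    ranks = stats.rankdata(allv)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact: bool = False) -> GroupTestResult:
    """Mann-Whitney U / Wilcoxon rank-sum test, two-sided.

    The reported statistic W follows the convention W = #{(x_i, y_j):
    x_i > y_j} + half the ties — the value standard statistical
    environments print for the first group.  The default p-value uses the
    normal approximation with tie correction and continuity correction;
    ``exact=True`` (n1 + n2 <= 12 only) enumerates all group assignments
    of the pooled values and is valid under ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("each group needs n >= 1")
    n1, n2 = len(x), len(y)
    W = _rank_u_statistic(x, y)

    if exact:
        if n1 + n2 > 12:
            raise ValueError("exact enumeration limited to n1 + n2 <= 12")
        pooled = np.concatenate([x, y])
        center = n1 * n2 / 2.0
        obs_dev = abs(W - center)
        count = 0
        total = 0
        idx = range(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _rank_u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return GroupTestResult(W, None, float(min(p, 1.0)), (n1, n2), "mann_whitney_u")


def first_trial_selection(panel: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Keep each female's first-trial row (avoids pseudoreplication).

    With ``strict`` (default) every female must have a round-1 trial and
    that row is kept; otherwise each female's earliest round is used
    (covers designs where one female sits out a round).
    """
    if "trial_round" not in panel.columns:
        raise ValueError("panel must carry a trial_round column")
    if strict:
        first = panel[panel["trial_round"] == 1]
        missing = sorted(set(panel["female_id"]) - set(first["female_id"]))
        if missing:
            raise ValueError(f"female(s) without a round-1 trial: {missing}")
    else:
        idx = panel.groupby("female_id")["trial_round"].idxmin()
        first = panel.loc[idx]
    dup = first["female_id"].duplicated()
    if dup.any():
        raise ValueError("multiple first-trial rows for a female")
    return first.reset_index(drop=True)


@dataclass
class ResourceUseReport:
    patrolling: PatrollingSummary
    body_size_test: Optional[GroupTestResult]
    interaction_test: Optional[GroupTestResult]
    n_excluded_no_size: int

    def summary_frame(self, females: Sequence[FemaleRecord],
                      initiated: pd.DataFrame) -> pd.DataFrame:
        size = {f.female_id: f.elytra_length for f in females}
        rows = []
        for _, r in initiated.iterrows():
            fid = r["female_id"]
            rows.append({"female_id": fid,
                         "any_patrol": self.patrolling.any_patrol.get(fid, False),
                         "elytra_length_mm": size.get(fid),
                         "n_initiated_first_trial": int(r["count"])})
        return pd.DataFrame(rows)


def analyze_resource_use(females: Sequence[FemaleRecord], trials: Sequence[TrialRecord],
                         events: Sequence[BehaviorEvent],
                         occupancy: Sequence[OccupancyInterval],
                         min_dwell: float = 0.0) -> ResourceUseReport:
    """The full resource-monopolization analysis.

    Patrollers vs non-patrollers are compared on elytra length (Welch t)
    and on the number of behaviors each female initiated in her first
    trial (Mann-Whitney U).
    """
    summary = patrolling_durations(occupancy, trials, min_dwell=min_dwell)

    # total initiated behaviors per female per trial (any non-end behavior)
    tally: Dict[Tuple[str, str], int] = {}
    for ev in events:
        if ev.behavior != "end" and not ev.synthetic_end:
            tally[(ev.actor_id, ev.trial_id)] = tally.get((ev.actor_id, ev.trial_id), 0) + 1
    rows = [{"female_id": fid, "trial_id": t.trial_id, "trial_round": t.trial_round,
             "count": tally.get((fid, t.trial_id), 0)}
            for t in trials for fid in t.females]
    panel = pd.DataFrame(rows)
    first = first_trial_selection(panel, strict=False)

    is_pat = {fid: summary.any_patrol.get(fid, False) for fid in first["female_id"]}
    size = {f.female_id: f.elytra_length for f in females}

    sx = [size[f] for f, p in is_pat.items() if p and size.get(f) is not None]
    sy = [size[f] for f, p in is_pat.items() if not p and size.get(f) is not None]
    n_excluded = sum(1 for f in is_pat if size.get(f) is None)
    body_test = welch_t_test(sx, sy) if len(sx) >= 2 and len(sy) >= 2 else None

    cx = first.loc[[is_pat[f] for f in first["female_id"]], "count"].tolist()
    cy = first.loc[[not is_pat[f] for f in first["female_id"]], "count"].tolist()
    inter_test = mann_whitney_u(cx, cy) if cx and cy else None

    return ResourceUseReport(summary, body_test, inter_test, n_excluded)


__all__ = [
    "PatrollingSummary", "GroupTestResult", "patrolling_durations",
    "welch_t_test", "mann_whitney_u", "first_trial_selection",
    "ResourceUseReport", "analyze_resource_use",
]
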