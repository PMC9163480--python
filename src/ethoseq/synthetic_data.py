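"""Synthetic dyadic-trial datasets with known ground truth.

The generator emulates the study design the analysis assumes: ~47
paint-marked females, three rounds of random white-x-black pairings, 4-h
trials scored on a 5-s snapshot grid, bouts of interactive behavior that
follow a known first-order Markov chain until an explicit ``end``, a
configurable share of proximity-only approaches, independent fungus
occupancy intervals, and per-trial behavior counts whose among-female
variance is controlled by latent normal effects on the log scale.  Every
quantity the pipeline estimates therefore has a planted true value that
recovery tests can assert against.

Two presets mirror the interpretive frame of the female-vs-male contrast:
``null_female`` (no aggressive transition structure, zero among-female
variance, behavior shares matching the observed female frequencies) and
``male_like`` (planted aggressive behaviors grapple/chase/flip whose
modal, over-represented consequence is ending the interaction, plus high
among-female variance giving a latent ICC of 0.8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .event_log import (BehaviorEvent, Dataset, FemaleRecord, OccupancyInterval,
                        PHYSICAL_BEHAVIORS, SOURCE_STATES, TARGET_STATES,
                        TrialRecord, write_event_log)

_SRC_INDEX = {s: i for i, s in enumerate(SOURCE_STATES)}
_TGT_INDEX = {s: j for j, s in enumerate(TARGET_STATES)}


@dataclass
class SimConfig:
    """Generative parameters for a synthetic study.

    ``true_transition`` is row-stochastic over source states x target
    states (targets include ``end``).  ``start_dist`` gives the first
    state of non-proximity-only bouts.  ``bout_rate`` is the expected
    number of bouts per trial at zero latent effects; each bout's
    initiator draws her own Poisson share, modulated by
    exp(a_female + b_trial + e), with the latent variances below.
    """

    n_females: int = 47
    n_rounds: int = 3
    trial_duration: float = 14400.0
    snapshot_interval: float = 5.0
    true_transition: np.ndarray = field(default=None)  # type: ignore[assignment]
    start_dist: np.ndarray = field(default=None)       # type: ignore[assignment]
    bout_rate: float = 10.0
    proximity_only_prob: float = 0.48
    dwell_mean_snapshots: float = 2.0
    mu_count: float = 1.5  # baseline log count for the direct panel generator
    V_female_true: float = 0.0
    V_trial_true: float = 0.0
    V_resid_true: float = 0.3
    patrol_prob: float = 0.15
    patrol_mean_s: float = 3600.0
    body_size_mean_mm: float = 9.0
    body_size_sd_mm: float = 0.7
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.true_transition is None:
            self.true_transition = uniform_transition_matrix()
        self.true_transition = np.asarray(self.true_transition, dtype=float)
        if self.true_transition.shape != (len(SOURCE_STATES), len(TARGET_STATES)):
            raise ValueError("true_transition must be n_sources x n_targets")
        rows = self.true_transition.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("true_transition rows must sum to 1")
        if self.start_dist is None:
            sd = np.zeros(len(SOURCE_STATES))
            for b in PHYSICAL_BEHAVIORS:
                sd[_SRC_INDEX[b]] = 1.0
            self.start_dist = sd / sd.sum()
        self.start_dist = np.asarray(self.start_dist, dtype=float)
        if not np.isclose(self.start_dist.sum(), 1.0, atol=1e-9):
            raise ValueError("start_dist must sum to 1")
        if not 0.0 <= self.proximity_only_prob <= 1.0:
            raise ValueError("proximity_only_prob must be a probability")
        for v in (self.V_female_true, self.V_trial_true, self.V_resid_true):
            if v < 0:
                raise ValueError("variances must be >= 0")

    def to_jsonable(self) -> Dict:
        d = asdict(self)
        d["true_transition"] = self.true_transition.tolist()
        d["start_dist"] = self.start_dist.tolist()
        return d


@dataclass
class SimTruth:
    """Realized latent quantities a recovery test can compare against."""

    config: SimConfig
    female_effects: Dict[str, float]
    trial_effects: Dict[str, float]
    obs_effects: Dict[Tuple[str, str], float]  # (female, trial) -> e

    @property
    def latent_icc(self) -> float:
        vf, ve = self.config.V_female_true, self.config.V_resid_true
        return vf / (vf + ve) if (vf + ve) > 0 else 0.0

    def to_jsonable(self) -> Dict:
        return {
            "config": self.config.to_jsonable(),
            "female_effects": self.female_effects,
            "trial_effects": self.trial_effects,
            "obs_effects": {f"{f}|{t}": v for (f, t), v in self.obs_effects.items()},
            "latent_icc": self.latent_icc,
        }


# ---------------------------------------------------------------------------
# preset transition structures

def _matrix_from_rows(rows: Dict[str, Dict[str, float]]) -> np.ndarray:
    m = np.zeros((len(SOURCE_STATES), len(TARGET_STATES)))
    for src, targets in rows.items():
        for tgt, p in targets.items():
            m[_SRC_INDEX[src], _TGT_INDEX[tgt]] = p
    return m


#: Behavior shares matching the observed female frequency profile: bumping
#: dominates, touch and mount are common, head/chase/flip rare, grapples
#: absent.
_FEMALE_SHARES = {"touch": 0.30, "bump": 0.326, "head": 0.097, "mount": 0.231,
                  "grapple": 0.0, "chase": 0.035, "flip": 0.011}


def null_female_config(seed: int = 0, **overrides) -> SimConfig:
    """No aggression, no among-female variance, female-like frequencies.

    Every physical behavior's targets follow one common distribution (the
    female behavior shares with a flat 15% chance of ending), so no
    transition is over-represented relative to independence and no
    behavior has ``end`` as its modal consequence.  48% of bouts are
    proximity-only approaches.
    """
    rows: Dict[str, Dict[str, float]] = {"proximity": {"end": 1.0}}
    for src in PHYSICAL_BEHAVIORS:
        w = {b: s for b, s in _FEMALE_SHARES.items() if b != src}
        tot = sum(w.values())
        rows[src] = {b: 0.85 * s / tot for b, s in w.items()}
        rows[src]["end"] = 0.15
    start = np.zeros(len(SOURCE_STATES))
    for b, s in _FEMALE_SHARES.items():
        start[_SRC_INDEX[b]] = s
    start /= start.sum()
    cfg = SimConfig(true_transition=_matrix_from_rows(rows), start_dist=start,
                    proximity_only_prob=0.48, bout_rate=10.0,
                    V_female_true=0.0, V_trial_true=0.0, V_resid_true=0.3,
                    seed=seed, name="null_female")
    return replace(cfg, **overrides) if overrides else cfg


def male_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Planted aggressive subset {grapple, chase, flip}, high repeatability.

    Aggressive behaviors end the interaction with probability 0.6 (their
    modal, strongly over-represented consequence); nonaggressive behaviors
    end with probability 0.1 and funnel some transitions into the
    aggressive states so those rows are well populated.  Latent
    among-female variance 0.8 against residual 0.2 gives a true ICC of
    0.8 for behavior counts.
    """
    aggressive = ("grapple", "chase", "flip")
    nonagg = ("touch", "bump", "head", "mount")
    rows: Dict[str, Dict[str, float]] = {"proximity": {"end": 1.0}}
    for src in nonagg:
        r = {b: 0.55 / (len(nonagg) - 1) for b in nonagg if b != src}
        r.update({"grapple": 0.14, "chase": 0.14, "flip": 0.07, "end": 0.10})
        rows[src] = r
    for src in aggressive:
        r = {b: 0.30 / len(nonagg) for b in nonagg}
        others = [b for b in aggressive if b != src]
        r.update({b: 0.05 for b in others})
        r["end"] = 0.60
        rows[src] = r
    start = np.zeros(len(SOURCE_STATES))
    for b, s in {"touch": 0.35, "bump": 0.35, "head": 0.1, "mount": 0.1,
                 "grapple": 0.04, "chase": 0.04, "flip": 0.02}.items():
        start[_SRC_INDEX[b]] = s
    cfg = SimConfig(true_transition=_matrix_from_rows(rows), start_dist=start,
                    proximity_only_prob=0.20, bout_rate=20.0,
                    V_female_true=0.8, V_trial_true=0.0, V_resid_true=0.2,
                    seed=seed, name="male_like")
    return replace(cfg, **overrides) if overrides else cfg


MALE_LIKE_AGGRESSIVE = ("chase", "flip", "grapple")


def uniform_transition_matrix(end_prob: float = 0.1) -> np.ndarray:
    """A benchmark chain visiting all eight source states roughly evenly.

    Off-diagonal targets in row i get weight 1 + ((i + j) mod 3) so the
    rows are unequal (recovery is not trivially symmetric) but every state
    is recurrent; each row ends with probability ``end_prob``.
    """
    n = len(SOURCE_STATES)
    m = np.zeros((n, len(TARGET_STATES)))
    for i in range(n):
        w = np.array([0.0 if j == i else 1.0 + ((i + j) % 3) for j in range(n)])
        m[i, :n] = (1.0 - end_prob) * w / w.sum()
        m[i, _TGT_INDEX["end"]] = end_prob
    return m


def recovery_config(seed: int = 0, **overrides) -> SimConfig:
    """Benchmark config for transition-recovery checks: every source state
    reachable from the start distribution, no proximity shortcut."""
    start = np.full(len(SOURCE_STATES), 1.0 / len(SOURCE_STATES))
    cfg = SimConfig(true_transition=uniform_transition_matrix(),
                    start_dist=start, proximity_only_prob=0.0,
                    bout_rate=12.0, seed=seed, name="recovery")
    return replace(cfg, **overrides) if overrides else cfg


PRESETS = {"null_female": null_female_config, "male_like": male_like_config,
           "recovery": recovery_config}


# ---------------------------------------------------------------------------
# generators

def simulate_roster(config: SimConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[List[FemaleRecord], List[TrialRecord]]:
    """Females with paint and body size, plus random white-x-black pairings.

    Half the females (rounded up) are painted white, the rest black; each
    round pairs a random shuffle of whites with a random shuffle of
    blacks, so with an odd count one female sits out per round.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.n_females < 2:
        raise ValueError("need at least 2 females to pair")
    n = config.n_females
    females = []
    for i in range(n):
        paint = "white" if i < (n + 1) // 2 else "black"
        size = float(rng.normal(config.body_size_mean_mm, config.body_size_sd_mm))
        size = max(size, 0.1)
        females.append(FemaleRecord(f"F{i + 1:03d}", round(size, 2), paint))
    whites = [f.female_id for f in females if f.paint == "white"]
    blacks = [f.female_id for f in females if f.paint == "black"]
    if not whites or not blacks:
        raise ValueError("need both paint groups to pair")
    trials = []
    for r in range(1, config.n_rounds + 1):
        w = list(rng.permutation(whites))
        b = list(rng.permutation(blacks))
        for k, (fw, fb) in enumerate(zip(w, b), start=1):
            trials.append(TrialRecord(f"R{r}T{k:02d}", str(fw), str(fb), r,
                                      config.trial_duration))
    return females, trials


def draw_truth(config: SimConfig, females: Sequence[FemaleRecord],
               trials: Sequence[TrialRecord],
               rng: Optional[np.random.Generator] = None) -> SimTruth:
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    fe = {f.female_id: float(rng.normal(0.0, np.sqrt(config.V_female_true)))
          for f in females}
    te = {t.trial_id: float(rng.normal(0.0, np.sqrt(config.V_trial_true)))
          for t in trials}
    oe = {(fid, t.trial_id): float(rng.normal(0.0, np.sqrt(config.V_resid_true)))
          for t in trials for fid in t.females}
    return SimTruth(config, fe, te, oe)


def simulate_bout_states(config: SimConfig, rng: np.random.Generator,
                         max_len: int = 200) -> List[str]:
    """State sequence of one bout, always terminated by ``end``."""
    if rng.random() < config.proximity_only_prob:
        return ["proximity", "end"]
    states = [SOURCE_STATES[rng.choice(len(SOURCE_STATES), p=config.start_dist)]]
    while states[-1] != "end" and len(states) < max_len:
        row = config.true_transition[_SRC_INDEX[states[-1]]]
        states.append(TARGET_STATES[rng.choice(len(TARGET_STATES), p=row)])
    if states[-1] != "end":
        states.append("end")
    return states


def simulate_trial_events(config: SimConfig, truth: SimTruth, trial: TrialRecord,
                          rng: Optional[np.random.Generator] = None
                          ) -> Tuple[List[BehaviorEvent], List[OccupancyInterval]]:
    """Events and occupancy for one trial.

    Each female initiates her own Poisson number of bouts with rate
    (bout_rate / 2) * exp(a_female + b_trial + e); all events in a bout
    are attributed to its initiator.  Bout onsets sit on the snapshot
    grid; dwell times are geometric on the grid; bouts are laid out
    left-to-right with at least two empty snapshots between them.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    snap = config.snapshot_interval
    n_slots = int(config.trial_duration / snap)

    bout_specs: List[Tuple[str, List[str]]] = []
    for fid in trial.females:
        lam = (config.bout_rate / 2.0) * np.exp(
            truth.female_effects[fid] + truth.trial_effects[trial.trial_id]
            + truth.obs_effects[(fid, trial.trial_id)])
        n_bouts = rng.poisson(lam)
        for _ in range(n_bouts):
            bout_specs.append((fid, simulate_bout_states(config, rng)))
    order = rng.permutation(len(bout_specs))
    bout_specs = [bout_specs[i] for i in order]

    starts = np.sort(rng.integers(0, max(n_slots - 1, 1), size=len(bout_specs)))
    events: List[BehaviorEvent] = []
    cursor = 0  # first free slot
    p_dwell = 1.0 / max(config.dwell_mean_snapshots, 1.0)
    for (fid, states), s0 in zip(bout_specs, starts):
        slot = max(int(s0), cursor)
        for st in states:
            if slot >= n_slots:
                break
            if st == "end":
                events.append(BehaviorEvent(trial.trial_id, fid, "end",
                                            slot * snap, 0.0))
                slot += 1
            else:
                # dwell capped at 5 snapshots (25 s) so inter-onset gaps
                # within a bout never reach the default 30-s gap threshold
                dwell = min(int(rng.geometric(p_dwell)), 5, n_slots - slot)
                events.append(BehaviorEvent(trial.trial_id, fid, st,
                                            slot * snap, dwell * snap))
                slot += dwell
        cursor = slot + 2  # >= two empty snapshots between bouts

    occupancy: List[OccupancyInterval] = []
    for fid in trial.females:
        if rng.random() < config.patrol_prob:
            dur = float(rng.exponential(config.patrol_mean_s))
            dur = max(snap, min(dur, config.trial_duration))
            start = float(rng.uniform(0.0, config.trial_duration - dur))
            occupancy.append(OccupancyInterval(trial.trial_id, fid,
                                               round(start, 1),
                                               round(start + dur, 1), True))
    return events, occupancy


def simulate_dataset(config: SimConfig) -> Tuple[Dataset, SimTruth]:
    """A full synthetic study: roster, truth, events, occupancy."""
    rng = np.random.default_rng(config.seed)
    females, trials = simulate_roster(config, rng)
    truth = draw_truth(config, females, trials, rng)
    events: List[BehaviorEvent] = []
    occupancy: List[OccupancyInterval] = []
    for t in trials:
        ev, occ = simulate_trial_events(config, truth, t, rng)
        events.extend(ev)
        occupancy.extend(occ)
    ds = Dataset(females, trials, events, occupancy,
                 snapshot_interval=config.snapshot_interval)
    return ds, truth


def make_fixture(config: SimConfig, outdir) -> Tuple[Dataset, SimTruth]:
    """Write a complete synthetic dataset (CSV tables + truth.json)."""
    ds, truth = simulate_dataset(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_event_log(ds, outdir)
    (outdir / "truth.json").write_text(
        json.dumps(truth.to_jsonable(), indent=1, sort_keys=True) + "\n")
    return ds, truth


def simulate_count_panel(n_females: int, n_rounds: int, mu: float,
                         V_female: float, V_trial: float, V_resid: float,
                         seed: int) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Direct Poisson count panel with dyadic trial sharing.

    Bypasses event generation: counts are drawn straight from the mixed
    model the repeatability module fits, with females paired per round so
    each trial effect is shared by the two members of a dyad.  Returns
    the panel and the true latent-scale ICC.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, np.sqrt(V_female), size=n_females)
    rows = []
    for r in range(1, n_rounds + 1):
        perm = rng.permutation(n_females)
        for k in range(0, n_females - 1, 2):
            i, j = perm[k], perm[k + 1]
            tid = f"R{r}T{k // 2:03d}"
            bt = rng.normal(0.0, np.sqrt(V_trial))
            for f in (i, j):
                e = rng.normal(0.0, np.sqrt(V_resid))
                y = rng.poisson(np.exp(mu + a[f] + bt + e))
                rows.append({"female_id": f"F{f + 1:03d}", "trial_id": tid,
                             "trial_round": r, "count": int(y)})
    icc = V_female / (V_female + V_resid) if V_female + V_resid > 0 else 0.0
    return pd.DataFrame(rows), {"icc": icc, "V_female": V_female,
                                "V_trial": V_trial, "V_resid": V_resid, "mu": mu}


__all__ = [
    "SimConfig", "SimTruth", "PRESETS", "MALE_LIKE_AGGRESSIVE",
    "null_female_config", "male_like_config", "recovery_config",
    "uniform_transition_matrix", "simulate_roster", "draw_truth",
    "simulate_bout_states", "simulate_trial_events", "simulate_dataset",
    "make_fixture", "simulate_count_panel",
]
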