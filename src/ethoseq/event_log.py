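"""Event-log data model for dyadic behavioral trials.

A trial pairs two paint-marked females in an arena for a fixed duration
(default 4 h) and every interactive behavior is scored from time-lapse
imagery: a closed vocabulary of physical acts (touch, bump, head, mount,
grapple, chase, flip), the non-contact approach ``proximity``, and the
explicit ``end`` of an interaction.  Time on the fungal resource is scored
separately as occupancy intervals.

This module defines the record types, reads/writes the tidy-CSV dataset
layout (females.csv, trials.csv, events.csv, occupancy.csv), validates all
invariants, and segments event streams into interaction bouts — the unit
over which behavior-to-behavior transitions are counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._intervals import total_length

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Closed behavior vocabulary. ``proximity`` is an approach to within one
#: body length without contact; ``end`` marks one individual leaving.
BEHAVIOR_VOCAB: Tuple[str, ...] = (
    "proximity", "touch", "bump", "head", "mount", "grapple", "chase",
    "flip", "end",
)

#: Physical contact / interactive behaviors (the denominator for the
#: "share of initiated physical behaviors" frequency basis).
PHYSICAL_BEHAVIORS: Tuple[str, ...] = (
    "touch", "bump", "head", "mount", "grapple", "chase", "flip",
)

#: Source states of the transition matrix: everything an animal can be
#: "in" that can lead somewhere.  ``end`` is absorbing (target only).
SOURCE_STATES: Tuple[str, ...] = ("proximity",) + PHYSICAL_BEHAVIORS
TARGET_STATES: Tuple[str, ...] = SOURCE_STATES + ("end",)

DEFAULT_TRIAL_DURATION = 14400.0  # 4 h in seconds
DEFAULT_SNAPSHOT_INTERVAL = 5.0   # scoring granularity of the time-lapse
DEFAULT_GAP_THRESHOLD = 30.0      # 6 snapshots without events closes a bout


class EventLogError(ValueError):
    """Base class for dataset validation failures."""


class SchemaError(EventLogError):
    """A required file or column is missing or malformed."""


class VocabularyError(EventLogError):
    """A behavior label outside the closed vocabulary."""


class IntegrityError(EventLogError):
    """Cross-reference or invariant violation among records."""


@dataclass(frozen=True)
class FemaleRecord:
    female_id: str
    elytra_length: Optional[float]  # mm; None = not measured
    paint: str  # "white" or "black"


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    female_white: str
    female_black: str
    trial_round: int  # 1..3
    trial_duration: float = DEFAULT_TRIAL_DURATION

    @property
    def females(self) -> Tuple[str, str]:
        return (self.female_white, self.female_black)


@dataclass(frozen=True)
class BehaviorEvent:
    trial_id: str
    actor_id: str
    behavior: str
    onset: float      # seconds from trial start
    duration: float   # seconds, >= 0
    synthetic_end: bool = False  # True for ends inserted by bout segmentation

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class OccupancyInterval:
    trial_id: str
    female_id: str
    start: float
    stop: float
    on_fungus: bool


@dataclass(frozen=True)
class Bout:
    """A contiguous run of interactive events, closed by an ``end``.

    ``terminated`` is True when the bout was closed (by an explicit scored
    ``end`` or by a scoring gap, in which case a synthetic ``end`` event is
    appended and flagged).
    """

    trial_id: str
    events: Tuple[BehaviorEvent, ...]
    terminated: bool

    @property
    def behaviors(self) -> Tuple[str, ...]:
        return tuple(ev.behavior for ev in self.events)

    @property
    def is_proximity_only(self) -> bool:
        physical = [ev for ev in self.events if ev.behavior in PHYSICAL_BEHAVIORS]
        prox = [ev for ev in self.events if ev.behavior == "proximity"]
        return not physical and bool(prox)


@dataclass
class Dataset:
    females: List[FemaleRecord]
    trials: List[TrialRecord]
    events: List[BehaviorEvent]
    occupancy: List[OccupancyInterval] = field(default_factory=list)
    snapshot_interval: Optional[float] = None

    def trial(self, trial_id: str) -> TrialRecord:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    def events_for_trial(self, trial_id: str) -> List[BehaviorEvent]:
        evs = [e for e in self.events if e.trial_id == trial_id]
        return sort_events(evs)


def sort_events(events: Sequence[BehaviorEvent]) -> List[BehaviorEvent]:
    """Deterministic order: (onset, actor_id, behavior).

    Snapshot scoring makes same-onset ties likely; this stable key makes
    bout construction reproducible.
    """
    return sorted(events, key=lambda e: (e.onset, e.actor_id, e.behavior))


# ---------------------------------------------------------------------------
# validation

def validate_dataset(ds: Dataset) -> List[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    problems: List[str] = []
    fem_ids = [f.female_id for f in ds.females]
    if len(fem_ids) != len(set(fem_ids)):
        dupes = sorted({i for i in fem_ids if fem_ids.count(i) > 1})
        problems.append(f"duplicate female_id(s): {dupes}")
    fem_set = set(fem_ids)
    for f in ds.females:
        if f.paint not in ("white", "black"):
            problems.append(f"female {f.female_id}: paint must be white/black, got {f.paint!r}")
        if f.elytra_length is not None and not f.elytra_length > 0:
            problems.append(f"female {f.female_id}: elytra_length must be > 0")

    trial_ids = [t.trial_id for t in ds.trials]
    if len(trial_ids) != len(set(trial_ids)):
        problems.append("duplicate trial_id(s)")
    seen_round: Dict[Tuple[str, int], str] = {}
    for t in ds.trials:
        if t.female_white == t.female_black:
            problems.append(f"trial {t.trial_id}: female paired with herself")
        if t.trial_round not in (1, 2, 3):
            problems.append(f"trial {t.trial_id}: trial_round must be in 1..3")
        if t.trial_duration <= 0:
            problems.append(f"trial {t.trial_id}: nonpositive trial_duration")
        for fid in t.females:
            if fid not in fem_set:
                problems.append(f"trial {t.trial_id}: unknown female {fid}")
            key = (fid, t.trial_round)
            if key in seen_round:
                problems.append(
                    f"female {fid} appears in two trials of round {t.trial_round} "
                    f"({seen_round[key]}, {t.trial_id})")
            seen_round[key] = t.trial_id

    trials_by_id = {t.trial_id: t for t in ds.trials}
    for i, ev in enumerate(ds.events):
        t = trials_by_id.get(ev.trial_id)
        if t is None:
            problems.append(f"event row {i}: unknown trial {ev.trial_id}")
            continue
        if ev.behavior not in BEHAVIOR_VOCAB:
            problems.append(f"event row {i}: unknown behavior {ev.behavior!r}")
        if ev.actor_id not in t.females:
            problems.append(f"event row {i}: actor {ev.actor_id} not in trial {ev.trial_id}")
        if not (0 <= ev.onset <= t.trial_duration):
            problems.append(f"event row {i}: onset {ev.onset} outside [0, {t.trial_duration}]")
        elif ev.onset + ev.duration > t.trial_duration + 1e-9:
            problems.append(f"event row {i}: event extends past trial end")
        if ev.duration < 0:
            problems.append(f"event row {i}: negative duration")
        if ds.snapshot_interval and not ev.synthetic_end:
            q = ev.onset / ds.snapshot_interval
            if abs(q - round(q)) > 1e-6:
                problems.append(
                    f"event row {i}: onset {ev.onset} not on the "
                    f"{ds.snapshot_interval}-s snapshot grid")

    per_female: Dict[Tuple[str, str], List[Tuple[float, float]]] = {}
    for i, iv in enumerate(ds.occupancy):
        t = trials_by_id.get(iv.trial_id)
        if t is None:
            problems.append(f"occupancy row {i}: unknown trial {iv.trial_id}")
            continue
        if iv.female_id not in t.females:
            problems.append(f"occupancy row {i}: female {iv.female_id} not in trial {iv.trial_id}")
        if not iv.start < iv.stop:
            problems.append(f"occupancy row {i}: start must be < stop")
        per_female.setdefault((iv.trial_id, iv.female_id), []).append((iv.start, iv.stop))
    for (tid, fid), ivs in per_female.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1 - 1e-9:
                problems.append(f"occupancy overlap for female {fid} in trial {tid}")
                break
    return problems


# ---------------------------------------------------------------------------
# CSV I/O

_FEMALE_COLS = ["female_id", "elytra_length_mm", "paint"]
_TRIAL_COLS = ["trial_id", "female_white", "female_black", "trial_round", "trial_duration_s"]
_EVENT_COLS = ["trial_id", "actor_id", "behavior", "onset_s", "duration_s"]
_OCC_COLS = ["trial_id", "female_id", "start_s", "stop_s", "on_fungus"]


def _read_table(path: Path, required: List[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing file: {path}")
    df = pd.read_csv(path, comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    return df


def read_event_log(datadir, schema_version: str = SCHEMA_VERSION,
                   snapshot_interval: Optional[float] = None,
                   strict: bool = True) -> Dataset:
    """Read a tidy-CSV dataset directory and validate it.

    Parameters
    ----------
    datadir : path
        Directory containing females.csv, trials.csv, events.csv and
        (optionally) occupancy.csv.
    schema_version : str
        Declared schema version; only ``"1"`` is known.
    snapshot_interval : float, optional
        If given, event onsets must lie on this grid.
    strict : bool
        Raise on the first validation problem (default).  With
        ``strict=False`` problems are logged and the dataset returned.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unknown schema version {schema_version!r}")
    datadir = Path(datadir)

    fdf = _read_table(datadir / "females.csv", _FEMALE_COLS)
    females = []
    for _, r in fdf.iterrows():
        el = r["elytra_length_mm"]
        el = None if (el is None or (isinstance(el, float) and math.isnan(el))) else float(el)
        females.append(FemaleRecord(str(r["female_id"]), el, str(r["paint"])))
    n_missing = sum(f.elytra_length is None for f in females)
    if n_missing:
        logger.warning("%d female(s) lack elytra_length; excluded from body-size tests", n_missing)

    tdf = _read_table(datadir / "trials.csv", _TRIAL_COLS)
    trials = [TrialRecord(str(r["trial_id"]), str(r["female_white"]), str(r["female_black"]),
                          int(r["trial_round"]), float(r["trial_duration_s"]))
              for _, r in tdf.iterrows()]

    edf = _read_table(datadir / "events.csv", _EVENT_COLS)
    events = []
    for i, r in edf.iterrows():
        behavior = str(r["behavior"])
        if behavior not in BEHAVIOR_VOCAB:
            raise VocabularyError(f"events.csv row {i}: unknown behavior {behavior!r}")
        events.append(BehaviorEvent(str(r["trial_id"]), str(r["actor_id"]), behavior,
                                    float(r["onset_s"]), float(r["duration_s"])))

    occupancy: List[OccupancyInterval] = []
    occ_path = datadir / "occupancy.csv"
    if occ_path.exists():
        odf = _read_table(occ_path, _OCC_COLS)
        occupancy = [OccupancyInterval(str(r["trial_id"]), str(r["female_id"]),
                                       float(r["start_s"]), float(r["stop_s"]),
                                       bool(r["on_fungus"]))
                     for _, r in odf.iterrows()]

    ds = Dataset(females, trials, events, occupancy, snapshot_interval=snapshot_interval)
    problems = validate_dataset(ds)
    if problems:
        msg = "; ".join(problems[:20])
        if strict:
            raise IntegrityError(msg)
        logger.warning("dataset has %d problem(s): %s", len(problems), msg)
    logger.info("read %d females, %d trials, %d events, %d occupancy intervals",
                len(females), len(trials), len(events), len(occupancy))
    return ds


def write_event_log(ds: Dataset, datadir) -> None:
    """Write a dataset as the tidy-CSV layout (lossless round-trip)."""
    datadir = Path(datadir)
    datadir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    pd.DataFrame(
        [{"female_id": f.female_id, "elytra_length_mm": f.elytra_length, "paint": f.paint}
         for f in ds.females], columns=_FEMALE_COLS,
    ).to_csv(datadir / "females.csv", index=False, float_format=fmt)
    pd.DataFrame(
        [{"trial_id": t.trial_id, "female_white": t.female_white,
          "female_black": t.female_black, "trial_round": t.trial_round,
          "trial_duration_s": t.trial_duration} for t in ds.trials],
        columns=_TRIAL_COLS,
    ).to_csv(datadir / "trials.csv", index=False, float_format=fmt)
    pd.DataFrame(
        [{"trial_id": e.trial_id, "actor_id": e.actor_id, "behavior": e.behavior,
          "onset_s": e.onset, "duration_s": e.duration}
         for e in ds.events if not e.synthetic_end], columns=_EVENT_COLS,
    ).to_csv(datadir / "events.csv", index=False, float_format=fmt)
    pd.DataFrame(
        [{"trial_id": o.trial_id, "female_id": o.female_id, "start_s": o.start,
          "stop_s": o.stop, "on_fungus": o.on_fungus} for o in ds.occupancy],
        columns=_OCC_COLS,
    ).to_csv(datadir / "occupancy.csv", index=False, float_format=fmt)


# ---------------------------------------------------------------------------
# bout segmentation

def segment_bouts(events: Sequence[BehaviorEvent],
                  gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> List[Bout]:
    """Split one trial's sorted event stream into interaction bouts.

    An explicit ``end`` event closes the current bout.  An inter-onset gap
    greater than ``gap_threshold`` also closes it, in which case a
    zero-duration synthetic ``end`` (flagged ``synthetic_end=True``) is
    appended so every terminated bout ends in ``end``.  The trailing bout,
    if any, is closed the same way.

    Raises
    ------
    EventLogError
        If events span several trials or are not sorted by onset.
    """
    events = list(events)
    if not events:
        return []
    trial_ids = {e.trial_id for e in events}
    if len(trial_ids) > 1:
        raise EventLogError(f"events span multiple trials: {sorted(trial_ids)}")
    onsets = [e.onset for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise EventLogError("events must be sorted by onset (use sort_events)")

    trial_id = events[0].trial_id
    bouts: List[Bout] = []
    current: List[BehaviorEvent] = []

    def close(synthetic: bool) -> None:
        nonlocal current
        if not current:
            return
        evs = current
        if synthetic:
            last = evs[-1]
            evs = evs + [BehaviorEvent(trial_id, last.actor_id, "end",
                                       last.offset, 0.0, synthetic_end=True)]
        bouts.append(Bout(trial_id, tuple(evs), terminated=True))
        current = []

    prev: Optional[BehaviorEvent] = None
    for ev in events:
        if prev is not None and current and ev.onset - prev.onset > gap_threshold:
            close(synthetic=True)
        if ev.behavior == "end":
            if not current:
                # an end with no open bout: keep it as its own degenerate bout
                current = [ev]
                bouts.append(Bout(trial_id, tuple(current), terminated=True))
                current = []
            else:
                current.append(ev)
                bouts.append(Bout(trial_id, tuple(current), terminated=True))
                current = []
        else:
            current.append(ev)
        prev = ev
    close(synthetic=True)
    return bouts


def interaction_time_fraction(bouts: Sequence[Bout], trial_duration: float) -> float:
    """Fraction of the trial spent interacting.

    The union of all event time spans within the bouts, divided by the
    trial duration; overlapping spans are counted once.
    """
    if trial_duration <= 0:
        raise EventLogError("trial_duration must be positive")
    spans = [(ev.onset, ev.offset) for b in bouts for ev in b.events if ev.duration > 0]
    return total_length(spans) / trial_duration


__all__ = [
    "BEHAVIOR_VOCAB", "PHYSICAL_BEHAVIORS", "SOURCE_STATES", "TARGET_STATES",
    "DEFAULT_TRIAL_DURATION", "DEFAULT_SNAPSHOT_INTERVAL", "DEFAULT_GAP_THRESHOLD",
    "EventLogError", "SchemaError", "VocabularyError", "IntegrityError",
    "FemaleRecord", "TrialRecord", "BehaviorEvent", "OccupancyInterval", "Bout",
    "Dataset", "sort_events", "validate_dataset", "read_event_log",
    "write_event_log", "segment_bouts", "interaction_time_fraction",
]
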