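"""Event-log reading, validation, bout segmentation, interaction time."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethoseq import synthetic_data as sd
from ethoseq.event_log import (BehaviorEvent, Bout, Dataset, EventLogError,
                               FemaleRecord, IntegrityError, SchemaError,
                               TrialRecord, VocabularyError,
                               interaction_time_fraction, read_event_log,
                               segment_bouts, sort_events, validate_dataset,
                               write_event_log)


def _toy_dir(tmp_path, events_rows):
    (tmp_path / "females.csv").write_text(
        "female_id,elytra_length_mm,paint\nA,9.1,white\nB,8.7,black\n")
    (tmp_path / "trials.csv").write_text(
        "trial_id,female_white,female_black,trial_round,trial_duration_s\n"
        "T1,A,B,1,14400\n")
    (tmp_path / "events.csv").write_text(
        "trial_id,actor_id,behavior,onset_s,duration_s\n" + events_rows)
    return tmp_path


class TestReadEventLog:
    def test_minimal_well_formed_file(self, tmp_path):
        d = _toy_dir(tmp_path, "T1,A,touch,10,5\nT1,A,bump,20,5\nT1,A,end,30,0\n")
        ds = read_event_log(d)
        assert len(ds.events) == 3
        assert len(ds.trials) == 1
        assert len(ds.females) == 2

    def test_unknown_behavior_label_rejected(self, tmp_path):
        d = _toy_dir(tmp_path, "T1,A,bite,10,5\n")
        with pytest.raises(VocabularyError, match="bite"):
            read_event_log(d)

    def test_onset_beyond_trial_duration_rejected(self, tmp_path):
        d = _toy_dir(tmp_path, "T1,A,touch,15000,5\n")
        with pytest.raises(IntegrityError, match="onset"):
            read_event_log(d)

    def test_missing_column_names_the_column(self, tmp_path):
        d = _toy_dir(tmp_path, "T1,A,touch,10,5\n")
        (d / "events.csv").write_text("trial_id,actor_id,behavior,onset_s\n")
        with pytest.raises(SchemaError, match="duration_s"):
            read_event_log(d)

    def test_event_referencing_unknown_trial_rejected(self, tmp_path):
        d = _toy_dir(tmp_path, "T9,A,touch,10,5\n")
        with pytest.raises(IntegrityError, match="T9"):
            read_event_log(d)

    def test_round_trip_is_lossless(self, tmp_path):
        ds, _ = sd.simulate_dataset(sd.null_female_config(seed=2, n_females=8))
        write_event_log(ds, tmp_path / "out")
        back = read_event_log(tmp_path / "out")
        assert [f for f in back.females] == [f for f in ds.females]
        assert back.trials == ds.trials
        assert back.events == [e for e in ds.events if not e.synthetic_end]
        assert back.occupancy == ds.occupancy


class TestValidation:
    def test_duplicate_round_appearance_flagged(self):
        fem = [FemaleRecord(i, 9.0, p) for i, p in
               [("A", "white"), ("B", "black"), ("C", "black")]]
        trials = [TrialRecord("T1", "A", "B", 1), TrialRecord("T2", "A", "C", 1)]
        problems = validate_dataset(Dataset(fem, trials, []))
        assert any("two trials of round 1" in p for p in problems)

    def test_off_grid_onset_flagged_when_interval_declared(self):
        fem = [FemaleRecord("A", 9.0, "white"), FemaleRecord("B", 8.5, "black")]
        trials = [TrialRecord("T1", "A", "B", 1)]
        ev = [BehaviorEvent("T1", "A", "touch", 7.0, 5.0)]
        problems = validate_dataset(Dataset(fem, trials, ev, snapshot_interval=5.0))
        assert any("snapshot grid" in p for p in problems)


class TestSegmentBouts:
    def _ev(self, behavior, onset, dur=5.0):
        return BehaviorEvent("T1", "A", behavior, onset, dur)

    def test_explicit_end_closes_single_bout(self):
        evs = [self._ev("touch", 10), self._ev("bump", 20),
               self._ev("end", 30, 0.0)]
        bouts = segment_bouts(evs, gap_threshold=60)
        assert len(bouts) == 1
        assert bouts[0].behaviors == ("touch", "bump", "end")
        assert bouts[0].terminated

    def test_gap_splits_and_appends_synthetic_ends(self):
        evs = [self._ev("touch", 10), self._ev("touch", 500)]
        bouts = segment_bouts(evs, gap_threshold=60)
        assert len(bouts) == 2
        for b in bouts:
            assert b.events[-1].behavior == "end"
            assert b.events[-1].synthetic_end

    def test_unsorted_input_rejected(self):
        evs = [self._ev("touch", 20), self._ev("bump", 10)]
        with pytest.raises(EventLogError, match="sorted"):
            segment_bouts(evs)

    def test_empty_input_gives_empty_list(self):
        assert segment_bouts([]) == []

    def test_idempotent_on_own_flattened_output(self):
        rng = np.random.default_rng(0)
        onsets = np.cumsum(rng.integers(1, 20, size=60)) * 5.0
        behaviors = rng.choice(["touch", "bump", "end"], size=60, p=[0.4, 0.4, 0.2])
        evs = sort_events([BehaviorEvent("T1", "A", b, float(o),
                                         0.0 if b == "end" else 5.0)
                           for b, o in zip(behaviors, onsets)])
        bouts = segment_bouts(evs, gap_threshold=30)
        flat = [ev for b in bouts for ev in b.events]
        again = segment_bouts(flat, gap_threshold=30)
        assert [b.behaviors for b in again] == [b.behaviors for b in bouts]

    @given(st.lists(st.tuples(st.integers(1, 40),
                              st.sampled_from(["touch", "bump", "proximity", "end"])),
                    min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bout_count_matches_independent_closure_scan(self, steps):
        gap = 30.0
        onset = 0.0
        evs = []
        for delta, behavior in steps:
            onset += delta * 5.0
            evs.append(BehaviorEvent("T1", "A", behavior, onset,
                                     0.0 if behavior == "end" else 5.0))
        bouts = segment_bouts(evs, gap_threshold=gap)
        # oracle: linear re-scan counting closures (ends and long gaps)
        n_expected = 0
        open_bout = False
        prev = None
        for ev in evs:
            if open_bout and prev is not None and ev.onset - prev > gap:
                n_expected += 1
                open_bout = False
            if ev.behavior == "end":
                n_expected += 1
                open_bout = False
            else:
                open_bout = True
            prev = ev.onset
        if open_bout:
            n_expected += 1
        assert len(bouts) == n_expected
        # union of (non-synthetic) bout events = input events
        flat = [ev for b in bouts for ev in b.events if not ev.synthetic_end]
        assert flat == evs


class TestInteractionTime:
    def test_no_bouts_is_zero(self):
        assert interaction_time_fraction([], 14400) == 0.0

    def test_single_span_arithmetic(self):
        b = Bout("T1", (BehaviorEvent("T1", "A", "touch", 0.0, 1440.0),), False)
        assert interaction_time_fraction([b], 14400) == pytest.approx(0.10)

    def test_overlapping_spans_counted_once(self):
        evs = (BehaviorEvent("T1", "A", "touch", 0.0, 100.0),
               BehaviorEvent("T1", "B", "bump", 50.0, 100.0))
        b = Bout("T1", evs, False)
        assert interaction_time_fraction([b], 14400) == pytest.approx(150 / 14400)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(EventLogError):
            interaction_time_fraction([], 0)

    @given(st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 300)),
                    min_size=0, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_one_second_grid_oracle(self, spans):
        T = 3600
        evs = tuple(BehaviorEvent("T1", "A", "touch", float(s), float(d))
                    for s, d in spans if s + d <= T)
        bouts = [Bout("T1", evs, False)] if evs else []
        frac = interaction_time_fraction(bouts, T)
        grid = np.zeros(T, dtype=bool)
        for s, d in spans:
            if s + d <= T:
                grid[s:s + d] = True
        assert frac == pytest.approx(grid.sum() / T, abs=1e-12)

    def test_monotone_in_added_events(self):
        evs = [BehaviorEvent("T1", "A", "touch", 100.0 * i, 50.0) for i in range(10)]
        prev = 0.0
        for k in range(1, 11):
            b = Bout("T1", tuple(evs[:k]), False)
            cur = interaction_time_fraction([b], 14400)
            assert cur >= prev
            prev = cur
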