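import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeits import (EventConfig, detect_blinks, detect_events,
                     detect_fixations_idt, derive_saccades)
from gazeits.events import Blink, merge_adjacent_fixations

from conftest import make_trial


def _dispersion(x, y):
    return (x.max() - x.min()) + (y.max() - y.min())


class TestBlinkDetection:
    def test_60ms_invalid_run_at_250hz_is_one_blink(self):
        valid = np.ones(1000, dtype=bool)
        valid[300:315] = False  # 15 samples = 60 ms >= 50 ms
        trial = make_trial(np.zeros(1000), np.zeros(1000), valid=valid)
        blinks = detect_blinks(trial)
        assert len(blinks) == 1
        assert blinks[0].duration == pytest.approx(0.060)

    def test_40ms_run_is_below_threshold(self):
        valid = np.ones(1000, dtype=bool)
        valid[300:310] = False  # 10 samples = 40 ms < 50 ms
        trial = make_trial(np.zeros(1000), np.zeros(1000), valid=valid)
        assert detect_blinks(trial) == []

    def test_fully_valid_trial_has_no_blinks(self, constant_gaze_trial):
        assert detect_blinks(constant_gaze_trial) == []

    def test_blinks_sorted_and_disjoint(self):
        valid = np.ones(2000, dtype=bool)
        valid[100:150] = False
        valid[900:960] = False
        valid[1500:1540] = False
        trial = make_trial(np.zeros(2000), np.zeros(2000), valid=valid)
        blinks = detect_blinks(trial)
        assert len(blinks) == 3
        for a, b in zip(blinks, blinks[1:]):
            assert a.offset <= b.onset


class TestIDT:
    def test_constant_gaze_is_single_full_fixation(self, constant_gaze_trial):
        fix = detect_fixations_idt(constant_gaze_trial)
        assert len(fix) == 1
        assert fix[0].onset == 0.0
        assert fix[0].offset == pytest.approx(2.0)
        assert fix[0].centroid_x == pytest.approx(3.0)
        assert fix[0].centroid_y == pytest.approx(-1.0)

    def test_two_planted_clusters_recovered_with_centroids(self):
        rng = np.random.default_rng(0)
        n = 75  # 300 ms at 250 Hz
        x = np.concatenate([rng.normal(0, 0.1, n), rng.normal(5, 0.1, n)])
        y = np.concatenate([rng.normal(0, 0.1, n), rng.normal(0, 0.1, n)])
        trial = make_trial(x, y)
        fix = detect_events(trial).fixations
        assert len(fix) == 2
        assert fix[0].centroid_x == pytest.approx(0.0, abs=0.1)
        assert fix[1].centroid_x == pytest.approx(5.0, abs=0.1)

    def test_fast_linear_drift_yields_no_fixations(self):
        # 30 deg/s crosses 1 degree inside any 100-ms window
        t = np.arange(1000) / 250.0
        trial = make_trial(30.0 * t, np.zeros(1000))
        assert detect_fixations_idt(trial) == []

    def test_every_fixation_respects_dispersion_threshold(self,
                                                          small_dataset):
        cfg = EventConfig()
        for trial in small_dataset.trials[:10]:
            rec = trial.recording
            gx, gy = rec.mean_gaze()
            half = 0.5 / rec.sampling_rate
            for f in detect_fixations_idt(trial, cfg):
                # offset convention: last member sample's time + one period
                m = (rec.timestamps >= f.onset) \
                    & (rec.timestamps < f.offset - half) & rec.valid
                assert _dispersion(gx[m], gy[m]) <= \
                    cfg.dispersion_threshold_deg + 1e-9

    def test_unit_error_for_pixel_gaze(self, constant_gaze_trial):
        constant_gaze_trial.recording.units = "px"
        with pytest.raises(Exception, match="degree"):
            detect_fixations_idt(constant_gaze_trial)


class TestSaccades:
    def test_clean_jump_gives_one_saccade_with_amplitude(self):
        n = 100
        ramp = np.linspace(0, 5, 10)
        x = np.concatenate([np.zeros(n), ramp, np.full(n, 5.0)])
        trial = make_trial(x, np.zeros(len(x)))
        fix = detect_fixations_idt(trial)
        sacc = derive_saccades(fix, trial)
        assert len(sacc) == 1
        assert sacc[0].amplitude == pytest.approx(5.0, rel=0.1)
        assert sacc[0].peak_velocity > 0

    def test_single_fixation_no_saccades(self, constant_gaze_trial):
        fix = detect_fixations_idt(constant_gaze_trial)
        assert derive_saccades(fix, constant_gaze_trial) == []

    def test_gap_inside_blink_produces_no_saccade(self):
        n = 100
        valid = np.ones(2 * n + 20, dtype=bool)
        valid[n:n + 20] = False  # 80 ms blink while gaze "jumps"
        x = np.concatenate([np.zeros(n), np.zeros(20), np.full(n, 5.0)])
        trial = make_trial(x, np.zeros(len(x)), valid=valid)
        ev = detect_events(trial)
        assert len(ev.blinks) == 1
        assert len(ev.fixations) == 2
        assert ev.saccades == []


class TestPlantedRecovery:
    def test_fixation_counts_recovered_on_synthetic_trials(self,
                                                           small_dataset):
        ok = 0
        for trial in small_dataset.trials:
            ev = detect_events(trial)
            planted = small_dataset.truth_for(trial.trial_id, "fixation")
            ok += len(ev.fixations) == len(planted)
        assert ok / len(small_dataset.trials) >= 0.95

    def test_long_blinks_recovered_exactly(self, small_dataset):
        for trial in small_dataset.trials:
            det = [b for b in detect_events(trial).blinks
                   if b.duration >= 0.06]
            planted = [e for e in small_dataset.truth_for(trial.trial_id,
                                                          "blink")
                       if e.offset_s - e.onset_s >= 0.06]
            assert len(det) == len(planted)

    def test_no_fixation_overlaps_a_blink(self, small_dataset):
        for trial in small_dataset.trials[:10]:
            ev = detect_events(trial)
            for f in ev.fixations:
                for b in ev.blinks:
                    assert f.offset <= b.onset + 1e-9 \
                        or f.onset >= b.offset - 1e-9


class TestMerge:
    def test_adjacent_same_place_pieces_merge(self):
        from gazeits.events import Fixation
        a = Fixation(0.0, 0.1, 1.0, 1.0)
        b = Fixation(0.1, 0.3, 1.1, 1.0)
        merged = merge_adjacent_fixations([a, b])
        assert len(merged) == 1
        assert merged[0].onset == 0.0 and merged[0].offset == 0.3
        # duration-weighted centroid
        assert merged[0].centroid_x == pytest.approx((1.0 * .1 + 1.1 * .2) / .3)

    def test_distant_fixations_not_merged(self):
        from gazeits.events import Fixation
        a = Fixation(0.0, 0.1, 0.0, 0.0)
        b = Fixation(0.12, 0.3, 4.0, 0.0)
        assert len(merge_adjacent_fixations([a, b])) == 2


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_fuzz_event_lists_sorted_and_in_bounds(seed):
    """Arbitrary noise input: events sorted, disjoint, inside the trial."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(100, 600))
    x = rng.normal(0, rng.uniform(0.05, 5.0), n).cumsum() * 0.1
    y = rng.normal(0, rng.uniform(0.05, 5.0), n).cumsum() * 0.1
    valid = rng.uniform(size=n) > 0.05
    trial = make_trial(x, y, fs=120, valid=valid)
    ev = detect_events(trial)
    duration = trial.recording.duration
    for seq in (ev.blinks, ev.fixations, ev.saccades):
        for e in seq:
            assert 0.0 <= e.onset < e.offset <= duration + 1e-9
        for a, b in zip(seq, seq[1:]):
            assert a.offset <= b.onset + 1e-9
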