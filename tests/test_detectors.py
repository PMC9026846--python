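import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swdscore import (IntervalSet, Recording, SWDetectorParams,
                      SleepDetectorParams, SWDEvent, compute_thresholds,
                      detect_sleep_wake, detect_swd, hysteresis_detect,
                      score_recording, swd_characteristic, validate_swd)
from swdscore.synthetic import SimulationConfig, evaluate, simulate
from conftest import tone


def hysteresis_oracle(series, up, down):
    """Naive sample-by-sample state machine (independent of the
    vectorised implementation)."""
    events, start, inside = [], None, False
    for i, v in enumerate(series):
        if not inside and v > up:
            inside, start = True, i
        elif inside and v < down:
            events.append((start, i))
            inside = False
    if inside:
        events.append((start, len(series)))
    return events


class TestHysteresis:
    def test_constant_series_below_threshold_yields_nothing(self):
        series = np.full(100, 10.0)
        assert hysteresis_detect(series, 17.5, 15.5) == []

    def test_single_pulse(self):
        series = np.array([0.0, 0.0, 2.0, 2.0, 0.0, 0.0])
        assert hysteresis_detect(series, 1.5, 1.0) == [(2, 4)]

    def test_open_event_closed_at_end(self):
        series = np.array([0.0, 2.0, 2.0, 2.0])
        assert hysteresis_detect(series, 1.5, 1.0) == [(1, 4)]

    def test_up_below_down_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_detect(np.zeros(4), 1.0, 2.0)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        # piecewise-constant levels make threshold crossings frequent
        series = rng.choice([0.0, 0.5, 1.0, 1.5, 2.0],
                            size=n)[np.repeat(np.arange(n),
                                              rng.integers(1, 4, size=n))]
        up = float(rng.uniform(0.5, 2.0))
        down = float(rng.uniform(0.0, up))
        assert hysteresis_detect(series, up, down) == \
            hysteresis_oracle(series, up, down)


class TestThresholds:
    def test_constant_series_defaults(self):
        assert compute_thresholds(np.full(50, 10.0), 1.75, 1.55) == \
            pytest.approx((17.5, 15.5))

    def test_zero_series(self):
        assert compute_thresholds(np.zeros(10), 1.75, 1.55) == (0.0, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.random(100)
        u1, d1 = compute_thresholds(x, 1.75, 1.55)
        u2, d2 = compute_thresholds(2.0 * x, 1.75, 1.55)
        assert (u2, d2) == pytest.approx((2 * u1, 2 * d1))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            compute_thresholds(np.array([]), 1.75, 1.55)


class TestSWDCharacteristic:
    def test_spike_band_tone_dominates_delta_tone(self):
        hi = swd_characteristic(tone(16.5, duration_s=30, n_channels=3))
        lo = swd_characteristic(tone(3.5, duration_s=30, n_channels=3))
        interior = slice(len(hi) // 4, 3 * len(hi) // 4)
        assert hi[interior].mean() > 50.0 * lo[interior].mean()

    def test_identical_channels_equal_single_channel(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12000)
        r3 = Recording(np.tile(x, (3, 1)), fs=400.0)
        r1 = Recording(x[None, :], fs=400.0)
        np.testing.assert_allclose(swd_characteristic(r3),
                                   swd_characteristic(r1), rtol=1e-9)

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(1)
        rec = Recording(rng.normal(size=(2, 12000)), fs=400.0)
        c1 = swd_characteristic(rec)
        c2 = swd_characteristic(rec.scaled(5.0))
        np.testing.assert_allclose(c1, c2, rtol=1e-9)


def _spike_train_recording(ratio=8.0, fs=400.0, seed=0):
    """Noise baseline with an embedded periodic spike train whose peaks
    are ``ratio`` times the baseline peak level."""
    rng = np.random.default_rng(seed)
    n = int(30 * fs)
    x = rng.normal(size=n)
    t = np.arange(n) / fs
    ev = (t >= 15.0) & (t < 20.0)
    # baseline local-extrema mean of white noise is ~0.85 sd; scale spikes
    # relative to that empirical peak level
    base_peak = 0.85
    cycle = t * 9.0
    frac = cycle - np.floor(cycle)
    u = (frac - 0.5) / (0.008 * 9.0)
    x[ev] = ratio * base_peak * (-u * np.exp(0.5 * (1 - u * u)))[ev]
    return Recording(x[None, :], fs), (15.0, 20.0)


class TestValidateSWD:
    def test_large_spike_train_accepted(self):
        # spike peaks ~8x baseline peaks -> Xmax + Xmin far above 6
        rec, event = _spike_train_recording(ratio=8.0)
        ev = validate_swd(rec, event)
        assert ev.validated and ev.valid
        assert ev.x_max + ev.x_min > 6.0

    def test_event_identical_to_baseline_invalid(self):
        # statistically identical noise: both ratios ~1, sum ~2 < 6
        rng = np.random.default_rng(5)
        rec = Recording(rng.normal(size=(1, 12000)), fs=400.0)
        ev = validate_swd(rec, (15.0, 20.0))
        assert not ev.valid
        assert ev.x_max + ev.x_min == pytest.approx(2.0, abs=0.75)

    def test_boundary_sum_equal_to_criterion_is_invalid(self):
        # the criterion is a strict inequality
        rec, event = _spike_train_recording(ratio=8.0)
        ev = validate_swd(rec, event)
        exact = SWDetectorParams(criterion_threshold=ev.x_max + ev.x_min)
        assert not validate_swd(rec, event, exact).valid

    def test_baseline_outside_recording_skips_validation(self):
        rec, _ = _spike_train_recording()
        ev = validate_swd(rec, (2.0, 6.0))
        assert ev.valid and not ev.validated

    def test_flat_signal_handled_without_crash(self):
        rec = Recording(np.zeros((1, 12000)), fs=400.0)
        ev = validate_swd(rec, (15.0, 20.0))
        assert ev.validated and not ev.valid


class TestDetectSWD:
    def test_all_injected_events_found_with_overlap(self, short_recording):
        rec, truth = short_recording
        events = detect_swd(rec)
        true_swd = truth.for_label("SWD")
        assert len(events) == len(true_swd)
        for ev, tr in zip(events, true_swd):
            inter = min(ev.t_down, tr.offset_s) - max(ev.t_up, tr.onset_s)
            assert inter >= 0.8 * tr.duration_s

    def test_no_injected_events_no_detections(self, swd_free_recording):
        rec, _ = swd_free_recording
        assert detect_swd(rec) == []

    def test_events_sorted_valid_and_long_enough(self, short_recording):
        rec, _ = short_recording
        events = detect_swd(rec)
        assert all(ev.valid for ev in events)
        assert all(ev.duration_s >= 2.0 for ev in events)
        assert all(a.t_down <= b.t_up for a, b in zip(events, events[1:]))

    def test_sinusoidal_artifact_rejected_by_criterion(self):
        # an oscillatory artifact crosses the energy threshold but lacks
        # spike-wave morphology: the extrema criterion must reject it
        cfg = SimulationConfig(schedule=[("BS", 90.0)], seed=3,
                               artifacts=[(40.0, 4.0)])
        rec, _ = simulate(cfg)
        accepted, rejected = detect_swd(rec, return_rejected=True)
        overlapping = [e for e in rejected if e.t_up < 44.0 and e.t_down > 40.0]
        assert len(overlapping) == 1
        assert not any(e.t_up < 44.0 and e.t_down > 40.0 for e in accepted)


class TestDetectSleepWake:
    def test_alternating_schedule_boundaries_within_5s(self):
        schedule = [("AW", 60.0), ("BS", 60.0)] * 3
        rec, truth = simulate(SimulationConfig(schedule=schedule, seed=9))
        states = detect_sleep_wake(rec)
        assert states.tiles(rec.duration_s)
        det = {lab: states.for_label(lab) for lab in ("AW", "BS")}
        for lab in ("AW", "BS"):
            tru = truth.for_label(lab)
            assert len(det[lab]) == len(tru)
            for d, t in zip(det[lab], tru):
                assert abs(d.onset_s - t.onset_s) <= 5.0
                assert abs(d.offset_s - t.offset_s) <= 5.0

    def test_all_nrem_recording_is_single_bs_interval(self):
        rec, _ = simulate(SimulationConfig(schedule=[("BS", 120.0)], seed=2))
        states = detect_sleep_wake(
            rec, params=SleepDetectorParams(bs_up_mult=0.95,
                                            bs_down_mult=0.7))
        assert [iv.label for iv in states] == ["BS"]
        assert states.tiles(rec.duration_s)

    def test_partition_property(self, short_recording):
        rec, _ = short_recording
        hypnogram, _ = score_recording(rec)
        assert hypnogram.tiles(rec.duration_s)
        assert hypnogram.labels() <= {"AW", "BS", "SWD", "MA"}


class TestScaleInvariance:
    def test_detections_unchanged_under_amplitude_scaling(self,
                                                          short_recording):
        # every decision is ratio-based; a gain change (x7.3) must not
        # move any boundary by more than one sample
        rec, _ = short_recording
        h1, e1 = score_recording(rec)
        h2, e2 = score_recording(rec.scaled(7.3))
        tol = 1.0 / rec.fs + 1e-12
        assert len(e1) == len(e2)
        for a, b in zip(e1, e2):
            assert abs(a.t_up - b.t_up) <= tol
            assert abs(a.t_down - b.t_down) <= tol
            assert a.valid == b.valid
        assert len(h1) == len(h2)
        for a, b in zip(h1, h2):
            assert a.label == b.label
            assert abs(a.onset_s - b.onset_s) <= tol
            assert abs(a.offset_s - b.offset_s) <= tol
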