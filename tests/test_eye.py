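"""Blink masking, trial segmentation, microsaccade detection, summaries."""

import numpy as np
import pandas as pd
import pytest

from vplearn import synth
from vplearn.eye import (
    Microsaccade,
    Segment,
    detect_microsaccades,
    fixation_variability,
    main_sequence,
    mask_blinks,
    ms_percentage,
    ms_rate,
    segment_trials,
)


def flat_trace(n=3000, trial_id=0):
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "t_ms": np.arange(n),
            "x_dva": 0.0,
            "y_dva": 0.0,
            "valid": True,
        }
    )


class TestMaskBlinks:
    def test_margins_around_blink(self):
        tr = flat_trace()
        tr.loc[(tr.t_ms >= 500) & (tr.t_ms <= 600), "valid"] = False
        out = mask_blinks(tr)
        t = out["t_ms"].to_numpy()
        invalid = ~out["valid"].to_numpy()
        assert invalid[(t >= 400) & (t <= 750)].all()
        assert out.loc[t == 399, "valid"].item()
        assert out.loc[t == 751, "valid"].item()

    def test_no_blinks_unchanged(self):
        tr = flat_trace()
        out = mask_blinks(tr)
        assert out["valid"].all()

    def test_adjacent_blinks_merge_into_one_run(self):
        tr = flat_trace()
        tr.loc[(tr.t_ms >= 500) & (tr.t_ms <= 520), "valid"] = False
        tr.loc[(tr.t_ms >= 600) & (tr.t_ms <= 620), "valid"] = False
        out = mask_blinks(tr)
        t = out["t_ms"].to_numpy()
        # gap between the two extended windows is fully covered
        assert (~out["valid"].to_numpy()[(t >= 400) & (t <= 770)]).all()

    def test_idempotent(self):
        tr = flat_trace()
        tr.loc[(tr.t_ms >= 500) & (tr.t_ms <= 600), "valid"] = False
        once = mask_blinks(tr)
        twice = mask_blinks(once)
        pd.testing.assert_frame_equal(once, twice)


def markers_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "ref_onset_ms",
            "ref_offset_ms",
            "test_onset_ms",
            "test_offset_ms",
            "fix_x_dva",
            "fix_y_dva",
        ],
    )


class TestSegmentation:
    def test_window_arithmetic(self):
        tr = flat_trace(n=3000)
        mk = markers_frame([(0, 1000, 1092, 2092, 2184, 0.0, 0.0)])
        segs, skipped = segment_trials(tr, mk)
        assert not skipped
        t = segs[0].data["t_ms"]
        assert t.iloc[0] == 800 and t.iloc[-1] == 2534

    def test_blink_trial_flagged_invalid(self):
        tr = flat_trace(n=3000)
        tr.loc[(tr.t_ms >= 1200) & (tr.t_ms <= 1300), "valid"] = False
        tr = mask_blinks(tr)
        mk = markers_frame([(0, 1000, 1092, 2092, 2184, 0.0, 0.0)])
        segs, _ = segment_trials(tr, mk)
        assert segs[0].has_blink

    def test_missing_markers_skip_with_partition_preserved(self):
        tr = pd.concat([flat_trace(trial_id=0), flat_trace(trial_id=1)])
        mk = markers_frame([(0, 1000, 1092, 2092, 2184, 0.0, 0.0)])
        with pytest.warns(UserWarning, match="missing event markers"):
            segs, skipped = segment_trials(tr, mk)
        assert len(segs) + len(skipped) == 2
        assert skipped == [1]


class TestDetector:
    def test_single_injected_saccade_recovered(self):
        spec = synth.TraceSpec(
            n_trials=1, ms_rate_hz=0.0, blink_prob=0.0, seed=4, noise_sd=0.005
        )
        rng = np.random.default_rng(4)
        trace, markers, _ = synth.simulate_trace(spec, rng=rng)
        x = trace["x_dva"].to_numpy().copy()
        onset, dur, amp = 900, 20, 0.5
        prof = amp * (
            10 * np.linspace(0, 1, dur + 1) ** 3
            - 15 * np.linspace(0, 1, dur + 1) ** 4
            + 6 * np.linspace(0, 1, dur + 1) ** 5
        )
        x[onset : onset + dur + 1] += prof
        x[onset + dur + 1 :] += amp
        trace["x_dva"] = x
        events = detect_microsaccades(trace)
        assert len(events) == 1
        assert abs(events[0].onset_ms - onset) <= 5
        assert events[0].amplitude_dva == pytest.approx(amp, abs=0.1)

    def test_large_saccade_discarded(self):
        spec = synth.TraceSpec(n_trials=1, ms_rate_hz=0.0, blink_prob=0.0, seed=4)
        trace, _, _ = synth.simulate_trace(spec, rng=np.random.default_rng(4))
        x = trace["x_dva"].to_numpy().copy()
        tau = np.linspace(0, 1, 21)
        x[900:921] += 1.2 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        x[921:] += 1.2
        trace["x_dva"] = x
        assert detect_microsaccades(trace) == []

    def test_close_events_merge(self):
        spec = synth.TraceSpec(n_trials=1, ms_rate_hz=0.0, blink_prob=0.0, seed=4)
        trace, _, _ = synth.simulate_trace(spec, rng=np.random.default_rng(4))
        x = trace["x_dva"].to_numpy().copy()
        tau = np.linspace(0, 1, 16)
        prof = 0.3 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        for onset, sign in ((900, 1.0), (917, -1.0)):  # ~5 ms between speed runs
            x[onset : onset + 16] += sign * prof
            x[onset + 16 :] += sign * 0.3
        trace["x_dva"] = x
        events = detect_microsaccades(trace)
        assert len(events) == 1

    def test_all_invalid_trace_yields_nothing(self):
        tr = flat_trace(n=500)
        tr["valid"] = False
        assert detect_microsaccades(tr) == []

    def test_detected_events_satisfy_invariants(self, small_trace_set):
        trace, markers, _ = small_trace_set
        trace = mask_blinks(trace)
        segs, _ = segment_trials(trace, markers)
        last_off = {}
        for seg in segs:
            for ev in detect_microsaccades(seg):
                assert ev.offset_ms - ev.onset_ms + 1 >= 6
                assert ev.amplitude_dva < 1.0
                if ev.trial_id in last_off:
                    assert ev.onset_ms - last_off[ev.trial_id] >= 10
                last_off[ev.trial_id] = ev.offset_ms


class TestSummaries:
    def test_rate_forced_by_definition(self):
        assert ms_rate([1] * 100, 1000) == pytest.approx(1.0)
        assert ms_rate([0] * 10, 1500) == 0.0

    def test_rate_invariant_to_duplicating_trials(self):
        a = ms_rate([2, 0, 1], 1200)
        b = ms_rate([2, 0, 1, 2, 0, 1], 1200)
        assert a == pytest.approx(b)

    def test_percentage(self):
        assert ms_percentage(50, 200) == 0.25
        assert ms_percentage(0, 10) == 0.0
        with pytest.raises(ValueError):
            ms_percentage(5, 0)

    def test_window_counts_bounded_by_whole_trial(self, small_trace_set):
        trace, markers, _ = small_trace_set
        trace = mask_blinks(trace)
        segs, _ = segment_trials(trace, markers)
        n_ref = n_test = n_all = 0
        for seg in segs:
            evs = detect_microsaccades(seg)
            n_all += len(evs)
            m = seg.markers
            n_ref += sum(
                m["ref_onset_ms"] <= e.onset_ms <= m["ref_offset_ms"] for e in evs
            )
            n_test += sum(
                m["test_onset_ms"] <= e.onset_ms <= m["test_offset_ms"] for e in evs
            )
        assert n_ref + n_test <= n_all

    def test_fixation_variability_zero_for_identical_trials(self):
        segs = []
        for tid in range(3):
            d = flat_trace(n=1200, trial_id=tid)
            d["x_dva"] = 0.2
            segs.append(
                Segment(
                    tid,
                    d,
                    {
                        "ref_onset_ms": 400,
                        "ref_offset_ms": 492,
                        "test_onset_ms": 1092,
                        "test_offset_ms": 1184,
                    },
                    False,
                )
            )
        assert fixation_variability(segs) == pytest.approx(0.0)

    def test_two_trial_sample_sd(self):
        segs = []
        for tid, d_off in ((0, 0.1), (1, 0.3)):
            d = flat_trace(n=1200, trial_id=tid)
            d["x_dva"] = d_off
            segs.append(
                Segment(
                    tid,
                    d,
                    {
                        "ref_onset_ms": 400,
                        "ref_offset_ms": 492,
                        "test_onset_ms": 1092,
                        "test_offset_ms": 1184,
                    },
                    False,
                )
            )
        assert fixation_variability(segs) == pytest.approx(0.14142, abs=1e-4)

    def test_variability_increases_with_drift(self):
        out = []
        for drift in (0.001, 0.004):
            spec = synth.TraceSpec(
                n_trials=40, drift_step_sd=drift, ms_rate_hz=0.0,
                blink_prob=0.0, seed=9,
            )
            trace, markers, _ = synth.simulate_trace(spec, rng=np.random.default_rng(9))
            segs, _ = segment_trials(mask_blinks(trace), markers)
            out.append(fixation_variability(segs))
        assert out[1] > out[0]

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError):
            fixation_variability([])


class TestMainSequence:
    def test_linear_relation_recovered(self, small_trace_set, rng):
        trace, markers, _ = small_trace_set
        segs, _ = segment_trials(mask_blinks(trace), markers)
        events = [e for s in segs for e in detect_microsaccades(s)]
        assert len(events) >= 10
        res = main_sequence(events)
        assert res.r > 0.9

    def test_constant_amplitude_rejected(self):
        events = [
            Microsaccade(0, i * 100, i * 100 + 10, 0.5, 40.0 + i) for i in range(6)
        ]
        with pytest.raises(ValueError):
            main_sequence(events)

    def test_invariant_to_unit_rescaling(self):
        amps = [0.2, 0.3, 0.5, 0.6, 0.8]
        vels = [18.0, 33.0, 48.0, 55.0, 90.0]
        ev1 = [Microsaccade(0, i * 100, i * 100 + 10, a, v)
               for i, (a, v) in enumerate(zip(amps, vels))]
        ev2 = [Microsaccade(0, i * 100, i * 100 + 10, a, v * 60)
               for i, (a, v) in enumerate(zip(amps, vels))]
        assert main_sequence(ev1).r == pytest.approx(main_sequence(ev2).r)
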