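import numpy as np
import pytest

from nirstate import (
    ChannelMontage,
    Chronogram,
    EventSchedule,
    Recording,
    Trial,
    average_active_channels,
    detect_crossovers,
    latency_analysis,
    read_chronogram,
    score_chronogram,
    transition_times,
    truth_chronogram,
    write_chronogram,
)


def chron_from_states(states, fs=2.0, t0=0.0):
    return Chronogram(fs=fs, states=np.asarray(states, dtype=bool), t0=t0)


def rec_from_rows(rows):
    rows = np.asarray(rows, dtype=float)
    m = ChannelMontage(channel_ids=tuple(range(1, len(rows) + 1)), excluded=frozenset())
    return Recording(fs=2.0, hbo2=rows, hhb=np.zeros_like(rows), montage=m)


class TestChannelAverage:
    def test_identical_channels_pass_through(self):
        s = np.array([1.0, -2.0, 3.0])
        rec = rec_from_rows([s, s, s])
        np.testing.assert_array_equal(average_active_channels(rec), s)

    def test_opposite_channels_cancel(self):
        v = np.array([0.5, -1.5, 2.5])
        rec = rec_from_rows([v, -v])
        np.testing.assert_array_equal(average_active_channels(rec), np.zeros(3))

    def test_matches_direct_summation(self, rng):
        rows = rng.standard_normal((14, 100))
        rec = rec_from_rows(rows)
        expected = np.array([sum(rows[c][t] for c in range(14)) / 14 for t in range(100)])
        np.testing.assert_allclose(average_active_channels(rec), expected, rtol=1e-12)

    def test_both_species_averages_28_series(self, rng):
        rows = rng.standard_normal((3, 10))
        m = ChannelMontage(channel_ids=(1, 2, 3), excluded=frozenset())
        rec = Recording(fs=2.0, hbo2=rows, hhb=2 * rows, montage=m)
        np.testing.assert_allclose(
            average_active_channels(rec, "both"), 1.5 * rows.mean(axis=0)
        )


class TestCrossoverDetection:
    def test_single_up_then_down_crossing(self):
        d = np.array([-1.0, -1.0, 1.0, 1.0, -1.0])
        chron = detect_crossovers(d, np.zeros(5))
        np.testing.assert_array_equal(chron.states, [False, False, True, True, False])

    def test_all_negative_difference_stays_off(self):
        chron = detect_crossovers(-np.ones(10), np.zeros(10))
        assert not chron.states.any()

    def test_exact_ties_never_trigger(self):
        chron = detect_crossovers(np.zeros(10), np.zeros(10))
        assert not chron.states.any()

    def test_transitions_alternate(self, rng):
        d = rng.standard_normal(500)
        chron = detect_crossovers(d, np.zeros(500))
        s = chron.states.astype(int)
        kinds = np.diff(s)[np.diff(s) != 0]
        assert np.all(kinds[:-1] + kinds[1:] == 0)  # +1/-1 strictly alternating

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_crossovers(np.zeros(5), np.zeros(4))


class TestScoring:
    def test_perfect_match_scores_one(self):
        c = chron_from_states([0, 1, 1, 0, 1, 0] * 10)
        score = score_chronogram(c, c, warmup_s=0)
        assert (score.accuracy, score.sensitivity, score.specificity) == (1.0, 1.0, 1.0)
        assert np.all(score.labels == "Correct")

    def test_always_on_estimate_against_half_on_truth(self):
        est = chron_from_states([1] * 100)
        truth = chron_from_states([1] * 50 + [0] * 50)
        score = score_chronogram(est, truth, warmup_s=0)
        assert score.accuracy == 0.5
        assert score.sensitivity == 1.0
        assert score.specificity == 0.0

    def test_matches_brute_force_confusion_matrix(self, rng):
        e = rng.integers(0, 2, 1000).astype(bool)
        t = rng.integers(0, 2, 1000).astype(bool)
        score = score_chronogram(chron_from_states(e), chron_from_states(t), warmup_s=0)
        tp = sum(1 for a, b in zip(e, t) if a and b)
        tn = sum(1 for a, b in zip(e, t) if not a and not b)
        fp = sum(1 for a, b in zip(e, t) if a and not b)
        fn = sum(1 for a, b in zip(e, t) if not a and b)
        assert score.accuracy == (tp + tn) / 1000
        assert score.sensitivity == tp / (tp + fn)
        assert score.specificity == tn / (tn + fp)

    def test_metrics_invariant_to_sample_order(self, rng):
        e = rng.integers(0, 2, 200).astype(bool)
        t = rng.integers(0, 2, 200).astype(bool)
        perm = rng.permutation(200)
        s1 = score_chronogram(chron_from_states(e), chron_from_states(t), warmup_s=0)
        s2 = score_chronogram(chron_from_states(e[perm]), chron_from_states(t[perm]),
                              warmup_s=0)
        assert (s1.accuracy, s1.sensitivity, s1.specificity) == (
            s2.accuracy, s2.sensitivity, s2.specificity)

    def test_warmup_excluded_from_tally(self):
        est = chron_from_states([1] * 36 + [0] * 64)   # wrong only during warm-up
        truth = chron_from_states([0] * 100)
        assert score_chronogram(est, truth, warmup_s=18.0).accuracy == 1.0
        assert score_chronogram(est, truth, warmup_s=0.0).accuracy == 0.64

    def test_shuffled_truth_accuracy_near_base_rate(self, rng):
        """Permutation sanity check: against label-shuffled truth the accuracy
        approaches the chance level p·q + (1-p)(1-q)."""
        est = chron_from_states(rng.random(5000) < 0.3)
        truth = chron_from_states(rng.random(5000) < 0.4)
        score = score_chronogram(est, truth, warmup_s=0)
        chance = 0.3 * 0.4 + 0.7 * 0.6
        assert abs(score.accuracy - chance) < 0.05


def schedule_with_onsets(onsets, loads=None):
    loads = loads or ["low"] * len(onsets)
    return EventSchedule([Trial(o, load) for o, load in zip(onsets, loads)])


def chron_with_on_periods(periods, n, fs=2.0):
    states = np.zeros(n, dtype=bool)
    for a, b in periods:
        states[int(a * fs):int(b * fs)] = True
    return Chronogram(fs=fs, states=states)


class TestLatencyAnalysis:
    def test_exact_transitions_give_zero_latency(self):
        onsets = [20.0, 80.0, 140.0]
        sched = schedule_with_onsets(onsets)
        est = chron_with_on_periods([(o, o + 11.0) for o in onsets], n=400)
        rep = latency_analysis(est, sched)
        np.testing.assert_array_equal(rep.onset_latencies_s, np.zeros(3))
        np.testing.assert_array_equal(rep.offset_latencies_s, np.zeros(3))
        assert rep.unmatched_onsets == 0

    def test_uniform_shift_appears_in_mean(self):
        onsets = [20.0, 80.0, 140.0]
        sched = schedule_with_onsets(onsets)
        est = chron_with_on_periods([(o + 2.0, o + 13.0) for o in onsets], n=400)
        rep = latency_analysis(est, sched)
        assert rep.onset_mean_s == pytest.approx(2.0)
        assert rep.offset_mean_s == pytest.approx(2.0)

    def test_out_of_window_transition_is_unmatched(self):
        sched = schedule_with_onsets([40.0])
        est = chron_with_on_periods([(10.0, 15.0)], n=200)  # 30 s early
        rep = latency_analysis(est, sched)
        assert rep.unmatched_onsets == 1
        assert len(rep.onset_latencies_s) == 0

    def test_jittered_transitions_match_exhaustive_search(self, rng):
        """Nearest-in-window matching agrees with a brute-force oracle."""
        onsets = np.arange(5) * 60.0 + 30.0
        jitter = rng.uniform(-6, 6, size=5)
        loads = ["low", "high", "high", "low", "low"]
        sched = schedule_with_onsets(list(onsets), loads)
        est = chron_with_on_periods(
            [(o + j, o + j + 11.0) for o, j in zip(onsets, jitter)], n=800
        )
        rep = latency_analysis(est, sched)

        on_times, _ = transition_times(est)
        expected = []
        for o in onsets:
            cands = [t for t in on_times if o - 10 <= t <= o + 15]
            best = min(cands, key=lambda t: (abs(t - o), t))
            expected.append(best - o)
        np.testing.assert_allclose(rep.onset_latencies_s, expected)
        # per-load split partitions the matched trials
        assert rep.per_load["low"]["n_matched"] + rep.per_load["high"]["n_matched"] == 5

    def test_schedule_beyond_recording_rejected(self):
        est = chron_with_on_periods([], n=100)  # 50 s long
        with pytest.raises(ValueError, match="span"):
            latency_analysis(est, schedule_with_onsets([80.0]))


class TestChronogramIo:
    def test_truth_chronogram_marks_message_windows(self):
        sched = schedule_with_onsets([10.0])
        truth = truth_chronogram(sched, n_samples=100)
        assert truth.states[20:42].all()
        assert truth.states.sum() == 22

    def test_csv_roundtrip(self, tmp_path, rng):
        c = chron_from_states(rng.integers(0, 2, 50))
        path = tmp_path / "chron.csv"
        write_chronogram(c, path)
        back = read_chronogram(path)
        np.testing.assert_array_equal(back.states, c.states)
        assert back.fs == c.fs
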