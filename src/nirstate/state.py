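"""Real-time mental-state estimation from MACD/signal-line crossovers.

The estimator is calibration-free: the MACD-filtered concentration series is
averaged over the active channels, a signal line (EMA of the MACD) is
computed, and a strict upward crossing of the MACD through the signal line
flags a task onset (state switches to *on-task*); a strict downward crossing
flags an offset.  Ground truth marks the operator *on-task* during message
reception, ``[onset, onset + message_dur)``.

Scoring follows the per-sample labelling Correct / FalsePositive /
FalseNegative; accuracy is the fraction correct, sensitivity the recall of
on-task samples and specificity the recall of not-on-task samples.  A
configurable warm-up (default N_long + N_signal = 36 samples = 18 s) is
excluded from scoring so filter initialisation does not enter the tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventSchedule, Recording

__all__ = [
    "Chronogram",
    "StateScore",
    "LatencyReport",
    "truth_chronogram",
    "average_active_channels",
    "detect_crossovers",
    "transition_times",
    "score_chronogram",
    "latency_analysis",
    "write_chronogram",
    "read_chronogram",
]

DEFAULT_WARMUP_S = 18.0  # (n_long + n_signal) samples at 2 Hz
DEFAULT_MATCH_WINDOW_S = (-10.0, 15.0)


@dataclass
class Chronogram:
    """Per-sample boolean state stream (True = on-task)."""

    fs: float
    states: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 1:
            raise ValueError("states must be 1-D")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.states)) / self.fs


@dataclass
class StateScore:
    accuracy: float
    sensitivity: float
    specificity: float
    labels: np.ndarray  # per sample: 'Correct' / 'FalsePositive' / 'FalseNegative'
    n_scored: int
    warmup_samples: int


@dataclass
class LatencyReport:
    """Signed onset/offset latencies per matched trial (negative = early)."""

    onset_latencies_s: np.ndarray
    offset_latencies_s: np.ndarray
    matched_trials: list[int]
    offset_matched_trials: list[int]
    unmatched_onsets: int
    onset_mean_s: float
    onset_se_s: float
    offset_mean_s: float
    offset_se_s: float
    per_load: dict = field(default_factory=dict)


def truth_chronogram(
    schedule: EventSchedule, n_samples: int, fs: float = 2.0, t0: float = 0.0
) -> Chronogram:
    """Ground-truth chronogram: on-task during each message-reception window."""
    states = np.zeros(n_samples, dtype=bool)
    for trial in schedule:
        i0 = int(round((trial.onset_s - t0) * fs))
        i1 = int(round((trial.onset_s + trial.message_dur_s - t0) * fs))
        if i0 < 0 or i1 > n_samples:
            raise ValueError("schedule outside recording span")
        states[i0:i1] = True
    return Chronogram(fs=fs, states=states, t0=t0)


def average_active_channels(rec: Recording, species: str = "hbo2") -> np.ndarray:
    """Per-sample arithmetic mean across active channels (and species if 'both')."""
    if rec.montage.n_active == 0:
        raise ValueError("no active channels to average")
    if species == "hbo2":
        data = rec.hbo2
    elif species == "hhb":
        data = rec.hhb
    elif species == "both":
        data = np.vstack([rec.hbo2, rec.hhb])
    else:
        raise ValueError(f"unknown species: {species!r}")
    return data.mean(axis=0)


def detect_crossovers(
    macd_avg: np.ndarray,
    signal: np.ndarray,
    fs: float = 2.0,
    t0: float = 0.0,
) -> Chronogram:
    """Crossover state machine on the MACD/signal-line difference.

    The initial state is not-on-task.  At sample n >= 1 the state switches to
    on-task when ``d`` crosses strictly upward (``d[n-1] <= 0 < d[n]``) and
    to not-on-task when it crosses strictly downward (``d[n-1] >= 0 > d[n]``),
    where ``d = macd - signal``.  Exact ties (d == 0) never trigger a
    transition, so a flat difference yields all not-on-task.
    """
    macd_avg = np.asarray(macd_avg, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if macd_avg.shape != signal.shape or macd_avg.ndim != 1:
        raise ValueError("macd and signal series must be 1-D and equal length")
    d = macd_avg - signal
    states = np.zeros(len(d), dtype=bool)
    on = False
    for n in range(1, len(d)):
        if d[n - 1] <= 0.0 and d[n] > 0.0:
            on = True
        elif d[n - 1] >= 0.0 and d[n] < 0.0:
            on = False
        states[n] = on
    return Chronogram(fs=fs, states=states, t0=t0)


def transition_times(chron: Chronogram) -> tuple[np.ndarray, np.ndarray]:
    """Times of False->True (onsets) and True->False (offsets) transitions."""
    s = chron.states
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    onsets = chron.t0 + change[s[change]] / chron.fs
    offsets = chron.t0 + change[~s[change]] / chron.fs
    return onsets, offsets


def score_chronogram(
    est: Chronogram, truth: Chronogram, warmup_s: float = DEFAULT_WARMUP_S
) -> StateScore:
    """Per-sample comparison of estimated vs. actual state."""
    if len(est) != len(truth):
        raise ValueError("chronogram lengths differ")
    if est.fs != truth.fs:
        raise ValueError("chronogram sampling rates differ")
    e, t = est.states, truth.states
    labels = np.where(e == t, "Correct", np.where(e, "FalsePositive", "FalseNegative"))

    w = int(round(warmup_s * est.fs))
    w = min(w, len(e))
    es, ts = e[w:], t[w:]
    n = len(es)
    tp = int(np.sum(es & ts))
    tn = int(np.sum(~es & ~ts))
    fp = int(np.sum(es & ~ts))
    fn = int(np.sum(~es & ts))
    accuracy = (tp + tn) / n if n else float("nan")
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return StateScore(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        labels=labels,
        n_scored=n,
        warmup_samples=w,
    )


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    if len(x) == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
    return mean, se


def latency_analysis(
    est: Chronogram,
    schedule: EventSchedule,
    window_s: tuple[float, float] = DEFAULT_MATCH_WINDOW_S,
) -> LatencyReport:
    """Match estimated transitions to true trial onsets/offsets.

    For each trial the estimated onset is the on-task transition nearest to
    the true onset within ``[onset + window_s[0], onset + window_s[1]]``
    (ties resolved toward the earlier transition); its latency is
    ``t_est - onset``.  The estimated offset is the first off-transition
    after the matched onset, with latency relative to the message offset.
    Trials with no in-window transition count as unmatched.
    """
    span_end = est.t0 + len(est) / est.fs
    if schedule.trials and schedule.trials[-1].onset_s > span_end:
        raise ValueError("schedule outside recording span")
    on_times, off_times = transition_times(est)
    lo, hi = window_s

    onset_lat, offset_lat = [], []
    matched, offset_matched = [], []
    per_trial = {}
    unmatched = 0
    for k, trial in enumerate(schedule):
        cand = on_times[(on_times >= trial.onset_s + lo) & (on_times <= trial.onset_s + hi)]
        if cand.size == 0:
            unmatched += 1
            continue
        # nearest to the true onset; np.argmin takes the first (earliest) on ties
        t_on = float(cand[np.argmin(np.abs(cand - trial.onset_s))])
        onset_lat.append(t_on - trial.onset_s)
        matched.append(k)
        later_off = off_times[off_times > t_on]
        if later_off.size:
            offset_lat.append(float(later_off[0]) - trial.message_offset_s)
            offset_matched.append(k)
        per_trial[k] = trial.load

    onset_lat = np.asarray(onset_lat)
    offset_lat = np.asarray(offset_lat)
    on_mean, on_se = _mean_se(onset_lat)
    off_mean, off_se = _mean_se(offset_lat)

    per_load = {}
    for load in ("low", "high"):
        on_l = np.asarray(
            [lat for k, lat in zip(matched, onset_lat) if schedule.trials[k].load == load]
        )
        off_l = np.asarray(
            [lat for k, lat in zip(offset_matched, offset_lat) if schedule.trials[k].load == load]
        )
        m1, s1 = _mean_se(on_l)
        m2, s2 = _mean_se(off_l)
        per_load[load] = {
            "onset_mean_s": m1,
            "onset_se_s": s1,
            "offset_mean_s": m2,
            "offset_se_s": s2,
            "n_matched": len(on_l),
        }

    return LatencyReport(
        onset_latencies_s=onset_lat,
        offset_latencies_s=offset_lat,
        matched_trials=matched,
        offset_matched_trials=offset_matched,
        unmatched_onsets=unmatched,
        onset_mean_s=on_mean,
        onset_se_s=on_se,
        offset_mean_s=off_mean,
        offset_se_s=off_se,
        per_load=per_load,
    )


def write_chronogram(chron: Chronogram, path) -> None:
    pd.DataFrame({"time_s": chron.times, "state": chron.states.astype(int)}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_chronogram(path) -> Chronogram:
    df = pd.read_csv(path, float_precision="round_trip")
    fs = 2.0
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        fs = 1.0 / (t[1] - t[0])
    return Chronogram(fs=fs, states=df["state"].to_numpy(dtype=int).astype(bool),
                      t0=float(t[0]) if len(t) else 0.0)
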