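"""Trial segmentation and sliding-window feature extraction.

Each trial is cut from the MACD-filtered recording over ``[-2, +31)`` s
around the message onset (66 samples at 2 Hz); the first 2 s (4 samples)
form the pre-trial baseline.  Features are computed on a grid of sliding
windows — offsets 10..16 s after onset, lengths 5/10/15 s — chosen to cover
the hemodynamic response across individual latency differences.  Per window
and channel, 8 values are extracted (4 statistics x 2 species):

* mean of Δ[HbO2] and Δ[hHb] over the window;
* Ā — the window mean referenced to the 2 s pre-trial baseline mean, which
  removes residual drift;
* excess kurtosis and skewness of the within-window sample distribution
  (biased/population moment estimators).

With 14 active channels this yields 14 x 21 x 8 = 2352 predictors per trial
(168 per channel).  Ordering is fixed: channel ascending, then offset
ascending, then length ascending, then the 8-feature block
(mean_hbo2, mean_hhb, amp_hbo2, amp_hhb, kurt_hbo2, kurt_hhb,
skew_hbo2, skew_hhb).

Windows with zero variance yield 0 for kurtosis and skewness (with a logged
warning) so degenerate flat channels remain classifiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventSchedule, Recording

__all__ = [
    "WindowSpec",
    "TrialData",
    "OFFSETS_S",
    "LENGTHS_S",
    "FEATURE_BLOCK",
    "segment_trials",
    "window_features",
    "trial_features",
    "feature_names",
    "feature_matrix",
    "features_frame",
    "peak_response",
]

logger = logging.getLogger(__name__)

OFFSETS_S = (10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0)
LENGTHS_S = (5.0, 10.0, 15.0)
FEATURE_BLOCK = (
    "mean_hbo2", "mean_hhb",
    "amp_hbo2", "amp_hhb",
    "kurt_hbo2", "kurt_hhb",
    "skew_hbo2", "skew_hhb",
)

TRIAL_PRE_S = 2.0    # baseline before onset
TRIAL_POST_S = 31.0  # last needed sample: max offset (16) + max length (15)
BASELINE_S = 2.0


@dataclass(frozen=True)
class WindowSpec:
    """One sliding window, ``[offset, offset+length)`` s after trial onset."""

    offset_s: float
    length_s: float

    def __post_init__(self) -> None:
        if self.offset_s < 0 or self.length_s <= 0:
            raise ValueError("window offset must be >= 0 and length > 0")
        if self.offset_s + self.length_s > TRIAL_POST_S:
            raise ValueError("window extends beyond the trial span")


@dataclass
class TrialData:
    """MACD-filtered samples for one trial, ``[-2, +31)`` s around onset."""

    index: int
    load: str
    onset_s: float
    fs: float
    channel_ids: tuple[int, ...]
    hbo2: np.ndarray  # (n_channels, n_samples)
    hhb: np.ndarray

    def __post_init__(self) -> None:
        self.hbo2 = np.asarray(self.hbo2, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        expected = int(round((TRIAL_PRE_S + TRIAL_POST_S) * self.fs))
        if self.hbo2.shape != (len(self.channel_ids), expected):
            raise ValueError(
                f"trial {self.index}: expected {expected} samples per channel"
            )
        if self.hbo2.shape != self.hhb.shape:
            raise ValueError("hbo2 and hhb shapes differ")

    @property
    def n_samples(self) -> int:
        return self.hbo2.shape[1]


def segment_trials(rec: Recording, schedule: EventSchedule) -> list[TrialData]:
    """Cut ``[-2, +31)`` s half-open windows around each trial onset.

    Sample indices are ``round((onset ± Δ)·fs)``; exact at 2 Hz for
    integer/half-integer onset times.
    """
    trials = []
    for k, trial in enumerate(schedule):
        i0 = int(round((trial.onset_s - rec.t0 - TRIAL_PRE_S) * rec.fs))
        i1 = int(round((trial.onset_s - rec.t0 + TRIAL_POST_S) * rec.fs))
        if i0 < 0 or i1 > rec.n_samples:
            raise ValueError(f"trial {k} span [{i0}, {i1}) outside recording")
        trials.append(
            TrialData(
                index=k,
                load=trial.load,
                onset_s=trial.onset_s,
                fs=rec.fs,
                channel_ids=rec.montage.active,
                hbo2=rec.hbo2[:, i0:i1],
                hhb=rec.hhb[:, i0:i1],
            )
        )
    return trials


def _shape_stats(x: np.ndarray) -> tuple[float, float]:
    """(excess kurtosis, skewness) with biased moment estimators; 0 if flat."""
    mu = x.mean()
    d = x - mu
    m2 = np.mean(d**2)
    if m2 <= 0:
        logger.warning("zero in-window variance; kurtosis/skewness set to 0")
        return 0.0, 0.0
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    return float(m4 / m2**2 - 3.0), float(m3 / m2**1.5)


def window_features(trial: TrialData, w: WindowSpec, channel: int) -> np.ndarray:
    """The 8-feature block for one window of one channel.

    Order: mean_hbo2, mean_hhb, amp_hbo2, amp_hhb, kurt_hbo2, kurt_hhb,
    skew_hbo2, skew_hhb — where amp is the baseline-referenced window mean.
    """
    try:
        row = trial.channel_ids.index(channel)
    except ValueError:
        raise ValueError(f"channel {channel} not in trial data") from None
    a = int(round((TRIAL_PRE_S + w.offset_s) * trial.fs))
    b = int(round((TRIAL_PRE_S + w.offset_s + w.length_s) * trial.fs))
    nb = int(round(BASELINE_S * trial.fs))

    out = np.empty(8)
    for j, series in enumerate((trial.hbo2[row], trial.hhb[row])):
        win = series[a:b]
        mean = float(win.mean())
        amp = mean - float(series[:nb].mean())
        kurt, skew = _shape_stats(win)
        out[0 + j] = mean
        out[2 + j] = amp
        out[4 + j] = kurt
        out[6 + j] = skew
    return out


def trial_features(trial: TrialData) -> np.ndarray:
    """Full predictor vector: channels x 21 windows x 8 features, fixed order."""
    blocks = [
        window_features(trial, WindowSpec(off, length), ch)
        for ch in trial.channel_ids
        for off in OFFSETS_S
        for length in LENGTHS_S
    ]
    return np.concatenate(blocks)


def feature_names(channel_ids) -> list[str]:
    """Self-describing column names matching ``trial_features`` ordering."""
    return [
        f"ch{ch:02d}_off{int(off):02d}_len{int(length):02d}_{feat}"
        for ch in channel_ids
        for off in OFFSETS_S
        for length in LENGTHS_S
        for feat in FEATURE_BLOCK
    ]


def feature_matrix(trials: list[TrialData]) -> tuple[np.ndarray, np.ndarray]:
    """Stack trial feature vectors into (X, y) for classification."""
    X = np.vstack([trial_features(t) for t in trials])
    y = np.array([t.load for t in trials])
    return X, y


def features_frame(trials: list[TrialData]) -> pd.DataFrame:
    """Feature matrix as a DataFrame with named columns plus the load label."""
    X, y = feature_matrix(trials)
    df = pd.DataFrame(X, columns=feature_names(trials[0].channel_ids))
    df.insert(0, "load", y)
    return df


def peak_response(trial: TrialData, species: str = "hbo2", channel: int | None = None) -> float:
    """Peak value within 30 s post-onset minus the 2 s pre-onset baseline mean.

    With ``channel=None`` the channel-averaged series is used.
    """
    data = {"hbo2": trial.hbo2, "hhb": trial.hhb}[species]
    if channel is not None:
        data = data[trial.channel_ids.index(channel)][None, :]
    series = data.mean(axis=0)
    nb = int(round(BASELINE_S * trial.fs))
    a = nb                                   # t = 0 s
    b = int(round((TRIAL_PRE_S + 30.0) * trial.fs)) + 1  # t = 30 s inclusive
    return float(series[a:b].max() - series[:nb].mean())
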