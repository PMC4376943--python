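"""Synthetic fNIRS sessions with known ground truth.

A session reproduces the experimental structure the pipeline targets: 40
auditory-instruction trials (11 s message + 18 s response window), two
working-memory load levels in a constrained pseudo-random order (the first
half balanced 10/10 for classifier training, never more than two equal
loads in a row), separated by uniform 10-20 s inter-trial intervals.

The evoked Δ[HbO2] response is a message-length neural boxcar convolved
with a canonical double-gamma hemodynamic response function (peak ~6 s,
undershoot ~16 s, undershoot ratio 1/6).  The convolution is normalised so
that ``amp_low``/``amp_high`` are the *peak* response amplitudes in μmol/L
at the focus channel (default channel 15, right DLPFC, where the load
effect is strongest); other channels are scaled by a spatial profile
decaying exponentially with channel distance.  Δ[hHb] is the HbO2 response
scaled by a negative ratio (default -1/3) and lagged by 1 s.

Additive physiological noise per channel and species: a random linear
drift, Mayer-wave and respiratory sinusoids (0.1 Hz / 0.25 Hz) with random
phases, and white measurement noise.  The drift lies below the MACD
passband and the white noise mostly above it; the sinusoids sit in-band and
make the task non-trivial.  All amplitudes are configuration values, not a
claim to reproduce any particular cohort.

Channels 8 and 10 are simulated like the others and removed by the montage
mask, mirroring their systematic exclusion in the modelled acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .io import ChannelMontage, EventSchedule, Recording, Trial
from .state import Chronogram, truth_chronogram

__all__ = [
    "SimulationConfig",
    "generate_trial_order",
    "canonical_hrf",
    "simulate_session",
]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_trials: int = 40
    message_dur_s: float = 11.0
    response_dur_s: float = 18.0
    iti_range_s: tuple[float, float] = (10.0, 20.0)
    initial_rest_s: float = 20.0
    tail_s: float = 40.0
    fs: float = 2.0

    # hemodynamic response
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    amp_low: float = 0.5    # μmol/L peak Δ[HbO2] at the focus channel
    amp_high: float = 1.0
    focus_channel: int = 15  # right DLPFC in the 16-channel montage
    spatial_decay: float = 3.0  # e-folding distance of the profile, in channels
    hhb_ratio: float = -1.0 / 3.0
    hhb_lag_s: float = 1.0

    # physiological + measurement noise (μmol/L)
    drift_slope: float = 5e-4       # max |slope|, μmol/L per s
    mayer_freq_hz: float = 0.1
    mayer_amp: float = 0.3
    resp_freq_hz: float = 0.25
    resp_amp: float = 0.2
    white_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.n_trials % 2:
            raise ValueError("n_trials must be even")
        for a in (self.amp_low, self.amp_high, self.mayer_amp, self.resp_amp,
                  self.white_sigma):
            if a < 0:
                raise ValueError("amplitudes must be >= 0")
        if self.hhb_ratio > 0:
            raise ValueError("hhb_ratio must be <= 0")


def _valid_order(order: list[str]) -> bool:
    n = len(order)
    half = n // 2
    n_high_first = sum(1 for x in order[:half] if x == "high")
    if n_high_first not in {half // 2, (half + 1) // 2}:
        return False
    return not any(order[i] == order[i + 1] == order[i + 2] for i in range(n - 2))


def generate_trial_order(n: int = 40, rng=0) -> list[str]:
    """Uniform sample over load orderings satisfying the design constraints.

    Constraints: n/2 trials of each load overall; the first half balanced
    (to within one trial when n/2 is odd); never three equal loads in a row.
    Rejection sampling from uniform permutations, deterministic per seed.
    """
    if n % 2:
        raise ValueError("n must be even")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = ["low"] * (n // 2) + ["high"] * (n // 2)
    while True:
        order = [labels[i] for i in rng.permutation(n)]
        if _valid_order(order):
            return order


def canonical_hrf(
    t: np.ndarray,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, normalised to peak 1.

    The positive lobe is a gamma density with mode at ``peak_s``; the
    undershoot a gamma with mode at ``undershoot_s`` scaled by the ratio.
    """
    if peak_s <= 0:
        raise ValueError("peak time must be positive")
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_s + 1.0) - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_s + 1.0
    )
    return h / h.max()


def _noise(cfg: SimulationConfig, rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    slope = cfg.drift_slope * rng.uniform(-1.0, 1.0)
    ph_mayer, ph_resp = rng.uniform(0.0, 2.0 * np.pi, size=2)
    white = rng.standard_normal(len(t)) * cfg.white_sigma
    return (
        slope * t
        + cfg.mayer_amp * np.sin(2.0 * np.pi * cfg.mayer_freq_hz * t + ph_mayer)
        + cfg.resp_amp * np.sin(2.0 * np.pi * cfg.resp_freq_hz * t + ph_resp)
        + white
    )


def simulate_session(
    cfg: SimulationConfig | None = None,
    montage: ChannelMontage | None = None,
) -> tuple[Recording, EventSchedule, Chronogram]:
    """Generate one session: recording, event schedule and truth chronogram.

    Same seed gives a bit-identical session.  The returned recording carries
    the montage's active channels only (default: 8 and 10 masked).
    """
    cfg = cfg or SimulationConfig()
    montage = montage or ChannelMontage()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs

    order = generate_trial_order(cfg.n_trials, rng)

    onsets = []
    t_cursor = cfg.initial_rest_s
    trial_len = cfg.message_dur_s + cfg.response_dur_s
    for _ in range(cfg.n_trials):
        onset = round(t_cursor * fs) / fs  # snap to the sample grid
        onsets.append(onset)
        t_cursor = onset + trial_len + rng.uniform(*cfg.iti_range_s)

    duration = onsets[-1] + trial_len + cfg.tail_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # neural boxcar scaled by per-trial peak amplitude
    stim = np.zeros(n)
    msg_samples = int(round(cfg.message_dur_s * fs))
    amps = {"low": cfg.amp_low, "high": cfg.amp_high}
    for onset, load in zip(onsets, order):
        i0 = int(round(onset * fs))
        stim[i0 : i0 + msg_samples] = amps[load]

    kernel = canonical_hrf(
        np.arange(0.0, 33.0, 1.0 / fs),
        cfg.hrf_peak_s,
        cfg.hrf_undershoot_s,
        cfg.hrf_undershoot_ratio,
    )
    # normalise so a unit message-length boxcar reaches peak 1 after convolution
    ref_peak = np.convolve(np.ones(msg_samples), kernel).max()
    response = np.convolve(stim, kernel)[:n] / ref_peak

    lag = int(round(cfg.hhb_lag_s * fs))
    hhb_response = np.zeros(n)
    hhb_response[lag:] = cfg.hhb_ratio * response[: n - lag]

    ids = montage.channel_ids
    profile = np.exp(-np.abs(np.asarray(ids) - cfg.focus_channel) / cfg.spatial_decay)

    hbo2 = np.empty((len(ids), n))
    hhb = np.empty((len(ids), n))
    for c in range(len(ids)):
        hbo2[c] = profile[c] * response + _noise(cfg, rng, t)
        hhb[c] = profile[c] * hhb_response + _noise(cfg, rng, t)

    keep = [i for i, ch in enumerate(ids) if ch not in montage.excluded]
    rec = Recording(fs=fs, hbo2=hbo2[keep], hhb=hhb[keep], montage=montage)

    schedule = EventSchedule(
        [
            Trial(
                onset_s=onset,
                load=load,
                message_dur_s=cfg.message_dur_s,
                response_dur_s=cfg.response_dur_s,
            )
            for onset, load in zip(onsets, order)
        ]
    )
    truth = truth_chronogram(schedule, n, fs=fs)
    return rec, schedule, truth
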