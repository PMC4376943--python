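"""Recording and event-schedule I/O for fNIRS sessions.

Data model
----------
A :class:`Recording` holds per-channel oxygenated (Δ[HbO2]) and deoxygenated
(Δ[hHb]) hemoglobin concentration changes in μmol/L, sampled at a fixed rate
(2 Hz for the fNIR100-style montage modelled here).  A
:class:`ChannelMontage` describes the 16-channel forehead band; channels 8
and 10 sit above the nasal sinus and are excluded by default because they
saturate, leaving 14 active channels.

Concentration changes can also be derived from raw two-wavelength light
intensities via the modified Beer-Lambert law (:func:`beer_lambert_convert`).

File formats are plain CSV: a recording file has a ``time_s`` column followed
by ``ch<k>_hbo2`` / ``ch<k>_hhb`` pairs; an event file has one row per trial
(``onset_s, message_dur_s, response_dur_s, load``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChannelMontage",
    "Recording",
    "Trial",
    "EventSchedule",
    "RawIntensityRecording",
    "DEFAULT_EXTINCTION_MM",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "beer_lambert_convert",
]

LOAD_LABELS = ("low", "high")

#: Molar extinction coefficients in cm^-1 per mM, rows = (730 nm, 850 nm),
#: columns = (HbO2, hHb).  Standard compiled in-vitro values; the device
#: firmware constants are not published, so these are explicit, overridable
#: defaults rather than a claim of equivalence.
DEFAULT_EXTINCTION_MM = np.array([[0.3900, 1.1022],
                                  [1.0580, 0.6913]])


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered channel layout with an exclusion mask.

    ``channel_ids`` is the full ordered montage (1..16 for the forehead
    band); ``excluded`` marks channels dropped for signal-quality reasons.
    Masking never reorders the retained channels.
    """

    channel_ids: tuple[int, ...] = tuple(range(1, 17))
    excluded: frozenset[int] = frozenset({8, 10})
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("duplicate channel ids")
        if not set(self.excluded) <= set(self.channel_ids):
            raise ValueError("excluded channels must be a subset of channel_ids")

    @property
    def active(self) -> tuple[int, ...]:
        """Retained channel ids, in montage order."""
        return tuple(c for c in self.channel_ids if c not in self.excluded)

    @property
    def n_active(self) -> int:
        return len(self.active)


@dataclass
class Recording:
    """Multichannel Δ[HbO2]/Δ[hHb] concentration time series (μmol/L).

    ``hbo2`` and ``hhb`` are ``(n_active_channels, n_samples)`` arrays whose
    rows follow ``montage.active`` order.
    """

    fs: float
    hbo2: np.ndarray
    hhb: np.ndarray
    montage: ChannelMontage = field(default_factory=ChannelMontage)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.hbo2 = np.asarray(self.hbo2, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        if self.hbo2.ndim != 2 or self.hhb.ndim != 2:
            raise ValueError("hbo2/hhb must be 2-D (channels x samples)")
        if self.hbo2.shape != self.hhb.shape:
            raise ValueError("hbo2 and hhb must have the same shape")
        if self.hbo2.shape[0] != self.montage.n_active:
            raise ValueError(
                f"expected {self.montage.n_active} channel rows, got {self.hbo2.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.hbo2).any() or np.isnan(self.hhb).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_samples(self) -> int:
        return self.hbo2.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class Trial:
    onset_s: float
    load: str
    message_dur_s: float = 11.0
    response_dur_s: float = 18.0

    def __post_init__(self) -> None:
        if self.load not in LOAD_LABELS:
            raise ValueError(f"unknown load label: {self.load!r}")

    @property
    def message_offset_s(self) -> float:
        return self.onset_s + self.message_dur_s

    @property
    def end_s(self) -> float:
        return self.onset_s + self.message_dur_s + self.response_dur_s


@dataclass
class EventSchedule:
    """Trial onsets, durations and load labels — the session ground truth."""

    trials: list[Trial]

    def __post_init__(self) -> None:
        if self.trials and self.trials[0].onset_s < 2.0:
            raise ValueError("first trial onset must be >= 2 s (baseline required)")
        for a, b in zip(self.trials, self.trials[1:]):
            if b.onset_s <= a.onset_s:
                raise ValueError("trial onsets must be strictly increasing")
            if b.onset_s < a.end_s:
                raise ValueError("trial windows must not overlap")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def loads(self) -> list[str]:
        return [t.load for t in self.trials]


@dataclass
class RawIntensityRecording:
    """Raw two-wavelength light intensities plus Beer-Lambert constants.

    ``intensities`` is ``(n_channels, 2, n_samples)`` with the wavelength
    axis ordered like ``wavelengths``; ``baseline_intensities`` is
    ``(n_channels, 2)``.  ``extinction`` is in cm^-1 per mM with rows per
    wavelength and columns (HbO2, hHb); ``separation_cm`` is the
    source-detector distance and ``dpf`` the per-wavelength differential
    pathlength factor.
    """

    fs: float
    intensities: np.ndarray
    baseline_intensities: np.ndarray
    wavelengths: tuple[float, float] = (730.0, 850.0)
    channel_ids: tuple[int, ...] = tuple(range(1, 17))
    separation_cm: float = 2.5
    dpf: tuple[float, float] = (6.0, 6.0)
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION_MM.copy())

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.baseline_intensities = np.asarray(self.baseline_intensities, dtype=float)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if len(self.wavelengths) != 2 or self.intensities.shape[1] != 2:
            raise ValueError("two wavelengths required")
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (channels, wavelengths, samples)")
        if self.intensities.shape[0] != len(self.channel_ids):
            raise ValueError("intensity rows must match channel_ids")
        if self.baseline_intensities.shape != self.intensities.shape[:2]:
            raise ValueError("baseline_intensities must be (channels, wavelengths)")
        if (self.intensities <= 0).any() or (self.baseline_intensities <= 0).any():
            raise ValueError("intensities must be strictly positive")
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")


def _check_uniform_time(time_s: np.ndarray) -> float:
    """Return the sampling rate, or raise if steps are not uniform."""
    if len(time_s) < 2:
        return 2.0
    dt = np.diff(time_s)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise ValueError("non-uniform sampling: time column steps are not constant")
    if dt[0] <= 0:
        raise ValueError("non-uniform sampling: time column must be increasing")
    return 1.0 / dt[0]


def read_recording(path, montage: ChannelMontage | None = None) -> Recording:
    """Read a recording CSV, validate the time base, apply the channel mask.

    Columns for excluded channels are tolerated and dropped; a missing
    *active* channel column is an error, as is any NaN cell or a
    non-uniform time column.
    """
    montage = montage or ChannelMontage()
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("missing 'time_s' column")
    fs = _check_uniform_time(df["time_s"].to_numpy(dtype=float))

    hbo2_rows, hhb_rows = [], []
    for ch in montage.active:
        for prefix, rows in (("hbo2", hbo2_rows), ("hhb", hhb_rows)):
            col = f"ch{ch}_{prefix}"
            if col not in df.columns:
                raise ValueError(f"missing channel column: {col}")
            vals = df[col].to_numpy(dtype=float)
            bad = np.flatnonzero(np.isnan(vals))
            if bad.size:
                raise ValueError(f"NaN value in column {col} at data row {bad[0]}")
            rows.append(vals)
    return Recording(
        fs=fs,
        hbo2=np.vstack(hbo2_rows),
        hhb=np.vstack(hhb_rows),
        montage=montage,
        t0=float(df["time_s"].iloc[0]) if len(df) else 0.0,
    )


def write_recording(rec: Recording, path) -> None:
    """Write a recording as CSV (active channels only); value-exact round trip."""
    data = {"time_s": rec.times}
    for i, ch in enumerate(rec.montage.active):
        data[f"ch{ch}_hbo2"] = rec.hbo2[i]
        data[f"ch{ch}_hhb"] = rec.hhb[i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_events(path) -> EventSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"onset_s", "message_dur_s", "response_dur_s", "load"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing event columns: {sorted(missing)}")
    trials = []
    for _, row in df.iterrows():
        load = str(row["load"])
        if load not in LOAD_LABELS:
            raise ValueError(f"unknown load label: {load!r}")
        trials.append(
            Trial(
                onset_s=float(row["onset_s"]),
                message_dur_s=float(row["message_dur_s"]),
                response_dur_s=float(row["response_dur_s"]),
                load=load,
            )
        )
    return EventSchedule(trials)


def write_events(schedule: EventSchedule, path) -> None:
    pd.DataFrame(
        {
            "onset_s": [t.onset_s for t in schedule],
            "message_dur_s": [t.message_dur_s for t in schedule],
            "response_dur_s": [t.response_dur_s for t in schedule],
            "load": [t.load for t in schedule],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def beer_lambert_convert(
    raw: RawIntensityRecording, montage: ChannelMontage | None = None
) -> Recording:
    """Convert raw intensities to Δ[HbO2]/Δ[hHb] via the modified Beer-Lambert law.

    Per sample and wavelength the optical-density change is
    ``ΔOD = -log10(I / I_baseline)``; the pair of ΔOD values is then solved
    against ``ΔOD_λ = (ε_HbO2,λ·ΔC_HbO2 + ε_hHb,λ·ΔC_hHb)·d·DPF_λ`` for the
    two concentration changes.  With extinction in cm^-1/mM and the
    separation in cm, the solution is in mM and is scaled to μmol/L.
    """
    montage = montage or ChannelMontage(channel_ids=raw.channel_ids)
    dod = -np.log10(raw.intensities / raw.baseline_intensities[:, :, None])
    # A[λ, chromophore] = ε·d·DPF_λ
    A = raw.extinction * raw.separation_cm * np.asarray(raw.dpf)[:, None]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if not math.isfinite(det) or abs(det) < 1e-12 * np.abs(A).max() ** 2:
        raise ValueError("singular extinction matrix")
    conc_mm = np.einsum("ij,cjt->cit", np.linalg.inv(A), dod)
    conc_um = conc_mm * 1000.0  # mM -> μmol/L

    keep = [i for i, ch in enumerate(raw.channel_ids) if ch not in montage.excluded]
    return Recording(
        fs=raw.fs,
        hbo2=conc_um[keep, 0, :],
        hhb=conc_um[keep, 1, :],
        montage=montage,
    )


def mask_channels(rec: Recording, montage: ChannelMontage) -> Recording:
    """Apply a stricter exclusion mask to an existing recording."""
    if set(montage.active) - set(rec.montage.active):
        raise ValueError("new montage activates channels absent from the recording")
    keep = [i for i, ch in enumerate(rec.montage.active) if ch in set(montage.active)]
    return replace(rec, hbo2=rec.hbo2[keep], hhb=rec.hhb[keep], montage=montage)
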