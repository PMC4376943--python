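"""End-to-end experiment orchestration.

A session runs in three phases: phase D gathers the first 20 labelled
trials, phase L trains the per-subject workload classifier (C selection by
repeated cross-validation, then a single fit), and phase T classifies the
remaining 20 trials with the frozen model.  In parallel, the calibration-
free crossover state estimator runs over the whole recording and is scored
against the ground-truth chronogram.

A trial's feature vector only exists once its last needed sample is in —
onset + max window offset (16 s) + max window length (15 s) = onset + 31 s,
which is 2 s after the response window ends (onset + 11 + 18 s).  That 2 s
gap is asserted as a startup self-check and reported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from .classifier import (
    C_GRID,
    CvPlan,
    classify_trial,
    evaluate,
    select_C,
    train,
)
from .features import LENGTHS_S, OFFSETS_S, feature_matrix, segment_trials
from .io import EventSchedule, Recording
from .macd import MacdConfig, filter_recording, signal_line
from .simulate import SimulationConfig, simulate_session
from .state import (
    DEFAULT_MATCH_WINDOW_S,
    DEFAULT_WARMUP_S,
    average_active_channels,
    detect_crossovers,
    latency_analysis,
    score_chronogram,
    truth_chronogram,
)

__all__ = [
    "ExperimentConfig",
    "SessionReport",
    "availability_gap_s",
    "run_experiment",
    "multi_subject_study",
]


def availability_gap_s(
    message_dur_s: float = 11.0,
    response_dur_s: float = 18.0,
    offsets_s=OFFSETS_S,
    lengths_s=LENGTHS_S,
) -> float:
    """Last-needed-sample time minus response-window end, in seconds.

    For the default timing: (16 + 15) - (11 + 18) = 2 s.
    """
    return (max(offsets_s) + max(lengths_s)) - (message_dur_s + response_dur_s)


@dataclass(frozen=True)
class ExperimentConfig:
    macd: MacdConfig = field(default_factory=MacdConfig)
    species: str = "hbo2"
    warmup_s: float = DEFAULT_WARMUP_S
    match_window_s: tuple[float, float] = DEFAULT_MATCH_WINDOW_S
    n_train: int = 20
    c_grid: tuple = C_GRID
    cv: CvPlan = field(default_factory=CvPlan)


@dataclass
class SessionReport:
    seed: int | None
    config: dict
    availability_gap_s: float
    state_accuracy: float
    state_sensitivity: float
    state_specificity: float
    onset_latency_mean_s: float
    onset_latency_se_s: float
    offset_latency_mean_s: float
    offset_latency_se_s: float
    unmatched_onsets: int
    latency_per_load: dict
    selected_C: float
    cv_table: list
    wm_accuracy: float
    wm_sensitivity: float
    wm_specificity: float
    predictions: list
    truth_labels: list

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)


def run_experiment(
    recording: Recording,
    schedule: EventSchedule,
    config: ExperimentConfig | None = None,
    seed: int | None = None,
) -> SessionReport:
    """Run the full phase D/L/T protocol plus continuous state estimation."""
    cfg = config or ExperimentConfig()
    if len(schedule) < cfg.n_train + 1:
        raise ValueError("schedule must extend beyond the training phase")

    gap = availability_gap_s(
        schedule.trials[0].message_dur_s, schedule.trials[0].response_dur_s
    )
    assert gap >= 0, "feature windows must not end before the response window"

    filtered = filter_recording(recording, cfg.macd)

    # --- continuous state estimation over the whole session
    avg = average_active_channels(filtered, cfg.species)
    sig = signal_line(avg, cfg.macd)
    est = detect_crossovers(avg, sig, fs=recording.fs, t0=recording.t0)
    truth = truth_chronogram(schedule, recording.n_samples, recording.fs, recording.t0)
    score = score_chronogram(est, truth, cfg.warmup_s)
    latency = latency_analysis(est, schedule, cfg.match_window_s)

    # --- phases D/L/T
    trials = segment_trials(filtered, schedule)
    X, y = feature_matrix(trials)
    X_train, y_train = X[: cfg.n_train], y[: cfg.n_train]
    counts = pd.Series(y_train).value_counts()
    if counts.min() != counts.max():
        raise ValueError("phase D must be balanced across load levels")
    selected_c, cv_table = select_C(X_train, y_train, cfg.c_grid, cfg.cv)
    model = train(X_train, y_train, selected_c)

    X_test, y_test = X[cfg.n_train :], y[cfg.n_train :]
    preds = [classify_trial(model, x) for x in X_test]
    wm = evaluate(model, X_test, y_test)

    return SessionReport(
        seed=seed,
        config={
            "species": cfg.species,
            "warmup_s": cfg.warmup_s,
            "match_window_s": list(cfg.match_window_s),
            "n_train": cfg.n_train,
            "macd": asdict(cfg.macd),
            "cv": asdict(cfg.cv),
            "c_grid": list(cfg.c_grid),
        },
        availability_gap_s=gap,
        state_accuracy=score.accuracy,
        state_sensitivity=score.sensitivity,
        state_specificity=score.specificity,
        onset_latency_mean_s=latency.onset_mean_s,
        onset_latency_se_s=latency.onset_se_s,
        offset_latency_mean_s=latency.offset_mean_s,
        offset_latency_se_s=latency.offset_se_s,
        unmatched_onsets=latency.unmatched_onsets,
        latency_per_load=latency.per_load,
        selected_C=selected_c,
        cv_table=[list(r) for r in cv_table.itertuples(index=False)],
        wm_accuracy=wm.accuracy,
        wm_sensitivity=wm.sensitivity,
        wm_specificity=wm.specificity,
        predictions=list(wm.predictions),
        truth_labels=list(y_test),
    )


def multi_subject_study(
    n_subjects: int,
    base_seed: int = 0,
    sim_config: SimulationConfig | None = None,
    exp_config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Simulate and analyse ``n_subjects`` sessions (seed = base_seed + i).

    Returns one row per subject plus aggregate ``mean`` and ``sd`` rows over
    the per-subject metrics.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    base_cfg = sim_config or SimulationConfig()

    rows = []
    for i in range(n_subjects):
        seed = base_seed + i
        cfg = SimulationConfig(**{**asdict(base_cfg), "seed": seed})
        rec, schedule, _ = simulate_session(cfg)
        rep = run_experiment(rec, schedule, exp_config, seed=seed)
        rows.append(
            {
                "subject": i + 1,
                "seed": seed,
                "wm_accuracy": rep.wm_accuracy,
                "wm_sensitivity": rep.wm_sensitivity,
                "wm_specificity": rep.wm_specificity,
                "state_accuracy": rep.state_accuracy,
                "selected_C": rep.selected_C,
                "onset_latency_mean_s": rep.onset_latency_mean_s,
            }
        )
    df = pd.DataFrame(rows)
    metrics = [c for c in df.columns if c not in ("subject", "seed")]
    agg = pd.DataFrame(
        [
            {"subject": "mean", "seed": None, **df[metrics].mean().to_dict()},
            {"subject": "sd", "seed": None, **df[metrics].std(ddof=1).to_dict()},
        ]
    )
    return pd.concat([df, agg], ignore_index=True)
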