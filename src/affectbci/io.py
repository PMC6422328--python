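"""File formats: EEG CSV/EDF, event and trajectory CSV, session logs.

EEG CSV layout: first column ``time_s``, remaining columns named after
channels, values in microvolts.  Events CSV: ``onset_s,duration_s,label``.
Trajectory CSV: ``time_s,valence,arousal``.  Models are JSON documents
(see :meth:`affectbci.decoder.AffectModel.save`).  A session directory
holds ``scores.csv`` (trial, task, period, time_s, score),
``features.csv`` (per-window observations by trial and period) and
``manifest.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import AffectModel, EEGRecording, Score
from .loop import SessionRecord, TrialRecord
from .music import Trajectory

__all__ = [
    "read_eeg_csv",
    "write_eeg_csv",
    "read_eeg_edf",
    "read_events_csv",
    "write_events_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_scores_csv",
    "write_session",
    "load_session",
]


def read_eeg_csv(path, events_path=None) -> EEGRecording:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError("EEG CSV must start with a time_s column")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError("EEG CSV too short")
    # endpoint-based rate estimate is insensitive to per-row rounding
    fs = (len(times) - 1) / float(times[-1] - times[0])
    channels = tuple(df.columns[1:])
    samples = df[list(channels)].to_numpy(dtype=float).T
    events = read_events_csv(events_path) if events_path else []
    return EEGRecording(
        samples=samples, fs=round(fs, 3), channel_names=channels,
        events=events,
    )


def write_eeg_csv(rec: EEGRecording, path) -> None:
    times = np.arange(rec.samples.shape[1]) / rec.fs
    df = pd.DataFrame({"time_s": times})
    for i, name in enumerate(rec.channel_names):
        df[name] = rec.samples[i]
    df.to_csv(path, index=False, float_format="%.6f")


def read_eeg_edf(path, events_path=None) -> EEGRecording:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = read_events_csv(events_path) if events_path else []
    return EEGRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        events=events,
    )


def read_events_csv(path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    required = {"onset_s", "duration_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"events CSV needs columns {sorted(required)}")
    return [
        (float(r.onset_s), float(r.duration_s), str(r.label))
        for r in df.itertuples()
    ]


def write_events_csv(events, path) -> None:
    pd.DataFrame(
        events, columns=["onset_s", "duration_s", "label"]
    ).to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    required = {"time_s", "valence", "arousal"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV needs columns {sorted(required)}")
    return Trajectory.from_breakpoints(
        [(r.time_s, r.valence, r.arousal) for r in df.itertuples()]
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame(
        [
            (t, p.valence, p.arousal)
            for t, p in traj.points
        ],
        columns=["time_s", "valence", "arousal"],
    ).to_csv(path, index=False)


def write_scores_csv(scores, path) -> None:
    pd.DataFrame(
        [(s.time, s.value) for s in scores], columns=["time_s", "score"]
    ).to_csv(path, index=False, float_format="%.8g")


def write_session(session: SessionRecord, outdir) -> None:
    """Write a session directory: scores, per-window features, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in session.trials:
        for period, scores in (
            ("rest", t.rest_scores),
            ("action", t.action_scores),
        ):
            for s in scores:
                rows.append(
                    {
                        "trial": t.index,
                        "task": t.task,
                        "period": period,
                        "time_s": s.time,
                        "score": s.value,
                    }
                )
    pd.DataFrame(rows).to_csv(
        outdir / "scores.csv", index=False, float_format="%.10g"
    )

    frows = []
    for t in session.trials:
        for period, mat in t.segments.items():
            for k, f in enumerate(mat):
                frows.append(
                    {"trial": t.index, "task": t.task, "period": period,
                     "window": k,
                     **{f"f{i:02d}": v for i, v in enumerate(f)}}
                )
    pd.DataFrame(frows).to_csv(
        outdir / "features.csv", index=False, float_format="%.6f"
    )

    session.model.save(outdir / "model.json")
    manifest = {
        "participant": session.participant,
        "n_trials": session.n_trials,
        "seed": session.seed,
        "mood_ratings": session.mood_ratings,
        "tasks": [t.task for t in session.trials],
        "valid": [t.valid for t in session.trials],
        "trial_start_times": [t.start_time for t in session.trials],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_session(indir) -> SessionRecord:
    """Rebuild a session record from a session directory."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    model = AffectModel.load(indir / "model.json")
    scores = pd.read_csv(indir / "scores.csv")
    # scores are open-interval; guard against text rounding at the ends
    scores["score"] = scores["score"].clip(1e-12, 1.0 - 1e-12)
    features = pd.read_csv(indir / "features.csv")
    fcols = [c for c in features.columns if c.startswith("f")]

    trials = []
    for idx, task, valid, t0 in zip(
        range(manifest["n_trials"]),
        manifest["tasks"],
        manifest["valid"],
        manifest["trial_start_times"],
    ):
        sub = scores[scores.trial == idx]
        rest = [
            Score(value=r.score, time=r.time_s)
            for r in sub[sub.period == "rest"].itertuples()
        ]
        action = [
            Score(value=r.score, time=r.time_s)
            for r in sub[sub.period == "action"].itertuples()
        ]
        fsub = features[features.trial == idx]
        segments = {
            period: fsub[fsub.period == period]
            .sort_values("window")[fcols]
            .to_numpy(dtype=float)
            for period in fsub.period.unique()
        }
        trials.append(
            TrialRecord(
                index=idx,
                task=task,
                rest_scores=rest,
                action_scores=action,
                rest_mean=float(np.mean([s.value for s in rest]))
                if rest
                else float("nan"),
                action_mean=float(np.mean([s.value for s in action]))
                if action
                else float("nan"),
                segments=segments,
                start_time=t0,
                valid=valid,
            )
        )
    return SessionRecord(
        participant=manifest["participant"],
        trials=trials,
        model=model,
        mood_ratings=manifest.get("mood_ratings"),
        seed=manifest.get("seed"),
    )
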