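"""On-disk bundle layout for simulated (or recorded) experiments.

A bundle directory holds::

    design.csv            listener, reader, text, condition, order, trial_index
    traces/<trial>.csv    time_s, ribcage, abdomen
    vc/<subject>.csv      vital-capacity maneuver traces, same format
    labels/<trial>.csv    tier, start_s, end_s, label, syllables
    truth/<trial>.csv     generator ground truth (simulated bundles only)

Reader trials are keyed ``<reader>_<text>_<condition>``, listener trials
``<listener>_t<index>``.  All files are plain CSV so bundles diff and
version cleanly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import read_trace, write_trace
from .simulate import ExperimentBundle
from .types import FormatError, GroundTruth, IntervalLabels, SpeechChunk

__all__ = [
    "reader_trial_id",
    "listener_trial_id",
    "write_labels",
    "read_labels",
    "write_truth",
    "read_truth",
    "write_bundle",
    "load_bundle",
]


def reader_trial_id(reader: str, text: str, condition: str) -> str:
    return f"{reader}_{text}_{condition}"


def listener_trial_id(listener: str, trial_index: int) -> str:
    return f"{listener}_t{int(trial_index):02d}"


def write_labels(labels: IntervalLabels, path: str | Path) -> None:
    rows = [
        dict(tier="task", start_s=labels.speech_onset_s, end_s=labels.speech_offset_s,
             label="speech", syllables=""),
    ]
    for ch in labels.chunks:
        rows.append(
            dict(tier="chunk", start_s=ch.start_s, end_s=ch.end_s,
                 label=ch.label, syllables=ch.syllables)
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def read_labels(path: str | Path, trial_id: str = "") -> IntervalLabels:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    task = df[df["tier"] == "task"]
    if len(task) != 1:
        raise FormatError(f"{path.name}: expected exactly one task row")
    chunks = [
        SpeechChunk(
            start_s=float(r.start_s),
            end_s=float(r.end_s),
            syllables=int(r.syllables),
            label=str(r.label),
        )
        for r in df[df["tier"] == "chunk"].itertuples(index=False)
    ]
    return IntervalLabels(
        trial_id=trial_id or path.stem,
        speech_onset_s=float(task["start_s"].iloc[0]),
        speech_offset_s=float(task["end_s"].iloc[0]),
        chunks=chunks,
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for i, onset in enumerate(truth.onsets):
        rows.append(
            dict(
                kind="onset",
                t1=onset,
                t2=truth.offsets[i] if i < len(truth.offsets) else np.nan,
                amp=truth.ampI[i] if i < len(truth.ampI) else np.nan,
            )
        )
    for a, b in truth.artifact_windows:
        rows.append(dict(kind="artifact", t1=a, t2=b, amp=np.nan))
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    on = df[df["kind"] == "onset"]
    offsets = on["t2"].dropna().tolist()
    amps = on["amp"].dropna().tolist()
    art = df[df["kind"] == "artifact"]
    return GroundTruth(
        onsets=on["t1"].tolist(),
        offsets=offsets,
        ampI=amps,
        artifact_windows=list(zip(art["t1"], art["t2"])),
    )


def write_bundle(bundle: ExperimentBundle, outdir: str | Path) -> Path:
    """Write a simulated experiment to the documented bundle layout."""
    outdir = Path(outdir)
    for sub in ("traces", "vc", "labels", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    bundle.design.to_csv(outdir / "design.csv", index=False)
    for (reader, text, cond), (rec, labels, truth) in bundle.reader_trials.items():
        tid = reader_trial_id(reader, text, cond)
        write_trace(rec, outdir / "traces" / f"{tid}.csv")
        write_labels(labels, outdir / "labels" / f"{tid}.csv")
        write_truth(truth, outdir / "truth" / f"{tid}.csv")
    for (listener, ti), (rec, truth) in bundle.listener_trials.items():
        tid = listener_trial_id(listener, ti)
        write_trace(rec, outdir / "traces" / f"{tid}.csv")
        write_truth(truth, outdir / "truth" / f"{tid}.csv")
    for subject, rec in bundle.vc.items():
        write_trace(rec, outdir / "vc" / f"{subject}.csv")
    return outdir


def load_bundle(bundledir: str | Path) -> ExperimentBundle:
    """Load a bundle directory back into memory.

    Ground-truth files are optional (real recordings have none); VC traces
    are required for every subject appearing in the design.
    """
    bundledir = Path(bundledir)
    design = pd.read_csv(bundledir / "design.csv")
    reader_trials = {}
    for reader, text, cond in (
        design[["reader", "text", "condition"]].drop_duplicates().itertuples(index=False)
    ):
        tid = reader_trial_id(reader, text, cond)
        rec = read_trace(bundledir / "traces" / f"{tid}.csv",
                         subject_id=reader, trial_id=tid)
        labels = read_labels(bundledir / "labels" / f"{tid}.csv", trial_id=tid)
        tpath = bundledir / "truth" / f"{tid}.csv"
        truth = read_truth(tpath) if tpath.exists() else GroundTruth()
        reader_trials[(reader, text, cond)] = (rec, labels, truth)
    listener_trials = {}
    for row in design.itertuples(index=False):
        tid = listener_trial_id(row.listener, row.trial_index)
        key = (row.listener, int(row.trial_index))
        if key in listener_trials:
            continue
        rec = read_trace(bundledir / "traces" / f"{tid}.csv",
                         subject_id=row.listener, trial_id=tid)
        tpath = bundledir / "truth" / f"{tid}.csv"
        truth = read_truth(tpath) if tpath.exists() else GroundTruth()
        listener_trials[key] = (rec, truth)
    vc = {}
    subjects = list(design["listener"].unique()) + list(design["reader"].unique())
    for subject in subjects:
        path = bundledir / "vc" / f"{subject}.csv"
        if not path.exists():
            raise FormatError(f"missing VC trace for subject {subject}")
        vc[subject] = read_trace(path, subject_id=subject, trial_id=f"{subject}_vc")
    return ExperimentBundle(
        design=design,
        reader_trials=reader_trials,
        listener_trials=listener_trials,
        vc=vc,
        vc_amp={},
    )
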