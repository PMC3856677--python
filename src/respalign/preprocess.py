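"""Filtering, resampling, band combination and %MD normalization.

The breathing fundamental sits around 0.2–0.5 Hz, so the default band is
0.05–5 Hz: the high-pass removes slow drift, the low-pass removes sensor
noise, and the passband keeps every harmonic that shapes inhalation
onsets.  Filtering is zero-phase (forward–backward FIR) because cycle
*timing* is the scientific quantity; any group delay would bias every
onset.  Amplitudes are normalized per subject by the maximal displacement
(MD) across vital-capacity maneuvers and reported in %MD.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .types import (
    CombinedTrace,
    DegenerateInputError,
    FormatError,
    KinematicRecording,
    MaximalDisplacement,
    ParameterError,
)

__all__ = [
    "DEFAULT_BAND",
    "LITERAL_BAND",
    "read_trace",
    "write_trace",
    "filter_resample",
    "combine_bands",
    "compute_md",
    "to_percent_md",
]

DEFAULT_BAND = (0.05, 5.0)
#: The acquisition chain's printed setting; suppresses the breathing
#: fundamental and is kept only as an explicit opt-in.
LITERAL_BAND = (1.0, 40.0)

TRACE_COLUMNS = ("time_s", "ribcage", "abdomen")


def read_trace(path: str | Path, subject_id: str = "", trial_id: str = "") -> KinematicRecording:
    """Read a trace CSV (time_s, ribcage, abdomen) into a recording.

    The time column must be uniformly sampled; the sampling rate is
    inferred from the median step.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    if df[list(TRACE_COLUMNS)].isna().any().any():
        raise FormatError(f"{path.name}: missing samples")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path.name}: need at least 2 samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > 0.01 * dt):
        raise FormatError(f"{path.name}: non-uniform time step")
    return KinematicRecording(
        subject_id=subject_id or path.stem,
        trial_id=trial_id or path.stem,
        fs=1.0 / dt,
        t0=float(t[0]),
        ribcage=df["ribcage"].to_numpy(dtype=float),
        abdomen=df["abdomen"].to_numpy(dtype=float),
    )


def write_trace(rec: KinematicRecording, path: str | Path) -> None:
    """Write a recording to the documented trace CSV format."""
    pd.DataFrame(
        {"time_s": rec.time, "ribcage": rec.ribcage, "abdomen": rec.abdomen}
    ).to_csv(path, index=False, float_format="%.8g")


def _fir_taps(fs: float, band: tuple[float, float], n_samples: int) -> np.ndarray:
    """Hamming-window FIR for the band; order adapts to the band edge.

    The transition width tracks the lower edge (a 0.05 Hz high-pass needs
    a much longer filter than a 1 Hz one) but is capped so that
    forward–backward application still has room to pad on short traces.
    """
    low, high = band
    edge = low if low > 0 else high
    width = max(edge * 0.8, 0.05)
    numtaps = int(np.ceil(3.3 * fs / width)) | 1
    max_taps = max((n_samples - 2) // 3 | 1, 5)
    numtaps = min(numtaps, max_taps)
    if low > 0:
        return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")
    return signal.firwin(numtaps, high, pass_zero=True, fs=fs, window="hamming")


def filter_resample(
    rec: KinematicRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    target_fs: float = 200.0,
) -> KinematicRecording:
    """Zero-phase band-pass filter both channels and resample.

    High sampling rates are reduced first (polyphase, with its own
    anti-aliasing), then the band filter runs forward–backward at the
    target rate so no landmark moves.  Output length is
    ``round(n * target_fs / fs)``.
    """
    low, high = band
    if not 0 <= low < high:
        raise ParameterError(f"invalid band {band}")
    if high >= rec.fs / 2:
        raise ParameterError(f"band edge {high} Hz at/above Nyquist ({rec.fs / 2} Hz)")
    if target_fs > rec.fs:
        raise ParameterError("upsampling not supported")
    if high >= target_fs / 2:
        raise ParameterError(f"band edge {high} Hz at/above target Nyquist")

    n_out = int(round(len(rec) * target_fs / rec.fs))

    def _one(x: np.ndarray) -> np.ndarray:
        if target_fs != rec.fs:
            frac = _as_fraction(target_fs, rec.fs)
            x = signal.resample_poly(x, frac[0], frac[1])
            x = _fit_length(x, n_out)
        taps = _fir_taps(target_fs, band, len(x))
        padlen = min(3 * (len(taps) - 1), len(x) - 1)
        return signal.filtfilt(taps, [1.0], x, padlen=padlen)

    return KinematicRecording(
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
        fs=target_fs,
        t0=rec.t0,
        ribcage=_one(rec.ribcage),
        abdomen=_one(rec.abdomen),
    )


def _as_fraction(target_fs: float, fs: float) -> tuple[int, int]:
    from fractions import Fraction

    f = Fraction(target_fs / fs).limit_denominator(100000)
    return f.numerator, f.denominator


def _fit_length(x: np.ndarray, n: int) -> np.ndarray:
    if len(x) > n:
        return x[:n]
    if len(x) < n:
        return np.concatenate([x, np.full(n - len(x), x[-1])])
    return x


def combine_bands(
    rec: KinematicRecording, w_rc: float = 1.0, w_ab: float = 1.0
) -> CombinedTrace:
    """Sample-wise weighted band sum (default: unweighted 1:1).

    A 2:1 rib-cage weighting is the standard lung-volume proxy for this
    hardware; with synchronized bands the choice moves amplitudes but not
    cycle timing.
    """
    if w_rc <= 0 or w_ab <= 0:
        raise ParameterError(f"weights must be positive, got ({w_rc}, {w_ab})")
    return CombinedTrace(
        fs=rec.fs,
        t0=rec.t0,
        values=w_rc * rec.ribcage + w_ab * rec.abdomen,
        weights=(w_rc, w_ab),
    )


def _detect_sweeps(values: np.ndarray, fs: float) -> list[float]:
    """Trough-to-peak excursions of VC-style maneuvers.

    A sweep is a rise from a local trough to the following local peak; only
    excursions exceeding half of the global range count as maneuvers.
    """
    smoothed = signal.savgol_filter(values, min(int(fs) | 1, len(values) - (1 - len(values) % 2)), 3)
    dv = np.diff(smoothed)
    sign = np.sign(dv)
    sign[sign == 0] = 1
    turns = np.where(np.diff(sign) != 0)[0] + 1
    pts = np.concatenate([[0], turns, [len(smoothed) - 1]])
    global_range = float(np.ptp(values))
    if global_range == 0:
        return []
    excursions = []
    for a, b in zip(pts[:-1], pts[1:]):
        rise = smoothed[b] - smoothed[a]
        if rise > 0.5 * global_range:
            excursions.append(float(values[a : b + 1].max() - values[a : b + 1].min()))
    return excursions


def compute_md(
    vc: KinematicRecording,
    w_rc: float = 1.0,
    w_ab: float = 1.0,
    maneuver_windows: list[tuple[float, float]] | None = None,
) -> MaximalDisplacement:
    """Maximal displacement: largest trough-to-peak excursion across maneuvers.

    Maneuvers come from explicit label windows when given, otherwise from
    automatic detection of monotone trough-to-peak sweeps exceeding 50% of
    the global range.
    """
    trace = combine_bands(vc, w_rc, w_ab)
    values = trace.values
    if float(np.ptp(values)) == 0.0:
        raise DegenerateInputError("flat VC trace: no maneuver visible")
    if maneuver_windows:
        excs = []
        for start, end in maneuver_windows:
            i0 = max(int((start - trace.t0) * trace.fs), 0)
            i1 = min(int((end - trace.t0) * trace.fs) + 1, len(values))
            if i1 - i0 >= 2:
                excs.append(float(np.ptp(values[i0:i1])))
    else:
        excs = _detect_sweeps(values, trace.fs)
    if not excs:
        raise DegenerateInputError("no VC maneuver sweep found")
    return MaximalDisplacement(subject_id=vc.subject_id, md=max(excs))


def to_percent_md(amp: float | np.ndarray, md: MaximalDisplacement | float):
    """Express a displacement amplitude in percent of maximal displacement."""
    md_value = md.md if isinstance(md, MaximalDisplacement) else float(md)
    if md_value <= 0:
        raise ParameterError(f"MD must be positive, got {md_value}")
    return 100.0 * amp / md_value
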