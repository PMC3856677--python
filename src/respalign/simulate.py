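"""Synthetic reader/listener breathing-kinematics generator.

Emulates the playback-paradigm study conditions: pre-recorded readers
(normal / loud / slow speech modes) and standing listeners whose rib-cage
and abdomen movements are recorded while they listen.  The generator
produces two-band traces with shared cycle timing and independent band
gains, interval labels with per-chunk syllable counts, vital-capacity
maneuvers, movement-artifact spikes, and a full ground truth so every
downstream stage (filtering, segmentation, alignment, statistics) can be
validated without the unreleased human recordings.

Reader breathing is speech-like: a fast raised-cosine inhalation occupying
a small fraction of the cycle, then a slow exponential exhalation spanning
labeled multi-syllable speech chunks.  Listener breathing is quiet-ish
(cycle ~3.3 s) and can be generated independent of the reader, as a
homogeneous Poisson process of inhalation onsets (the analytic null for
phase-position statistics), or phase-locked to the reader's cycles.

All randomness flows through ``numpy.random.Generator`` objects derived
from a master seed plus stable per-trial keys, so any trial is
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    ContractError,
    GroundTruth,
    IntervalLabels,
    KinematicRecording,
    ParameterError,
    SpeechChunk,
)

__all__ = [
    "ConditionEffect",
    "ReaderSimParams",
    "ListenerSimParams",
    "ExperimentBundle",
    "MALE_READER",
    "FEMALE_READER",
    "DEFAULT_LISTENER",
    "trial_rng",
    "simulate_reader_trial",
    "simulate_listener_trial",
    "simulate_vc",
    "make_design",
    "simulate_experiment",
    "simulate_parameter_table",
]


@dataclass(frozen=True)
class ConditionEffect:
    """Additive shifts applied under one speech-mode condition."""

    cycle_dur: float = 0.0  # s
    inhal_amp: float = 0.0  # displacement units
    syllables: float = 0.0  # syllables per cycle


@dataclass
class ReaderSimParams:
    """Generative parameters for one reader's speech breathing.

    Durations in seconds, amplitudes in arbitrary displacement units (the
    VC maneuver sets the %MD scale).  ``condition_effects`` maps condition
    labels to additive offsets on cycle duration, inhalation amplitude and
    syllables per cycle.
    """

    mean_cycle_dur: float = 5.5
    cycle_dur_sd: float = 0.8
    inhal_frac: float = 0.15
    inhal_amp_mean: float = 1.8
    inhal_amp_sd: float = 0.25
    syllables_per_cycle_mean: float = 16.0
    syllable_rate: float = 5.5
    condition_effects: dict[str, ConditionEffect] = field(default_factory=dict)
    trial_dur: float = 60.0
    fs: float = 200.0
    snr_db: float = 30.0

    def __post_init__(self) -> None:
        if self.mean_cycle_dur <= 0 or self.trial_dur <= 0 or self.fs <= 0:
            raise ParameterError("durations and fs must be positive")
        if not 0.0 < self.inhal_frac < 0.5:
            raise ParameterError(f"inhal_frac must be in (0, 0.5), got {self.inhal_frac}")
        if self.inhal_amp_mean <= 0:
            raise ParameterError("inhal_amp_mean must be positive")
        if self.cycle_dur_sd < 0 or self.inhal_amp_sd < 0:
            raise ParameterError("standard deviations must be non-negative")


@dataclass
class ListenerSimParams:
    """Generative parameters for listener breathing during the task.

    ``coupling_mode`` selects how inhalation onsets relate to the reader:
    ``independent`` (truncated-Gaussian renewal process), ``poisson``
    (homogeneous Poisson onsets — phase positions within reader cycles are
    then Uniform(0,1)), or ``phase_locked`` (one onset per reader cycle at
    ``coupling_phase`` of the cycle plus Gaussian jitter, both as cycle
    fractions).  ``artifact_rate`` is movement-spike events per minute.
    """

    mean_cycle_dur: float = 3.3
    cycle_dur_sd: float = 0.5
    inhal_frac: float = 0.30
    inhal_amp_mean: float = 1.5
    inhal_amp_sd: float = 0.3
    coupling_mode: str = "independent"
    coupling_phase: float = 0.15
    coupling_jitter_sd: float = 0.03
    condition_effects: dict[str, ConditionEffect] = field(default_factory=dict)
    artifact_rate: float = 0.0
    fs: float = 200.0
    snr_db: float = 20.0

    def __post_init__(self) -> None:
        if self.mean_cycle_dur <= 0 or self.fs <= 0:
            raise ParameterError("mean_cycle_dur and fs must be positive")
        if not 0.0 < self.inhal_frac < 0.5:
            raise ParameterError(f"inhal_frac must be in (0, 0.5), got {self.inhal_frac}")
        if self.coupling_mode not in ("independent", "poisson", "phase_locked"):
            raise ParameterError(f"unknown coupling_mode {self.coupling_mode!r}")
        if not 0.0 <= self.coupling_phase < 1.0:
            raise ParameterError("coupling_phase must be in [0, 1)")
        if self.artifact_rate < 0:
            raise ParameterError("artifact_rate must be >= 0")
        if self.inhal_amp_mean <= 0:
            raise ParameterError("inhal_amp_mean must be positive")


# Presets reflecting the study's two readers: the female reader breathed
# faster (cycles ~2.5 s shorter), with slightly smaller inhalations and
# ~8 fewer syllables per cycle; loud speech lengthened the male reader's
# cycles (+1.1 s) and deepened inhalation for both; slow speech deepened
# the female reader's inhalations and cut syllables per cycle.
MALE_READER = ReaderSimParams(
    mean_cycle_dur=5.5,
    inhal_amp_mean=1.8,
    syllables_per_cycle_mean=18.0,
    condition_effects={
        "L": ConditionEffect(cycle_dur=1.1, inhal_amp=0.55, syllables=2.8),
    },
)

FEMALE_READER = ReaderSimParams(
    mean_cycle_dur=3.0,
    cycle_dur_sd=0.5,
    inhal_amp_mean=1.4,
    syllables_per_cycle_mean=10.0,
    condition_effects={
        "L": ConditionEffect(cycle_dur=0.0, inhal_amp=0.25, syllables=-1.2),
        "Ln": ConditionEffect(cycle_dur=0.0, inhal_amp=0.25, syllables=-1.2),
        "S": ConditionEffect(cycle_dur=0.0, inhal_amp=0.87, syllables=-4.5),
    },
)

# Listener defaults follow the listening-condition averages (durC ~3.3 s,
# ampI ~15 %MD with MD = 10 units); the loud condition shortened cycles by
# ~139 ms and shallowed inhalation slightly.
DEFAULT_LISTENER = ListenerSimParams(
    condition_effects={
        "L": ConditionEffect(cycle_dur=-0.139, inhal_amp=-0.023),
        "Ln": ConditionEffect(cycle_dur=-0.139, inhal_amp=-0.05),
        "S": ConditionEffect(cycle_dur=0.178, inhal_amp=-0.1),
    },
)

VC_AMP_DEFAULT = 10.0  # displacement units; sets the %MD scale


def _key(*parts) -> list[int]:
    out = []
    for p in parts:
        if isinstance(p, (int, np.integer)):
            out.append(int(p) & 0x7FFFFFFF)
        else:
            out.append(zlib.crc32(str(p).encode()))
    return out


def trial_rng(master_seed: int, *parts) -> np.random.Generator:
    """Independent generator for one trial, keyed by (seed, ids...)."""
    return np.random.default_rng(_key(master_seed, *parts))


def _truncated_normal(rng, mean, sd, lower, size=None):
    """Gaussian draw redrawn (then clipped) to stay above ``lower``."""
    x = rng.normal(mean, sd, size=size)
    for _ in range(10):
        bad = x < lower
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
    return np.clip(x, lower, None)


def _draw_cycles(rng, mean_dur, sd_dur, amp_mean, amp_sd, t_start, t_end):
    """Renewal sequence of (onset, durC, amp) filling [t_start, t_end)."""
    onsets, durs, amps = [], [], []
    t = t_start
    min_dur = 0.5 * mean_dur  # truncation guards against degenerate cycles
    while True:
        d = float(_truncated_normal(rng, mean_dur, sd_dur, min_dur))
        if t + d > t_end:
            break
        onsets.append(t)
        durs.append(d)
        amps.append(float(_truncated_normal(rng, amp_mean, amp_sd, 0.1 * amp_mean)))
        t += d
    # closing onset: boundary of the last full cycle, rendered as a real
    # inhalation so the trace carries every ground-truth onset
    onsets.append(t)
    return onsets, durs, amps


def _render_trace(n, fs, onsets, durs, amps, inhal_frac):
    """Piecewise waveform: raised-cosine rise, exponential decay to baseline.

    Returns (values, offsets): offset i is the inhalation end of cycle i.
    The decay time constant is durPI/4, so each cycle returns to within
    ~2% of baseline before the next onset; onset/offset landmarks carry a
    single unambiguous velocity peak each, as in the detection model.
    """
    x = np.zeros(n)
    t = np.arange(n) / fs
    offsets = []
    for onset, dur, amp in zip(onsets, durs, amps):
        dur_i = inhal_frac * dur
        off = onset + dur_i
        offsets.append(off)
        i0 = int(np.ceil(onset * fs))
        i1 = min(int(np.floor(off * fs)), n - 1)
        u = (t[i0 : i1 + 1] - onset) / dur_i
        x0 = x[i0 - 1] if i0 > 0 else 0.0
        x[i0 : i1 + 1] = x0 + amp * 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0, 1)))
        peak = x0 + amp
        dur_pi = dur - dur_i
        tau = dur_pi / 4.0
        j0, j1 = i1 + 1, min(int(np.ceil((onset + dur) * fs)), n)
        if j0 < j1:
            x[j0:j1] = peak * np.exp(-(t[j0:j1] - off) / tau)
        # keep tail at final decay value until next cycle overwrites it
        if j1 < n:
            x[j1:] = x[j1 - 1] if j1 > 0 else 0.0
    return x, offsets


def _two_band(rng, values, fs, subject_id, trial_id, snr_db, t0=0.0):
    """Split a combined waveform into synchronized rib-cage/abdomen bands.

    Gains sum to 1 so the unweighted band sum reproduces ``values`` (plus
    noise); timing is shared exactly between bands.
    """
    rc_gain = float(rng.uniform(0.55, 0.75))
    ab_gain = 1.0 - rc_gain
    rms = float(np.sqrt(np.mean(np.square(values)))) or 1.0
    noise_sd = rms * 10.0 ** (-snr_db / 20.0)
    rib = rc_gain * values + rng.normal(0.0, noise_sd * rc_gain, len(values))
    abd = ab_gain * values + rng.normal(0.0, noise_sd * ab_gain, len(values))
    return KinematicRecording(
        subject_id=subject_id, trial_id=trial_id, fs=fs, ribcage=rib, abdomen=abd, t0=t0
    )


def simulate_reader_trial(
    params: ReaderSimParams,
    text_id: str,
    condition: str,
    seed: int,
    reader_id: str = "reader",
) -> tuple[KinematicRecording, IntervalLabels, GroundTruth]:
    """Simulate one reader recording of one text in one speech mode.

    The trace is a two-band recording with a fast inhalation and a long
    exhalation per cycle; each exhalation carries one labeled speech chunk
    whose syllable count follows the condition-shifted per-cycle mean.
    Speech onset is the start of the first chunk.
    """
    if not isinstance(params, ReaderSimParams):
        raise ParameterError("params must be ReaderSimParams")
    eff = params.condition_effects.get(condition, ConditionEffect())
    rng = trial_rng(seed, "reader", reader_id, text_id, condition)
    fs = params.fs
    n = int(round(params.trial_dur * fs))
    mean_dur = params.mean_cycle_dur + eff.cycle_dur
    amp_mean = params.inhal_amp_mean + eff.inhal_amp
    # leave room for the closing inhalation to complete before trial end
    margin = params.inhal_frac * mean_dur + 0.5
    onsets, durs, amps = _draw_cycles(
        rng, mean_dur, params.cycle_dur_sd, amp_mean, params.inhal_amp_sd,
        t_start=1.0, t_end=params.trial_dur - margin,
    )
    durs_ext = durs + [min(mean_dur, params.trial_dur - onsets[-1])]
    amps_ext = amps + [
        float(_truncated_normal(rng, amp_mean, params.inhal_amp_sd, 0.1 * amp_mean))
    ]
    values, offsets = _render_trace(n, fs, onsets, durs_ext, amps_ext, params.inhal_frac)
    trial_id = f"{reader_id}_{text_id}_{condition}"
    rec = _two_band(rng, values, fs, reader_id, trial_id, params.snr_db)

    chunks = []
    syl_mean = max(params.syllables_per_cycle_mean + eff.syllables, 1.0)
    for onset, dur, off in zip(onsets[:-1], durs, offsets):
        n_syl = max(1, int(round(rng.normal(syl_mean, 0.15 * syl_mean))))
        start = off + 0.1  # short pause after inhalation before speaking
        avail = onset + dur - 0.1 - start
        want = n_syl / params.syllable_rate
        end = start + min(want, max(avail, 0.2))
        chunks.append(SpeechChunk(start_s=start, end_s=end, syllables=n_syl))
    labels = IntervalLabels(
        trial_id=trial_id,
        speech_onset_s=chunks[0].start_s if chunks else 0.0,
        speech_offset_s=chunks[-1].end_s if chunks else params.trial_dur,
        chunks=chunks,
    )
    truth = GroundTruth(onsets=onsets, offsets=offsets, ampI=amps)
    return rec, labels, truth


def _inject_artifacts(rng, values, fs, rate_per_min, cycle_peak_vel):
    """Triangular movement spikes; returns (values, windows)."""
    windows = []
    n = len(values)
    dur_total_min = n / fs / 60.0
    n_spikes = rng.poisson(rate_per_min * dur_total_min)
    t = np.arange(n) / fs
    for _ in range(n_spikes):
        width = float(rng.uniform(0.15, 0.3))
        start = float(rng.uniform(1.0, n / fs - width - 1.0))
        # peak velocity of the triangle is height/(width/2); target >= 6x
        # the typical cycle peak velocity so a velocity flagger can see it
        mult = float(rng.uniform(6.0, 10.0))
        height = mult * cycle_peak_vel * (width / 2.0)
        mask = (t >= start) & (t <= start + width)
        tri = 1.0 - np.abs((t[mask] - start - width / 2.0) / (width / 2.0))
        values = values.copy()
        values[mask] += height * tri
        windows.append((start, start + width))
    windows.sort()
    return values, windows


def simulate_listener_trial(
    params: ListenerSimParams,
    reader_truth: GroundTruth | None,
    condition: str,
    seed: int,
    listener_id: str = "listener",
    trial_id: str | None = None,
    duration: float | None = None,
) -> tuple[KinematicRecording, GroundTruth]:
    """Simulate one listener recording for one playback trial."""
    if not isinstance(params, ListenerSimParams):
        raise ParameterError("params must be ListenerSimParams")
    if params.coupling_mode != "independent" and reader_truth is None:
        raise ContractError(
            f"coupling_mode={params.coupling_mode!r} requires reader ground truth"
        )
    eff = params.condition_effects.get(condition, ConditionEffect())
    rng = trial_rng(seed, "listener", listener_id, trial_id or "", condition)
    fs = params.fs
    if duration is None:
        duration = (reader_truth.onsets[-1] + 2.0) if reader_truth else 60.0
    n = int(round(duration * fs))
    mean_dur = params.mean_cycle_dur + eff.cycle_dur
    amp_mean = params.inhal_amp_mean + eff.inhal_amp

    # leave room for the closing inhalation to complete before trial end
    margin = params.inhal_frac * mean_dur + 0.5
    if params.coupling_mode == "independent":
        onsets, durs, amps = _draw_cycles(
            rng, mean_dur, params.cycle_dur_sd, amp_mean, params.inhal_amp_sd,
            t_start=1.0, t_end=duration - margin,
        )
    elif params.coupling_mode == "poisson":
        onsets = []
        t = 1.0
        while True:
            t += float(rng.exponential(mean_dur))
            if t > duration - margin:
                break
            onsets.append(t)
        if len(onsets) < 2:
            onsets = [1.0, duration - margin]
        durs = list(np.diff(onsets))
        amps = list(
            _truncated_normal(rng, amp_mean, params.inhal_amp_sd, 0.1 * amp_mean,
                              size=len(durs))
        )
    else:  # phase_locked
        r_on = np.asarray(reader_truth.onsets)
        onsets = []
        for i in range(len(r_on) - 1):
            dur_c = r_on[i + 1] - r_on[i]
            frac = params.coupling_phase + float(rng.normal(0.0, params.coupling_jitter_sd))
            onsets.append(float(r_on[i] + frac * dur_c))
        onsets = sorted(t for t in onsets if 0.5 < t < duration - margin)
        durs = list(np.diff(onsets))
        amps = list(
            _truncated_normal(rng, amp_mean, params.inhal_amp_sd, 0.1 * amp_mean,
                              size=len(durs))
        )
        if len(onsets) < 2:
            raise ContractError("phase-locked trial produced <2 listener onsets")

    # closing onset is rendered as a real inhalation so every ground-truth
    # onset is present in the trace; inhalation must also fit inside its
    # cycle even for short Poisson gaps
    durs_ext = durs + [min(mean_dur, duration - onsets[-1])]
    amps_ext = amps + [
        float(_truncated_normal(rng, amp_mean, params.inhal_amp_sd, 0.1 * amp_mean))
    ]
    inhal_durs = [min(params.inhal_frac * mean_dur, 0.5 * d) for d in durs_ext]
    values = np.zeros(n)
    tgrid = np.arange(n) / fs
    offsets = []
    for onset, d_i, d_c, amp in zip(onsets, inhal_durs, durs_ext, amps_ext):
        off = onset + d_i
        offsets.append(off)
        i0 = int(np.ceil(onset * fs))
        i1 = min(int(np.floor(off * fs)), n - 1)
        x0 = values[i0 - 1] if i0 > 0 else 0.0
        u = (tgrid[i0 : i1 + 1] - onset) / d_i
        values[i0 : i1 + 1] = x0 + amp * 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0, 1)))
        peak = x0 + amp
        tau = max(d_c - d_i, 1e-3) / 4.0
        j0 = i1 + 1
        j1 = min(int(np.ceil((onset + d_c) * fs)), n)
        if j0 < j1:
            values[j0:j1] = peak * np.exp(-(tgrid[j0:j1] - off) / tau)
        if j1 < n:
            values[j1:] = values[j1 - 1] if j1 > 0 else 0.0

    cycle_peak_vel = amp_mean * np.pi / (2.0 * params.inhal_frac * mean_dur)
    values, art_windows = _inject_artifacts(
        rng, values, fs, params.artifact_rate, cycle_peak_vel
    )
    rec = _two_band(
        rng, values, fs, listener_id, trial_id or f"{listener_id}_{condition}",
        params.snr_db,
    )
    truth = GroundTruth(
        onsets=list(onsets), offsets=offsets, ampI=list(amps),
        artifact_windows=art_windows,
    )
    return rec, truth


def simulate_vc(
    amp: float,
    n_trials: int = 3,
    seed: int = 0,
    subject_id: str = "subject",
    fs: float = 200.0,
) -> KinematicRecording:
    """Simulate vital-capacity maneuvers: max exhale then max inhale.

    ``n_trials`` trough-to-peak sweeps separated by rest; sweep excursions
    vary a few percent trial to trial, and the largest equals ``amp``
    exactly, so the maximal displacement downstream is ``amp``.
    """
    if amp <= 0:
        raise ParameterError(f"VC amplitude must be positive, got {amp}")
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = trial_rng(seed, "vc", subject_id)
    fractions = rng.uniform(0.88, 0.97, size=n_trials)
    fractions[int(rng.integers(n_trials))] = 1.0  # largest sweep == amp
    sweep_dur, rest_dur = 4.0, 2.0
    total = n_trials * (sweep_dur + rest_dur) + rest_dur
    n = int(round(total * fs))
    t = np.arange(n) / fs
    values = np.zeros(n)
    for k, f in enumerate(fractions):
        exc = amp * f
        start = rest_dur + k * (sweep_dur + rest_dur)
        lo, hi = -0.45 * exc, 0.55 * exc
        # descend to the trough, rise through the full excursion, return
        seg = [(start, start + 1.0, 0.0, lo),
               (start + 1.0, start + 3.0, lo, hi),
               (start + 3.0, start + 4.0, hi, 0.0)]
        for a, b, va, vb in seg:
            m = (t >= a) & (t < b)
            u = (t[m] - a) / (b - a)
            values[m] = va + (vb - va) * 0.5 * (1.0 - np.cos(np.pi * u))
    return _two_band(rng, values, fs, subject_id, f"{subject_id}_vc", snr_db=40.0)


@dataclass
class ExperimentBundle:
    """Everything one simulated experiment produced, keyed for lookup."""

    design: pd.DataFrame
    reader_trials: dict[tuple[str, str, str], tuple[KinematicRecording, IntervalLabels, GroundTruth]]
    listener_trials: dict[tuple[str, int], tuple[KinematicRecording, GroundTruth]]
    vc: dict[str, KinematicRecording]
    vc_amp: dict[str, float]
    seed: int = 0

    @property
    def n_listener_trials(self) -> int:
        return len(self.listener_trials)


def make_design(
    n_listeners: int,
    conditions: tuple[str, str] = ("N", "L"),
    readers: tuple[str, ...] = ("F", "M"),
    n_texts_per_condition: int = 5,
    text_pool: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Counter-balanced design table: one row per listener trial.

    Listeners split evenly across readers; condition order alternates
    (e.g. LN vs NL); each listener hears ``n_texts_per_condition`` distinct
    texts per condition drawn from a shared pool.
    """
    if n_listeners < 1:
        raise ParameterError("need at least one listener")
    if len(conditions) != 2:
        raise ParameterError("exactly two conditions per experiment")
    if text_pool < 2 * n_texts_per_condition:
        raise ParameterError("text pool too small for distinct per-condition texts")
    rng = trial_rng(seed, "design")
    rows = []
    for li in range(n_listeners):
        listener = f"S{li + 1:02d}"
        reader = readers[li % len(readers)]
        # order counterbalanced within each reader group, not aliased to it
        first_second = (
            conditions if (li // len(readers)) % 2 == 0 else conditions[::-1]
        )
        order = "".join(first_second)
        texts = rng.choice(text_pool, size=2 * n_texts_per_condition, replace=False)
        for ti in range(2 * n_texts_per_condition):
            cond = first_second[0] if ti < n_texts_per_condition else first_second[1]
            rows.append(
                dict(
                    listener=listener,
                    reader=reader,
                    text=f"T{int(texts[ti]) + 1:02d}",
                    condition=cond,
                    order=order,
                    trial_index=ti + 1,
                )
            )
    return pd.DataFrame(rows)


def _validate_design(design: pd.DataFrame) -> None:
    required = {"listener", "reader", "text", "condition", "order", "trial_index"}
    missing = required - set(design.columns)
    if missing:
        raise ParameterError(f"design table missing columns: {sorted(missing)}")
    if len(design) == 0:
        raise ParameterError("design table is empty")
    for listener, grp in design.groupby("listener"):
        if grp["trial_index"].duplicated().any():
            raise ParameterError(f"duplicate trial_index for listener {listener}")


def simulate_experiment(
    design: pd.DataFrame,
    reader_params: Mapping[str, ReaderSimParams] | ReaderSimParams | None = None,
    listener_params: ListenerSimParams | None = None,
    seed: int = 0,
    vc_amp: float = VC_AMP_DEFAULT,
) -> ExperimentBundle:
    """Simulate a full playback experiment from a design table.

    Reader recordings are generated once per (reader, text, condition) —
    the corpus is pre-recorded and shared across listeners, which is what
    makes the surrogate random re-pairing meaningful downstream.
    """
    _validate_design(design)
    if reader_params is None:
        reader_params = {"M": MALE_READER, "F": FEMALE_READER}
    if isinstance(reader_params, ReaderSimParams):
        reader_params = {r: reader_params for r in design["reader"].unique()}
    listener_params = listener_params or DEFAULT_LISTENER

    reader_trials = {}
    for reader, text, cond in (
        design[["reader", "text", "condition"]].drop_duplicates().itertuples(index=False)
    ):
        rp = reader_params[reader]
        reader_trials[(reader, text, cond)] = simulate_reader_trial(
            rp, text, cond, seed=seed, reader_id=reader
        )

    listener_trials = {}
    vc, vc_amp_map = {}, {}
    for row in design.itertuples(index=False):
        r_truth = reader_trials[(row.reader, row.text, row.condition)][2]
        trial_id = f"{row.listener}_t{row.trial_index:02d}"
        listener_trials[(row.listener, int(row.trial_index))] = simulate_listener_trial(
            listener_params,
            r_truth,
            row.condition,
            seed=seed,
            listener_id=row.listener,
            trial_id=trial_id,
        )
    subjects = list(design["listener"].unique()) + list(design["reader"].unique())
    rng = trial_rng(seed, "vc_amps")
    for sub in subjects:
        a = vc_amp * float(rng.uniform(0.9, 1.1))
        vc[sub] = simulate_vc(a, seed=seed, subject_id=sub)
        vc_amp_map[sub] = a
    return ExperimentBundle(
        design=design.copy(),
        reader_trials=reader_trials,
        listener_trials=listener_trials,
        vc=vc,
        vc_amp=vc_amp_map,
        seed=seed,
    )


def simulate_parameter_table(
    n_listeners: int = 26,
    trials_per_listener: int = 10,
    cycles_per_trial: int = 15,
    condition_effect_dur: float = 0.0,
    condition_effect_amp: float = 0.0,
    drift_per_trial_dur: float = 0.0,
    drift_trials: tuple[int, int] = (1, 5),
    mean_dur: float = 3.3,
    mean_amp: float = 14.7,
    sd_listener: float = 0.35,
    sd_text: float = 0.12,
    sd_resid_dur: float = 0.6,
    sd_resid_amp: float = 3.0,
    readers: tuple[str, ...] = ("F", "M"),
    conditions: tuple[str, str] = ("N", "L"),
    seed: int = 0,
) -> pd.DataFrame:
    """Cycle-parameter table drawn straight from the mixed-model DGP.

    Each retained cycle's duration (s) and inhalation amplitude (%MD) is
    mean + condition shift + listener intercept + text intercept + noise;
    an optional per-trial drift applies between ``drift_trials`` (used for
    trial-progression checks).  This bypasses trace synthesis so model
    calibration studies stay cheap; trace-level recovery is validated
    separately.
    """
    rng = trial_rng(seed, "paramtable")
    design = make_design(
        n_listeners, conditions=conditions, readers=readers,
        n_texts_per_condition=trials_per_listener // 2, seed=seed,
    )
    listeners = design["listener"].unique()
    texts = design["text"].unique()
    b_l = dict(zip(listeners, rng.normal(0.0, sd_listener, len(listeners))))
    b_t = dict(zip(texts, rng.normal(0.0, sd_text, len(texts))))
    b_l_amp = dict(zip(listeners, rng.normal(0.0, 2.0 * sd_listener, len(listeners))))
    b_t_amp = dict(zip(texts, rng.normal(0.0, 2.0 * sd_text, len(texts))))
    lo, hi = drift_trials
    rows = []
    for row in design.itertuples(index=False):
        is_second = row.condition == conditions[1]
        drift = 0.0
        if drift_per_trial_dur and lo <= row.trial_index <= hi:
            drift = drift_per_trial_dur * (row.trial_index - lo)
        elif drift_per_trial_dur and row.trial_index > hi:
            drift = drift_per_trial_dur * (hi - lo)
        mu_d = mean_dur + (condition_effect_dur if is_second else 0.0) + drift
        mu_a = mean_amp + (condition_effect_amp if is_second else 0.0)
        n_c = max(int(rng.poisson(cycles_per_trial)), 4)
        for ci in range(n_c):
            rows.append(
                dict(
                    listener=row.listener,
                    reader=row.reader,
                    text=row.text,
                    condition=row.condition,
                    order=row.order,
                    trial_index=row.trial_index,
                    cycle_index=ci,
                    durC=max(
                        mu_d + b_l[row.listener] + b_t[row.text]
                        + rng.normal(0.0, sd_resid_dur),
                        0.3,
                    ),
                    ampI=max(
                        mu_a + b_l_amp[row.listener] + b_t_amp[row.text]
                        + rng.normal(0.0, sd_resid_amp),
                        0.5,
                    ),
                )
            )
    return pd.DataFrame(rows)
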