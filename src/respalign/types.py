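"""Core containers for respiratory-kinematics analysis.

Displacement traces come from inductance-plethysmography bands around the
rib cage and the abdomen; their (optionally weighted) sum is the working
proxy for lung-volume change.  Amplitudes are expressed in percent of each
subject's maximal displacement (%MD) obtained from vital-capacity (VC)
maneuvers; all times are in seconds, sample k of a trace lives at
``t0 + k / fs`` (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KinematicRecording",
    "CombinedTrace",
    "MaximalDisplacement",
    "SpeechChunk",
    "IntervalLabels",
    "InhalationEvent",
    "BreathingCycle",
    "GroundTruth",
    "KSResult",
    "ParameterError",
    "FormatError",
    "LabelError",
    "DegenerateInputError",
    "ContractError",
]


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


class FormatError(ValueError):
    """Malformed input file."""


class LabelError(ValueError):
    """Missing or inconsistent interval labels."""


class DegenerateInputError(ValueError):
    """Input too short / flat / empty for the requested operation."""


class ContractError(ValueError):
    """Caller violated an operation's precondition."""


@dataclass
class KinematicRecording:
    """Two-band displacement recording (rib cage + abdomen), uniform rate."""

    subject_id: str
    trial_id: str
    fs: float
    ribcage: np.ndarray
    abdomen: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ribcage = np.asarray(self.ribcage, dtype=float)
        self.abdomen = np.asarray(self.abdomen, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.ribcage.ndim != 1 or self.abdomen.ndim != 1:
            raise FormatError("channels must be 1-D")
        if len(self.ribcage) != len(self.abdomen):
            raise FormatError(
                "rib-cage and abdomen channels have unequal lengths "
                f"({len(self.ribcage)} vs {len(self.abdomen)})"
            )
        if np.isnan(self.ribcage).any() or np.isnan(self.abdomen).any():
            raise FormatError("missing samples (NaN) in recording")

    def __len__(self) -> int:
        return len(self.ribcage)

    @property
    def duration(self) -> float:
        return len(self.ribcage) / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.ribcage)) / self.fs


@dataclass
class CombinedTrace:
    """Weighted band sum, the series on which cycles are detected."""

    fs: float
    values: np.ndarray
    weights: tuple[float, float] = (1.0, 1.0)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if any(w <= 0 for w in self.weights):
            raise ParameterError(f"weights must be positive, got {self.weights}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    def shifted(self, dt: float) -> "CombinedTrace":
        return replace(self, t0=self.t0 + dt)


@dataclass(frozen=True)
class MaximalDisplacement:
    """Per-subject maximal displacement (MD) from VC maneuvers."""

    subject_id: str
    md: float

    def __post_init__(self) -> None:
        if not self.md > 0:
            raise ParameterError(f"MD must be positive, got {self.md}")


@dataclass(frozen=True)
class SpeechChunk:
    """One inter-pausal speech interval with its syllable count."""

    start_s: float
    end_s: float
    syllables: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise LabelError(f"chunk end {self.end_s} <= start {self.start_s}")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class IntervalLabels:
    """Interval annotation for one trial: speech onset/offset + chunks."""

    trial_id: str
    speech_onset_s: float
    speech_offset_s: float
    chunks: list[SpeechChunk] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [c.start_s for c in self.chunks]
        if starts != sorted(starts):
            raise LabelError("speech chunks must be time-ordered")
        for a, b in zip(self.chunks, self.chunks[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise LabelError(
                    f"overlapping chunks at {a.end_s:.3f}/{b.start_s:.3f} s"
                )


@dataclass(frozen=True)
class InhalationEvent:
    """One detected inhalation: onset, offset and velocity-peak landmarks."""

    onset_t: float
    offset_t: float
    peak_vel_t: float
    peak_vel: float

    def __post_init__(self) -> None:
        if not (self.onset_t <= self.peak_vel_t <= self.offset_t):
            raise ContractError(
                f"landmarks out of order: onset {self.onset_t}, "
                f"peak {self.peak_vel_t}, offset {self.offset_t}"
            )


@dataclass
class BreathingCycle:
    """One breathing cycle: inhalation (I) then post-inhalation (PI) phase.

    ``durC`` is onset-to-next-onset, ``ampI`` the onset-to-offset displacement
    of the inhalation in %MD.  ``flags`` may contain ``artifact``, ``outlier``
    and ``first_cycle``; flagged cycles are retained in tables but excluded
    from analysis.
    """

    onset_t: float
    inhal_offset_t: float
    next_onset_t: float
    ampI: float
    subject_id: str = ""
    trial_id: str = ""
    cycle_index: int = 0
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.onset_t < self.inhal_offset_t < self.next_onset_t):
            raise ContractError(
                f"cycle boundaries out of order: {self.onset_t}, "
                f"{self.inhal_offset_t}, {self.next_onset_t}"
            )

    @property
    def durC(self) -> float:
        return self.next_onset_t - self.onset_t

    @property
    def durI(self) -> float:
        return self.inhal_offset_t - self.onset_t

    @property
    def durPI(self) -> float:
        return self.next_onset_t - self.inhal_offset_t


@dataclass
class GroundTruth:
    """Generator-side truth for one simulated trial."""

    onsets: list[float] = field(default_factory=list)
    offsets: list[float] = field(default_factory=list)
    ampI: list[float] = field(default_factory=list)
    artifact_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets)
        if len(on) > 1 and not (np.diff(on) > 0).all():
            raise ContractError("ground-truth onsets must be strictly increasing")
        for i, off in enumerate(self.offsets):
            if off <= self.onsets[i]:
                raise ContractError("offset must follow its onset")
            if i + 1 < len(self.onsets) and off >= self.onsets[i + 1]:
                raise ContractError("offset must precede the next onset")

    @property
    def durC(self) -> np.ndarray:
        """Cycle durations; the last onset has no following cycle."""
        return np.diff(np.asarray(self.onsets))

    @property
    def n_cycles(self) -> int:
        return max(len(self.onsets) - 1, 0)


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison."""

    D: float
    p: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.D <= 1.0):
            raise ContractError(f"D out of range: {self.D}")
        if not (0.0 <= self.p <= 1.0 + 1e-12):
            raise ContractError(f"p out of range: {self.p}")
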