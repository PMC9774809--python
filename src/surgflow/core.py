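"""Core domain types for timed phase-probability streams.

A laparoscopic cholecystectomy (LC) is modelled as a sequence of seven
procedural phases, from patient/port preparation through gallbladder
extraction.  Two classifier modalities produce probability estimates over
those phases:

* a **video** model scores individual endoscopic frames at a fixed frame
  rate, emitting one probability vector per frame over the procedural
  phases only;
* a **speech** model scores utterance fragments — half-open time intervals
  ``[start, end)`` cut at silences in the surgeon's narration — emitting a
  probability vector over the procedural phases *plus* a trailing
  pseudo-phase that absorbs off-task operating-room talk.

Time is continuous in seconds from procedure start (``t = 0`` at the first
frame).  Frames are instants; audio fragments are half-open intervals, which
gives unambiguous frame-to-fragment membership.  Probability vectors whose
mass deviates from 1 by at most :data:`PROB_TOL` are renormalised on ingest
(CSV round-trip jitter); larger deviations are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

__all__ = [
    "DEFAULT_PHASES",
    "PSEUDO_PHASE",
    "PROB_TOL",
    "TIME_TOL",
    "StreamValidationError",
    "PhaseSet",
    "FrameSample",
    "AudioFragment",
    "VideoStream",
    "AudioStream",
    "as_probabilities",
    "validate_stream",
]

#: Canonical LC phases, in procedural order (index-addressable 0..6).
DEFAULT_PHASES: tuple[str, ...] = (
    "preparation",
    "calot_triangle_dissection",
    "clipping_cutting",
    "gallbladder_dissection",
    "gallbladder_packaging",
    "cleaning_coagulation",
    "gallbladder_extraction",
)

#: Reserved class name for speech unrelated to any procedural phase.
PSEUDO_PHASE = "__pseudo__"

#: Tolerance on probability-vector mass; within it vectors are renormalised.
PROB_TOL = 1e-9

#: Tolerance on the frame grid (inter-frame spacing vs. 1/fps), seconds.
TIME_TOL = 1e-6


class StreamValidationError(ValueError):
    """A prediction stream violates one of its structural invariants."""


@dataclass(frozen=True)
class PhaseSet:
    """Ordered set of procedural phase names plus the audio pseudo-phase.

    The pseudo-phase is *not* a member of the procedural list: it exists
    only in audio probability vectors (always as the last index) and is
    consumed during fusion — it never reaches segments, metrics or
    workflow models.
    """

    phases: tuple[str, ...] = DEFAULT_PHASES
    pseudo_phase: str = PSEUDO_PHASE

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if len(self.phases) < 2:
            raise ValueError("a phase set needs at least 2 procedural phases")
        if len(set(self.phases)) != len(self.phases):
            raise ValueError("phase names must be unique")
        if self.pseudo_phase in self.phases:
            raise ValueError("the pseudo-phase may not be a procedural phase")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def audio_classes(self) -> tuple[str, ...]:
        """Class names seen by the speech model: phases + pseudo, pseudo last."""
        return self.phases + (self.pseudo_phase,)

    @property
    def pseudo_index(self) -> int:
        return len(self.phases)

    def index(self, name: str) -> int:
        try:
            return self.phases.index(name)
        except ValueError:
            raise KeyError(f"unknown phase {name!r}") from None

    def name(self, index: int) -> str:
        return self.phases[index]


def as_probabilities(
    values: Iterable[float],
    n_classes: int | None = None,
    *,
    where: str = "",
) -> np.ndarray:
    """Validate and renormalise a probability vector.

    Entries must be non-negative and sum to 1 within :data:`PROB_TOL`;
    vectors within tolerance are renormalised to an exact unit sum.
    """
    arr = np.asarray(values, dtype=float)
    ctx = f" {where}" if where else ""
    if arr.ndim != 1:
        raise StreamValidationError(f"probability vector must be 1-D{ctx}")
    if n_classes is not None and arr.size != n_classes:
        raise StreamValidationError(
            f"expected {n_classes} probabilities, got {arr.size}{ctx}"
        )
    if not np.all(np.isfinite(arr)):
        raise StreamValidationError(f"non-finite probability{ctx}")
    if np.any(arr < 0):
        raise StreamValidationError(f"negative probability{ctx}")
    total = float(arr.sum())
    if abs(total - 1.0) > PROB_TOL:
        raise StreamValidationError(f"probability mass {total:.6g} ≠ 1{ctx}")
    return arr / total


@dataclass(frozen=True)
class FrameSample:
    """One video frame: an instant with a distribution over procedural phases."""

    timestamp: float
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise StreamValidationError(
                f"frame timestamp {self.timestamp} < 0"
            )
        object.__setattr__(self, "probs", as_probabilities(self.probs))


@dataclass(frozen=True)
class AudioFragment:
    """One speech fragment over ``[start, end)`` scored over phases + pseudo."""

    start: float
    end: float
    probs: np.ndarray

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise StreamValidationError(
                f"fragment interval [{self.start}, {self.end}) is empty"
            )
        object.__setattr__(self, "probs", as_probabilities(self.probs))

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class VideoStream:
    """Frame-rate-regular sequence of :class:`FrameSample`."""

    fps: float
    frames: tuple[FrameSample, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        _check_video(self)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_classes(self) -> int:
        if not self.frames:
            raise StreamValidationError("empty video stream has no class count")
        return self.frames[0].probs.size

    @property
    def times(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    @property
    def prob_matrix(self) -> np.ndarray:
        """``(n_frames, n_phases)`` matrix of per-frame distributions."""
        return np.array([f.probs for f in self.frames], dtype=float)


@dataclass(frozen=True)
class AudioStream:
    """Sorted, pairwise non-overlapping sequence of :class:`AudioFragment`."""

    fragments: tuple[AudioFragment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments", tuple(self.fragments))
        _check_audio(self)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def n_classes(self) -> int:
        if not self.fragments:
            raise StreamValidationError("empty audio stream has no class count")
        return self.fragments[0].probs.size

    @property
    def starts(self) -> np.ndarray:
        return np.array([f.start for f in self.fragments], dtype=float)

    @property
    def ends(self) -> np.ndarray:
        return np.array([f.end for f in self.fragments], dtype=float)

    @property
    def prob_matrix(self) -> np.ndarray:
        return np.array([f.probs for f in self.fragments], dtype=float)


def _check_video(stream: VideoStream) -> None:
    if stream.fps <= 0:
        raise StreamValidationError(f"fps {stream.fps} must be > 0")
    sizes = {f.probs.size for f in stream.frames}
    if len(sizes) > 1:
        raise StreamValidationError(
            f"inconsistent probability-vector lengths {sorted(sizes)}"
        )
    times = stream.times
    period = 1.0 / stream.fps
    for i in range(1, len(times)):
        dt = times[i] - times[i - 1]
        if dt <= 0:
            raise StreamValidationError(
                f"non-increasing timestamp at frame {i}"
            )
        if abs(dt - period) > TIME_TOL:
            raise StreamValidationError(
                f"frame spacing {dt:.6g} s at frame {i} ≠ 1/fps = {period:.6g} s"
            )


def _check_audio(stream: AudioStream) -> None:
    sizes = {f.probs.size for f in stream.fragments}
    if len(sizes) > 1:
        raise StreamValidationError(
            f"inconsistent probability-vector lengths {sorted(sizes)}"
        )
    frags = stream.fragments
    for k in range(1, len(frags)):
        if frags[k].start < frags[k - 1].start:
            raise StreamValidationError(f"fragments out of order at fragment {k}")
        if frags[k].start < frags[k - 1].end:
            raise StreamValidationError(f"overlap at fragment {k}")


Stream = Union[VideoStream, AudioStream]


def validate_stream(stream: Stream, phase_set: PhaseSet | None = None) -> Stream:
    """Re-check all invariants of a stream and return it unchanged.

    With a :class:`PhaseSet` the probability-vector length is additionally
    checked: procedural phases only for video, phases + pseudo for audio.
    """
    if isinstance(stream, VideoStream):
        _check_video(stream)
        if phase_set is not None and stream.frames:
            if stream.n_classes != phase_set.n_phases:
                raise StreamValidationError(
                    f"video vectors have {stream.n_classes} classes, "
                    f"expected {phase_set.n_phases}"
                )
    elif isinstance(stream, AudioStream):
        _check_audio(stream)
        if phase_set is not None and stream.fragments:
            if stream.n_classes != phase_set.n_phases + 1:
                raise StreamValidationError(
                    f"audio vectors have {stream.n_classes} classes, "
                    f"expected {phase_set.n_phases + 1} (phases + pseudo)"
                )
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a stream: {type(stream).__name__}")
    return stream
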