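"""Time synchronisation and weighted late fusion of speech and video.

The speech and video classifiers run on different clocks: the video model
scores every frame, the speech model scores silence-delimited fragments.
Fusion synchronises the two by interval membership — frame *i* belongs to
fragment *f* iff ``f.start <= t_i < f.end`` — and combines the class
posteriors with a fixed modality weight (default 50% audio / 50% video).
When a fragment covers several frames the video half of the weight is split
equally among them, yielding a single fused distribution per fragment
window, which is assigned to every covered frame.

Fragments whose (tie-ruled) argmax is the pseudo-phase carry off-task talk
and are eliminated: their frames fall back to the plain video prediction,
as do frames with no speech at all.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    AudioStream,
    StreamValidationError,
    VideoStream,
    as_probabilities,
)

__all__ = [
    "ELIMINATED",
    "Provenance",
    "FusionConfig",
    "FusedFrame",
    "FusedTimeline",
    "argmax_label",
    "strip_pseudo",
    "synchronize",
    "fuse_window",
    "fuse_streams",
]

logger = logging.getLogger(__name__)


class _Eliminated:
    """Sentinel: an audio fragment dominated by the pseudo-phase."""

    _instance = None

    def __new__(cls) -> "_Eliminated":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ELIMINATED"


ELIMINATED = _Eliminated()


class Provenance(str, enum.Enum):
    """Which fusion branch produced a frame's final distribution."""

    VIDEO_ONLY = "video_only"
    FUSED = "fused"
    AUDIO_ELIMINATED = "audio_eliminated"


@dataclass(frozen=True)
class FusionConfig:
    """Knobs of the fusion rule.

    Parameters
    ----------
    audio_weight
        Fraction of the fused posterior taken from the speech fragment,
        in ``[0, 1]``; the video side receives ``1 - audio_weight`` split
        equally over the covered frames.  Default 0.5 (equal weight).
    tie_rule
        Deterministic argmax tie-breaking; only ``"lowest_index"`` is
        implemented (earliest phase in canonical order wins).
    pseudo_policy
        Handling of fragments whose argmax is the pseudo-phase; only
        ``"eliminate"`` (drop the fragment, video-only fallback).
    renormalize_residual_pseudo
        Whether residual pseudo mass on a *non*-eliminated fragment is
        redistributed by renormalising the procedural entries.
    """

    audio_weight: float = 0.5
    tie_rule: str = "lowest_index"
    pseudo_policy: str = "eliminate"
    renormalize_residual_pseudo: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.audio_weight <= 1.0:
            raise ValueError(f"audio_weight {self.audio_weight} not in [0, 1]")
        if self.tie_rule != "lowest_index":
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")
        if self.pseudo_policy != "eliminate":
            raise ValueError(f"unknown pseudo_policy {self.pseudo_policy!r}")

    @property
    def video_weight(self) -> float:
        return 1.0 - self.audio_weight


@dataclass(frozen=True)
class FusedFrame:
    """Final per-frame distribution, label and fusion branch."""

    timestamp: float
    probs: np.ndarray
    label: int
    provenance: Provenance

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", as_probabilities(self.probs))
        object.__setattr__(self, "provenance", Provenance(self.provenance))
        if self.label != argmax_label(self.probs):
            raise ValueError(
                f"label {self.label} is not the tie-ruled argmax of probs"
            )


@dataclass(frozen=True)
class FusedTimeline:
    """Fused per-frame timeline; same cardinality/timestamps as the video."""

    fps: float
    frames: tuple[FusedFrame, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        if self.fps <= 0:
            raise ValueError(f"fps {self.fps} must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return np.array([f.label for f in self.frames], dtype=int)

    @property
    def prob_matrix(self) -> np.ndarray:
        return np.array([f.probs for f in self.frames], dtype=float)

    def provenance_summary(self) -> dict[str, float]:
        """Fraction of frames per fusion branch."""
        n = max(self.n_frames, 1)
        return {
            p.value: sum(1 for f in self.frames if f.provenance is p) / n
            for p in Provenance
        }


def argmax_label(probs: np.ndarray, tie_rule: str = "lowest_index") -> int:
    """Deterministic argmax; ties go to the lowest phase index."""
    if tie_rule != "lowest_index":
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return int(np.argmax(probs))


def strip_pseudo(audio_probs: np.ndarray, config: FusionConfig | None = None):
    """Drop the trailing pseudo-phase entry from an audio distribution.

    Returns :data:`ELIMINATED` when the (tie-ruled) argmax is the
    pseudo-phase itself — the fragment is off-task talk and contributes
    nothing to the analysis.  Otherwise the pseudo entry is removed and,
    by default, the remaining procedural entries are renormalised to unit
    mass.
    """
    config = config or FusionConfig()
    probs = np.asarray(audio_probs, dtype=float)
    if probs.size < 2:
        raise ValueError("audio vector must cover at least one phase + pseudo")
    pseudo_index = probs.size - 1
    if argmax_label(probs, config.tie_rule) == pseudo_index:
        return ELIMINATED
    procedural = probs[:-1]
    if config.renormalize_residual_pseudo:
        return procedural / procedural.sum()
    return procedural


def synchronize(
    video: VideoStream, audio: AudioStream
) -> tuple[list[tuple[int, np.ndarray]], np.ndarray]:
    """Assign each frame to the fragment whose interval contains it.

    Returns ``(windows, uncovered)`` where ``windows[k] = (fragment_index,
    frame_indices)`` (possibly empty for fragments shorter than one frame
    period) and ``uncovered`` lists frames under no fragment.  Because
    fragments are non-overlapping, every frame appears exactly once across
    the windows and the uncovered list.
    """
    times = video.times
    windows: list[tuple[int, np.ndarray]] = []
    covered = np.zeros(len(times), dtype=bool)
    for k, frag in enumerate(audio.fragments):
        lo = int(np.searchsorted(times, frag.start, side="left"))
        hi = int(np.searchsorted(times, frag.end, side="left"))
        idx = np.arange(lo, hi)
        windows.append((k, idx))
        covered[idx] = True
    uncovered = np.flatnonzero(~covered)
    return windows, uncovered


def fuse_window(
    fragment_probs: np.ndarray,
    frame_probs: np.ndarray,
    config: FusionConfig | None = None,
) -> np.ndarray:
    """Weighted fusion of one fragment with the ``k`` frames it covers.

    ``fused = w·fragment + Σ_i ((1−w)/k)·frame_i`` with ``w`` the audio
    weight; a convex combination, so the result is a valid distribution.
    """
    config = config or FusionConfig()
    frames = np.atleast_2d(np.asarray(frame_probs, dtype=float))
    if frames.shape[0] == 0:
        raise ValueError("fuse_window needs at least one covered frame")
    fragment = np.asarray(fragment_probs, dtype=float)
    if fragment.size != frames.shape[1]:
        raise ValueError(
            f"fragment has {fragment.size} classes, frames have {frames.shape[1]}"
        )
    w = config.audio_weight
    return w * fragment + (1.0 - w) * frames.mean(axis=0)


def fuse_streams(
    video: VideoStream,
    audio: AudioStream,
    config: FusionConfig | None = None,
) -> FusedTimeline:
    """Produce the fused per-frame timeline from both modality streams.

    Covered frames under a non-eliminated fragment all receive that
    window's single fused distribution; frames under an eliminated
    (pseudo-dominant) fragment or under no fragment keep their own video
    distribution.  With ``audio_weight = 0`` the speech stream carries no
    weight and every frame degenerates to its own video prediction.
    """
    config = config or FusionConfig()
    if video.n_frames == 0:
        raise StreamValidationError("cannot fuse an empty video stream")
    n_phases = video.n_classes
    if audio.n_fragments and audio.n_classes != n_phases + 1:
        raise StreamValidationError(
            f"audio vectors have {audio.n_classes} classes, expected "
            f"{n_phases + 1} (video phases + pseudo)"
        )

    probs = video.prob_matrix
    provenance: list[Provenance] = [Provenance.VIDEO_ONLY] * video.n_frames

    n_eliminated = n_empty = 0
    if config.audio_weight > 0.0 and audio.n_fragments:
        windows, uncovered = synchronize(video, audio)
        for k, idx in windows:
            if idx.size == 0:
                n_empty += 1
                logger.warning(
                    "fragment %d [%g, %g) covers no frame; ignored",
                    k, audio.fragments[k].start, audio.fragments[k].end,
                )
                continue
            stripped = strip_pseudo(audio.fragments[k].probs, config)
            if stripped is ELIMINATED:
                n_eliminated += 1
                branch = Provenance.AUDIO_ELIMINATED
            else:
                probs[idx] = fuse_window(stripped, probs[idx], config)
                branch = Provenance.FUSED
            for i in idx:
                provenance[i] = branch
    else:
        uncovered = np.arange(video.n_frames)

    frames = tuple(
        FusedFrame(
            timestamp=video.frames[i].timestamp,
            probs=probs[i],
            label=argmax_label(probs[i], config.tie_rule),
            provenance=provenance[i],
        )
        for i in range(video.n_frames)
    )
    logger.info(
        "fused %d frames with %d fragments: %d uncovered frames, "
        "%d eliminated fragments, %d empty windows",
        video.n_frames, audio.n_fragments, uncovered.size, n_eliminated, n_empty,
    )
    return FusedTimeline(fps=video.fps, frames=frames)
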