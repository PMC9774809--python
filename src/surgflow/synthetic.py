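"""Synthetic LC procedures and noisy multimodal prediction streams.

The generator states a small world in which every pipeline stage can be
exercised without recorded surgeries or trained models:

* the **procedure** is sampled from an embedded Markov chain over the seven
  LC phases (a reference workflow with gallbladder extraction terminal),
  each visit drawing a lognormal dwell time — positive and right-skewed,
  like real surgical durations;
* the **video classifier** is emulated per frame: a predicted class is
  drawn from the row of a confusion matrix for the true phase, and a
  probability vector peaked at that predicted class is emitted (Dirichlet
  jitter around a fixed peaked template).  Per-class argmax accuracy
  therefore equals the confusion diagonal by construction, while the
  softness of the emitted posteriors is controlled separately;
* the **speech classifier** is emulated per fragment: fragment onsets come
  from a renewal process (minimum silence plus an exponential gap),
  durations are clipped normals, each fragment ends no later than the
  phase it started in (a narration fragment speaks about one phase), its
  true class is the phase at its midpoint — replaced by the pseudo-phase
  with the off-task probability — and the emitted vector spans the phases
  plus the trailing pseudo class.

Determinism: a :class:`numpy.random.SeedSequence` spawned from the single
``seed`` feeds three independent child generators (procedure+fragments,
video noise, audio noise), so re-rendering one modality can never
desynchronise the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assessment import PhaseSegment, WorkflowModel
from .core import AudioFragment, AudioStream, FrameSample, PhaseSet, VideoStream

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_workflow",
    "symmetric_confusion",
    "sample_embedded_sequence",
    "simulate_procedure",
    "render_video_stream",
    "render_audio_stream",
]

logger = logging.getLogger(__name__)

#: Shortest admissible speech fragment, seconds.
MIN_FRAGMENT_S = 0.25


def default_workflow() -> WorkflowModel:
    """Reference LC workflow: mostly sequential with a packaging/cleaning loop.

    The chain runs preparation → Calot's triangle dissection → clipping and
    cutting → gallbladder dissection → packaging, with occasional returns
    to clean and coagulate (packaging and cleaning alternate before
    extraction) and rare back-jumps after unclear dissection planes;
    gallbladder extraction is terminal.
    """
    m = np.zeros((7, 7))
    m[0, 1] = 1.0
    m[1, 2], m[1, 5] = 0.90, 0.10
    m[2, 3], m[2, 1] = 0.95, 0.05
    m[3, 4], m[3, 2], m[3, 5] = 0.85, 0.10, 0.05
    m[4, 5], m[4, 6] = 0.60, 0.40
    m[5, 4], m[5, 6] = 0.45, 0.55
    return WorkflowModel(matrix=m)


def symmetric_confusion(n_classes: int, accuracy: float) -> np.ndarray:
    """Row-stochastic confusion with ``accuracy`` on the diagonal and the
    remaining mass spread uniformly over the other classes."""
    if not 0.0 < accuracy <= 1.0:
        raise ValueError(f"accuracy {accuracy} not in (0, 1]")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    off = (1.0 - accuracy) / (n_classes - 1)
    m = np.full((n_classes, n_classes), off)
    np.fill_diagonal(m, accuracy)
    return m


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the simulator.

    Defaults describe a realistic teaching-video regime: a ~25–30 minute
    procedure (per-phase dwell means in seconds), 1 frame/s prediction
    rate, about four narration fragments per minute of ~6 s each with at
    least 1 s of silence between them, 15% off-task talk, and modality
    confusion diagonals matching the reported standalone accuracies of the
    video (≈0.79) and speech (≈0.81) models.
    """

    workflow: WorkflowModel = field(default_factory=default_workflow)
    phase_set: PhaseSet = field(default_factory=PhaseSet)
    initial_phase: int = 0
    dwell_mean: tuple[float, ...] = (120.0, 540.0, 180.0, 480.0, 120.0, 180.0, 90.0)
    dwell_sd: tuple[float, ...] | None = None  # default: 0.4 × dwell_mean
    fps: float = 1.0
    speech_rate: float = 4.0  # expected fragments per minute
    fragment_duration_mean: float = 6.0
    fragment_duration_sd: float = 2.0
    silence_min: float = 1.0
    offtask_prob: float = 0.15
    video_confusion: np.ndarray | None = None  # default symmetric(n, 0.79)
    audio_confusion: np.ndarray | None = None  # default symmetric(n+1, 0.81)
    video_peak: float = 0.85
    audio_peak: float = 0.60
    concentration: float = 60.0  # np.inf → deterministic templates
    max_transitions: int | None = 50
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.phase_set.n_phases
        if self.workflow.n_phases != n:
            raise ValueError("workflow size does not match the phase set")
        if not 0 <= self.initial_phase < n:
            raise ValueError(f"initial_phase {self.initial_phase} out of range")
        if len(self.dwell_mean) != n or any(d <= 0 for d in self.dwell_mean):
            raise ValueError("dwell_mean needs one positive entry per phase")
        if self.dwell_sd is None:
            object.__setattr__(
                self, "dwell_sd", tuple(0.4 * d for d in self.dwell_mean)
            )
        if len(self.dwell_sd) != n or any(s < 0 for s in self.dwell_sd):
            raise ValueError("dwell_sd needs one non-negative entry per phase")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not 0.0 <= self.offtask_prob <= 1.0:
            raise ValueError("offtask_prob must be in [0, 1]")
        if self.video_confusion is None:
            object.__setattr__(self, "video_confusion", symmetric_confusion(n, 0.79))
        if self.audio_confusion is None:
            object.__setattr__(
                self, "audio_confusion", symmetric_confusion(n + 1, 0.81)
            )
        for name, mat, k in (
            ("video_confusion", self.video_confusion, n),
            ("audio_confusion", self.audio_confusion, n + 1),
        ):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (k, k):
                raise ValueError(f"{name} must be {k}×{k}")
            if np.any(mat < 0) or np.any(np.abs(mat.sum(axis=1) - 1) > 1e-9):
                raise ValueError(f"{name} rows must be probability distributions")
            object.__setattr__(self, name, mat)
        for name, peak in (("video_peak", self.video_peak), ("audio_peak", self.audio_peak)):
            if not 0.0 < peak < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0 (np.inf for noise-free)")


@dataclass(frozen=True)
class GroundTruth:
    """True procedure underlying one simulated recording."""

    segments: tuple[PhaseSegment, ...]
    total_time: float
    fps: float
    frame_times: np.ndarray
    frame_labels: np.ndarray
    fragments: tuple[tuple[float, float], ...]
    fragment_labels: np.ndarray  # phase index, or n_phases for pseudo

    @property
    def phase_sequence(self) -> list[int]:
        """Embedded (collapsed) phase sequence of the procedure."""
        return [s.phase for s in self.segments]


def sample_embedded_sequence(
    workflow: WorkflowModel,
    rng: np.random.Generator,
    initial_phase: int = 0,
    max_transitions: int | None = 50,
) -> list[int]:
    """Sample a phase sequence from the embedded chain until a terminal
    phase is reached or ``max_transitions`` jumps have been made."""
    terminal = workflow.terminal_phases
    if not terminal and max_transitions is None:
        raise ValueError(
            "workflow has no terminal phase and no max_transitions: "
            "the chain would never stop"
        )
    seq = [int(initial_phase)]
    while seq[-1] not in terminal:
        if max_transitions is not None and len(seq) - 1 >= max_transitions:
            break
        seq.append(int(rng.choice(workflow.n_phases, p=workflow.matrix[seq[-1]])))
    return seq


def _lognormal_dwell(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    # moment-matched lognormal; sd == 0 degenerates to the exact mean
    if sd == 0:
        return mean
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _segment_bounds(segments: Sequence[PhaseSegment]) -> np.ndarray:
    return np.array([s.end for s in segments])


def _phase_at(segments: Sequence[PhaseSegment], t: float) -> int:
    ends = _segment_bounds(segments)
    k = int(np.searchsorted(ends, t, side="right"))
    k = min(k, len(segments) - 1)
    return segments[k].phase


def simulate_procedure(config: SimulationConfig) -> GroundTruth:
    """Sample one ground-truth procedure: phases, dwells, frame grid and
    speech-fragment layout (timing + true classes; no classifier noise).

    The child RNG is consumed in a fixed order — phase sequence, dwell
    times, fragment layout — so the truth is reproducible from the seed
    alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    seq = sample_embedded_sequence(
        config.workflow, rng, config.initial_phase, config.max_transitions
    )
    t = 0.0
    segments: list[PhaseSegment] = []
    for p in seq:
        dwell = _lognormal_dwell(rng, config.dwell_mean[p], config.dwell_sd[p])
        dwell = max(dwell, 1e-6)
        segments.append(PhaseSegment(phase=p, start=t, end=t + dwell))
        t += dwell
    total_time = t

    n_frames = int(math.floor(total_time * config.fps - 1e-9)) + 1
    frame_times = np.arange(n_frames) / config.fps
    ends = _segment_bounds(segments)
    frame_labels = np.array(
        [segments[min(int(k), len(segments) - 1)].phase
         for k in np.searchsorted(ends, frame_times, side="right")],
        dtype=int,
    )

    fragments: list[tuple[float, float]] = []
    labels: list[int] = []
    if config.speech_rate > 0:
        mean_gap = 60.0 / config.speech_rate
        exp_scale = max(
            1e-9, mean_gap - config.silence_min - config.fragment_duration_mean
        )
        cursor = 0.0
        while True:
            onset = cursor + config.silence_min + rng.exponential(exp_scale)
            if onset >= total_time - MIN_FRAGMENT_S:
                break
            dur = rng.normal(
                config.fragment_duration_mean, config.fragment_duration_sd
            )
            dur = max(dur, MIN_FRAGMENT_S)
            seg_idx = min(
                int(np.searchsorted(ends, onset, side="right")), len(segments) - 1
            )
            end = min(onset + dur, segments[seg_idx].end, total_time)
            if end - onset >= MIN_FRAGMENT_S:
                true_phase = _phase_at(segments, (onset + end) / 2.0)
                if rng.random() < config.offtask_prob:
                    true_phase = config.phase_set.pseudo_index
                fragments.append((onset, end))
                labels.append(true_phase)
                cursor = end
            else:
                cursor = max(onset, cursor + MIN_FRAGMENT_S)
        if not fragments:
            logger.warning(
                "speech settings produced no fragment in %.1f s of procedure",
                total_time,
            )

    return GroundTruth(
        segments=tuple(segments),
        total_time=total_time,
        fps=config.fps,
        frame_times=frame_times,
        frame_labels=frame_labels,
        fragments=tuple(fragments),
        fragment_labels=np.array(labels, dtype=int),
    )


def _peaked_template(n_classes: int, peak: float) -> np.ndarray:
    """Per-class emission templates: ``peak`` mass on the predicted class,
    the rest spread uniformly — one row per predicted class."""
    t = np.full((n_classes, n_classes), (1.0 - peak) / (n_classes - 1))
    np.fill_diagonal(t, peak)
    return t


def _sample_predictions(
    rng: np.random.Generator, confusion: np.ndarray, truth: np.ndarray
) -> np.ndarray:
    """Vectorised categorical draw of a predicted class per truth label."""
    cdf = np.cumsum(confusion[truth], axis=1)
    u = rng.random(len(truth))
    return (u[:, None] > cdf).sum(axis=1)


def _emit_vectors(
    rng: np.random.Generator,
    predicted: np.ndarray,
    n_classes: int,
    peak: float,
    concentration: float,
) -> np.ndarray:
    templates = _peaked_template(n_classes, peak)
    base = templates[predicted]
    if np.isinf(concentration):
        return base
    g = rng.gamma(shape=concentration * base)
    return g / g.sum(axis=1, keepdims=True)


def render_video_stream(truth: GroundTruth, config: SimulationConfig) -> VideoStream:
    """Emit the noisy per-frame video prediction stream for a ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = config.phase_set.n_phases
    predicted = _sample_predictions(rng, config.video_confusion, truth.frame_labels)
    probs = _emit_vectors(rng, predicted, n, config.video_peak, config.concentration)
    frames = tuple(
        FrameSample(timestamp=float(t), probs=probs[i])
        for i, t in enumerate(truth.frame_times)
    )
    return VideoStream(fps=config.fps, frames=frames)


def render_audio_stream(truth: GroundTruth, config: SimulationConfig) -> AudioStream:
    """Emit the noisy per-fragment speech prediction stream (phases + pseudo)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    if len(truth.fragments) == 0:
        return AudioStream(fragments=())
    k = config.phase_set.n_phases + 1
    predicted = _sample_predictions(rng, config.audio_confusion, truth.fragment_labels)
    probs = _emit_vectors(rng, predicted, k, config.audio_peak, config.concentration)
    frags = tuple(
        AudioFragment(start=s, end=e, probs=probs[i])
        for i, (s, e) in enumerate(truth.fragments)
    )
    return AudioStream(fragments=frags)
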