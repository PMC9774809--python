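"""Timeline metrics, embedded-Markov workflow models and workflow comparison.

The fused per-frame timeline is first run-length encoded into maximal
phase segments (every frame occupies ``1/fps`` seconds starting at its
timestamp).  From the segments we derive the timewise skill metrics: total
operating time, per-phase time and occupancy percentage, number of
occurrences and the min/max/mean duration of an occurrence.

The *workflow* of a procedure is modelled as the embedded Markov chain of
its phase sequence: self-transitions are discarded (consecutive frames of
the same phase carry no routing information), and the transition matrix is
estimated from the counts of jumps between distinct phases.  A trainee's
workflow is compared row-by-row against a reference workflow with the
first-order Wasserstein (earth mover's) distance, phases being embedded on
the line at unit spacing in canonical procedural order; the mean over the
comparable (non-terminal) rows summarises how far the trainee's routing
deviates from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import (
    confusion_matrix as _sk_confusion_matrix,
    jaccard_score as _sk_jaccard,
    precision_recall_fscore_support as _sk_prfs,
)

from .core import PhaseSet
from .fusion import FusedTimeline

__all__ = [
    "PhaseSegment",
    "PhaseMetrics",
    "MetricsReport",
    "WorkflowModel",
    "WorkflowComparison",
    "EvaluationReport",
    "segments_from_timeline",
    "compute_metrics",
    "collapse_runs",
    "estimate_transition_matrix",
    "wasserstein_categorical",
    "compare_workflows",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class PhaseSegment:
    """Maximal run of one phase over ``[start, end)`` seconds."""

    phase: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"segment interval [{self.start}, {self.end}) is empty"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PhaseMetrics:
    """Timewise statistics of one phase within a procedure."""

    total_time: float
    occupancy_pct: float
    n_occurrences: int
    min_duration: float
    max_duration: float
    mean_duration: float


@dataclass(frozen=True)
class MetricsReport:
    """Per-procedure time/occurrence metrics, keyed by phase name."""

    total_time: float
    per_phase: dict[str, PhaseMetrics]


@dataclass(frozen=True)
class WorkflowModel:
    """Row-stochastic transition matrix of the embedded phase chain.

    The diagonal is identically zero (no self-transitions); a phase with
    no outgoing transition is *terminal* and its row is all-zero.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"transition matrix must be square, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("negative transition probability")
        if np.any(np.abs(np.diag(m)) > 0):
            raise ValueError("self-transition forbidden (nonzero diagonal)")
        sums = m.sum(axis=1)
        bad = ~(np.isclose(sums, 1.0, rtol=0, atol=1e-7) | (sums == 0.0))
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"row {i} sums to {sums[i]:.6g}, expected 1 or 0")
        # renormalize only rows with real drift (e.g. rounded JSON), so that
        # count-estimated rows stay bit-exact
        drifted = (sums > 0) & (np.abs(sums - 1.0) > 1e-12)
        if np.any(drifted):
            m = m.copy()
            m[drifted] /= sums[drifted, None]
        object.__setattr__(self, "matrix", m)

    @property
    def n_phases(self) -> int:
        return self.matrix.shape[0]

    @property
    def terminal_phases(self) -> frozenset[int]:
        return frozenset(int(i) for i in np.flatnonzero(self.matrix.sum(axis=1) == 0))


@dataclass(frozen=True)
class WorkflowComparison:
    """Row-wise Wasserstein distances between two workflow models."""

    per_phase_distance: dict[int, float]
    excluded_phases: frozenset[int]
    average_distance: float


@dataclass(frozen=True)
class EvaluationReport:
    """Frame-classification scores against a ground-truth label sequence.

    Macro averages run over the classes present in the truth.  The two
    error percentages are interpretive summaries: ``avg_error_per_phase_pct``
    is the mean per-class miss rate ``100·mean(1 − recall_c)`` and
    ``avg_error_pct`` is ``100·(1 − accuracy)``.
    """

    f1: float
    precision: float
    recall: float
    accuracy: float
    jaccard: float
    avg_error_per_phase_pct: float
    avg_error_pct: float
    confusion: np.ndarray


def segments_from_timeline(timeline: FusedTimeline) -> list[PhaseSegment]:
    """Run-length encode a fused timeline into maximal phase segments.

    Each frame occupies ``1/fps`` seconds starting at its timestamp, so
    the segments tile ``[t_0, t_last + 1/fps)`` contiguously and the total
    duration equals ``n_frames / fps``.
    """
    if timeline.n_frames == 0:
        raise ValueError("cannot segment an empty timeline")
    labels = timeline.labels
    times = timeline.times
    starts = np.flatnonzero(np.r_[True, np.diff(labels) != 0])
    bounds = np.r_[times[starts], times[-1] + 1.0 / timeline.fps]
    return [
        PhaseSegment(phase=int(labels[s]), start=float(bounds[k]), end=float(bounds[k + 1]))
        for k, s in enumerate(starts)
    ]


def compute_metrics(
    segments: Sequence[PhaseSegment], phase_set: PhaseSet
) -> MetricsReport:
    """Compute total/per-phase time and occurrence statistics.

    Phases never visited report zeros with ``n_occurrences = 0``; for a
    single occurrence min = max = mean.  Per-phase times sum to the total
    and occupancies to 100% by construction.
    """
    if not segments:
        raise ValueError("cannot compute metrics from an empty segment list")
    total_time = float(sum(s.duration for s in segments))
    per_phase: dict[str, PhaseMetrics] = {}
    for p, name in enumerate(phase_set.phases):
        durations = [s.duration for s in segments if s.phase == p]
        if durations:
            t = float(sum(durations))
            per_phase[name] = PhaseMetrics(
                total_time=t,
                occupancy_pct=100.0 * t / total_time,
                n_occurrences=len(durations),
                min_duration=float(min(durations)),
                max_duration=float(max(durations)),
                mean_duration=t / len(durations),
            )
        else:
            per_phase[name] = PhaseMetrics(0.0, 0.0, 0, 0.0, 0.0, 0.0)
    return MetricsReport(total_time=total_time, per_phase=per_phase)


def collapse_runs(labels: Iterable[int]) -> list[int]:
    """Remove consecutive duplicates, keeping the first element of each run."""
    out: list[int] = []
    for x in labels:
        x = int(x)
        if not out or out[-1] != x:
            out.append(x)
    return out


def estimate_transition_matrix(
    sequences: Sequence[Sequence[int]] | Sequence[int],
    phase_set: PhaseSet,
) -> WorkflowModel:
    """Estimate the embedded transition matrix from phase sequences.

    Transitions are pooled across sequences (the reference "average
    workflow" of a video database is built this way); entry ``(i, j)`` is
    ``count(i→j) / count(i→·)``.  Sequences must already be collapsed
    (no adjacent duplicates); phases with no outgoing transition get an
    all-zero, terminal row.
    """
    if sequences and isinstance(sequences[0], (int, np.integer)):
        sequences = [sequences]  # type: ignore[list-item]
    n = phase_set.n_phases
    counts = np.zeros((n, n), dtype=float)
    for s_idx, seq in enumerate(sequences):
        seq = [int(x) for x in seq]
        for a, b in zip(seq, seq[1:]):
            if a == b:
                raise ValueError(
                    f"sequence {s_idx} has adjacent duplicate phase {a}; "
                    "apply collapse_runs first"
                )
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"phase index out of range in sequence {s_idx}")
            counts[a, b] += 1
    out = counts.sum(axis=1)
    matrix = np.zeros_like(counts)
    nonterm = out > 0
    matrix[nonterm] = counts[nonterm] / out[nonterm, None]
    return WorkflowModel(matrix=matrix)


def wasserstein_categorical(p: np.ndarray, q: np.ndarray) -> float:
    """First-order Wasserstein distance between two distributions on a line.

    The support is the ordered phase indices with unit spacing, so the
    distance reduces to the sum of absolute CDF differences,
    ``Σ_k |CDF_p(k) − CDF_q(k)|`` — the minimum-cost transport under the
    ``|i − j|`` ground metric.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(f"mismatched supports: {p.shape} vs {q.shape}")
    return float(np.abs(np.cumsum(p - q)[:-1]).sum())


def compare_workflows(
    reference: WorkflowModel, student: WorkflowModel
) -> WorkflowComparison:
    """Row-wise Wasserstein comparison of a student workflow to a reference.

    Rows terminal in *either* model are excluded (an all-zero row is not a
    probability distribution) and reported, never silently dropped; the
    average runs over the included rows only.
    """
    if reference.n_phases != student.n_phases:
        raise ValueError(
            f"phase-count mismatch: {reference.n_phases} vs {student.n_phases}"
        )
    excluded = frozenset(reference.terminal_phases | student.terminal_phases)
    included = [i for i in range(reference.n_phases) if i not in excluded]
    if not included:
        raise ValueError("no comparable rows: every phase is terminal somewhere")
    per_phase = {
        i: wasserstein_categorical(reference.matrix[i], student.matrix[i])
        for i in included
    }
    return WorkflowComparison(
        per_phase_distance=per_phase,
        excluded_phases=excluded,
        average_distance=float(np.mean(list(per_phase.values()))),
    )


def evaluate_predictions(
    predicted: Sequence[int],
    truth: Sequence[int],
    phase_set: PhaseSet,
) -> EvaluationReport:
    """Score a predicted label sequence against frame-wise ground truth.

    Precision, recall, F1 (harmonic mean of precision and recall) and
    Jaccard are macro-averaged over the classes present in the truth, with
    zero substituted for undefined per-class ratios; accuracy is the
    fraction of exactly matching frames.
    """
    pred = np.asarray(predicted, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.size != true.size:
        raise ValueError(f"length mismatch: {pred.size} predicted vs {true.size} truth")
    if pred.size == 0:
        raise ValueError("cannot evaluate empty label sequences")
    n = phase_set.n_phases
    if np.any((pred < 0) | (pred >= n)) or np.any((true < 0) | (true >= n)):
        raise ValueError("label outside the phase set")

    labels = np.arange(n)
    confusion = _sk_confusion_matrix(true, pred, labels=labels)
    present = np.unique(true)
    precision, recall, f1, _ = _sk_prfs(
        true, pred, labels=present, average="macro", zero_division=0
    )
    jaccard = _sk_jaccard(
        true, pred, labels=present, average="macro", zero_division=0
    )
    per_class_recall = _sk_prfs(
        true, pred, labels=present, average=None, zero_division=0
    )[1]
    accuracy = float(np.mean(pred == true))
    return EvaluationReport(
        f1=float(f1),
        precision=float(precision),
        recall=float(recall),
        accuracy=accuracy,
        jaccard=float(jaccard),
        avg_error_per_phase_pct=100.0 * float(np.mean(1.0 - per_class_recall)),
        avg_error_pct=100.0 * (1.0 - accuracy),
        confusion=confusion,
    )
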