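"""Readers and writers for streams, workflows, timelines and reports.

One diff-friendly CSV format serves both modality streams: a header row
``t_start,t_end,<phase names...>[,__pseudo__]`` followed by one row per
sample, with ``t_end == t_start`` for video frames (instants) and
``t_end > t_start`` for audio fragments.  Header phase names must match
the configured phase set exactly, order-sensitive.  Probabilities are
written at full ``repr`` precision so streams round-trip bit-exactly.

Workflow models, comparisons, evaluations and assessment reports are JSON
with sorted keys and floats fixed to 9 decimal places, making every write
deterministic byte-for-byte and re-parsable to 1e-9.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assessment import (
    EvaluationReport,
    MetricsReport,
    PhaseMetrics,
    PhaseSegment,
    WorkflowComparison,
    WorkflowModel,
    collapse_runs,
    compare_workflows,
    compute_metrics,
    estimate_transition_matrix,
    segments_from_timeline,
)
from .core import (
    AudioFragment,
    AudioStream,
    FrameSample,
    PhaseSet,
    StreamValidationError,
    VideoStream,
    validate_stream,
)
from .fusion import FusedFrame, FusedTimeline, Provenance
from .synthetic import SimulationConfig

__all__ = [
    "AssessmentReport",
    "build_report",
    "read_video_stream",
    "write_video_stream",
    "read_audio_stream",
    "write_audio_stream",
    "read_fused_timeline",
    "write_fused_timeline",
    "read_workflow",
    "write_workflow",
    "read_report",
    "write_report",
    "read_labels",
    "write_labels",
    "write_segments",
    "read_segments",
    "write_comparison",
    "write_evaluation",
    "load_simulation_config",
]


@dataclass(frozen=True)
class AssessmentReport:
    """Structured student report: metrics, timeline, workflow, comparison."""

    phase_set: PhaseSet
    metrics: MetricsReport
    segments: tuple[PhaseSegment, ...]
    student_workflow: WorkflowModel
    comparison: WorkflowComparison | None
    provenance_summary: dict[str, float]
    config_echo: dict[str, Any]
    version: str = __version__


# ---------------------------------------------------------------- streams


def _stream_columns(phase_set: PhaseSet, with_pseudo: bool) -> list[str]:
    names = phase_set.audio_classes if with_pseudo else phase_set.phases
    return ["t_start", "t_end", *names]


def _check_header(
    df: pd.DataFrame, phase_set: PhaseSet, with_pseudo: bool, path: Path
) -> None:
    expected = _stream_columns(phase_set, with_pseudo)
    got = list(df.columns)
    if got != expected:
        if sorted(got) == sorted(expected):
            raise StreamValidationError(
                f"{path}: phase order mismatch in header: {got}"
            )
        raise StreamValidationError(
            f"{path}: unexpected columns {got}, expected {expected}"
        )


def write_video_stream(stream: VideoStream, path: str | Path,
                       phase_set: PhaseSet | None = None) -> None:
    phase_set = phase_set or PhaseSet()
    validate_stream(stream, phase_set)
    df = pd.DataFrame(stream.prob_matrix if stream.n_frames else [],
                      columns=list(phase_set.phases))
    times = stream.times
    df.insert(0, "t_end", times)
    df.insert(0, "t_start", times)
    df.to_csv(path, index=False)


def read_video_stream(path: str | Path, phase_set: PhaseSet | None = None,
                      fps: float | None = None) -> VideoStream:
    """Parse a video stream CSV; ``fps`` is inferred from the frame spacing
    when not given (single-frame files then default to 1 frame/s)."""
    phase_set = phase_set or PhaseSet()
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, phase_set, with_pseudo=False, path=path)
    frames = []
    for i, row in enumerate(df.itertuples(index=False)):
        t_start, t_end = float(row[0]), float(row[1])
        if t_end != t_start:
            raise StreamValidationError(
                f"{path} line {i + 2}: video rows must have t_end == t_start"
            )
        try:
            frames.append(FrameSample(timestamp=t_start, probs=np.array(row[2:])))
        except StreamValidationError as e:
            raise StreamValidationError(f"{path} line {i + 2}: {e}") from None
    if fps is None:
        if len(frames) >= 2:
            fps = 1.0 / (frames[1].timestamp - frames[0].timestamp)
        else:
            fps = 1.0
    return validate_stream(VideoStream(fps=fps, frames=tuple(frames)), phase_set)


def write_audio_stream(stream: AudioStream, path: str | Path,
                       phase_set: PhaseSet | None = None) -> None:
    phase_set = phase_set or PhaseSet()
    validate_stream(stream, phase_set)
    df = pd.DataFrame(stream.prob_matrix if stream.n_fragments else [],
                      columns=list(phase_set.audio_classes))
    df.insert(0, "t_end", stream.ends if stream.n_fragments else [])
    df.insert(0, "t_start", stream.starts if stream.n_fragments else [])
    df.to_csv(path, index=False)


def read_audio_stream(path: str | Path,
                      phase_set: PhaseSet | None = None) -> AudioStream:
    phase_set = phase_set or PhaseSet()
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, phase_set, with_pseudo=True, path=path)
    fragments = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            fragments.append(
                AudioFragment(start=float(row[0]), end=float(row[1]),
                              probs=np.array(row[2:]))
            )
        except StreamValidationError as e:
            raise StreamValidationError(f"{path} line {i + 2}: {e}") from None
    return validate_stream(AudioStream(fragments=tuple(fragments)), phase_set)


# ---------------------------------------------------------------- timeline


def write_fused_timeline(timeline: FusedTimeline, path: str | Path,
                         phase_set: PhaseSet | None = None) -> None:
    phase_set = phase_set or PhaseSet()
    df = pd.DataFrame(timeline.prob_matrix, columns=list(phase_set.phases))
    df.insert(0, "provenance", [f.provenance.value for f in timeline.frames])
    df.insert(0, "label", [phase_set.name(f.label) for f in timeline.frames])
    df.insert(0, "t", timeline.times)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fps={timeline.fps!r}\n")
        df.to_csv(fh, index=False)


def read_fused_timeline(path: str | Path,
                        phase_set: PhaseSet | None = None) -> FusedTimeline:
    phase_set = phase_set or PhaseSet()
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# fps="):
            raise StreamValidationError(f"{path}: missing '# fps=' header line")
        fps = float(first[len("# fps="):])
        df = pd.read_csv(fh)
    expected = ["t", "label", "provenance", *phase_set.phases]
    if list(df.columns) != expected:
        raise StreamValidationError(
            f"{path}: unexpected columns {list(df.columns)}, expected {expected}"
        )
    frames = []
    for i, row in enumerate(df.itertuples(index=False)):
        probs = np.array(row[3:], dtype=float)
        frames.append(
            FusedFrame(
                timestamp=float(row[0]),
                probs=probs,
                label=phase_set.index(str(row[1])),
                provenance=Provenance(str(row[2])),
            )
        )
    return FusedTimeline(fps=fps, frames=tuple(frames))


# ---------------------------------------------------------------- JSON docs


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, float):
        return round(obj, 9)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def _dump_json(doc: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round_floats(doc), fh, sort_keys=True, indent=2)
        fh.write("\n")


def _load_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def workflow_to_dict(model: WorkflowModel, phase_set: PhaseSet) -> dict:
    return {
        "phases": list(phase_set.phases),
        "matrix": [list(map(float, row)) for row in model.matrix],
        "terminal_phases": sorted(
            phase_set.name(i) for i in model.terminal_phases
        ),
    }


def workflow_from_dict(doc: dict, phase_set: PhaseSet | None = None) -> WorkflowModel:
    phases = doc["phases"]
    if phase_set is not None and list(phase_set.phases) != list(phases):
        raise ValueError(
            f"workflow phases {phases} do not match the configured phase set"
        )
    matrix = np.asarray(doc["matrix"], dtype=float)
    model = WorkflowModel(matrix=matrix)  # raises on invariant violations
    declared = set(doc.get("terminal_phases", []))
    ps = phase_set or PhaseSet(phases=tuple(phases))
    actual = {ps.name(i) for i in model.terminal_phases}
    if declared and declared != actual:
        raise ValueError(
            f"declared terminal phases {sorted(declared)} disagree with "
            f"all-zero rows {sorted(actual)}"
        )
    return model


def write_workflow(model: WorkflowModel, path: str | Path,
                   phase_set: PhaseSet | None = None) -> None:
    _dump_json(workflow_to_dict(model, phase_set or PhaseSet()), path)


def read_workflow(path: str | Path,
                  phase_set: PhaseSet | None = None) -> WorkflowModel:
    return workflow_from_dict(_load_json(path), phase_set)


def comparison_to_dict(cmp: WorkflowComparison, phase_set: PhaseSet) -> dict:
    return {
        "per_phase_distance": {
            phase_set.name(i): float(d) for i, d in cmp.per_phase_distance.items()
        },
        "excluded_phases": sorted(phase_set.name(i) for i in cmp.excluded_phases),
        "average_distance": float(cmp.average_distance),
    }


def comparison_from_dict(doc: dict, phase_set: PhaseSet) -> WorkflowComparison:
    return WorkflowComparison(
        per_phase_distance={
            phase_set.index(k): float(v)
            for k, v in doc["per_phase_distance"].items()
        },
        excluded_phases=frozenset(
            phase_set.index(k) for k in doc["excluded_phases"]
        ),
        average_distance=float(doc["average_distance"]),
    )


def write_comparison(cmp: WorkflowComparison, path: str | Path,
                     phase_set: PhaseSet | None = None) -> None:
    _dump_json(comparison_to_dict(cmp, phase_set or PhaseSet()), path)


def evaluation_to_dict(report: EvaluationReport, phase_set: PhaseSet) -> dict:
    return {
        "f1": report.f1,
        "precision": report.precision,
        "recall": report.recall,
        "accuracy": report.accuracy,
        "jaccard": report.jaccard,
        "avg_error_per_phase_pct": report.avg_error_per_phase_pct,
        "avg_error_pct": report.avg_error_pct,
        "confusion": {
            "labels": list(phase_set.phases),
            "matrix": [list(map(int, row)) for row in report.confusion],
        },
    }


def write_evaluation(report: EvaluationReport, path: str | Path,
                     phase_set: PhaseSet | None = None) -> None:
    _dump_json(evaluation_to_dict(report, phase_set or PhaseSet()), path)


def report_to_dict(report: AssessmentReport) -> dict:
    ps = report.phase_set
    doc = {
        "version": report.version,
        "phases": list(ps.phases),
        "metrics": {
            "total_time_s": report.metrics.total_time,
            "per_phase": {
                name: dataclasses.asdict(pm)
                for name, pm in report.metrics.per_phase.items()
            },
        },
        "timeline": [
            {"phase": ps.name(s.phase), "start_s": s.start, "end_s": s.end}
            for s in report.segments
        ],
        "student_workflow": workflow_to_dict(report.student_workflow, ps),
        "provenance_summary": dict(report.provenance_summary),
        "config": report.config_echo,
    }
    if report.comparison is not None:
        doc["comparison"] = comparison_to_dict(report.comparison, ps)
    return doc


def report_from_dict(doc: dict) -> AssessmentReport:
    ps = PhaseSet(phases=tuple(doc["phases"]))
    per_phase = {
        name: PhaseMetrics(**vals)
        for name, vals in doc["metrics"]["per_phase"].items()
    }
    metrics = MetricsReport(
        total_time=float(doc["metrics"]["total_time_s"]), per_phase=per_phase
    )
    segments = tuple(
        PhaseSegment(phase=ps.index(s["phase"]), start=float(s["start_s"]),
                     end=float(s["end_s"]))
        for s in doc["timeline"]
    )
    comparison = (
        comparison_from_dict(doc["comparison"], ps) if "comparison" in doc else None
    )
    return AssessmentReport(
        phase_set=ps,
        metrics=metrics,
        segments=segments,
        student_workflow=workflow_from_dict(doc["student_workflow"], ps),
        comparison=comparison,
        provenance_summary=dict(doc["provenance_summary"]),
        config_echo=dict(doc["config"]),
        version=str(doc["version"]),
    )


def write_report(report: AssessmentReport, path: str | Path) -> None:
    _dump_json(report_to_dict(report), path)


def read_report(path: str | Path) -> AssessmentReport:
    return report_from_dict(_load_json(path))


# ---------------------------------------------------------------- labels/segments


def write_labels(labels: Sequence[int], path: str | Path,
                 phase_set: PhaseSet | None = None) -> None:
    """One label per row, by phase name (``__pseudo__`` allowed for truth)."""
    ps = phase_set or PhaseSet()
    names = ps.audio_classes
    pd.DataFrame({"phase": [names[int(x)] for x in labels]}).to_csv(
        path, index=False
    )


def read_labels(path: str | Path, phase_set: PhaseSet | None = None) -> np.ndarray:
    ps = phase_set or PhaseSet()
    df = pd.read_csv(path)
    if list(df.columns) != ["phase"]:
        raise StreamValidationError(
            f"{path}: expected single column 'phase', got {list(df.columns)}"
        )
    lookup = {name: i for i, name in enumerate(ps.audio_classes)}
    out = []
    for i, name in enumerate(df["phase"]):
        if name not in lookup:
            raise StreamValidationError(f"{path} line {i + 2}: unknown phase {name!r}")
        out.append(lookup[name])
    return np.array(out, dtype=int)


def write_segments(segments: Sequence[PhaseSegment], path: str | Path,
                   phase_set: PhaseSet | None = None) -> None:
    ps = phase_set or PhaseSet()
    pd.DataFrame(
        {
            "phase": [ps.name(s.phase) for s in segments],
            "start_s": [s.start for s in segments],
            "end_s": [s.end for s in segments],
        }
    ).to_csv(path, index=False)


def read_segments(path: str | Path,
                  phase_set: PhaseSet | None = None) -> list[PhaseSegment]:
    ps = phase_set or PhaseSet()
    df = pd.read_csv(path)
    if list(df.columns) != ["phase", "start_s", "end_s"]:
        raise StreamValidationError(
            f"{path}: expected columns phase,start_s,end_s, got {list(df.columns)}"
        )
    return [
        PhaseSegment(phase=ps.index(str(r.phase)), start=float(r.start_s),
                     end=float(r.end_s))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- report builder


def build_report(
    timeline: FusedTimeline,
    phase_set: PhaseSet | None = None,
    reference: WorkflowModel | None = None,
    config_echo: dict[str, Any] | None = None,
) -> AssessmentReport:
    """Assemble the full assessment report from a fused timeline.

    Segments the timeline, computes the time/occurrence metrics, estimates
    the student's embedded-Markov workflow and — when a reference workflow
    is supplied — the row-wise Wasserstein comparison against it.
    """
    ps = phase_set or PhaseSet()
    segments = segments_from_timeline(timeline)
    metrics = compute_metrics(segments, ps)
    student = estimate_transition_matrix(
        collapse_runs(timeline.labels), ps
    )
    comparison = (
        compare_workflows(reference, student) if reference is not None else None
    )
    return AssessmentReport(
        phase_set=ps,
        metrics=metrics,
        segments=tuple(segments),
        student_workflow=student,
        comparison=comparison,
        provenance_summary=timeline.provenance_summary(),
        config_echo=config_echo or {},
    )


# ---------------------------------------------------------------- config


def load_simulation_config(path: str | Path, *,
                           seed: int | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML or JSON mapping.

    Recognised keys mirror the dataclass fields; ``workflow`` may be an
    inline workflow document (as written by :func:`write_workflow`) or a
    path to one, and ``phases`` overrides the canonical phase names.
    A ``seed`` argument overrides any seed in the file.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    kwargs: dict[str, Any] = dict(doc)
    phases = kwargs.pop("phases", None)
    ps = PhaseSet(phases=tuple(phases)) if phases else PhaseSet()
    kwargs["phase_set"] = ps
    wf = kwargs.pop("workflow", None)
    if isinstance(wf, str):
        kwargs["workflow"] = read_workflow(path.parent / wf, ps)
    elif isinstance(wf, dict):
        kwargs["workflow"] = workflow_from_dict(wf, ps)
    for key in ("dwell_mean", "dwell_sd"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(float(x) for x in kwargs[key])
    for key in ("video_confusion", "audio_confusion"):
        if kwargs.get(key) is not None:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    if seed is not None:
        kwargs["seed"] = int(seed)
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(SimulationConfig)}
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return SimulationConfig(**kwargs)
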