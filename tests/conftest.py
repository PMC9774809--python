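import numpy as np
import pytest

from surgflow import (
    FrameSample,
    FusedFrame,
    FusedTimeline,
    PhaseSet,
    Provenance,
    VideoStream,
    argmax_label,
)


@pytest.fixture
def phase_set() -> PhaseSet:
    return PhaseSet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220753)


def delta(i: int, n: int) -> np.ndarray:
    """One-hot distribution on class ``i`` of ``n``."""
    v = np.zeros(n)
    v[i] = 1.0
    return v


def make_video(prob_rows, fps: float = 1.0) -> VideoStream:
    """Video stream with frames at 0, 1/fps, ... from a matrix of rows."""
    rows = np.atleast_2d(np.asarray(prob_rows, dtype=float))
    frames = tuple(
        FrameSample(timestamp=i / fps, probs=row) for i, row in enumerate(rows)
    )
    return VideoStream(fps=fps, frames=frames)


def make_timeline(labels, n_phases: int = 7, fps: float = 1.0) -> FusedTimeline:
    """One-hot fused timeline from a label sequence."""
    frames = tuple(
        FusedFrame(
            timestamp=i / fps,
            probs=delta(int(lab), n_phases),
            label=int(lab),
            provenance=Provenance.VIDEO_ONLY,
        )
        for i, lab in enumerate(labels)
    )
    return FusedTimeline(fps=fps, frames=frames)


def video_labels(video: VideoStream) -> np.ndarray:
    return np.array([argmax_label(f.probs) for f in video.frames])
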