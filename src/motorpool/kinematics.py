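"""Muscle length from tracked attachment-point coordinates.

In the semi-intact muscle-imaging preparation, the two attachment points of
each muscle (posterior/anterior for the longitudinal LO1, medial/lateral for
the transverse LT2) are tracked frame by frame; the Euclidean distance
between them is the muscle length, used as the measure of muscle activation.
Length waveforms (not contraction = negative length) feed the coherency
analysis, so troughs are contractions for both muscles and the phase-lag
sign convention is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import TimeSeriesTrace, _validate_uniform

__all__ = [
    "AttachmentTrack",
    "MuscleLengthTrace",
    "muscle_length",
    "normalize_to_rest",
    "read_attachment_csv",
]


@dataclass
class AttachmentTrack:
    """Per-frame 2D coordinates of a muscle's two attachment points.

    ``points`` has shape (n_frames, 4): columns x1, y1, x2, y2 in the
    tracking units (pixels or micrometers — both supported, lengths come
    out in the same units).
    """

    muscle_label: str
    sampling_rate: float
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise ValueError("points must have shape (n_frames, 4): x1,y1,x2,y2")
        if self.points.shape[0] < 2:
            raise ValueError("track needs >= 2 frames")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("track contains non-finite coordinates")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


@dataclass
class MuscleLengthTrace:
    """Per-frame muscle length, optionally normalized to resting length.

    ``flagged_frames`` marks frames where the two attachment points
    coincided (zero length — a tracking glitch, flagged not fatal).
    """

    trace: TimeSeriesTrace
    flagged_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    rest_length: float | None = None
    normalized: bool = False

    @property
    def label(self) -> str:
        return self.trace.label

    @property
    def lengths(self) -> np.ndarray:
        return self.trace.values


def muscle_length(track: AttachmentTrack) -> MuscleLengthTrace:
    """Euclidean distance between the two attachment points per frame."""
    p = track.points
    lengths = np.hypot(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
    flagged = np.where(lengths == 0.0)[0]
    return MuscleLengthTrace(
        trace=TimeSeriesTrace(
            label=track.muscle_label,
            sampling_rate=track.sampling_rate,
            values=lengths,
        ),
        flagged_frames=flagged,
    )


def normalize_to_rest(
    mtrace: MuscleLengthTrace, rest_definition: str = "percentile_95"
) -> MuscleLengthTrace:
    """Divide lengths by the resting length.

    ``rest_definition``: ``"max"`` uses the maximum observed length;
    ``"percentile_95"`` (default) uses the 95th percentile, robust to
    tracking glitches — a few frames may then exceed 1.
    """
    lengths = mtrace.lengths
    if rest_definition == "max":
        rest = float(np.max(lengths))
    elif rest_definition == "percentile_95":
        rest = float(np.percentile(lengths, 95))
    else:
        raise ValueError(f"unknown rest_definition {rest_definition!r}")
    if rest <= 0:
        raise ValueError(f"trace {mtrace.label!r}: resting length is zero")
    return MuscleLengthTrace(
        trace=TimeSeriesTrace(
            label=mtrace.label,
            sampling_rate=mtrace.trace.sampling_rate,
            values=lengths / rest,
            start_time=mtrace.trace.start_time,
        ),
        flagged_frames=mtrace.flagged_frames.copy(),
        rest_length=rest,
        normalized=True,
    )


def read_attachment_csv(path: str | Path, muscle_label: str | None = None) -> AttachmentTrack:
    """Read a per-muscle tracking CSV: time_s, x1, y1, x2, y2."""
    df = pd.read_csv(path)
    required = ["time_s", "x1", "y1", "x2", "y2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    fs = _validate_uniform(df["time_s"].to_numpy(dtype=float), str(path))
    label = muscle_label or Path(path).stem
    return AttachmentTrack(
        muscle_label=label,
        sampling_rate=fs,
        points=df[["x1", "y1", "x2", "y2"]].to_numpy(dtype=float),
    )
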