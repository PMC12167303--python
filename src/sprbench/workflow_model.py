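"""Phase schemas, procedure timelines and annotation-file readers/writers.

A surgical procedure is modelled as an ordered sequence of labelled time
segments on a 0-based seconds axis.  Intervals are half-open ``[start, end)``
so that adjacent segments share a boundary without overlap and so that the
per-frame annotation dialect (one label per frame at a fixed FPS) converts
losslessly.  Gaps between segments are legal and represent discarded footage
(out-of-body sequences, ambiguous transitions); nothing downstream may sample
from a gap.

Procedures may be nonlinear: a phase can recur as several segments, and its
duration is the sum over all of its segments.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "PhaseSchema",
    "DurationTable",
    "Segment",
    "ProcedureTimeline",
    "ValidationError",
    "read_segments",
    "write_segments",
    "read_frame_labels",
    "frames_to_segments",
    "RAPN_SCHEMA",
    "CHOLEC80_SCHEMA",
    "RAPN_DURATIONS",
    "CHOLEC80_DURATIONS",
    "get_schema",
    "get_durations",
]


class ValidationError(ValueError):
    """Raised when an annotation file or domain object violates its contract."""


@dataclass(frozen=True)
class PhaseSchema:
    """An ordered, fixed set of workflow phase labels.

    Order matters: it is the canonical phase order of the procedure type and
    the axis along which "temporally adjacent" confusion is defined.
    """

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValidationError(f"schema {self.name!r} needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"schema {self.name!r} has duplicate labels")
        if any(not lab for lab in self.labels):
            raise ValidationError(f"schema {self.name!r} has an empty label")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown phase label {label!r} for schema {self.name!r}"
            ) from None

    def __contains__(self, label: object) -> bool:
        return label in self.labels


@dataclass(frozen=True)
class DurationTable:
    """Per-phase duration parameters (mean, sd) in minutes.

    Every schema label must appear exactly once with a strictly positive mean
    and a non-negative standard deviation.
    """

    schema: PhaseSchema
    minutes: Mapping[str, tuple[float, float]]  # label -> (mean, sd)

    def __post_init__(self) -> None:
        missing = [lab for lab in self.schema.labels if lab not in self.minutes]
        extra = [lab for lab in self.minutes if lab not in self.schema]
        if missing or extra:
            raise ValidationError(
                f"duration table does not match schema (missing={missing}, extra={extra})"
            )
        for lab, (mean, sd) in self.minutes.items():
            if mean <= 0:
                raise ValidationError(f"phase {lab!r}: mean must be > 0, got {mean}")
            if sd < 0:
                raise ValidationError(f"phase {lab!r}: sd must be >= 0, got {sd}")

    def mean_minutes(self, label: str) -> float:
        return self.minutes[label][0]

    def sd_minutes(self, label: str) -> float:
        return self.minutes[label][1]


@dataclass(frozen=True)
class Segment:
    """One half-open occurrence ``[start_s, end_s)`` of a phase."""

    phase: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValidationError(f"segment start must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValidationError(
                f"segment end ({self.end_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProcedureTimeline:
    """Ordered, non-overlapping labelled segments of one procedure.

    Segments are sorted by start time on construction; overlap is an error.
    Gaps between consecutive segments model discarded footage.
    """

    procedure_id: str
    segments: tuple[Segment, ...]
    _starts: tuple[float, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError(f"timeline {self.procedure_id!r} has no segments")
        ordered = tuple(sorted(self.segments, key=lambda s: s.start_s))
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start_s < prev.end_s:
                raise ValidationError(
                    f"timeline {self.procedure_id!r}: segment {cur.phase!r} at "
                    f"{cur.start_s} overlaps {prev.phase!r} ending at {prev.end_s}"
                )
        object.__setattr__(self, "segments", ordered)
        object.__setattr__(self, "_starts", tuple(s.start_s for s in ordered))

    @property
    def start_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def phases(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.phase, None)
        return tuple(seen)

    def segments_of(self, phase: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.phase == phase)

    def phase_duration(self, phase: str, schema: Optional[PhaseSchema] = None) -> float:
        """Total seconds spent in ``phase``, summed over all its segments."""
        if schema is not None and phase not in schema:
            raise ValidationError(f"unknown phase label {phase!r}")
        return sum(s.duration_s for s in self.segments_of(phase))

    def phase_at(self, t_s: float) -> Optional[str]:
        """Label active at time ``t_s``; None inside a gap or past the end."""
        if t_s < 0:
            raise ValidationError(f"time must be >= 0, got {t_s}")
        i = bisect.bisect_right(self._starts, t_s) - 1
        if i < 0:
            return None
        seg = self.segments[i]
        return seg.phase if t_s < seg.end_s else None

    def covers(self, start_s: float, end_s: float) -> bool:
        """True iff ``[start_s, end_s)`` lies entirely inside annotated footage."""
        if end_s <= start_s:
            raise ValidationError("empty interval")
        t = start_s
        for seg in self.segments:
            if seg.end_s <= t:
                continue
            if seg.start_s > t:
                return False  # gap at t
            t = seg.end_s
            if t >= end_s:
                return True
        return False


# --------------------------------------------------------------------------
# Built-in schemas and duration tables
# --------------------------------------------------------------------------

RAPN_SCHEMA = PhaseSchema(
    name="rapn",
    labels=(
        "Port insertion and surgical access",
        "Colon (and spleen) mobilisation",
        "General hilar control",
        "Selective hilar control",
        "Kidney mobilisation",
        "Tumour identification",
        "Hilar clamping",
        "Tumour excision",
        "Inner renorrhaphy",
        "Hilar unclamping",
        "Outer renorrhaphy",
        "Specimen retrieval",
        "Specimen removal and closing",
        "Retroperitonealisation of the Kidney",
        "Instrument removal",
    ),
)

#: Published per-phase duration statistics, mean +/- sd in minutes.
RAPN_DURATIONS = DurationTable(
    schema=RAPN_SCHEMA,
    minutes={
        "Port insertion and surgical access": (9.2, 9.7),
        "Colon (and spleen) mobilisation": (14.2, 10.3),
        "General hilar control": (13.7, 11.7),
        "Selective hilar control": (12.3, 11.5),
        "Kidney mobilisation": (23.8, 17.8),
        "Tumour identification": (16.9, 15.7),
        "Hilar clamping": (2.0, 4.7),
        "Tumour excision": (12.1, 16.9),
        "Inner renorrhaphy": (9.6, 7.5),
        "Hilar unclamping": (4.0, 8.8),
        "Outer renorrhaphy": (10.4, 6.6),
        "Specimen retrieval": (3.0, 7.7),
        "Specimen removal and closing": (5.6, 10.6),
        "Retroperitonealisation of the Kidney": (6.9, 4.4),
        "Instrument removal": (4.2, 3.9),
    },
)

CHOLEC80_SCHEMA = PhaseSchema(
    name="cholec80",
    labels=(
        "Preparation",
        "Calot triangle dissection",
        "Clipping and cutting",
        "Gallbladder dissection",
        "Gallbladder packaging",
        "Cleaning and coagulation",
        "Gallbladder retraction",
    ),
)

CHOLEC80_DURATIONS = DurationTable(
    schema=CHOLEC80_SCHEMA,
    minutes={
        "Preparation": (2.1, 1.6),
        "Calot triangle dissection": (15.9, 9.0),
        "Clipping and cutting": (2.8, 2.5),
        "Gallbladder dissection": (14.3, 9.2),
        "Gallbladder packaging": (1.6, 0.9),
        "Cleaning and coagulation": (3.0, 2.8),
        "Gallbladder retraction": (1.4, 0.9),
    },
)

_BUILTIN_SCHEMAS = {"rapn": RAPN_SCHEMA, "cholec80": CHOLEC80_SCHEMA}
_BUILTIN_DURATIONS = {"rapn": RAPN_DURATIONS, "cholec80": CHOLEC80_DURATIONS}


def get_schema(name: str) -> PhaseSchema:
    """Look up a built-in schema by name ('rapn' or 'cholec80')."""
    try:
        return _BUILTIN_SCHEMAS[name]
    except KeyError:
        raise ValidationError(
            f"unknown schema {name!r}; built-ins: {sorted(_BUILTIN_SCHEMAS)}"
        ) from None


def get_durations(name: str) -> DurationTable:
    try:
        return _BUILTIN_DURATIONS[name]
    except KeyError:
        raise ValidationError(
            f"no built-in duration table {name!r}; built-ins: {sorted(_BUILTIN_DURATIONS)}"
        ) from None


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

SEGMENT_COLUMNS = ["procedure_id", "phase", "start_s", "end_s"]


def read_segments(path: str | Path, schema: PhaseSchema) -> list[ProcedureTimeline]:
    """Read a segment CSV (``procedure_id,phase,start_s,end_s``) into timelines.

    Rows may appear in any order; each procedure's segments are sorted by
    start time.  Unknown phase labels and overlapping segments raise
    :class:`ValidationError` naming the offending row or segment.
    """
    df = pd.read_csv(path)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for row in df.itertuples():
        if row.phase not in schema:
            raise ValidationError(
                f"{path}: row {row.Index + 2}: unknown phase label {row.phase!r}"
            )
    timelines = []
    for pid, grp in df.groupby("procedure_id", sort=True):
        segments = tuple(
            Segment(phase=r.phase, start_s=float(r.start_s), end_s=float(r.end_s))
            for r in grp.itertuples()
        )
        timelines.append(ProcedureTimeline(procedure_id=str(pid), segments=segments))
    return timelines


def write_segments(timelines: Iterable[ProcedureTimeline], path: str | Path) -> None:
    """Write timelines as a segment CSV, one row per segment."""
    rows = [
        (tl.procedure_id, seg.phase, seg.start_s, seg.end_s)
        for tl in timelines
        for seg in tl.segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, index=False)


def frames_to_segments(per_frame_labels: Sequence[str], fps: float) -> list[Segment]:
    """Convert a per-frame label sequence (fixed FPS) to segments.

    Maximal runs of identical labels become one segment each; frame ``i``
    covers ``[i/fps, (i+1)/fps)``, so output durations sum to
    ``n_frames / fps`` exactly.
    """
    if fps <= 0:
        raise ValidationError(f"fps must be > 0, got {fps}")
    labels = list(per_frame_labels)
    if not labels:
        raise ValidationError("empty per-frame label sequence")
    segments = []
    run_start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[run_start]:
            segments.append(
                Segment(labels[run_start], run_start / fps, i / fps)
            )
            run_start = i
    return segments


def read_frame_labels(path: str | Path, fps: float) -> list[Segment]:
    """Read a per-frame annotation file (``Frame<TAB>Phase``, one header line)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two tab-separated columns")
    frames = df.iloc[:, 0].to_numpy()
    if len(frames) == 0:
        raise ValidationError(f"{path}: no frames")
    if not (frames == range(len(frames))).all():
        raise ValidationError(f"{path}: frame indices must be 0-based and ascending")
    return frames_to_segments(df.iloc[:, 1].astype(str).tolist(), fps)
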