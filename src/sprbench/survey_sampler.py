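"""Constrained temporal sampling of survey questions from a procedure timeline.

The sampler draws a fixed number of timestamps per procedure (default 17),
at least one per phase, with the extras assigned to long phases (those over
10 minutes).  Within a phase, a timestamp is drawn from a normal distribution
centred on the phase midpoint with standard deviation equal to one tenth of
the phase duration, truncated by rejection to the central 5%-95% band of the
phase so that frames near ambiguous transitions are never selected.  Draws
closer than 30 s to an already-accepted timestamp are discarded and redrawn.
Every accepted timestamp yields two survey items: the single frame at the
timestamp and the 10-second video snippet immediately preceding it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .workflow_model import PhaseSchema, ProcedureTimeline, ValidationError

__all__ = [
    "SamplerConfig",
    "SampledItem",
    "SamplingError",
    "allocate_samples",
    "sample_phase_timestamp",
    "phase_relative_position",
    "sample_procedure",
    "snippet_window",
    "items_to_frame",
    "write_items",
    "read_items",
]

log = logging.getLogger(__name__)


class SamplingError(RuntimeError):
    """Raised when the sampling constraints cannot be satisfied."""


@dataclass(frozen=True)
class SamplerConfig:
    """Constraint set for the survey sampler; defaults are the study design.

    n_samples:
        timestamps per procedure (17 in the study).
    min_gap_s:
        minimum pairwise spacing between accepted timestamps (30 s).
    trim_lo / trim_hi:
        phase-relative band (fractions of elapsed phase time) from which
        timestamps may be drawn; the default 0.05/0.95 excludes the first and
        last 5% of each phase, i.e. the transition-adjacent footage.
    sigma_ratio:
        the draw's standard deviation as a fraction of the phase duration.
    oversample_threshold_s:
        phases longer than this (600 s = 10 min) receive the extra samples.
    snippet_len_s:
        length of the video snippet preceding each timestamp (10 s).
    allow_crossing:
        if False (default), a snippet window must stay inside its own phase's
        segment; if True it may span preceding segments as long as it stays
        within annotated footage.
    missing_phase:
        'strict' errors when a schema phase is absent from the timeline;
        'lenient' redistributes its quota over the present phases.
    """

    n_samples: int = 17
    min_gap_s: float = 30.0
    trim_lo: float = 0.05
    trim_hi: float = 0.95
    sigma_ratio: float = 0.1
    oversample_threshold_s: float = 600.0
    snippet_len_s: float = 10.0
    max_retries: int = 1000
    allow_crossing: bool = False
    missing_phase: str = "strict"

    def __post_init__(self) -> None:
        if not (0 <= self.trim_lo < self.trim_hi <= 1):
            raise ValidationError(
                f"require 0 <= trim_lo < trim_hi <= 1, got {self.trim_lo}/{self.trim_hi}"
            )
        if self.sigma_ratio <= 0:
            raise ValidationError("sigma_ratio must be > 0")
        if self.n_samples < 1 or self.max_retries < 1:
            raise ValidationError("n_samples and max_retries must be positive")
        if self.missing_phase not in ("strict", "lenient"):
            raise ValidationError("missing_phase must be 'strict' or 'lenient'")


@dataclass(frozen=True)
class SampledItem:
    """One survey question: a timestamp with its true phase and modality."""

    procedure_id: str
    item_id: str
    timestamp_s: float
    true_phase: str
    modality: str  # 'frame' | 'snippet'
    window: Optional[tuple[float, float]] = None  # [start, end) for snippets


def allocate_samples(
    timeline: ProcedureTimeline, schema: PhaseSchema, config: SamplerConfig
) -> dict[str, int]:
    """Decide how many timestamps each phase receives.

    Every phase present in the timeline gets one sample; the remaining
    ``n_samples - n_present`` extras go one each to the phases exceeding the
    oversampling threshold, in descending duration order (ties broken by
    schema order), wrapping onto the longest remaining phases (and then
    around again) if there are more extras than long phases.
    """
    durations = {p: timeline.phase_duration(p) for p in schema.labels}
    absent = [p for p in schema.labels if durations[p] <= 0]
    if absent:
        if config.missing_phase == "strict":
            raise SamplingError(
                f"{timeline.procedure_id}: phases absent from timeline: {absent}"
            )
        log.info(
            "%s: redistributing quota of absent phases %s",
            timeline.procedure_id,
            absent,
        )
    present = [p for p in schema.labels if durations[p] > 0]
    if not present:
        raise SamplingError(f"{timeline.procedure_id}: timeline covers no schema phase")
    if config.n_samples < len(present):
        raise SamplingError(
            f"{timeline.procedure_id}: n_samples={config.n_samples} < "
            f"{len(present)} present phases"
        )
    counts = {p: 1 for p in present}
    # descending duration, ties by schema order; long phases first
    ranked = sorted(
        present, key=lambda p: (-durations[p], schema.index(p))
    )
    long_first = [p for p in ranked if durations[p] > config.oversample_threshold_s]
    long_first += [p for p in ranked if p not in long_first]
    extras = config.n_samples - len(present)
    for i in range(extras):
        counts[long_first[i % len(long_first)]] += 1
    return counts


def _phase_relative_to_absolute(
    timeline: ProcedureTimeline, phase: str, x_s: float
) -> float:
    """Map elapsed-time-within-phase ``x_s`` to absolute time by walking segments."""
    acc = 0.0
    for seg in timeline.segments_of(phase):
        if x_s < acc + seg.duration_s:
            return seg.start_s + (x_s - acc)
        acc += seg.duration_s
    # x_s == total duration can only arise at trim_hi == 1; clamp inside
    last = timeline.segments_of(phase)[-1]
    return np.nextafter(last.end_s, last.start_s)


def phase_relative_position(
    timeline: ProcedureTimeline, phase: str, t_s: float
) -> float:
    """Elapsed time within ``phase`` at absolute time ``t_s`` (inverse of the
    segment walk used by the sampler)."""
    acc = 0.0
    for seg in timeline.segments_of(phase):
        if seg.start_s <= t_s < seg.end_s:
            return acc + (t_s - seg.start_s)
        acc += seg.duration_s
    raise ValidationError(f"time {t_s} s is not inside phase {phase!r}")


def _window_ok(
    timeline: ProcedureTimeline, phase: str, t_s: float, config: SamplerConfig,
    crossing: bool,
) -> bool:
    start = t_s - config.snippet_len_s
    if start < timeline.start_s:
        return False
    if crossing:
        return timeline.covers(start, t_s)
    # window must stay inside the segment that contains the timestamp
    for seg in timeline.segments_of(phase):
        if seg.start_s <= t_s < seg.end_s:
            return start >= seg.start_s
    return False


def sample_phase_timestamp(
    timeline: ProcedureTimeline,
    phase: str,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> float:
    """Draw one timestamp inside ``phase``.

    In phase-relative time (0 at the first second of the phase, accumulated
    across recurrences) the draw is Normal(0.5*D, sigma_ratio*D) with D the
    total phase duration, rejected until it lands in
    ``[trim_lo*D, trim_hi*D]`` and its snippet window is admissible.  If the
    no-crossing snippet constraint starves the sampler, it is relaxed to
    within-footage crossing before giving up.
    """
    D = timeline.phase_duration(phase)
    if D <= 0:
        raise SamplingError(f"{timeline.procedure_id}: phase {phase!r} not present")
    lo, hi = config.trim_lo * D, config.trim_hi * D
    mu, sigma = 0.5 * D, config.sigma_ratio * D
    for crossing in (config.allow_crossing, True):
        for _ in range(config.max_retries):
            x = rng.normal(mu, sigma)
            if not (lo <= x <= hi):
                continue
            t = _phase_relative_to_absolute(timeline, phase, x)
            if _window_ok(timeline, phase, t, config, crossing):
                return t
        if not crossing:
            log.info(
                "%s/%s: relaxing snippet no-crossing constraint",
                timeline.procedure_id,
                phase,
            )
    raise SamplingError(
        f"{timeline.procedure_id}: could not draw a timestamp in phase {phase!r} "
        f"after {config.max_retries} retries"
    )


def snippet_window(
    timestamp_s: float, config: SamplerConfig, footage_start_s: float = 0.0
) -> tuple[float, float]:
    """The ``[timestamp - snippet_len, timestamp)`` window for one item."""
    start = timestamp_s - config.snippet_len_s
    if start < footage_start_s:
        raise SamplingError(
            f"snippet window would start at {start} s, before footage start "
            f"({footage_start_s} s)"
        )
    return (start, timestamp_s)


def _spacing_violators(times: list[float], min_gap: float) -> set[int]:
    """Indices to redraw: both members of every too-close pair.

    Redrawing both sides keeps the scheme symmetric; blaming only one slot
    can deadlock when the other sits at an extreme of its admissible band.
    """
    order = sorted(range(len(times)), key=times.__getitem__)
    bad: set[int] = set()
    for a, b in zip(order, order[1:]):
        if abs(times[b] - times[a]) < min_gap:
            bad.update((a, b))
    return bad


def sample_procedure(
    timeline: ProcedureTimeline,
    schema: PhaseSchema,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> list[SampledItem]:
    """Sample all survey items for one procedure.

    Returns ``2 * n_samples`` items: for each accepted timestamp, a 'frame'
    item and a 'snippet' item sharing the timestamp.  Deterministic given the
    generator state.
    """
    counts = allocate_samples(timeline, schema, config)
    slots = [p for p in schema.labels for _ in range(counts.get(p, 0))]
    times = [sample_phase_timestamp(timeline, p, config, rng) for p in slots]

    for _ in range(config.max_retries):
        bad = _spacing_violators(times, config.min_gap_s)
        if not bad:
            break
        for i in sorted(bad):
            times[i] = sample_phase_timestamp(timeline, slots[i], config, rng)
    else:
        # last resort: fully resample the most crowded phase once
        crowded = max(counts, key=lambda p: (counts[p], -schema.index(p)))
        log.info("%s: resampling crowded phase %r", timeline.procedure_id, crowded)
        for i, p in enumerate(slots):
            if p == crowded:
                times[i] = sample_phase_timestamp(timeline, p, config, rng)
        if _spacing_violators(times, config.min_gap_s):
            raise SamplingError(
                f"{timeline.procedure_id}: spacing constraint ({config.min_gap_s} s) "
                f"unsatisfiable after {config.max_retries} rounds"
            )

    items: list[SampledItem] = []
    order = sorted(range(len(times)), key=times.__getitem__)
    for rank, i in enumerate(order):
        t, phase = times[i], slots[i]
        window = snippet_window(t, config, timeline.start_s)
        base = f"{timeline.procedure_id}-q{rank:02d}"
        items.append(
            SampledItem(timeline.procedure_id, f"{base}-f", t, phase, "frame")
        )
        items.append(
            SampledItem(timeline.procedure_id, f"{base}-s", t, phase, "snippet", window)
        )
    return items


# --------------------------------------------------------------------------
# Item table IO
# --------------------------------------------------------------------------

ITEM_COLUMNS = [
    "procedure_id",
    "item_id",
    "timestamp_s",
    "true_phase",
    "modality",
    "window_start_s",
    "window_end_s",
]


def items_to_frame(items: Iterable[SampledItem]) -> pd.DataFrame:
    rows = []
    for it in items:
        ws, we = it.window if it.window else (np.nan, np.nan)
        rows.append(
            (it.procedure_id, it.item_id, it.timestamp_s, it.true_phase, it.modality, ws, we)
        )
    return pd.DataFrame(rows, columns=ITEM_COLUMNS)


def write_items(items: Iterable[SampledItem], path: str | Path) -> None:
    items_to_frame(items).to_csv(path, index=False)


def read_items(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df
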