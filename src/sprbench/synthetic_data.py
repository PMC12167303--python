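"""Simulators for procedures, survey respondents and frame-level predictors.

Everything the real study collected is emulated here so the whole benchmark
pipeline runs without any recordings:

* **timelines** — one segment per schema phase in canonical order, with
  durations drawn from a family moment-matched to the published per-phase
  mean +/- sd (in minutes).  The default family is lognormal because several
  phases have sd > mean (e.g. hilar clamping, 2.0 +/- 4.7 min), which no
  positive-support normal can represent without severe truncation bias.
* **respondents** — three expertise groups answering frame and snippet
  questions.  A respondent answers correctly with a group-level probability
  (plus an additive snippet boost); wrong answers fall on other phases with
  geometrically decaying weight in schema-order distance, reflecting that
  confusion is concentrated on temporally adjacent phases.  Confidence (1-5)
  is drawn from an ordinal latent model with configurable correlation to
  correctness; response times are lognormal.
* **predictors** — per-second label emitters with a configurable per-phase
  correct-classification probability and an optional trailing majority-vote
  smoother, standing in for frame-level models without and with temporal
  context.

Group accuracy defaults follow the published survey results (frames
30.3 / 41.5 / 41.2 %, snippet boosts 13.3 / 11.4 / 12.0 points for medical
students / surgical trainees / consultants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .survey_sampler import SampledItem, SamplerConfig, sample_procedure
from .workflow_model import (
    DurationTable,
    PhaseSchema,
    ProcedureTimeline,
    Segment,
    ValidationError,
)

__all__ = [
    "CohortConfig",
    "RespondentConfig",
    "PredictorConfig",
    "ResponseRecord",
    "DEFAULT_GROUPS",
    "simulate_timeline",
    "simulate_cohort",
    "simulate_response",
    "simulate_survey",
    "simulate_ai_predictions",
    "responses_to_frame",
]

log = logging.getLogger(__name__)

RESPONSE_COLUMNS = [
    "participant_id",
    "group",
    "procedure_id",
    "item_id",
    "modality",
    "true_phase",
    "answer",
    "confidence",
    "response_time_s",
]

#: thresholds carving the latent N(0,1)-ish confidence score into ratings 1-5
_CONFIDENCE_CUTS = (-1.2, -0.4, 0.4, 1.2)


@dataclass(frozen=True)
class CohortConfig:
    """How to simulate a cohort of procedure timelines."""

    schema: PhaseSchema
    durations: DurationTable
    n_procedures: int = 143
    family: str = "lognormal"  # 'lognormal' | 'truncated-normal' | 'degenerate'
    seed: int = 0
    #: floor (seconds) applied to drawn durations: annotated phases are never
    #: shorter than a few breaths, and sub-30-s phases cannot host a spaced
    #: survey timestamp at all
    min_phase_s: float = 30.0

    def __post_init__(self) -> None:
        if self.n_procedures < 1:
            raise ValidationError("n_procedures must be >= 1")
        if self.min_phase_s < 0:
            raise ValidationError("min_phase_s must be >= 0")
        if self.family not in ("lognormal", "truncated-normal", "degenerate"):
            raise ValidationError(f"unknown duration family {self.family!r}")
        if self.durations.schema is not self.schema and (
            self.durations.schema.labels != self.schema.labels
        ):
            raise ValidationError("duration table does not match schema")


@dataclass(frozen=True)
class RespondentConfig:
    """Behavioural parameters of one expertise group.

    adjacency_spread in [0, 1] controls how sharply wrong answers decay with
    schema-order distance: weight ~ spread**(distance - 1), so 0 confines
    errors to the two adjacent phases and 1 spreads them uniformly.
    """

    group: str
    p_correct_frame: float
    snippet_boost: float = 0.0
    adjacency_spread: float = 0.55
    confidence_correlation: float = 0.3
    rt_median_s: float = 12.0
    rt_sigma: float = 0.6

    def __post_init__(self) -> None:
        if not (0 <= self.p_correct_frame <= 1):
            raise ValidationError("p_correct_frame must be in [0, 1]")
        if self.p_correct_frame + self.snippet_boost > 1 or (
            self.p_correct_frame + self.snippet_boost < 0
        ):
            raise ValidationError("p_correct_frame + snippet_boost must be in [0, 1]")
        if self.adjacency_spread < 0:
            raise ValidationError("adjacency_spread must be >= 0")
        if not (-1 <= self.confidence_correlation <= 1):
            raise ValidationError("confidence_correlation must be in [-1, 1]")


#: study-condition defaults per expertise group (frame accuracy, snippet boost)
DEFAULT_GROUPS: dict[str, RespondentConfig] = {
    "medical-student": RespondentConfig(
        "medical-student", p_correct_frame=0.303, snippet_boost=0.133
    ),
    "surgical-trainee": RespondentConfig(
        "surgical-trainee", p_correct_frame=0.415, snippet_boost=0.114
    ),
    "consultant": RespondentConfig(
        "consultant", p_correct_frame=0.412, snippet_boost=0.120
    ),
}


@dataclass(frozen=True)
class PredictorConfig:
    """A per-second label emitter with optional temporal smoothing."""

    p_correct: float | Mapping[str, float] = 0.6
    smoothing_window_s: int = 1

    def __post_init__(self) -> None:
        probs = (
            [self.p_correct]
            if isinstance(self.p_correct, (int, float))
            else list(self.p_correct.values())
        )
        if any(not (0 <= p <= 1) for p in probs):
            raise ValidationError("correct-classification probabilities must be in [0, 1]")
        if self.smoothing_window_s < 1:
            raise ValidationError("smoothing_window_s must be >= 1")

    def prob_for(self, phase: str) -> float:
        if isinstance(self.p_correct, (int, float)):
            return float(self.p_correct)
        return float(self.p_correct[phase])


@dataclass(frozen=True)
class ResponseRecord:
    """One survey answer."""

    participant_id: str
    group: str
    procedure_id: str
    item_id: str
    modality: str
    true_phase: str
    answer: str
    confidence: int
    response_time_s: float


# --------------------------------------------------------------------------
# Timelines
# --------------------------------------------------------------------------

def _draw_duration_s(
    mean_min: float, sd_min: float, family: str, rng: np.random.Generator
) -> float:
    mean, sd = mean_min * 60.0, sd_min * 60.0
    if family == "degenerate" or sd == 0:
        return mean
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - 0.5 * sigma2
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    # truncated-normal: N(mean, sd) restricted to positive durations.
    # With an expected rejection fraction above 50% moment matching is
    # hopeless; fall back to the lognormal family.
    from scipy.stats import norm

    if norm.cdf(-mean / sd) > 0.5:
        log.warning(
            "truncated-normal rejects >50%% for mean=%.1f sd=%.1f min; "
            "falling back to lognormal",
            mean_min,
            sd_min,
        )
        return _draw_duration_s(mean_min, sd_min, "lognormal", rng)
    while True:
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)


def simulate_timeline(
    config: CohortConfig,
    rng: np.random.Generator,
    procedure_id: str = "sim-000",
) -> ProcedureTimeline:
    """One procedure: every schema phase once, in canonical order, no gaps."""
    t = 0.0
    segments = []
    for phase in config.schema.labels:
        mean, sd = config.durations.minutes[phase]
        dur = _draw_duration_s(mean, sd, config.family, rng)
        dur = max(dur, config.min_phase_s)
        segments.append(Segment(phase, t, t + dur))
        t += dur
    return ProcedureTimeline(procedure_id=procedure_id, segments=tuple(segments))


def simulate_cohort(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> list[ProcedureTimeline]:
    """``n_procedures`` independent timelines, reproducible from the config seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [
        simulate_timeline(config, rng, procedure_id=f"sim-{i:03d}")
        for i in range(config.n_procedures)
    ]


# --------------------------------------------------------------------------
# Respondents
# --------------------------------------------------------------------------

def _wrong_answer(
    true_phase: str, schema: PhaseSchema, spread: float, rng: np.random.Generator
) -> str:
    i = schema.index(true_phase)
    dist = np.abs(np.arange(schema.k) - i)
    with np.errstate(divide="ignore"):
        weights = np.where(dist > 0, np.power(float(spread), dist - 1.0), 0.0)
    if weights.sum() == 0:  # spread == 0: adjacent phases only
        weights = (dist == 1).astype(float)
    weights /= weights.sum()
    return schema.labels[rng.choice(schema.k, p=weights)]


def _confidence(correct: bool, rho: float, rng: np.random.Generator) -> int:
    z = rho * (1.0 if correct else -1.0) + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal()
    return 1 + int(np.searchsorted(_CONFIDENCE_CUTS, z))


def simulate_response(
    item: SampledItem,
    cfg: RespondentConfig,
    schema: PhaseSchema,
    rng: np.random.Generator,
    participant_id: str = "p000",
) -> ResponseRecord:
    """One simulated answer to one survey item."""
    p = cfg.p_correct_frame
    if item.modality == "snippet":
        p += cfg.snippet_boost
    correct = rng.random() < p
    answer = (
        item.true_phase
        if correct
        else _wrong_answer(item.true_phase, schema, cfg.adjacency_spread, rng)
    )
    return ResponseRecord(
        participant_id=participant_id,
        group=cfg.group,
        procedure_id=item.procedure_id,
        item_id=item.item_id,
        modality=item.modality,
        true_phase=item.true_phase,
        answer=answer,
        confidence=_confidence(correct, cfg.confidence_correlation, rng),
        response_time_s=float(
            rng.lognormal(np.log(cfg.rt_median_s), cfg.rt_sigma)
        ),
    )


def simulate_survey(
    cohort: Sequence[ProcedureTimeline],
    schema: PhaseSchema,
    sampler_config: SamplerConfig,
    group_sizes: Mapping[str, int],
    rng: np.random.Generator,
    group_configs: Optional[Mapping[str, RespondentConfig]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a full simulated survey.

    Each participant is assigned a distinct procedure (a procedure is used at
    most once), answers its 17 frame items and then its 17 snippet items.
    Returns ``(items, responses)`` tables.
    """
    if group_configs is None:
        group_configs = DEFAULT_GROUPS
    unknown = [g for g in group_sizes if g not in group_configs]
    if unknown:
        raise ValidationError(f"no respondent config for groups {unknown}")
    n_participants = sum(group_sizes.values())
    if n_participants > len(cohort):
        raise ValidationError(
            f"{n_participants} participants but only {len(cohort)} procedures; "
            "every procedure may be assigned only once"
        )
    assignment = rng.permutation(len(cohort))[:n_participants]
    from .survey_sampler import items_to_frame

    all_items: list[SampledItem] = []
    responses: list[ResponseRecord] = []
    idx = 0
    pnum = 0
    for group, size in group_sizes.items():
        cfg = group_configs[group]
        for _ in range(size):
            timeline = cohort[assignment[idx]]
            idx += 1
            pid = f"p{pnum:03d}"
            pnum += 1
            items = sample_procedure(timeline, schema, sampler_config, rng)
            all_items.extend(items)
            frames = [it for it in items if it.modality == "frame"]
            snippets = [it for it in items if it.modality == "snippet"]
            for it in frames + snippets:
                responses.append(
                    simulate_response(it, cfg, schema, rng, participant_id=pid)
                )
    items_df = items_to_frame(all_items)
    responses_df = pd.DataFrame(
        [
            (
                r.participant_id,
                r.group,
                r.procedure_id,
                r.item_id,
                r.modality,
                r.true_phase,
                r.answer,
                r.confidence,
                r.response_time_s,
            )
            for r in responses
        ],
        columns=RESPONSE_COLUMNS,
    )
    return items_df, responses_df


def responses_to_frame(responses: Sequence[ResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(r, c) for c in RESPONSE_COLUMNS] for r in responses],
        columns=RESPONSE_COLUMNS,
    )


# --------------------------------------------------------------------------
# Predictors
# --------------------------------------------------------------------------

def simulate_ai_predictions(
    timeline: ProcedureTimeline,
    cfg: PredictorConfig,
    schema: PhaseSchema,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-second predicted labels over the annotated footage of one procedure.

    Raw per-second predictions are correct with the configured per-phase
    probability (wrong answers uniform over the other phases); a trailing
    majority vote over ``smoothing_window_s`` seconds is then applied (window
    1 = no smoothing).  Ties in the vote go to the earliest schema label.
    """
    times: list[float] = []
    truth_idx: list[int] = []
    for seg in timeline.segments:
        ts = np.arange(np.ceil(seg.start_s), seg.end_s, 1.0)
        times.extend(ts)
        truth_idx.extend([schema.index(seg.phase)] * len(ts))
    if not times:
        raise ValidationError("timeline shorter than one second")
    truth = np.asarray(truth_idx)
    n, k = len(truth), schema.k
    p_correct = np.asarray([cfg.prob_for(schema.labels[i]) for i in truth])
    correct = rng.random(n) < p_correct
    offsets = rng.integers(1, k, size=n)  # uniform over the k-1 wrong labels
    raw = np.where(correct, truth, (truth + offsets) % k)

    w = cfg.smoothing_window_s
    if w == 1:
        smoothed = raw
    else:
        onehot = np.zeros((n, k), dtype=np.int32)
        onehot[np.arange(n), raw] = 1
        csum = np.cumsum(onehot, axis=0)
        win = csum.copy()
        win[w:] -= csum[:-w]
        smoothed = win.argmax(axis=1)  # argmax tie-break = earliest schema label
    return pd.DataFrame(
        {
            "procedure_id": timeline.procedure_id,
            "time_s": times,
            "predicted_phase": [schema.labels[i] for i in smoothed],
        }
    )
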