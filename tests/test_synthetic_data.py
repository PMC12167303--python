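"""Generators: timelines, respondents, surveys and per-second predictors."""

import numpy as np
import pytest
from scipy import stats

from sprbench import (
    CHOLEC80_DURATIONS,
    CHOLEC80_SCHEMA,
    CohortConfig,
    PredictorConfig,
    RAPN_DURATIONS,
    RAPN_SCHEMA,
    RespondentConfig,
    SampledItem,
    SamplerConfig,
    ValidationError,
    simulate_ai_predictions,
    simulate_cohort,
    simulate_response,
    simulate_survey,
    simulate_timeline,
    spearman_rho,
)


def rapn_cfg(**kw):
    return CohortConfig(schema=RAPN_SCHEMA, durations=RAPN_DURATIONS, **kw)


class TestTimelines:
    def test_degenerate_family_returns_means_exactly(self, rng):
        tl = simulate_timeline(rapn_cfg(family="degenerate"), rng)
        assert tl.end_s / 60 == pytest.approx(147.9)  # sum of the mean column
        assert tl.phase_duration("Kidney mobilisation") == pytest.approx(23.8 * 60)
        assert [s.phase for s in tl.segments] == list(RAPN_SCHEMA.labels)

    def test_same_seed_gives_identical_cohort(self):
        cfg = rapn_cfg(n_procedures=3, seed=5)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a == b
        assert len({tl.procedure_id for tl in a}) == 3

    def test_lognormal_moments_recovered(self):
        cfg = rapn_cfg(n_procedures=400, seed=8)
        cohort = simulate_cohort(cfg)
        for phase in ("Kidney mobilisation", "Colon (and spleen) mobilisation"):
            durs = np.array([tl.phase_duration(phase) for tl in cohort]) / 60
            mean, _ = RAPN_DURATIONS.minutes[phase]
            se = durs.std(ddof=1) / np.sqrt(len(durs))
            assert abs(durs.mean() - mean) <= 3 * se

    def test_durations_respect_floor(self):
        cfg = rapn_cfg(n_procedures=200, seed=13)
        for tl in simulate_cohort(cfg):
            assert min(s.duration_s for s in tl.segments) >= cfg.min_phase_s

    def test_truncated_normal_family_positive_and_reasonable(self):
        cfg = rapn_cfg(n_procedures=100, family="truncated-normal", seed=3)
        durs = np.array(
            [tl.phase_duration("Kidney mobilisation") for tl in simulate_cohort(cfg)]
        )
        assert (durs > 0).all()
        assert abs(durs.mean() / 60 - 23.8) < 6.0


def make_item(phase, modality="frame"):
    return SampledItem("p0", "p0-q00-f", 1000.0, phase, modality)


class TestRespondents:
    def test_perfect_rater_always_correct(self, rng):
        cfg = RespondentConfig("g", p_correct_frame=1.0)
        for phase in RAPN_SCHEMA.labels:
            r = simulate_response(make_item(phase), cfg, RAPN_SCHEMA, rng)
            assert r.answer == phase

    def test_adjacency_kernel_at_zero_spread(self, rng):
        """With spread -> 0 every error lands on a schema-adjacent phase,
        split evenly; checked with a chi-square frequency test."""
        cfg = RespondentConfig("g", p_correct_frame=0.0, adjacency_spread=0.0)
        phase = RAPN_SCHEMA.labels[7]
        answers = [
            simulate_response(make_item(phase), cfg, RAPN_SCHEMA, rng).answer
            for _ in range(10_000)
        ]
        neighbours = {RAPN_SCHEMA.labels[6], RAPN_SCHEMA.labels[8]}
        assert set(answers) == neighbours
        counts = [answers.count(n) for n in neighbours]
        assert stats.chisquare(counts).pvalue > 0.001

    def test_adjacency_kernel_geometric_decay(self, rng):
        spread = 0.5
        cfg = RespondentConfig("g", p_correct_frame=0.0, adjacency_spread=spread)
        i = 7
        phase = RAPN_SCHEMA.labels[i]
        answers = [
            simulate_response(make_item(phase), cfg, RAPN_SCHEMA, rng).answer
            for _ in range(10_000)
        ]
        dist = np.abs(np.arange(RAPN_SCHEMA.k) - i)
        weights = np.where(dist > 0, spread ** (dist - 1.0), 0.0)
        expected = weights / weights.sum() * len(answers)
        observed = np.array([answers.count(lab) for lab in RAPN_SCHEMA.labels])
        keep = dist > 0  # the true phase itself is never answered here
        chi = stats.chisquare(observed[keep], expected[keep])
        assert chi.pvalue > 0.001

    def test_snippet_boost_raises_accuracy(self, rng):
        cfg = RespondentConfig("g", p_correct_frame=0.3, snippet_boost=0.2)
        n = 4000
        frame_hits = sum(
            simulate_response(make_item("Hilar clamping"), cfg, RAPN_SCHEMA, rng).answer
            == "Hilar clamping"
            for _ in range(n)
        )
        snip_hits = sum(
            simulate_response(
                make_item("Hilar clamping", "snippet"), cfg, RAPN_SCHEMA, rng
            ).answer
            == "Hilar clamping"
            for _ in range(n)
        )
        assert frame_hits / n == pytest.approx(0.3, abs=2.5 * np.sqrt(0.3 * 0.7 / n))
        assert snip_hits / n == pytest.approx(0.5, abs=2.5 * np.sqrt(0.5 * 0.5 / n))

    def test_zero_confidence_correlation(self, rng):
        cfg = RespondentConfig(
            "g", p_correct_frame=0.5, confidence_correlation=0.0
        )
        records = [
            simulate_response(make_item("Hilar clamping"), cfg, RAPN_SCHEMA, rng)
            for _ in range(10_000)
        ]
        conf = [r.confidence for r in records]
        correct = [float(r.answer == r.true_phase) for r in records]
        rho = spearman_rho(conf, correct).statistic
        assert abs(rho) < 0.03
        assert set(conf) <= {1, 2, 3, 4, 5}

    def test_positive_confidence_correlation_detected(self, rng):
        cfg = RespondentConfig("g", p_correct_frame=0.5, confidence_correlation=0.8)
        records = [
            simulate_response(make_item("Hilar clamping"), cfg, RAPN_SCHEMA, rng)
            for _ in range(4000)
        ]
        rho = spearman_rho(
            [r.confidence for r in records],
            [float(r.answer == r.true_phase) for r in records],
        ).statistic
        assert rho > 0.3


class TestSurvey:
    def survey(self, n_proc=12, sizes=None, seed=4, **resp_kw):
        cohort = simulate_cohort(rapn_cfg(n_procedures=n_proc, seed=1))
        sizes = sizes or {"consultant": 4, "medical-student": 4}
        groups = {
            g: RespondentConfig(g, p_correct_frame=0.4, **resp_kw) for g in sizes
        }
        return simulate_survey(
            cohort,
            RAPN_SCHEMA,
            SamplerConfig(),
            sizes,
            np.random.default_rng(seed),
            groups,
        )

    def test_each_participant_answers_34_items(self):
        items, responses = self.survey()
        per = responses.groupby("participant_id")
        assert (per.size() == 34).all()
        by_mod = responses.groupby(["participant_id", "modality"]).size()
        assert (by_mod == 17).all()

    def test_distinct_procedures_per_participant(self):
        _, responses = self.survey()
        assign = responses.groupby("participant_id")["procedure_id"].nunique()
        assert (assign == 1).all()
        procs = responses.groupby("participant_id")["procedure_id"].first()
        assert procs.nunique() == len(procs)

    def test_more_participants_than_procedures_errors(self):
        with pytest.raises(ValidationError, match="only once"):
            self.survey(n_proc=3, sizes={"consultant": 4})

    def test_reproducible_from_seed(self):
        a_items, a_resp = self.survey(seed=9)
        b_items, b_resp = self.survey(seed=9)
        assert a_items.equals(b_items)
        assert a_resp.equals(b_resp)

    def test_zero_boost_gives_equal_modality_accuracy(self):
        _, responses = self.survey(
            n_proc=40,
            sizes={"consultant": 36},
            snippet_boost=0.0,
            seed=21,
        )
        acc = (
            responses.assign(ok=responses["answer"] == responses["true_phase"])
            .groupby("modality")["ok"]
            .mean()
        )
        n = 36 * 17
        se = np.sqrt(2 * 0.4 * 0.6 / n)
        assert abs(acc["frame"] - acc["snippet"]) < 3 * se


class TestPredictors:
    def test_perfect_predictor_matches_truth(self, rapn_mean_timeline, rng):
        cfg = PredictorConfig(p_correct=1.0)
        preds = simulate_ai_predictions(rapn_mean_timeline, cfg, RAPN_SCHEMA, rng)
        truth = [rapn_mean_timeline.phase_at(t) for t in preds["time_s"]]
        assert (preds["predicted_phase"] == truth).all()

    def test_window_one_equals_raw_draws(self, rapn_mean_timeline):
        a = simulate_ai_predictions(
            rapn_mean_timeline,
            PredictorConfig(p_correct=0.7, smoothing_window_s=1),
            RAPN_SCHEMA,
            np.random.default_rng(3),
        )
        b = simulate_ai_predictions(
            rapn_mean_timeline,
            PredictorConfig(p_correct=0.7, smoothing_window_s=1),
            RAPN_SCHEMA,
            np.random.default_rng(3),
        )
        assert a.equals(b)

    def test_majority_smoothing_improves_accuracy(self, rapn_mean_timeline):
        seed = 11
        raw = simulate_ai_predictions(
            rapn_mean_timeline,
            PredictorConfig(p_correct=0.8, smoothing_window_s=1),
            RAPN_SCHEMA,
            np.random.default_rng(seed),
        )
        smooth = simulate_ai_predictions(
            rapn_mean_timeline,
            PredictorConfig(p_correct=0.8, smoothing_window_s=11),
            RAPN_SCHEMA,
            np.random.default_rng(seed),
        )
        truth = np.array([rapn_mean_timeline.phase_at(t) for t in raw["time_s"]])
        acc_raw = (raw["predicted_phase"].to_numpy() == truth).mean()
        acc_smooth = (smooth["predicted_phase"].to_numpy() == truth).mean()
        assert acc_smooth > acc_raw

    def test_per_phase_probabilities(self, rng):
        cfg = PredictorConfig(
            p_correct={lab: (1.0 if i % 2 else 0.0) for i, lab in enumerate(CHOLEC80_SCHEMA.labels)}
        )
        cohort_cfg = CohortConfig(
            schema=CHOLEC80_SCHEMA, durations=CHOLEC80_DURATIONS, family="degenerate"
        )
        tl = simulate_timeline(cohort_cfg, rng)
        preds = simulate_ai_predictions(tl, cfg, CHOLEC80_SCHEMA, rng)
        truth = np.array([tl.phase_at(t) for t in preds["time_s"]])
        for i, lab in enumerate(CHOLEC80_SCHEMA.labels):
            mask = truth == lab
            acc = (preds["predicted_phase"].to_numpy()[mask] == lab).mean()
            assert acc == (1.0 if i % 2 else 0.0)
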