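"""Jaccard scoring, stratification, bootstrap CIs, cohort evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from headseg import (
    EmptyInputError,
    MovementEvent,
    OrientationSignal,
    PredictionTrack,
    SessionRecord,
    ShapeError,
    bootstrap_ci,
    evaluate_cohort,
    jaccard,
    stratified_scores,
)
from headseg.errors import DataError
from headseg.evaluate import EvalConfig, trial_scores


def brute_force_jaccard(a, b):
    """Independent oracle: explicit sample-index sets."""
    sa = {i for i, v in enumerate(a) if v}
    sb = {i for i, v in enumerate(b) if v}
    if not sa | sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


class TestJaccard:
    def test_identity_is_one(self):
        m = (np.random.default_rng(0).random(50) < 0.4).astype(int)
        assert jaccard(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([0, 0, 1, 1])
        assert jaccard(a, b) == 0.0

    def test_hand_computed_third(self):
        # intersection 1, union 3
        assert jaccard([1, 1, 0, 0], [0, 1, 1, 0]) == pytest.approx(1 / 3)

    def test_both_empty_is_one(self):
        assert jaccard(np.zeros(10), np.zeros(10)) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeError):
            jaccard(np.zeros(3), np.zeros(4))

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 200))
    def test_matches_brute_force_sets(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.random(n) < rng.random()
        b = rng.random(n) < rng.random()
        assert jaccard(a, b) == pytest.approx(brute_force_jaccard(a, b))

    def test_symmetry_and_monotonicity(self, rng):
        a = rng.random(100) < 0.4
        b = rng.random(100) < 0.4
        assert jaccard(a, b) == jaccard(b, a)
        # adding correctly-predicted samples never lowers the score
        missing = a & ~b
        if missing.any():
            b2 = b.copy()
            b2[np.flatnonzero(missing)[0]] = True
            assert jaccard(a, b2) >= jaccard(a, b)


class TestBootstrapCI:
    def test_zero_variance_collapses(self):
        lo, hi = bootstrap_ci([0.7] * 20, n_boot=500, seed=0)
        assert lo == hi == pytest.approx(0.7)

    def test_interval_contains_mean_strictly_inside_range(self):
        scores = [0.0, 1.0] * 50
        lo, hi = bootstrap_ci(scores, n_boot=2000, seed=0)
        assert 0.0 < lo <= 0.5 <= hi < 1.0

    def test_reproducible_under_seed(self):
        scores = list(np.random.default_rng(0).random(30))
        assert bootstrap_ci(scores, seed=5) == bootstrap_ci(scores, seed=5)

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            bootstrap_ci([])


def _session_with_events(fs=30.0, n=1800):
    events = [
        MovementEvent(3.0, 6.0, "updown", "slow", "half"),
        MovementEvent(15.0, 19.0, "leftright", "fast", "complete"),
        MovementEvent(27.0, 32.0, "bend", "slow", "repeated"),
        MovementEvent(39.0, 42.0, "updown", "fast", "half"),
        MovementEvent(51.0, 55.0, "leftright", "slow", "complete"),
    ]
    sig = OrientationSignal(np.zeros((n, 3)), fs)
    return SessionRecord("p01", sig, events)


class TestStratifiedScores:
    def test_perfect_prediction_scores_one_everywhere(self):
        s = _session_with_events()
        track = PredictionTrack(s.mask.astype(float), s.mask, 0.5, 30.0)
        for stratum in ("axis", "speed", "mtype"):
            buckets = stratified_scores(track, s, stratum)
            assert all(v == 1.0 for scores in buckets.values() for v in scores)

    def test_empty_prediction_scores_zero(self):
        s = _session_with_events()
        pred = np.zeros(len(s.mask), dtype=np.uint8)
        buckets = stratified_scores(pred, s, "mtype")
        assert set(buckets) == {"half", "complete", "repeated"}
        assert all(v == 0.0 for scores in buckets.values() for v in scores)

    def test_designed_half_overlap(self):
        # prediction covers exactly the second half of the first up/down trial
        # (3.0-6.0 s): intersection 45 samples, union 90 -> J = 0.5
        s = _session_with_events()
        pred = s.mask.copy()
        pred[90:135] = 0  # remove first half of event 1 (samples 90..179)
        buckets = stratified_scores(pred, s, "axis")
        updown = sorted(buckets["updown"])
        assert updown[0] == pytest.approx(0.5)
        assert updown[1] == 1.0

    def test_unknown_stratum_and_unlabeled_events_raise(self):
        s = _session_with_events()
        with pytest.raises(DataError):
            stratified_scores(s.mask, s, "direction")
        bare = SessionRecord(
            "p02",
            OrientationSignal(np.zeros((300, 3)), 30.0),
            [MovementEvent(1.0, 2.0)],
        )
        with pytest.raises(DataError):
            stratified_scores(bare.mask, bare, "axis")

    def test_margin_catches_nearby_false_alarm(self):
        s = _session_with_events()
        pred = s.mask.copy().astype(bool)
        pred[int(6.2 * 30):int(6.8 * 30)] = True  # spill just after event 1
        scores = trial_scores(pred, s, margin_s=1.0)
        assert scores[0].score < 1.0
        no_margin = trial_scores(pred, s, margin_s=0.0)
        assert no_margin[0].score == 1.0


class TestEvaluateCohort:
    def _cohort(self):
        train = [_session_with_events()]
        test = [
            SessionRecord("p99", _session_with_events().signal,
                          _session_with_events().events)
        ]
        return train, test

    @staticmethod
    def _oracle(session):
        return PredictionTrack(session.mask.astype(float), session.mask, 0.5,
                               session.signal.fs)

    def test_oracle_model_scores_one_with_degenerate_cis(self):
        train, test = self._cohort()
        cfg = EvalConfig(n_boot=200)
        report = evaluate_cohort(None, train, test, cfg, predictor=self._oracle)
        for part in ("train", "test"):
            assert report.overall[part].score == 1.0
            assert report.overall[part].ci == (1.0, 1.0)
            for d in (report.by_axis, report.by_speed, report.by_mtype):
                for cs in d[part].values():
                    assert cs.score == 1.0

    def test_all_zero_model_scores_zero(self):
        train, test = self._cohort()

        def zero(session):
            z = np.zeros(len(session.mask), dtype=np.uint8)
            return PredictionTrack(z.astype(float), z, 0.5, session.signal.fs)

        report = evaluate_cohort(None, train, test, EvalConfig(n_boot=200), predictor=zero)
        assert report.overall["train"].score == 0.0
        assert report.overall["test"].score == 0.0

    def test_shared_participant_rejected(self):
        train, _ = self._cohort()
        with pytest.raises(DataError, match="p01"):
            evaluate_cohort(None, train, train, EvalConfig(n_boot=200),
                            predictor=self._oracle)

    def test_session_without_annotations_rejected(self):
        train, test = self._cohort()
        test[0].events = []
        with pytest.raises(DataError, match="p99"):
            evaluate_cohort(None, train, test, EvalConfig(n_boot=200),
                            predictor=self._oracle)

    def test_scores_and_cis_bounded(self):
        train, test = self._cohort()

        def noisy(session):
            rng = np.random.default_rng(hash(session.participant_id) % 2**31)
            m = (rng.random(len(session.mask)) < 0.3).astype(np.uint8)
            return PredictionTrack(m.astype(float), m, 0.5, session.signal.fs)

        report = evaluate_cohort(None, train, test, EvalConfig(n_boot=300), predictor=noisy)
        df = report.to_table()
        assert ((df.score >= 0) & (df.score <= 1)).all()
        assert ((df.ci_lo >= 0) & (df.ci_hi <= 1)).all()
        assert (df.ci_lo <= df.score + 1e-12).all()
        assert (df.score <= df.ci_hi + 1e-12).all()

    def test_pooled_mode_matches_count_ratio(self):
        train, test = self._cohort()
        pred = train[0].mask.copy()
        pred[90:135] = 0

        def half(session):
            return PredictionTrack(pred.astype(float), pred, 0.5, session.signal.fs)

        cfg = EvalConfig(n_boot=200, pooled=True)
        report = evaluate_cohort(None, train, test, cfg, predictor=half)
        trials = trial_scores(pred.astype(bool), train[0], cfg.margin_s)
        expect = sum(t.intersection for t in trials) / sum(t.union for t in trials)
        assert report.overall["train"].score == pytest.approx(expect)
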