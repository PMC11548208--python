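"""Agreement between predicted and reference movement annotations.

The headline statistic is the Jaccard index J(A, B) = |A ∩ B| / |A ∪ B| over
positively-labelled samples, scored per reference trial inside a window
around each annotated event, then aggregated per partition (train/test) and
stratified by movement axis, speed and type.  Uncertainty comes from a
seeded percentile bootstrap over trials (2.5–97.5% by default).

Two aggregation conventions are available: the default averages per-trial
scores (giving the bootstrap a natural resampling unit); ``pooled=True``
instead pools intersection and union counts across trials before dividing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, EmptyInputError, ShapeError
from .segment import PredictionTrack, predict_session
from .synth import SessionRecord

_STRATA = ("axis", "speed", "mtype")


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two equal-length binary masks.

    Returns 1.0 when both masks are empty (perfect agreement on absence),
    avoiding the 0/0 case.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask lengths differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


@dataclass
class TrialScore:
    """Jaccard of one reference trial, with its overlap counts and labels."""

    score: float
    intersection: int
    union: int
    axis: str | None
    speed: str | None
    mtype: str | None


def trial_scores(
    pred_mask: np.ndarray,
    truth: SessionRecord,
    margin_s: float = 1.0,
) -> list[TrialScore]:
    """Score each reference trial inside its evaluation window.

    The window is the annotated event interval extended by ``margin_s`` on
    each side (clipped to the session), so misses, spillover and nearby false
    alarms all count against the trial.
    """
    if not truth.events:
        raise DataError(f"session {truth.participant_id} has no reference annotations")
    fs = truth.signal.fs
    n = len(truth.mask)
    pred_mask = np.asarray(pred_mask).astype(bool)
    if pred_mask.shape != (n,):
        raise ShapeError(
            f"prediction length {pred_mask.shape} does not match session length {n}"
        )
    out = []
    for ev in truth.events:
        i0 = max(0, int(np.ceil((ev.onset - margin_s) * fs - 1e-9)))
        i1 = min(n, int(np.ceil((ev.offset + margin_s) * fs - 1e-9)))
        a = truth.mask[i0:i1].astype(bool)
        b = pred_mask[i0:i1]
        inter = int(np.count_nonzero(a & b))
        union = int(np.count_nonzero(a | b))
        score = 1.0 if union == 0 else inter / union
        out.append(TrialScore(score, inter, union, ev.axis, ev.speed, ev.mtype))
    return out


def stratified_scores(
    pred: PredictionTrack | np.ndarray,
    truth: SessionRecord,
    strata: str,
    margin_s: float = 1.0,
) -> dict[str, list[float]]:
    """Per-trial Jaccard scores bucketed by a stratification label."""
    if strata not in _STRATA:
        raise DataError(f"unknown stratum {strata!r}; expected one of {_STRATA}")
    mask = pred.mask if isinstance(pred, PredictionTrack) else pred
    buckets: dict[str, list[float]] = {}
    for ts in trial_scores(mask, truth, margin_s):
        label = getattr(ts, strata)
        if label is None:
            raise DataError(f"reference event lacks a {strata} label")
        buckets.setdefault(label, []).append(ts.score)
    return buckets


def bootstrap_ci(
    scores: list[float] | np.ndarray,
    n_boot: int = 10_000,
    lo_pct: float = 2.5,
    hi_pct: float = 97.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI of the mean of ``scores``.

    Resamples with replacement ``n_boot`` times and returns the
    (lo_pct, hi_pct) percentiles of the resample means.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise EmptyInputError("cannot bootstrap an empty score list")
    if n_boot < 100:
        raise DataError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(n_boot, scores.size))
    means = scores[idx].mean(axis=1)
    lo, hi = np.percentile(means, [lo_pct, hi_pct])
    return float(lo), float(hi)


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings: inference, trial windows, bootstrap."""

    window_len: int = 320
    threshold: float = 0.5
    stride: int | None = None  # inference stride; None = one window (no overlap)
    normalize: bool = True
    margin_s: float = 1.0
    n_boot: int = 10_000
    lo_pct: float = 2.5
    hi_pct: float = 97.5
    seed: int = 0
    pooled: bool = False


@dataclass
class CategoryScore:
    score: float
    ci: tuple[float, float]
    n_trials: int


@dataclass
class EvalReport:
    """Overall and stratified Jaccard scores with bootstrap CIs."""

    overall: dict[str, CategoryScore] = field(default_factory=dict)
    by_axis: dict[str, dict[str, CategoryScore]] = field(default_factory=dict)
    by_speed: dict[str, dict[str, CategoryScore]] = field(default_factory=dict)
    by_mtype: dict[str, dict[str, CategoryScore]] = field(default_factory=dict)
    n_boot: int = 10_000
    ci_level: tuple[float, float] = (2.5, 97.5)
    pooled: bool = False

    def to_dict(self) -> dict:
        def enc(cs: CategoryScore) -> dict:
            return {"score": cs.score, "ci": list(cs.ci), "n_trials": cs.n_trials}

        return {
            "overall": {p: enc(cs) for p, cs in self.overall.items()},
            "by_axis": {p: {k: enc(v) for k, v in d.items()} for p, d in self.by_axis.items()},
            "by_speed": {p: {k: enc(v) for k, v in d.items()} for p, d in self.by_speed.items()},
            "by_mtype": {p: {k: enc(v) for k, v in d.items()} for p, d in self.by_mtype.items()},
            "n_boot": self.n_boot,
            "ci_level": list(self.ci_level),
            "pooled": self.pooled,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self) -> pd.DataFrame:
        """Flat (partition, stratum, category, score, ci, n) table for plotting."""
        rows = []
        for part, cs in self.overall.items():
            rows.append((part, "overall", "all", cs.score, cs.ci[0], cs.ci[1], cs.n_trials))
        for stratum, data in (("axis", self.by_axis), ("speed", self.by_speed),
                              ("mtype", self.by_mtype)):
            for part, cats in data.items():
                for label, cs in cats.items():
                    rows.append((part, stratum, label, cs.score, cs.ci[0], cs.ci[1], cs.n_trials))
        return pd.DataFrame(
            rows,
            columns=["partition", "stratum", "category", "score", "ci_lo", "ci_hi", "n_trials"],
        )


def _aggregate(trials: list[TrialScore], cfg: EvalConfig, seed: int) -> CategoryScore:
    scores = np.array([t.score for t in trials])
    if cfg.pooled:
        inter = np.array([t.intersection for t in trials], dtype=np.float64)
        union = np.array([t.union for t in trials], dtype=np.float64)
        point = 1.0 if union.sum() == 0 else float(inter.sum() / union.sum())
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(trials), size=(cfg.n_boot, len(trials)))
        u = union[idx].sum(axis=1)
        stat = np.where(u == 0, 1.0, inter[idx].sum(axis=1) / np.where(u == 0, 1.0, u))
        lo, hi = np.percentile(stat, [cfg.lo_pct, cfg.hi_pct])
        return CategoryScore(point, (float(lo), float(hi)), len(trials))
    point = float(scores.mean())
    ci = bootstrap_ci(scores, cfg.n_boot, cfg.lo_pct, cfg.hi_pct, seed)
    return CategoryScore(point, ci, len(trials))


def evaluate_cohort(
    model,
    train_sessions: list[SessionRecord],
    test_sessions: list[SessionRecord],
    cfg: EvalConfig | None = None,
    predictor=None,
) -> EvalReport:
    """Score a model on both partitions, overall and stratified.

    ``predictor`` overrides the default inference path (useful for oracle or
    mock predictors in tests): it maps a session to a
    :class:`~headseg.segment.PredictionTrack`.

    Raises
    ------
    DataError
        If a participant appears in both partitions, or a session lacks
        annotations.
    """
    cfg = cfg or EvalConfig()
    ids_train = {s.participant_id for s in train_sessions}
    ids_test = {s.participant_id for s in test_sessions}
    common = ids_train & ids_test
    if common:
        raise DataError(f"participants in both partitions: {sorted(common)}")

    if predictor is None:
        def predictor(session: SessionRecord) -> PredictionTrack:
            return predict_session(
                model, session.signal, cfg.window_len, cfg.threshold,
                stride=cfg.stride, normalize=cfg.normalize,
            )

    report = EvalReport(n_boot=cfg.n_boot, ci_level=(cfg.lo_pct, cfg.hi_pct), pooled=cfg.pooled)
    for part, sessions in (("train", train_sessions), ("test", test_sessions)):
        trials: list[TrialScore] = []
        for session in sessions:
            track = predictor(session)
            trials.extend(trial_scores(track.mask, session, cfg.margin_s))
        if not trials:
            raise DataError(f"partition {part!r} produced no trials")
        # deterministic per-category bootstrap seeds
        report.overall[part] = _aggregate(trials, cfg, cfg.seed)
        for stratum, store in (("axis", report.by_axis), ("speed", report.by_speed),
                               ("mtype", report.by_mtype)):
            store[part] = {}
            labels = sorted({getattr(t, stratum) for t in trials}, key=str)
            for k, label in enumerate(labels):
                if label is None:
                    raise DataError(f"a reference event lacks a {stratum} label")
                subset = [t for t in trials if getattr(t, stratum) == label]
                sub_seed = cfg.seed + 1000 * (1 + _STRATA.index(stratum)) + k
                store[part][label] = _aggregate(subset, cfg, sub_seed)
    return report
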