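"""Metrics, cross-validation protocol and validation analyses.

Implements the confusion-matrix metric family used to report imbalanced
endpoint classifiers (MCC, F1, sensitivity, specificity, PPV, NPV,
balanced accuracy, accuracy), stratified k-fold cross validation with
in-fold SMOTE (oversampling never touches held-out folds), the
endpoint-combination specificity analysis on pooled out-of-fold triples,
y-randomization (label-shuffle) controls, and condition-level Spearman
correlation between predicted positive counts and mean injury scores.

Degenerate-denominator conventions: MCC is 0 whenever a denominator factor
vanishes, and any 0/0 ratio is reported as 0 with a ``degenerate`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .models import TrainedModel, predict
from .rebalance import SmoteConfig, smote_oversample, \
    smote_oversample_multilabel
from .syndata import ENDPOINTS, ExpressionStudy

METRIC_NAMES = ("mcc", "f1", "sensitivity", "specificity", "ppv", "npv",
                "balanced_accuracy", "accuracy")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.675 -> 0.68), as printed report tables
    round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    mcc: float
    f1: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    balanced_accuracy: float
    accuracy: float
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is
    zero (all-one-class truth or predictions)."""
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) *
                      (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0.0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of recall and precision: 2TP / (2TP + FN + FP)."""
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return 0.0
    return 2 * c.tp / denom


def _ratio(num: int, denom: int, name: str, degenerate: list[str]) -> float:
    if denom == 0:
        degenerate.append(name)
        return 0.0
    return num / denom


def full_metrics(c: ConfusionCounts) -> MetricReport:
    """All report-table metrics from one confusion matrix.

    Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
    NPV TN/(TN+FN), balanced accuracy (Sen+Spc)/2, accuracy
    (TP+TN)/total; 0/0 ratios are 0 and flagged in ``degenerate``.
    """
    degenerate: list[str] = []
    sen = _ratio(c.tp, c.tp + c.fn, "sensitivity", degenerate)
    spc = _ratio(c.tn, c.tn + c.fp, "specificity", degenerate)
    ppv = _ratio(c.tp, c.tp + c.fp, "ppv", degenerate)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", degenerate)
    return MetricReport(
        mcc=mcc(c), f1=f1(c), sensitivity=sen, specificity=spc,
        ppv=ppv, npv=npv, balanced_accuracy=(sen + spc) / 2,
        accuracy=(c.tp + c.tn) / c.total, degenerate=degenerate)


def accuracy_report(n_correct: int, n_total: int) -> float:
    """Percent correct, half-up rounded to 1 decimal place."""
    if n_total < 1 or not 0 <= n_correct <= n_total:
        raise ValueError("invalid correct/total counts")
    return round_half_up(100.0 * n_correct / n_total, 1)


# ---------------------------------------------------------------------------
# cross validation

@dataclass
class Pipeline:
    """Everything needed to go from a study to out-of-fold predictions.

    ``feature_fn`` maps a study to a samples x features DataFrame whose
    index covers the treated sample ids.  ``endpoint`` selects one of bh /
    fib / nec for single-output models, or ``None`` for a multi-task model
    predicting all three.  ``model_fn(X, y, seed)`` returns a
    TrainedModel; ``smote`` (optional) is applied to training folds only.
    """

    feature_fn: Callable[[ExpressionStudy], pd.DataFrame]
    model_fn: Callable[[np.ndarray, np.ndarray, int], TrainedModel]
    endpoint: int | None = None
    smote: SmoteConfig | None = None
    name: str = "pipeline"


@dataclass
class CVResult:
    """Per-fold metrics plus pooled out-of-fold predictions.

    ``fold_metrics`` has one row per fold (and per endpoint for
    multi-task); every sample is predicted exactly once out-of-fold.
    """

    fold_metrics: pd.DataFrame     # columns: fold, endpoint, <metrics>
    sample_ids: list[str]
    y_true: np.ndarray             # (n, n_endpoints)
    oof_pred: np.ndarray
    oof_proba: np.ndarray
    fold_of_sample: np.ndarray
    train_fold_indices: list[np.ndarray]

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric across folds, per endpoint."""
        g = self.fold_metrics.groupby("endpoint")[list(METRIC_NAMES)]
        out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, axis=0)
        return out.swaplevel().sort_index()

    def mean_metric(self, metric: str, endpoint: str | None = None) -> float:
        df = self.fold_metrics
        if endpoint is not None:
            df = df[df["endpoint"] == endpoint]
        return float(df[metric].mean())


def _split_labels(study: ExpressionStudy, endpoint: int | None):
    labels = study.label_matrix()
    if endpoint is None:
        return labels.to_numpy(), labels.to_numpy().max(axis=1)
    y = labels.iloc[:, endpoint].to_numpy()
    return y[:, None], y


def kfold_cv(pipeline: Pipeline, study: ExpressionStudy, k: int = 10,
             seed: int = 0) -> CVResult:
    """Stratified k-fold cross validation of a pipeline on a study.

    Folds stratify on the target endpoint (any-positive for multi-task);
    SMOTE and model fitting see only the training fold, predictions are
    made on the held-out fold, and per-fold metrics are kept alongside the
    pooled out-of-fold predictions for specificity analysis.
    """
    feats = pipeline.feature_fn(study)
    sample_ids = study.treated_sample_ids()
    X = feats.loc[sample_ids].to_numpy(dtype=float)
    Y, strat = _split_labels(study, pipeline.endpoint)
    return _run_cv(X, Y, strat, sample_ids, pipeline, k, seed)


def _run_cv(X: np.ndarray, Y: np.ndarray, strat: np.ndarray,
            sample_ids: list[str], pipeline: Pipeline, k: int,
            seed: int) -> CVResult:
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pos = int(strat.sum())
    if min(n_pos, len(strat) - n_pos) < k:
        raise ValueError(
            f"only {min(n_pos, len(strat) - n_pos)} samples in the rarer "
            f"class; use k <= that (requested k={k})")
    n, n_out = X.shape[0], Y.shape[1]
    endpoint_names = ([ENDPOINTS[pipeline.endpoint]]
                      if pipeline.endpoint is not None else list(ENDPOINTS))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_pred = np.full((n, n_out), -1, dtype=int)
    oof_proba = np.full((n, n_out), np.nan)
    fold_of_sample = np.full(n, -1, dtype=int)
    rows = []
    train_idx_per_fold = []
    for fold, (tr, te) in enumerate(skf.split(X, strat)):
        train_idx_per_fold.append(tr)
        X_tr, Y_tr = X[tr], Y[tr]
        if pipeline.smote is not None:
            cfg = SmoteConfig(k_neighbors=pipeline.smote.k_neighbors,
                              target_ratio=pipeline.smote.target_ratio,
                              seed=pipeline.smote.seed + fold)
            if n_out == 1:
                X_tr, y_tr = smote_oversample(X_tr, Y_tr[:, 0], cfg)
                Y_tr = y_tr[:, None]
            else:
                X_tr, Y_tr = smote_oversample_multilabel(X_tr, Y_tr, cfg)
        model = pipeline.model_fn(
            X_tr, Y_tr if n_out > 1 else Y_tr[:, 0], seed + fold)
        pred, proba = predict(model, X[te])
        oof_pred[te] = pred
        oof_proba[te] = proba
        fold_of_sample[te] = fold
        for j, ep in enumerate(endpoint_names):
            rep = full_metrics(confusion(Y[te, j], pred[:, j]))
            rows.append({"fold": fold, "endpoint": ep, **rep.as_dict()})
    assert (fold_of_sample >= 0).all(), "some sample never held out"
    return CVResult(pd.DataFrame(rows), list(sample_ids), Y, oof_pred,
                    oof_proba, fold_of_sample, train_idx_per_fold)


# ---------------------------------------------------------------------------
# endpoint-combination specificity

NONZERO_PATTERNS = tuple(
    (a, b, c) for a in (1, 0) for b in (1, 0) for c in (1, 0)
    if (a, b, c) != (0, 0, 0))


@dataclass(frozen=True)
class EndpointCombination:
    """A presence/absence pattern over (biliary hyperplasia, fibrosis,
    necrosis); the all-absent pattern is not a valid positive class."""

    bh: int
    fib: int
    nec: int

    def __post_init__(self) -> None:
        if (self.bh, self.fib, self.nec) == (0, 0, 0):
            raise ValueError("all-zero pattern cannot define positives")
        if not {self.bh, self.fib, self.nec} <= {0, 1}:
            raise ValueError("pattern flags must be 0/1")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.bh, self.fib, self.nec)


def combination_metrics(true_triples, predicted_triples,
                        pattern: EndpointCombination
                        ) -> tuple[ConfusionCounts, MetricReport]:
    """Exact-match specificity analysis for one endpoint pattern.

    A sample is condition-positive iff its true triple equals the pattern
    exactly, prediction-positive iff its jointly predicted triple does;
    all other samples are negatives, so TP+TN+FP+FN is the sample count
    for every pattern.
    """
    T = np.asarray(true_triples, dtype=int)
    P = np.asarray(predicted_triples, dtype=int)
    if T.shape != P.shape or T.ndim != 2 or T.shape[1] != 3:
        raise ValueError("true and predicted triples must both be (n, 3)")
    pat = np.asarray(pattern.as_tuple())
    y_true = (T == pat).all(axis=1).astype(int)
    y_pred = (P == pat).all(axis=1).astype(int)
    c = confusion(y_true, y_pred)
    return c, full_metrics(c)


def combination_table(true_triples, predicted_triples) -> pd.DataFrame:
    """All seven non-zero patterns, one row each, in report-table layout
    (pattern flags, MCC, counts, then the ratio metrics)."""
    rows = []
    for pat in NONZERO_PATTERNS:
        c, rep = combination_metrics(true_triples, predicted_triples,
                                     EndpointCombination(*pat))
        rows.append({
            "bh": pat[0], "fib": pat[1], "nec": pat[2],
            "mcc": rep.mcc, "tp": c.tp, "tn": c.tn, "fn": c.fn, "fp": c.fp,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "ppv": rep.ppv, "npv": rep.npv,
            "balanced_accuracy": rep.balanced_accuracy, "f1": rep.f1,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# y-randomization

def y_randomization(pipeline: Pipeline, study: ExpressionStudy,
                    endpoint: int, n_shuffles: int = 10, seed: int = 0,
                    k: int = 10) -> pd.DataFrame:
    """Label-shuffle control: rerun the full cross-validated pipeline on
    uniformly permuted endpoint labels (features untouched) ``n_shuffles``
    times and report per-shuffle mean MCC and F1.

    A model that has learned real signal should beat this chance
    distribution by a wide margin.
    """
    feats = pipeline.feature_fn(study)
    sample_ids = study.treated_sample_ids()
    X = feats.loc[sample_ids].to_numpy(dtype=float)
    y = study.label_matrix().iloc[:, endpoint].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_shuffles):
        y_perm = y[rng.permutation(len(y))]
        assert y_perm.sum() == y.sum()  # shuffling preserves label counts
        res = _run_cv(X, y_perm[:, None], y_perm, sample_ids,
                      Pipeline(pipeline.feature_fn, pipeline.model_fn,
                               endpoint=endpoint, smote=pipeline.smote),
                      k, seed=seed + 1000 + s)
        rows.append({"shuffle": s,
                     "mean_mcc": res.mean_metric("mcc"),
                     "mean_f1": res.mean_metric("f1")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# condition-level correlation

def condition_correlation(predicted_positives_per_condition,
                          mean_injury_score_per_condition
                          ) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, two-sided
    asymptotic p) between a per-condition predicted positive count and the
    observed mean injury score."""
    x = np.asarray(predicted_positives_per_condition, dtype=float)
    y = np.asarray(mean_injury_score_per_condition, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 conditions")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
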