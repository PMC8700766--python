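"""Metrics, the repeated stratified CV protocol, and model comparison.

Metrics follow the standard confusion-matrix definitions with the
positive class fixed to label 1: precision = TP/(TP+FP), recall =
TP/(TP+FN), F-measure = their harmonic mean (F1), accuracy =
(TP+TN)/total, and AUC = the rank-based probability that a random
positive outscores a random negative with ties counted 1/2.  Metrics
whose denominator vanishes are reported as undefined with a flag, never
silently zero.

The evaluation protocol is k-fold stratified cross-validation repeated
r times (10 x 10 by default, i.e. 100 runs), with fold-level metrics
averaged across runs and paired t-tests on per-run values for model
comparison.  All models in one benchmark share identical fold
assignments so the pairing is valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .base_pool import CountVector, Family, derive_seed
from .cascade import CascadeConfig
from .models import (
    CascadeClassifier,
    SingleFamilyClassifier,
    TPEVotingClassifier,
    TunedCascadeClassifier,
)
from .tpe import TPEConfig

METRIC_NAMES = ("precision", "recall", "f_measure", "accuracy", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricRecord:
    """One evaluation run's metrics; undefined entries are None with a flag."""

    precision: float | None
    recall: float | None
    f_measure: float | None
    accuracy: float
    auc: float | None
    confusion: ConfusionCounts
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    significant_05: bool
    significant_01: bool
    flag: str | None = None


@dataclass
class MetricsReport:
    runs: list[MetricRecord]
    n_folds: int
    n_repeats: int
    seed: int

    def per_run_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.runs])

    def means(self) -> dict[str, float]:
        frame = self.per_run_frame()
        return {name: float(frame[name].dropna().mean()) for name in METRIC_NAMES}


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_confusion(c: ConfusionCounts) -> tuple[dict[str, float | None], list[str]]:
    flags: list[str] = []
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision = None
        flags.append("precision_undefined")
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = None
        flags.append("recall_undefined")
    if precision is not None and recall is not None and precision + recall > 0:
        f_measure = 2 * precision * recall / (precision + recall)
    else:
        f_measure = None
        flags.append("f_measure_undefined")
    accuracy = (c.tp + c.tn) / c.total
    return (
        {"precision": precision, "recall": recall, "f_measure": f_measure,
         "accuracy": accuracy},
        flags,
    )


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    y_score: Sequence[float] | None = None,
) -> MetricRecord:
    """Single-run metric record from labels, predictions and (optionally)
    positive-class scores."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    c = confusion_counts(y_true, y_pred)
    values, flags = metrics_from_confusion(c)
    auc: float | None = None
    if y_score is not None:
        y_score = np.asarray(y_score, dtype=float)
        if y_score.shape[0] != y_true.shape[0]:
            raise ValueError("y_score length mismatch")
        if np.unique(y_true).size < 2:
            flags.append("auc_undefined")
        else:
            auc = float(roc_auc_score(y_true, y_score))
    else:
        flags.append("auc_missing_scores")
    return MetricRecord(
        precision=values["precision"],
        recall=values["recall"],
        f_measure=values["f_measure"],
        accuracy=values["accuracy"],
        auc=auc,
        confusion=c,
        flags=flags,
    )


def cv_splits(
    y: np.ndarray, n_folds: int, n_repeats: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The protocol's seeded fold assignments: per repeat a stratified
    partition into n_folds test folds (train = the other n_folds-1)."""
    y = np.asarray(y).astype(int)
    class_min = np.bincount(y).min()
    if class_min < n_folds:
        raise ValueError(
            f"rarest class has {class_min} members; use at most that many folds"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed % (2**31 - 1)
    )
    return list(splitter.split(np.zeros_like(y), y))


def repeated_stratified_cv(
    model_factory: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Evaluate a model over n_folds x n_repeats seeded stratified runs.

    ``model_factory`` returns a fresh unfitted model per run; metrics are
    recorded per run and averaged over all runs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    runs: list[MetricRecord] = []
    for train_idx, test_idx in cv_splits(y, n_folds, n_repeats, seed):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        pred = np.asarray(model.predict(X[test_idx]))
        score = np.asarray(model.predict_proba(X[test_idx]))[:, 1]
        runs.append(compute_metrics(y[test_idx], pred, score))
    return MetricsReport(runs=runs, n_folds=n_folds, n_repeats=n_repeats, seed=seed)


def paired_t_test(runs_a: Sequence[float], runs_b: Sequence[float]) -> PairedTestResult:
    """Classic paired t-test on per-run differences, two-sided.

    Degenerate cases are flagged: identical pairs give t=0, p=1; zero
    variance with a nonzero mean difference is reported significant with
    p ~ 0.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired runs must be equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least 2 paired runs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTestResult(0.0, 1.0, False, False, flag="identical_runs")
        t = math.inf if d.mean() > 0 else -math.inf
        return PairedTestResult(t, 0.0, True, True, flag="zero_variance")
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), bool(p < 0.05), bool(p < 0.01))


BENCHMARK_MODELS = ("rf", "adaboost", "et", "gbdt", "tpe_voting", "dem", "tpe_dem")


@dataclass
class BenchmarkResult:
    table: pd.DataFrame  # models x metrics (means over runs)
    per_run: dict[str, pd.DataFrame]
    tests: dict[str, dict[str, PairedTestResult]]  # baseline -> metric -> test vs tpe_dem

    def formatted(self) -> pd.DataFrame:
        """Mean metrics as percentages with significance stars against the
        tuned cascade (* p<0.05, ** p<0.01)."""
        out = {}
        for model in self.table.index:
            row = {}
            for metric in self.table.columns:
                cell = f"{100 * self.table.loc[model, metric]:.2f}%"
                test = self.tests.get(model, {}).get(metric)
                if test is not None and test.significant_01:
                    cell += " **"
                elif test is not None and test.significant_05:
                    cell += " *"
                row[metric] = cell
            out[model] = row
        return pd.DataFrame(out).T.loc[list(self.table.index)]


def _default_factories(
    seed: int,
    learner_params: Mapping[Family, Mapping] | None,
    cascade_config: CascadeConfig | None,
    tpe_config: TPEConfig | None,
    k_tune: int,
) -> dict[str, Callable[[], object]]:
    cascade_config = cascade_config or CascadeConfig(seed=derive_seed(seed, "cascade"),
                                                     learner_params=learner_params)
    tpe_config = tpe_config or TPEConfig(seed=derive_seed(seed, "tpe"))
    single = {
        "rf": Family.RF,
        "adaboost": Family.ADA,
        "et": Family.ET,
        "gbdt": Family.GBDT,
    }
    factories: dict[str, Callable[[], object]] = {}
    for name, family in single.items():
        params = (learner_params or {}).get(family)
        factories[name] = (
            lambda family=family, params=params: SingleFamilyClassifier(
                family, seed=derive_seed(seed, name), params=params
            )
        )
    factories["dem"] = lambda: CascadeClassifier(CountVector(1, 1, 1, 1), cascade_config)
    factories["tpe_voting"] = lambda: TPEVotingClassifier(
        tpe_config, seed=derive_seed(seed, "tpe-voting"),
        params=learner_params or {}, k_tune=k_tune
    )
    factories["tpe_dem"] = lambda: TunedCascadeClassifier(
        tpe_config, cascade_config, k_tune=k_tune
    )
    return factories


def run_benchmark(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_folds: int = 10,
    n_repeats: int = 10,
    models: Sequence[str] = BENCHMARK_MODELS,
    learner_params: Mapping[Family, Mapping] | None = None,
    cascade_config: CascadeConfig | None = None,
    tpe_config: TPEConfig | None = None,
    k_tune: int = 3,
) -> BenchmarkResult:
    """Evaluate the comparison grid under identical CV partitions.

    Baselines: the four single-family ensembles, the fixed-composition
    cascade (one learner of each family per layer, no tuning), and the
    TPE-weighted flat soft voter.  Paired t-tests compare each baseline's
    per-run metrics with the tuned cascade's when both are present.
    """
    factories = _default_factories(seed, learner_params, cascade_config,
                                   tpe_config, k_tune)
    unknown = set(models) - set(BENCHMARK_MODELS)
    if unknown:
        raise ValueError(f"unknown model(s): {sorted(unknown)}")
    per_run: dict[str, pd.DataFrame] = {}
    means: dict[str, dict[str, float]] = {}
    for name in models:
        report = repeated_stratified_cv(
            factories[name], X, y, n_folds=n_folds, n_repeats=n_repeats, seed=seed
        )
        per_run[name] = report.per_run_frame()
        means[name] = report.means()

    table = pd.DataFrame(means).T.loc[list(models), list(METRIC_NAMES)]
    tests: dict[str, dict[str, PairedTestResult]] = {}
    if "tpe_dem" in per_run:
        ref = per_run["tpe_dem"]
        for name in models:
            if name == "tpe_dem":
                continue
            tests[name] = {}
            for metric in METRIC_NAMES:
                a = per_run[name][metric]
                b = ref[metric]
                mask = a.notna() & b.notna()
                if mask.sum() >= 2:
                    tests[name][metric] = paired_t_test(a[mask], b[mask])
    return BenchmarkResult(table=table, per_run=per_run, tests=tests)
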