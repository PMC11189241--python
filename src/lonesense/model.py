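"""Per-participant random-forest loneliness detection and evaluation.

Evaluation protocol: for each target participant, the training set is that
participant's earliest 50 % of labeled EMAs plus *all* rows of every other
participant; the test set is the target's most recent 50 %.  One personal
model per participant; confusion counts are pooled over all test rows before
the pooled metrics are computed.  The mean squared error of binary
predictions equals (fp + fn) / n, so accuracy + mse = 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .assemble import ALL_DEVICES, Assembly, FeatureTable, znormalize_split
from .errors import DataError

DEFAULT_SEED = 20240620


@dataclass(frozen=True)
class Hyperparams:
    n_trees: int = 100
    max_features: str = "sqrt"
    min_samples_leaf: int = 5
    max_depth: int | None = None


@dataclass
class SplitPlan:
    """Temporal per-participant holdout: the target's earliest ceil(n/2)
    labeled rows plus everyone else's rows train; the target's most recent
    rows test."""

    target: str
    train_index: np.ndarray
    test_index: np.ndarray


def make_split(table: FeatureTable, target: str, min_rows: int = 4) -> SplitPlan:
    df = table.df
    mine = df[df["participant_id"] == target]
    if len(mine) < min_rows:
        raise DataError(f"participant {target} has fewer than {min_rows} labeled rows")
    order = mine.sort_values("t", kind="stable").index.to_numpy()
    n_tr = int(np.ceil(len(order) / 2))
    others = df.index[df["participant_id"] != target].to_numpy()
    return SplitPlan(target, np.concatenate([others, order[:n_tr]]), order[n_tr:])


def train_model(X: np.ndarray, y: np.ndarray, hyperparams: Hyperparams | None = None,
                seed: int = DEFAULT_SEED) -> RandomForestClassifier:
    """Fit the bagged decision-tree ensemble; deterministic given the seed."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")
    hp = hyperparams or Hyperparams()
    rf = RandomForestClassifier(n_estimators=hp.n_trees, max_features=hp.max_features,
                                min_samples_leaf=hp.min_samples_leaf,
                                max_depth=hp.max_depth, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    mse: float
    auc: float
    n_test: int
    device_subset: tuple = ALL_DEVICES
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("tp", "fp", "tn", "fn", "accuracy", "precision", "recall",
              "f1", "mse", "auc", "n_test")}
        d["device_subset"] = list(self.device_subset)
        return d


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties mid-ranked)."""
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    r = rankdata(scores)
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(labels: np.ndarray, predictions: np.ndarray,
                    probabilities: np.ndarray | None = None,
                    device_subset: tuple = ALL_DEVICES) -> MetricsReport:
    """Confusion counts and the derived metrics; undefined ratios are NaN
    with a flag."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if len(labels) == 0:
        raise DataError("empty evaluation input")
    if len(labels) != len(predictions):
        raise DataError("labels and predictions differ in length")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    n = len(labels)
    flags = {}

    def ratio(num, den, name):
        if den == 0:
            flags[name] = "undefined (zero denominator)"
            return np.nan
        return num / den

    accuracy = (tp + tn) / n
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = np.nan
        flags["f1"] = "undefined"
    mse = (fp + fn) / n
    auc = rank_auc(labels, probabilities) if probabilities is not None else np.nan
    return MetricsReport(tp, fp, tn, fn, accuracy, precision, recall, f1, mse, auc,
                         n, device_subset, flags)


@dataclass
class EvaluationResult:
    pooled: MetricsReport
    per_participant: dict[str, MetricsReport]
    predictions: pd.DataFrame  # participant_id, t, label, prediction, probability
    models: dict = field(default_factory=dict)  # pid -> (rf, X_test df, y_test)


def _participant_seed(base_seed: int, idx: int) -> int:
    return int((base_seed + 7919 * (idx + 1)) % (2 ** 31 - 1))


def evaluate_all(table: FeatureTable, hyperparams: Hyperparams | None = None,
                 seed: int = DEFAULT_SEED, keep_models: bool = False,
                 device_subset: tuple = ALL_DEVICES) -> EvaluationResult:
    """Train and test one personal model per participant; pool the confusion
    counts over all test rows for the aggregate report."""
    df = table.df
    pids = sorted(df["participant_id"].unique())
    per: dict[str, MetricsReport] = {}
    rows = []
    models = {}
    for i, pid in enumerate(pids):
        try:
            plan = make_split(table, pid)
        except DataError as e:
            warnings.warn(str(e))
            continue
        all_idx = np.concatenate([plan.train_index, plan.test_index])
        z, _ = znormalize_split(df, table.feature_cols, plan.train_index, all_idx)
        Xtr = z.loc[plan.train_index, table.feature_cols].to_numpy(float)
        ytr = z.loc[plan.train_index, "label"].to_numpy(int)
        Xte = z.loc[plan.test_index, table.feature_cols].to_numpy(float)
        yte = z.loc[plan.test_index, "label"].to_numpy(int)
        try:
            rf = train_model(Xtr, ytr, hyperparams, _participant_seed(seed, i))
        except DataError as e:
            warnings.warn(f"{pid}: {e}")
            continue
        proba = rf.predict_proba(Xte)[:, list(rf.classes_).index(1)]
        pred = (proba > 0.5).astype(int)  # vote ties go to the negative class
        per[pid] = compute_metrics(yte, pred, proba, device_subset)
        for t, lab, pr, pb in zip(z.loc[plan.test_index, "t"], yte, pred, proba):
            rows.append((pid, t, int(lab), int(pr), float(pb)))
        if keep_models:
            models[pid] = (rf, z.loc[plan.test_index, table.feature_cols], yte)
    if not rows:
        raise DataError("no participant could be evaluated")
    preds = pd.DataFrame(rows, columns=["participant_id", "t", "label",
                                        "prediction", "probability"])
    pooled = compute_metrics(preds["label"], preds["prediction"],
                             preds["probability"].to_numpy(), device_subset)
    return EvaluationResult(pooled, per, preds, models)


DEFAULT_SUBSETS = (("ring",), ("watch",), ("phone",), ALL_DEVICES)


def evaluate_ablation(assembly: Assembly, hyperparams: Hyperparams | None = None,
                      seed: int = DEFAULT_SEED,
                      subsets: tuple = DEFAULT_SUBSETS) -> dict[tuple, EvaluationResult]:
    """Re-run the full evaluation per device subset.

    Column restriction happens before the imputation-method vote, which is
    re-taken on the restricted feature set (window choices are per-feature
    and unaffected by subsetting)."""
    out = {}
    for subset in subsets:
        try:
            table = assembly.materialize(subset)
        except DataError as e:
            warnings.warn(f"subset {subset}: {e}")
            continue
        out[tuple(subset)] = evaluate_all(table, hyperparams, seed,
                                          device_subset=tuple(subset))
    return out
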