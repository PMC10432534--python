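"""Infant-grouped 5-fold cross-validation and performance statistics.

Folds are assigned by infant, never by snippet, so no infant contributes
to both the training and the test side of a fold.  Within each fold the
training infants are further split into fit and validation subsets (5/6 vs
1/6 of the infants); model selection — the SVM grid or the lowest
validation loss across network restarts — only ever sees the validation
subset, and the test subset is touched exactly once.

Per fold the confusion counts yield sensitivity (TPR), specificity (TNR)
and balanced accuracy BA = (TPR + TNR) / 2, with the fidgety-present class
as positive.  Cross-fold means are reported with t-based 95% confidence
intervals, and variants are compared with a two-sample t-test (pooled
variance by default, Welch behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import (ModelSpec, TrainingConfig, train_network,
                     train_svm_grid, train_with_restarts)
from .synth import LABEL_POS


@dataclass
class FoldAssignment:
    """One fold's infant-level split: 1/n test, remainder fit + validation."""

    fold_id: int
    test_infants: list[str]
    fit_infants: list[str]
    val_infants: list[str]

    @property
    def train_infants(self) -> list[str]:
        return self.fit_infants + self.val_infants


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FoldResult:
    fold_id: int
    counts: ConfusionCounts
    tpr: float
    tnr: float
    ba: float
    extra: dict = field(default_factory=dict)


def make_folds(manifest: pd.DataFrame, n_folds: int = 5, seed: int = 0,
               val_fraction: float = 1.0 / 6.0) -> list[FoldAssignment]:
    """Partition infants into n_folds test groups; split the rest fit/val.

    Infants are shuffled by ``seed`` and chunked; each fold's training
    infants are split so that ``val_fraction`` of them (rounded, >= 1)
    form the validation subset.  With 45 infants and 5 folds this yields
    the study design: 9 test, 30 fit, 6 validation infants per fold.
    """
    infants = sorted(manifest["infant_id"].unique())
    if len(infants) < n_folds:
        raise ValueError("fewer infants than folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(infants))
    chunks = [list(c) for c in np.array_split(order, n_folds)]
    folds = []
    for k in range(n_folds):
        test = chunks[k]
        train = [i for i in order if i not in test]
        n_val = max(1, round(len(train) * val_fraction))
        val = train[:n_val]
        fit = train[n_val:]
        folds.append(FoldAssignment(fold_id=k + 1, test_infants=sorted(test),
                                    fit_infants=sorted(fit), val_infants=sorted(val)))
    return folds


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(TPR, TNR, BA) from confusion counts; errors if a class is empty."""
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive snippets in the test set: TPR undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative snippets in the test set: TNR undefined")
    tpr = counts.tp / (counts.tp + counts.fn)
    tnr = counts.tn / (counts.tn + counts.fp)
    return tpr, tnr, (tpr + tnr) / 2.0


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, bool)
    y_pred = np.asarray(y_pred, bool)
    return ConfusionCounts(
        tp=int(np.sum(y_pred & y_true)), tn=int(np.sum(~y_pred & ~y_true)),
        fp=int(np.sum(y_pred & ~y_true)), fn=int(np.sum(~y_pred & y_true)),
    )


@dataclass
class Dataset:
    """Inputs for one model family: manifest plus features and/or signals."""

    manifest: pd.DataFrame
    features12: np.ndarray | None = None
    features24: np.ndarray | None = None
    signals: np.ndarray | None = None   # (n, 500, 6)

    def inputs_for(self, spec: ModelSpec) -> np.ndarray:
        x = {"features12": self.features12, "features24": self.features24,
             "signals500x6": self.signals}[spec.input_kind]
        if x is None:
            raise ValueError(f"dataset lacks {spec.input_kind} inputs")
        return x

    def labels(self) -> np.ndarray:
        return (self.manifest["label"] == LABEL_POS).to_numpy()


def cross_validate(spec: ModelSpec, dataset: Dataset,
                   folds: list[FoldAssignment],
                   config: TrainingConfig | None = None,
                   master_seed: int = 0) -> list[FoldResult]:
    """Evaluate one variant across all folds; one test evaluation per fold.

    For SVM specs the 25-point grid is selected on the validation subset;
    for network specs ``config.n_restarts`` trainings run and the lowest
    validation-loss restart is kept.  The returned per-fold results carry
    confusion counts, TPR/TNR/BA and selection diagnostics.
    """
    config = config or TrainingConfig()
    x_all = dataset.inputs_for(spec)
    y_all = dataset.labels()
    infant = dataset.manifest["infant_id"].to_numpy()
    results = []
    for fold in folds:
        leak = set(fold.test_infants) & set(fold.train_infants)
        if leak:
            raise ValueError(f"fold {fold.fold_id}: infants {leak} leak into training")
        m_fit = np.isin(infant, fold.fit_infants)
        m_val = np.isin(infant, fold.val_infants)
        m_test = np.isin(infant, fold.test_infants)
        extra: dict = {}
        if spec.family == "svm":
            clf, report = train_svm_grid(x_all[m_fit], y_all[m_fit],
                                         x_all[m_val], y_all[m_val],
                                         kernel=spec.kernel, degree=spec.degree)
            pred = clf.predict(x_all[m_test])
            extra["grid_report"] = report
        else:
            fold_seed = int(np.random.default_rng(master_seed + fold.fold_id).integers(2**31 - 1))
            model, losses = train_with_restarts(spec, config,
                                                x_all[m_fit], y_all[m_fit],
                                                x_all[m_val], y_all[m_val],
                                                master_seed=fold_seed)
            pred = model.predict_proba(np.asarray(x_all[m_test], np.float32)) >= 0.5
            extra["restart_losses"] = losses
        counts = confusion_from_predictions(y_all[m_test], pred)
        tpr, tnr, ba = compute_metrics(counts)
        results.append(FoldResult(fold.fold_id, counts, tpr, tnr, ba, extra))
    return results


def summarize(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mean and t-based 95% confidence interval of the mean.

    CI = mean +- t(0.975, n-1) * s / sqrt(n) with the sample SD.
    """
    values = np.asarray(values, float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two folds to summarise")
    mean = float(values.mean())
    half = float(stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n))
    return mean, (mean - half, mean + half)


def compare_models(values_a: np.ndarray, values_b: np.ndarray,
                   welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-fold balanced accuracies.

    Pooled-variance by default; Welch behind the flag.  Two zero-variance
    groups with equal means give (t, p) = (0, 1) by convention.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def results_frame(spec_name: str, results: list[FoldResult]) -> pd.DataFrame:
    """Tidy per-fold results table for one variant."""
    return pd.DataFrame([{
        "variant": spec_name, "fold": r.fold_id,
        "TP": r.counts.tp, "TN": r.counts.tn, "FP": r.counts.fp, "FN": r.counts.fn,
        "TPR": r.tpr, "TNR": r.tnr, "BA": r.ba,
    } for r in results])
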