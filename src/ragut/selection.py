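"""Cross-validated random-forest feature selection over species profiles.

Species are ranked once by random-forest variable importance, then added to
the model one at a time; in each of 5 trials a stratified 10-fold
cross-validation records the misclassification error of the top-m model.
The error curves are averaged, and the cut-off is the minimum of the
averaged curve plus the between-trial standard deviation at that point;
among all feature counts with error at or below the cut-off, the smallest
is the optimal set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .tables import AbundanceTable


@dataclass
class SelectionResult:
    ranked_features: list[str]
    averaged_error: np.ndarray          # error at m = 1..M
    per_trial_error: np.ndarray         # n_trials x M
    sd_at_min: float
    cutoff: float
    candidate_sizes: list[int]
    optimal_size: int
    optimal_set: list[str] = field(default_factory=list)


def _as_xy(table: AbundanceTable, labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(list(labels))
    x = table.values().T  # samples x features
    if x.shape[0] != y.size:
        raise ValueError("labels length does not match sample count")
    return x, y


def importance_ranking(table: AbundanceTable, labels, n_trees: int = 500,
                       seed: int = 0, method: str = "permutation",
                       n_repeats: int = 5) -> list[str]:
    """Rank features by random-forest importance, descending.

    ``permutation`` importance (default) measures the accuracy drop when a
    feature is shuffled; ``impurity`` uses the forest's mean decrease in
    impurity.  Ties are broken by feature order for determinism.
    """
    x, y = _as_xy(table, labels)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if class_counts.min() < 5:
        raise ValueError("need at least 5 samples per class")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(x, y)
    if method == "permutation":
        imp = permutation_importance(rf, x, y, n_repeats=n_repeats,
                                     random_state=seed).importances_mean
    elif method == "impurity":
        imp = rf.feature_importances_
    else:
        raise ValueError(f"unknown importance method {method!r}")
    order = np.lexsort((np.arange(len(imp)), -imp))
    return [table.feature_ids[i] for i in order]


def cv_error_curve(table: AbundanceTable, labels, ranked_features,
                   n_trials: int = 5, n_folds: int = 10, seed: int = 0,
                   n_trees: int = 500,
                   max_features_scanned: int | None = None):
    """Averaged cross-validated error as features are added in rank order.

    Returns (averaged_error, per_trial_error) where per_trial_error is
    n_trials × M and the averaged curve is its mean over trials (each trial
    already averages over folds via pooled out-of-fold predictions).
    """
    x, y = _as_xy(table, labels)
    if x.shape[0] < n_folds:
        raise ValueError("need at least n_folds samples")
    fid_to_col = {fid: i for i, fid in enumerate(table.feature_ids)}
    cols = [fid_to_col[f] for f in ranked_features]
    m_max = min(max_features_scanned or 100, len(cols))
    per_trial = np.zeros((n_trials, m_max))
    for trial in range(n_trials):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + 1000 * trial)
        folds = list(skf.split(x, y))
        for m in range(1, m_max + 1):
            sub = x[:, cols[:m]]
            wrong = 0
            for f, (train, test) in enumerate(folds):
                if len(np.unique(y[train])) < 2:
                    raise ValueError("fold with a single class despite stratification")
                rf = RandomForestClassifier(
                    n_estimators=n_trees,
                    random_state=seed + 1000 * trial + f)
                rf.fit(sub[train], y[train])
                wrong += int((rf.predict(sub[test]) != y[test]).sum())
            per_trial[trial, m - 1] = wrong / x.shape[0]
    return per_trial.mean(axis=0), per_trial


def select_optimal_feature_set(ranked_features, averaged_error,
                               per_trial_error) -> SelectionResult:
    """Apply the minimum-plus-sd cut-off rule to an averaged error curve."""
    avg = np.asarray(averaged_error, dtype=float)
    per_trial = np.asarray(per_trial_error, dtype=float)
    argmin = int(np.argmin(avg))
    sd_at_min = float(per_trial[:, argmin].std(ddof=1)) if per_trial.shape[0] > 1 else 0.0
    cutoff = float(avg[argmin] + sd_at_min)
    candidates = [m + 1 for m in range(len(avg)) if avg[m] <= cutoff + 1e-12]
    optimal = min(candidates)
    return SelectionResult(
        ranked_features=list(ranked_features)[: len(avg)],
        averaged_error=avg, per_trial_error=per_trial,
        sd_at_min=sd_at_min, cutoff=cutoff,
        candidate_sizes=candidates, optimal_size=optimal,
        optimal_set=list(ranked_features)[:optimal],
    )


def run_feature_selection(table: AbundanceTable, labels, n_trials: int = 5,
                          n_folds: int = 10, seed: int = 0, n_trees: int = 500,
                          max_features_scanned: int | None = None,
                          importance_method: str = "permutation") -> SelectionResult:
    """Full procedure: rank → CV error curve → minimum-plus-sd cut-off."""
    ranked = importance_ranking(table, labels, n_trees=n_trees, seed=seed,
                                method=importance_method)
    avg, per_trial = cv_error_curve(table, labels, ranked, n_trials=n_trials,
                                    n_folds=n_folds, seed=seed, n_trees=n_trees,
                                    max_features_scanned=max_features_scanned)
    return select_optimal_feature_set(ranked, avg, per_trial)
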