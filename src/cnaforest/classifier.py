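"""Random-forest scoring, impurity-based feature ranking, and the
label-permutation significance test.

The model is a plain random forest over the binary gene x event matrix,
scored by mean accuracy over stratified k-fold cross-validation (folds are
stratified because with a near-balanced ~17/18 cohort an unstratified split
can produce single-class test folds). Feature importances come from a
single forest fit on all samples (mean impurity decrease, normalized to
sum to 1). Significance of the cross-validated accuracy is assessed by
refitting under random label permutations; the p-value uses the add-one
estimator p = (1 + #{null >= observed}) / (B + 1), which is never zero and
equals 1/(B+1) when the whole null distribution lies below the observed
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .encoding import GeneEventMatrix
from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class ModelConfig:
    """Forest and resampling settings.

    ``n_trees`` defaults to 500: large enough that majority votes over
    bootstrap replicates are stable on a 35-sample cohort, small enough to
    keep a 10-fold fit interactive.
    """

    n_folds: int = 10
    n_trees: int = 500
    n_permutations: int = 1000
    top_k: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")


def _subseeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def _as_xy(
    matrix: GeneEventMatrix, labels
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix with columns in canonical (lexicographic-id) order,
    so results are invariant to how the matrix columns were arranged."""
    X = np.asarray(matrix.values, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if y.shape != (X.shape[0],):
        raise ValidationError(
            f"labels length {y.shape} does not match {X.shape[0]} samples"
        )
    ids = matrix.feature_ids
    order = sorted(range(len(ids)), key=ids.__getitem__)
    return X[:, order] if ids else X, y, [ids[j] for j in order]


def _check_classes(y: np.ndarray, n_folds: int) -> None:
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("labels contain a single class; need both "
                              "MRD-positive and MRD-negative samples")
    smallest = min(n_pos, n_neg)
    if n_folds > smallest:
        raise ValidationError(
            f"n_folds={n_folds} exceeds the smallest class count "
            f"({smallest}); stratified folds would be empty of one class — "
            "reduce n_folds or enlarge the cohort"
        )


def cv_accuracy(
    matrix: GeneEventMatrix, labels, config: ModelConfig = ModelConfig()
) -> float:
    """Mean accuracy of a random forest over stratified k-fold CV."""
    X, y, _ = _as_xy(matrix, labels)
    _check_classes(y, config.n_folds)
    fold_seed, forest_seed = _subseeds(config.seed, 2)
    cv = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                         random_state=fold_seed)
    clf = RandomForestClassifier(n_estimators=config.n_trees,
                                 random_state=forest_seed, n_jobs=1)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def rank_features(
    matrix: GeneEventMatrix, labels, config: ModelConfig = ModelConfig()
) -> pd.DataFrame:
    """Impurity-decrease importances from a forest fit on all samples.

    Returns the ``top_k`` rows of a table with columns ``feature_id``,
    ``importance``, ``rank`` (1-based), ``direction`` and the per-group
    carrier frequencies. Ties in importance break lexicographically by
    feature id. ``direction`` is ``"risk"`` when the feature is more
    frequent among MRD-positive samples (impurity importance is unsigned,
    so the sign is read off the raw group frequencies) and ``"favorable"``
    otherwise.
    """
    X, y, ids = _as_xy(matrix, labels)
    _check_classes(y, config.n_folds)
    _, forest_seed = _subseeds(config.seed, 2)
    clf = RandomForestClassifier(n_estimators=config.n_trees,
                                 random_state=forest_seed, n_jobs=1)
    clf.fit(X, y)
    freq_pos = X[y].mean(axis=0)
    freq_neg = X[~y].mean(axis=0)
    table = pd.DataFrame(
        {
            "feature_id": ids,
            "importance": clf.feature_importances_,
            "freq_mrd_pos": freq_pos,
            "freq_mrd_neg": freq_neg,
        }
    )
    table["direction"] = np.where(table.freq_mrd_pos > table.freq_mrd_neg,
                                  "risk", "favorable")
    table = table.sort_values(
        ["importance", "feature_id"], ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(2, "rank", np.arange(1, len(table) + 1))
    return table.head(config.top_k).copy()


def permutation_pvalue(observed: float, nulls: Sequence[float]) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (B + 1)."""
    nulls = np.asarray(nulls, dtype=float)
    return float((1 + (nulls >= observed).sum()) / (nulls.size + 1))


@dataclass(frozen=True)
class PermutationResult:
    """Observed CV accuracy, its permutation null, and the p-value."""

    observed_accuracy: float
    null_accuracies: tuple[float, ...]
    p_value: float

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p_value out of (0,1]: {self.p_value}")


def permutation_test(
    matrix: GeneEventMatrix, labels, config: ModelConfig = ModelConfig()
) -> PermutationResult:
    """Label-permutation significance of the cross-validated accuracy.

    Labels are shuffled (features fixed, class balance preserved exactly)
    ``n_permutations`` times and the full CV accuracy is recomputed on each
    shuffle; the null accuracies are retained for plotting.
    """
    _, y, _ = _as_xy(matrix, labels)
    _check_classes(y, config.n_folds)
    observed = cv_accuracy(matrix, labels, config)
    shuffle_seed = _subseeds(config.seed, 3)[2]
    rng = np.random.default_rng(shuffle_seed)
    perm_seeds = rng.integers(0, 2**31, size=config.n_permutations)
    nulls = []
    for b in range(config.n_permutations):
        y_perm = rng.permutation(y)
        cfg_b = ModelConfig(
            n_folds=config.n_folds, n_trees=config.n_trees,
            n_permutations=config.n_permutations, top_k=config.top_k,
            seed=int(perm_seeds[b]),
        )
        nulls.append(cv_accuracy(matrix, y_perm, cfg_b))
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=tuple(nulls),
        p_value=permutation_pvalue(observed, nulls),
    )
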