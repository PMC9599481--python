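"""Predictor screening and greedy leading-predictor model search.

The classification stage: stratified train/test split, repeated
bootstrap-forest predictor screening into a fixed-size pool, then a greedy
forward search restarted from every pool member ("leading predictor") over
Gaussian-hidden-node MLP classifiers, evaluated with confusion matrices and
one-vs-rest ROC AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ann import AnnSpec, GaussianMLP, train_ann
from .core import GroupDesign, QuantTable, TableError


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise TableError("train_fraction must lie in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(
    design: GroupDesign, spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Split samples into train/test id lists.

    Stratified mode hits ``round(total * fraction)`` exactly via
    largest-remainder allocation of per-group quotas (remainder ties broken
    by group label order); simple-random mode draws without stratification.
    Deterministic under the split seed.
    """
    rng = np.random.default_rng(spec.seed)
    samples = list(design.assignment.index)
    total_train = _round_half_up(len(samples) * spec.train_fraction)
    if total_train == 0 or total_train == len(samples):
        raise TableError("split leaves train or test set empty")
    if not spec.stratified:
        perm = rng.permutation(len(samples))
        train = sorted(samples[i] for i in perm[:total_train])
        test = sorted(set(samples) - set(train))
        return train, test

    groups = design.groups
    quotas = {g: len(design.samples_in(g)) * spec.train_fraction for g in groups}
    counts = {g: int(np.floor(quotas[g])) for g in groups}
    leftover = total_train - sum(counts.values())
    # largest remainder; ties broken by group label order of the design
    order = sorted(
        range(len(groups)),
        key=lambda i: (-(quotas[groups[i]] - counts[groups[i]]), i),
    )
    for i in order[:leftover]:
        counts[groups[i]] += 1
    train: list[str] = []
    for g in groups:
        members = design.samples_in(g)
        if counts[g] >= len(members):
            raise TableError(f"group {g} too small for the requested split")
        picked = rng.permutation(len(members))[: counts[g]]
        train.extend(members[i] for i in picked)
    train = sorted(train)
    test = sorted(set(samples) - set(train))
    return train, test


# ---------------------------------------------------------------------------
# bootstrap-forest predictor screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Selection frequencies and the ordered predictor pool."""

    table: pd.DataFrame  # index feature; columns frequency, mean_contribution
    pool: list[str]      # ordered by mean contribution, descending
    cycles: int


def screen_predictors(
    X: pd.DataFrame,
    y: Sequence[str],
    cycles: int = 100,
    per_cycle_top: int = 20,
    pool_size: int = 20,
    seed: int = 0,
    n_trees: int = 50,
) -> ScreeningResult:
    """Repeated bootstrap-forest screening of candidate predictors.

    Each cycle fits a random-forest classifier on a bootstrap resample of
    the training rows and records the ``per_cycle_top`` features by
    impurity-decrease importance.  The pool is the ``pool_size`` most
    frequently recorded features (frequency ties broken by mean
    contribution), ordered by mean contribution.
    """
    from sklearn.ensemble import RandomForestClassifier

    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise TableError("screening needs >=2 classes")
    features = list(X.columns)
    arr = X.to_numpy(dtype=float)
    n = len(X)
    freq = np.zeros(len(features))
    contrib = np.zeros(len(features))
    rng = np.random.default_rng(seed)
    for cycle in range(cycles):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        boot_rng = np.random.default_rng(sub_seed)
        idx = boot_rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=sub_seed, n_jobs=1
        )
        forest.fit(arr[idx], y[idx])
        importances = forest.feature_importances_
        top = np.argsort(-importances, kind="stable")[:per_cycle_top]
        freq[top] += 1
        contrib += importances
    table = pd.DataFrame(
        {
            "frequency": freq.astype(int),
            "mean_contribution": contrib / max(cycles, 1),
        },
        index=pd.Index(features, name="feature_id"),
    )
    chosen = sorted(
        features,
        key=lambda f: (
            -table.loc[f, "frequency"],
            -table.loc[f, "mean_contribution"],
            f,
        ),
    )[: min(pool_size, len(features))]
    pool = sorted(
        chosen, key=lambda f: (-table.loc[f, "mean_contribution"], f)
    )
    return ScreeningResult(table=table, pool=pool, cycles=cycles)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def auc_one_vs_rest(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Rank-based one-vs-rest AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ModelEvaluation:
    confusion_matrix: pd.DataFrame  # rows true class, columns predicted
    overall_accuracy: float
    per_class_auc: dict[str, float]

    @property
    def macro_auc(self) -> float:
        vals = [v for v in self.per_class_auc.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def evaluate(model: GaussianMLP, X, y) -> ModelEvaluation:
    """Confusion matrix, overall accuracy and per-class one-vs-rest AUC."""
    y = np.asarray(y)
    proba = model.predict_proba(np.asarray(X, dtype=float))
    pred = model.classes_[np.argmax(proba, axis=1)]
    classes = list(model.classes_)
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for truth, guess in zip(y, pred):
        cm.loc[truth, guess] += 1
    acc = float(np.trace(cm.to_numpy()) / len(y))
    aucs = {}
    for j, cls in enumerate(classes):
        aucs[str(cls)] = auc_one_vs_rest(proba[:, j], y == cls)
    return ModelEvaluation(cm, acc, aucs)


# ---------------------------------------------------------------------------
# greedy leading-predictor search
# ---------------------------------------------------------------------------

SelectionMode = Literal["cv", "paper"]


@dataclass
class SearchTrace:
    """Complete record of a greedy leading-predictor search."""

    runs: list[dict]            # per leading predictor: accepted steps
    best_predictors: list[str]
    best_accuracy: float        # selection-metric accuracy of the winner
    best_macro_auc: float
    selection_mode: str
    pool: list[str]

    def accuracy_curve(self) -> pd.DataFrame:
        """Best selection accuracy observed at each predictor-set size."""
        rows: dict[int, float] = {}
        for run in self.runs:
            for step in run["steps"]:
                k = len(step["predictors"])
                rows[k] = max(rows.get(k, -np.inf), step["accuracy"])
        return pd.DataFrame(
            {"n_predictors": sorted(rows), "accuracy": [rows[k] for k in sorted(rows)]}
        )


def _cv_accuracy(
    X: pd.DataFrame,
    y: np.ndarray,
    predictors: Sequence[str],
    spec: AnnSpec,
    folds: int,
    cv_seed: int,
) -> float:
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
    arr = X[list(predictors)].to_numpy(dtype=float)
    hits = 0
    for train_idx, val_idx in skf.split(arr, y):
        model = train_ann(arr[train_idx], y[train_idx], spec)
        hits += int((model.predict(arr[val_idx]) == y[val_idx]).sum())
    return hits / len(y)


def greedy_leading_search(
    pool: ScreeningResult | Sequence[str],
    X_train: pd.DataFrame,
    y_train: Sequence[str],
    X_test: Optional[pd.DataFrame] = None,
    y_test: Optional[Sequence[str]] = None,
    selection_mode: SelectionMode = "cv",
    max_size: Optional[int] = None,
    hidden_nodes: int = 5,
    restarts: int = 2,
    max_iter: int = 300,
    cv_folds: int = 5,
    seed: int = 0,
) -> SearchTrace:
    """Greedy forward search restarted from every pool member.

    For each leading predictor the set grows by the candidate whose
    addition maximizes the selection metric, accepted only on strict
    improvement.  The metric is stratified ``cv_folds``-fold CV accuracy on
    the training set (mode ``cv``) or held-out test accuracy (mode
    ``paper``, which leaks the test set into selection and is provided for
    protocol replication only).  The overall winner maximizes selection
    accuracy, then macro AUC, then smaller set size, then pool order.
    """
    pool_list = list(pool.pool) if isinstance(pool, ScreeningResult) else list(pool)
    if not pool_list:
        raise TableError("empty predictor pool")
    if max_size is not None and max_size < 1:
        raise TableError("max_size must be >= 1")
    if selection_mode not in ("cv", "paper"):
        raise TableError(f"unknown selection mode {selection_mode!r}")
    if selection_mode == "paper" and (X_test is None or y_test is None):
        raise TableError("paper mode needs the held-out test set")
    y_train = np.asarray(y_train)
    if y_test is not None:
        y_test = np.asarray(y_test)
    max_size = max_size or len(pool_list)

    def make_spec(predictors: Sequence[str]) -> AnnSpec:
        return AnnSpec(
            predictors=tuple(predictors),
            hidden_nodes=hidden_nodes,
            restarts=restarts,
            max_iter=max_iter,
            seed=seed,
        )

    def metric(predictors: Sequence[str]) -> float:
        spec = make_spec(predictors)
        if selection_mode == "cv":
            return _cv_accuracy(X_train, y_train, predictors, spec, cv_folds, seed)
        model = train_ann(
            X_train[list(predictors)].to_numpy(dtype=float), y_train, spec
        )
        pred = model.predict(X_test[list(predictors)].to_numpy(dtype=float))
        return float(np.mean(pred == y_test))

    runs = []
    best: Optional[tuple[float, float, int, int, list[str]]] = None
    for lead_idx, lead in enumerate(pool_list):
        current = [lead]
        acc = metric(current)
        steps = [{"predictors": list(current), "accuracy": acc}]
        while len(current) < max_size:
            candidates = [f for f in pool_list if f not in current]
            if not candidates:
                break
            scored = [(metric(current + [f]), f) for f in candidates]
            # argmax with pool-order tie-break
            best_step = max(
                scored, key=lambda t: (t[0], -pool_list.index(t[1]))
            )
            if best_step[0] <= acc:
                break
            current.append(best_step[1])
            acc = best_step[0]
            steps.append({"predictors": list(current), "accuracy": acc})
        # tie-break metric: macro AUC of a refit under the selection regime
        spec = make_spec(current)
        model = train_ann(
            X_train[list(current)].to_numpy(dtype=float), y_train, spec
        )
        if selection_mode == "paper":
            tie_eval = evaluate(
                model, X_test[list(current)].to_numpy(dtype=float), y_test
            )
        else:
            tie_eval = evaluate(
                model, X_train[list(current)].to_numpy(dtype=float), y_train
            )
        runs.append(
            {
                "leading": lead,
                "steps": steps,
                "final_predictors": list(current),
                "selection_accuracy": acc,
                "macro_auc": tie_eval.macro_auc,
            }
        )
        key = (acc, tie_eval.macro_auc, -len(current), -lead_idx)
        if best is None or key > best[:4]:
            best = (acc, tie_eval.macro_auc, -len(current), -lead_idx, current)

    return SearchTrace(
        runs=runs,
        best_predictors=list(best[4]),
        best_accuracy=float(best[0]),
        best_macro_auc=float(best[1]),
        selection_mode=selection_mode,
        pool=pool_list,
    )


# ---------------------------------------------------------------------------
# end-to-end stage
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    split: SplitSpec
    train_ids: list[str]
    test_ids: list[str]
    screening: ScreeningResult
    trace: SearchTrace
    final_spec: AnnSpec
    train_eval: ModelEvaluation
    test_eval: ModelEvaluation


def run_classification_stage(
    table: QuantTable,
    design: GroupDesign,
    split: Optional[SplitSpec] = None,
    cycles: int = 100,
    per_cycle_top: int = 20,
    pool_size: int = 20,
    selection_mode: SelectionMode = "cv",
    max_size: Optional[int] = None,
    hidden_nodes: int = 5,
    restarts: int = 2,
    max_iter: int = 300,
    cv_folds: int = 5,
    n_trees: int = 50,
    seed: int = 0,
) -> ClassificationReport:
    """Split, screen, search and evaluate in one orchestrated pass.

    In ``cv`` mode the held-out test set is only touched once, for the
    final evaluation of the chosen model.
    """
    if table.values.isna().any().any():
        raise TableError("classification needs a filtered+imputed table")
    design.check_table(table)
    split = split or SplitSpec(seed=seed)
    train_ids, test_ids = split_train_test(design, split)
    X = table.values
    y = design.assignment
    X_train, y_train = X.loc[train_ids], y.loc[train_ids].to_numpy()
    X_test, y_test = X.loc[test_ids], y.loc[test_ids].to_numpy()

    screening = screen_predictors(
        X_train, y_train, cycles=cycles, per_cycle_top=per_cycle_top,
        pool_size=pool_size, seed=seed, n_trees=n_trees,
    )
    trace = greedy_leading_search(
        screening, X_train, y_train,
        X_test=X_test if selection_mode == "paper" else None,
        y_test=y_test if selection_mode == "paper" else None,
        selection_mode=selection_mode, max_size=max_size,
        hidden_nodes=hidden_nodes, restarts=restarts, max_iter=max_iter,
        cv_folds=cv_folds, seed=seed,
    )
    final_spec = AnnSpec(
        predictors=tuple(trace.best_predictors),
        hidden_nodes=hidden_nodes, restarts=restarts, max_iter=max_iter,
        seed=seed,
    )
    preds = list(final_spec.predictors)
    model = train_ann(X_train[preds].to_numpy(dtype=float), y_train, final_spec)
    train_eval = evaluate(model, X_train[preds].to_numpy(dtype=float), y_train)
    test_eval = evaluate(model, X_test[preds].to_numpy(dtype=float), y_test)
    return ClassificationReport(
        split=split, train_ids=train_ids, test_ids=test_ids,
        screening=screening, trace=trace, final_spec=final_spec,
        train_eval=train_eval, test_eval=test_eval,
    )
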