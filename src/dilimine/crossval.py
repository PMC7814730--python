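"""Nested cross-validation engine.

The evaluation scheme is a 5-fold leave-one-cluster-out (LOCO) grid search
nested inside a 10-fold stratified training scheme: the outer split is
stratified on the binary DILI label; within each outer training fold the
hyperparameter grid is searched with 5 inner folds built from whole
structure clusters, so no inner train/validation pair exceeds Tanimoto
similarity 0.5. Chance-level baselines come from y-scrambling: the identical
procedure run on permuted labels (3 runs, median reported).

Models are linear-kernel max-margin classifiers (SVM) and tree ensembles
(random forest), with the hyperparameter grids stored verbatim in
``SVM_GRID`` and ``RF_GRID``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix, Scaler
from .metrics import ConfusionMatrix, UndefinedMetricError, balanced_accuracy, mcc
from .similarity import mean_knn_similarity

SVM_GRID: dict[str, list] = {"C": [0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1]}

RF_GRID: dict[str, list] = {
    "max_depth": [10, 15, None],
    "min_samples_leaf": [1, 2, 3],
    "n_estimators": [100, 200, 300, 400, 500, 750, 1000],
}


def make_model(algorithm: str, params: dict, seed: int = 0):
    """Instantiate a classifier for one grid point."""
    if algorithm == "svm":
        return SVC(
            kernel="linear",
            class_weight="balanced",
            decision_function_shape="ovr",
            shrinking=True,
            C=params["C"],
        )
    if algorithm == "rf":
        return RandomForestClassifier(
            bootstrap=True,
            class_weight="balanced_subsample",
            max_depth=params["max_depth"],
            min_samples_leaf=params["min_samples_leaf"],
            n_estimators=params["n_estimators"],
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def default_grid(algorithm: str) -> dict[str, list]:
    return {"svm": SVM_GRID, "rf": RF_GRID}[algorithm]


def _grid_points(grid: dict[str, list]) -> list[dict]:
    """Cartesian product in declaration order.

    Simpler configurations come first (smallest C, shallowest depth, fewest
    estimators), so the first maximizer wins ties toward the simpler model.
    """
    points: list[dict] = [{}]
    for key, values in grid.items():
        points = [{**p, key: v} for p in points for v in values]
    return points


@dataclass
class FoldPlan:
    """Outer stratified folds plus per-outer-fold inner LOCO groups."""

    outer: list[tuple[np.ndarray, np.ndarray]]
    inner_groups: list[np.ndarray]  # per outer fold: group id per training row


def _pack_clusters(cluster_labels: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Greedy bin-packing of whole clusters into n balanced groups.

    Clusters are sorted by descending size (ties by label) and each assigned
    to the currently smallest group, keeping group sizes balanced while
    guaranteeing group-disjointness of clusters.
    """
    labels, counts = np.unique(cluster_labels, return_counts=True)
    if counts.max() > 0.8 * len(cluster_labels):
        raise ValueError(
            f"cluster of size {counts.max()} exceeds 80% of the training fold; "
            f"cannot form {n_groups} cluster-disjoint groups"
        )
    order = sorted(range(len(labels)), key=lambda i: (-counts[i], labels[i]))
    group_of: dict[int, int] = {}
    sizes = np.zeros(n_groups, dtype=int)
    for i in order:
        g = int(np.argmin(sizes))
        group_of[labels[i]] = g
        sizes[g] += counts[i]
    return np.array([group_of[c] for c in cluster_labels])


def build_fold_plan(
    labels: np.ndarray,
    clusters: np.ndarray,
    seed: int,
    n_outer: int = 10,
    n_inner: int = 5,
    strict_loco_outer: bool = False,
) -> FoldPlan:
    """Construct the outer stratified / inner cluster-grouped fold plan.

    The outer split is stratified on the label only (faithful to the source
    scheme); ``strict_loco_outer=True`` additionally forbids clusters from
    spanning outer folds by stratifying over whole clusters.
    """
    labels = np.asarray(labels).astype(int)
    clusters = np.asarray(clusters)
    if labels.shape != clusters.shape:
        raise ValueError("labels and clusters must align")
    if strict_loco_outer:
        outer = _grouped_stratified_outer(labels, clusters, seed, n_outer)
    else:
        skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
        outer = [(tr.copy(), te.copy()) for tr, te in skf.split(labels, labels)]
    inner_groups = [_pack_clusters(clusters[tr], n_inner) for tr, _ in outer]
    return FoldPlan(outer=outer, inner_groups=inner_groups)


def _grouped_stratified_outer(labels, clusters, seed, n_outer):
    """Outer folds that keep whole clusters together (strict LOCO variant)."""
    rng = np.random.default_rng(seed)
    uniq = np.unique(clusters)
    rng.shuffle(uniq)
    # assign clusters round-robin by positive count to balance stratification
    pos_counts = np.array([(labels[clusters == c] == 1).sum() for c in uniq])
    order = np.argsort(-pos_counts, kind="stable")
    fold_of: dict = {}
    sizes = np.zeros(n_outer)
    for i in order:
        f = int(np.argmin(sizes))
        fold_of[uniq[i]] = f
        sizes[f] += (clusters == uniq[i]).sum()
    fold_idx = np.array([fold_of[c] for c in clusters])
    all_idx = np.arange(len(labels))
    return [
        (all_idx[fold_idx != f], all_idx[fold_idx == f]) for f in range(n_outer)
    ]


@dataclass
class GridSearchResult:
    best_params: dict
    best_score: float
    inner_scores: dict  # repr(params) -> list of per-fold balanced accuracies
    model: object
    scaler: Scaler | None = None

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            return x
        ids = [str(i) for i in range(len(x))]
        names = [f"f{j}" for j in range(x.shape[1])]
        return self.scaler.apply(
            FeatureMatrix(ids, names, x, "descriptor_continuous")
        ).values


def _scaled(x_train: np.ndarray, x_other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit the scaler on training rows only; transform both parts with it."""
    ids = [str(i) for i in range(len(x_train))]
    names = [f"f{j}" for j in range(x_train.shape[1])]
    scaler = Scaler().fit(
        FeatureMatrix(ids, names, x_train, "descriptor_continuous")
    )
    ids_o = [str(i) for i in range(len(x_other))]
    return (
        scaler.apply(FeatureMatrix(ids, names, x_train, "descriptor_continuous")).values,
        scaler.apply(FeatureMatrix(ids_o, names, x_other, "descriptor_continuous")).values,
    )


def grid_search_fit(
    x: np.ndarray,
    y: np.ndarray,
    inner_group: np.ndarray,
    algorithm: str,
    grid: dict[str, list] | None = None,
    seed: int = 0,
    scale: bool = False,
) -> GridSearchResult:
    """Inner 5-fold LOCO grid search maximizing mean balanced accuracy.

    Inner folds whose validation part is single-class are skipped with a
    warning; if every fold is degenerate the search fails. The winning
    configuration is refit on the full training fold. With ``scale=True``
    (continuous descriptors) a zero-mean/unit-variance scaler is fitted on
    the inner-training rows of each split only.
    """
    grid = default_grid(algorithm) if grid is None else grid
    points = _grid_points(grid)
    if not points:
        raise ValueError("empty hyperparameter grid")
    groups = np.unique(inner_group)
    best: tuple[float, dict] | None = None
    inner_scores: dict[str, list[float]] = {}
    for params in points:
        scores = []
        for g in groups:
            val = inner_group == g
            tr = ~val
            if len(np.unique(y[val])) < 2 or len(np.unique(y[tr])) < 2:
                warnings.warn(
                    f"inner fold {g} skipped: single-class split", stacklevel=2
                )
                continue
            x_tr, x_val = x[tr], x[val]
            if scale:
                x_tr, x_val = _scaled(x_tr, x_val)
            model = make_model(algorithm, params, seed)
            model.fit(x_tr, y[tr])
            cm = ConfusionMatrix.from_predictions(y[val], model.predict(x_val))
            scores.append(balanced_accuracy(cm))
        if not scores:
            raise UndefinedMetricError("all inner folds degenerate")
        inner_scores[repr(params)] = scores
        mean_score = float(np.mean(scores))
        if best is None or mean_score > best[0]:
            best = (mean_score, params)
    outer_scaler = None
    x_fit = x
    if scale:
        ids = [str(i) for i in range(len(x))]
        names = [f"f{j}" for j in range(x.shape[1])]
        fm = FeatureMatrix(ids, names, x, "descriptor_continuous")
        outer_scaler = Scaler().fit(fm)
        x_fit = outer_scaler.apply(fm).values
    final = make_model(algorithm, best[1], seed)
    final.fit(x_fit, y)
    return GridSearchResult(
        best_params=best[1],
        best_score=best[0],
        inner_scores=inner_scores,
        model=final,
        scaler=outer_scaler,
    )


def extract_importance(model) -> np.ndarray:
    """Per-feature importance vector.

    Tree ensembles: mean impurity-decrease importances (non-negative, sum 1).
    Linear max-margin models: signed hyperplane coefficients, whose sign
    indicates the favored class. Anything else is unsupported.
    """
    if isinstance(model, RandomForestClassifier):
        return model.feature_importances_.copy()
    if isinstance(model, SVC):
        if model.kernel != "linear":
            raise ValueError("importance extraction requires a linear kernel")
        return model.coef_.ravel().copy()
    raise ValueError(f"unsupported model type: {type(model).__name__}")


@dataclass
class FoldResult:
    fold: int
    params: dict
    cm: ConfusionMatrix
    balanced_accuracy: float
    mcc: float
    importance: np.ndarray


@dataclass
class EvalResult:
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean([f.balanced_accuracy for f in self.folds]))

    @property
    def sd_balanced_accuracy(self) -> float:
        """Sample standard deviation (ddof=1) across folds."""
        vals = [f.balanced_accuracy for f in self.folds]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def importance_matrix(self) -> np.ndarray:
        return np.stack([f.importance for f in self.folds])


def nested_cv(
    x: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    algorithm: str,
    seed: int,
    grid: dict[str, list] | None = None,
    plan: FoldPlan | None = None,
    scale: bool = False,
) -> EvalResult:
    """Full nested run: outer 10-fold stratified, inner 5-fold LOCO search.

    Returns per-outer-fold confusion matrices, metrics, winning parameters
    and feature-importance vectors. Fully deterministic for a fixed seed.
    With ``scale=True`` each outer fold scales with training statistics only.
    """
    x = np.asarray(x)
    y = np.asarray(y).astype(int)
    if plan is None:
        plan = build_fold_plan(y, clusters, seed)
    result = EvalResult()
    for k, (tr, te) in enumerate(plan.outer):
        search = grid_search_fit(
            x[tr], y[tr], plan.inner_groups[k], algorithm, grid=grid, seed=seed,
            scale=scale,
        )
        cm = ConfusionMatrix.from_predictions(
            y[te], search.model.predict(search.transform(x[te]))
        )
        result.folds.append(
            FoldResult(
                fold=k,
                params=search.best_params,
                cm=cm,
                balanced_accuracy=balanced_accuracy(cm),
                mcc=mcc(cm),
                importance=extract_importance(search.model),
            )
        )
    return result


def y_scramble_baseline(
    x: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    algorithm: str,
    seed: int,
    grid: dict[str, list] | None = None,
    n_scrambles: int = 3,
) -> tuple[list[EvalResult], float]:
    """Chance baseline: the identical nested procedure on permuted labels.

    Each run permutes the labels with its own child seed before the full
    training procedure (fold construction included). Returns the per-run
    results and the median of the per-run mean balanced accuracies.
    """
    runs = []
    for r in range(n_scrambles):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(88, r))
        )
        y_perm = np.asarray(y).astype(int).copy()
        rng.shuffle(y_perm)
        runs.append(nested_cv(x, y_perm, clusters, algorithm, seed, grid=grid))
    median = float(np.median([r.mean_balanced_accuracy for r in runs]))
    return runs, median


def similarity_response_analysis(
    fps: np.ndarray,
    y: np.ndarray,
    model_factory: Callable[[], object],
    x: np.ndarray | None = None,
    k: int = 5,
    bin_width: float = 0.1,
):
    """Leave-one-out analysis of classification rate vs. training-set similarity.

    For each compound, fit on the remainder, predict the held-out label, and
    record the mean Tanimoto similarity to its k nearest training neighbors.
    Results are aggregated into left-closed bins of the given width spanning
    [0, 1]; empty bins carry n=0 and a null rate. Bins defined by a single
    compound are flagged.
    """
    import pandas as pd

    fps = np.asarray(fps)
    y = np.asarray(y).astype(int)
    feats = fps if x is None else np.asarray(x)
    n = len(y)
    if n < 6:
        raise ValueError("similarity-response analysis needs at least 6 compounds")
    sims = np.empty(n)
    correct = np.empty(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = model_factory()
        model.fit(feats[mask], y[mask])
        pred = model.predict(feats[i : i + 1])[0]
        correct[i] = pred == y[i]
        sims[i] = mean_knn_similarity(fps[i : i + 1], fps[mask], k=k)[0]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    rows = []
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        in_bin = (sims >= lo) & ((sims < hi) | (b == len(edges) - 2) & (sims <= hi))
        nb = int(in_bin.sum())
        rows.append(
            {
                "bin_low": round(lo, 10),
                "bin_high": round(hi, 10),
                "n": nb,
                "n_correct": int(correct[in_bin].sum()),
                "rate": float(correct[in_bin].mean()) if nb else None,
                "single_compound": nb == 1,
            }
        )
    return pd.DataFrame(rows)
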