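"""Balanced dataset assembly and the boosted-tree training protocol.

One-vs-one models compare two categories after down-sampling the larger to
the smaller's size; one-vs-all models compare one category against an
equal-sized mixture drawn as evenly as possible from the other five.  Model
selection runs a grid search over (min_child_weight, max_depth) — 400
combinations by default — with five-fold cross-validation on an 80% training
split, keeping subsample 0.8, column subsample 0.8, learning rate 0.1 and
gamma 1 fixed.  The winning parameters then train five models on five
disjoint test subsets that together cover 100% of the data, giving one
held-out prediction per element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import xgboost as xgb
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .categorize import CategoryLabel

logger = logging.getLogger("rebel")


def default_grid() -> tuple[tuple[int, int], ...]:
    """400 (min_child_weight, max_depth) combinations: {1..20} x {2..21}."""
    return tuple(
        (mcw, depth) for mcw in range(1, 21) for depth in range(2, 22)
    )


@dataclass(frozen=True)
class ModelConfig:
    subsample: float = 0.8
    colsample_per_tree: float = 0.8
    learning_rate: float = 0.1
    gamma: float = 1.0
    grid: tuple[tuple[int, int], ...] = field(default_factory=default_grid)
    n_folds: int = 5
    test_fraction: float = 0.2
    n_subsets: int = 5
    boosting_rounds: int = 200
    early_stop: int = 20
    seed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(self.grid))
        for f in (self.subsample, self.colsample_per_tree, self.test_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError("fractions must be in (0, 1)")

    def xgb_params(self, min_child_weight: int, max_depth: int) -> dict:
        return {
            "objective": "binary:logistic",
            "eval_metric": "auc",
            "eta": self.learning_rate,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_per_tree,
            "gamma": self.gamma,
            "min_child_weight": min_child_weight,
            "max_depth": max_depth,
            "tree_method": "hist",
            "nthread": 1,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TrainedModelBundle:
    """Five boosted models covering one comparison, with held-out predictions.

    The five test subsets partition the elements: every element is predicted
    exactly once, by the model for which it was held out (its
    ``source_model`` index).
    """

    comparison: str
    best_params: tuple[int, int]  # (min_child_weight, max_depth)
    n_rounds: int
    models: tuple[xgb.Booster, ...]
    element_ids: tuple[str, ...]
    labels: np.ndarray
    heldout_predictions: np.ndarray
    source_model: np.ndarray  # subset index per element
    auc_per_subset: tuple[float, ...]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_subset))


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------


def balance_one_vs_one(
    class_a: Sequence[str], class_b: Sequence[str], seed: int
) -> tuple[list[str], list[str]]:
    """Down-sample the larger class uniformly without replacement."""
    if not class_a or not class_b:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    a, b = list(class_a), list(class_b)
    if len(a) > len(b):
        a = [a[i] for i in sorted(rng.choice(len(a), len(b), replace=False))]
    elif len(b) > len(a):
        b = [b[i] for i in sorted(rng.choice(len(b), len(a), replace=False))]
    return a, b


def assemble_one_vs_all(
    focal: Sequence[str],
    others: Mapping[str, Sequence[str]],
    seed: int,
) -> tuple[list[str], list[str]]:
    """Balanced one-vs-all sets: |negatives| = |focal|, drawn evenly.

    Negatives are sampled without replacement as equally as possible from the
    other classes (per-class quotas differ by at most 1; remainder classes
    chosen by seeded draw).  A class smaller than its quota contributes all
    its members and the deficit is redistributed over the remaining classes.
    """
    if not focal:
        raise ValueError("focal class is empty")
    names = sorted(others)
    pool = {k: list(others[k]) for k in names}
    if sum(len(v) for v in pool.values()) < len(focal):
        raise ValueError("insufficient negatives to balance the focal class")
    rng = np.random.default_rng(seed)
    quotas = {k: 0 for k in names}
    need = len(focal)
    active = [k for k in names if pool[k]]
    while need > 0 and active:
        base = need // len(active)
        rem = need % len(active)
        extra = set(rng.choice(len(active), rem, replace=False)) if rem else set()
        next_active = []
        allocated = 0
        for i, k in enumerate(active):
            want = base + (1 if i in extra else 0)
            take = min(want, len(pool[k]) - quotas[k])
            quotas[k] += take
            allocated += take
            if quotas[k] < len(pool[k]):
                next_active.append(k)
        need -= allocated
        active = next_active
    negatives: list[str] = []
    for k in names:
        idx = sorted(rng.choice(len(pool[k]), quotas[k], replace=False))
        negatives.extend(pool[k][i] for i in idx)
    return list(focal), negatives


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (Mann-Whitney statistic) with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)  # midranks
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridResult:
    best_params: tuple[int, int]
    n_rounds: int  # CV-selected boosting rounds for the winner
    cv_table: tuple[tuple[int, int, float], ...]  # (mcw, depth, mean CV AUC)


def _cv_folds(
    y: np.ndarray, n_folds: int, seed: int, max_attempts: int = 5
):
    """Stratified folds, re-drawn (new seed) if a fold is single-class."""
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2
               for tr, te in folds):
            return folds
    raise ValueError("could not form folds with both classes present")


def grid_search(
    features: np.ndarray, labels: np.ndarray, config: ModelConfig
) -> GridResult:
    """Select (min_child_weight, max_depth) by mean five-fold CV AUC.

    CV runs on an 80% training split (the held-back 20% plays no role in
    selection and is re-merged before subset training).  Each fold trains with
    early stopping on the validation fold's AUC.  Ties break toward lower
    max_depth, then lower min_child_weight.
    """
    y = np.asarray(labels, dtype=int)
    X = np.asarray(features, dtype=float)
    idx_train, _ = train_test_split(
        np.arange(len(y)), test_size=config.test_fraction,
        stratify=y, random_state=config.seed,
    )
    Xt, yt = X[idx_train], y[idx_train]
    folds = _cv_folds(yt, config.n_folds, config.seed)
    dmats = [
        (
            xgb.DMatrix(Xt[tr], label=yt[tr]),
            xgb.DMatrix(Xt[te], label=yt[te]),
            yt[te],
        )
        for tr, te in folds
    ]
    table = []
    best = None  # (-auc, depth, mcw, n_rounds)
    for mcw, depth in config.grid:
        params = config.xgb_params(mcw, depth)
        aucs, iters = [], []
        for dtr, dte, yte in dmats:
            bst = xgb.train(
                params, dtr,
                num_boost_round=config.boosting_rounds,
                evals=[(dte, "val")],
                early_stopping_rounds=config.early_stop,
                verbose_eval=False,
            )
            pred = bst.predict(dte, iteration_range=(0, bst.best_iteration + 1))
            aucs.append(compute_auc(pred, yte))
            iters.append(bst.best_iteration + 1)
        mean_auc = float(np.mean(aucs))
        table.append((mcw, depth, mean_auc))
        cand = (-mean_auc, depth, mcw, int(round(np.mean(iters))))
        if best is None or cand < best:
            best = cand
    _, depth, mcw, n_rounds = best
    logger.info(
        "grid_search: best (min_child_weight=%d, max_depth=%d) "
        "mean CV AUC %.4f, %d rounds", mcw, depth, -best[0], n_rounds,
    )
    return GridResult(
        best_params=(mcw, depth),
        n_rounds=max(n_rounds, 1),
        cv_table=tuple(table),
    )


# ---------------------------------------------------------------------------
# five-subset training
# ---------------------------------------------------------------------------


def train_eval_subsets(
    features: np.ndarray,
    labels: np.ndarray,
    element_ids: Sequence[str],
    best_params: tuple[int, int],
    config: ModelConfig,
    n_rounds: int | None = None,
    comparison: str = "",
) -> TrainedModelBundle:
    """Train/test on five disjoint stratified subsets covering 100% of data."""
    y = np.asarray(labels, dtype=int)
    X = np.asarray(features, dtype=float)
    if min((y == 1).sum(), (y == 0).sum()) < config.n_subsets * 2:
        raise ValueError(
            "category too small to form five informative test subsets"
        )
    rounds = n_rounds if n_rounds is not None else config.boosting_rounds
    folds = _cv_folds(y, config.n_subsets, config.seed + 97)
    models = []
    preds = np.full(len(y), np.nan)
    source = np.full(len(y), -1, dtype=int)
    aucs = []
    mcw, depth = best_params
    params = config.xgb_params(mcw, depth)
    for i, (tr, te) in enumerate(folds):
        dtr = xgb.DMatrix(X[tr], label=y[tr])
        dte = xgb.DMatrix(X[te], label=y[te])
        bst = xgb.train(params, dtr, num_boost_round=rounds)
        p = bst.predict(dte)
        preds[te] = p
        source[te] = i
        aucs.append(compute_auc(p, y[te]))
        models.append(bst)
    assert not np.isnan(preds).any()
    return TrainedModelBundle(
        comparison=comparison,
        best_params=best_params,
        n_rounds=rounds,
        models=tuple(models),
        element_ids=tuple(element_ids),
        labels=y,
        heldout_predictions=preds,
        source_model=source,
        auc_per_subset=tuple(aucs),
    )


# ---------------------------------------------------------------------------
# orchestration over categories
# ---------------------------------------------------------------------------


def train_one_vs_all(
    category: CategoryLabel,
    elements_by_category: Mapping[CategoryLabel, Sequence[str]],
    feature_lookup: Mapping[str, np.ndarray],
    config: ModelConfig,
) -> TrainedModelBundle:
    """Full protocol for one category against the balanced rest."""
    focal = list(elements_by_category[category])
    others = {
        c.code: list(v) for c, v in elements_by_category.items()
        if c != category
    }
    pos, neg = assemble_one_vs_all(focal, others, seed=config.seed)
    ids = pos + neg
    X = np.stack([feature_lookup[e] for e in ids])
    y = np.array([1] * len(pos) + [0] * len(neg))
    grid_result = grid_search(X, y, config)
    return train_eval_subsets(
        X, y, ids, grid_result.best_params, config,
        n_rounds=grid_result.n_rounds,
        comparison=f"{category.code}_vs_all",
    )


def train_one_vs_one(
    cat_a: CategoryLabel,
    cat_b: CategoryLabel,
    elements_by_category: Mapping[CategoryLabel, Sequence[str]],
    feature_lookup: Mapping[str, np.ndarray],
    config: ModelConfig,
) -> TrainedModelBundle:
    a, b = balance_one_vs_one(
        elements_by_category[cat_a], elements_by_category[cat_b],
        seed=config.seed,
    )
    ids = list(a) + list(b)
    X = np.stack([feature_lookup[e] for e in ids])
    y = np.array([1] * len(a) + [0] * len(b))
    grid_result = grid_search(X, y, config)
    return train_eval_subsets(
        X, y, ids, grid_result.best_params, config,
        n_rounds=grid_result.n_rounds,
        comparison=f"{cat_a.code}_vs_{cat_b.code}",
    )
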