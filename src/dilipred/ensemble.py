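"""Balanced-undersampling SVM ensemble with recursive feature elimination.

The labeled compound pool is imbalanced and small, so model performance is
characterized over many balanced trials: each trial undersamples the majority
class to the minority size, splits each class 90/10 into train/held-out,
ranks descriptors by recursive feature elimination (RFE) on the training
rows, keeps the ``top`` ranked features, fits a soft-margin SVM with penalty
``cost``, and evaluates probability scores on the held-out 10%.  A (cost,
top) grid is scored by the arithmetic mean of each metric over trials and the
cell maximizing mean AUC wins (ties broken toward parsimony: smaller top,
then smaller cost).

RFE here is block elimination: fit the classifier on the surviving features,
score each feature by its squared weight (linear kernel) or permutation
importance (rbf), drop the lowest-scoring block down to the next schedule
size, and repeat; the final ranking is the reverse elimination order with
survivors ordered by the last fit's importances.

Each trial's decision threshold is the probability maximizing Youden's J
(sensitivity + specificity - 1) on its held-out ROC; the ensemble's
probability threshold is the mean of these.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

# libsvm's built-in Platt scaling is the probability model this method uses;
# silence sklearn's migration advice toward its own calibration wrapper
warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated", category=FutureWarning
)


@dataclass(frozen=True)
class ModelParams:
    cost: float  # SVM error-penalty / margin trade-off
    top: int  # number of top-ranked features retained
    kernel: str = "linear"
    rfe_schedule: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.top < 1:
            raise ValueError("top must be a positive integer")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.rfe_schedule is not None:
            sched = list(self.rfe_schedule)
            if sched != sorted(set(sched), reverse=True):
                raise ValueError("rfe_schedule must be strictly decreasing")


@dataclass(frozen=True)
class TrialSplit:
    """One balanced undersampling trial's train/held-out membership."""

    index: int
    seed: int
    train_pos: tuple[str, ...]
    train_neg: tuple[str, ...]
    test_pos: tuple[str, ...]
    test_neg: tuple[str, ...]

    @property
    def train_ids(self) -> list[str]:
        return list(self.train_pos) + list(self.train_neg)

    @property
    def test_ids(self) -> list[str]:
        return list(self.test_pos) + list(self.test_neg)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Threshold-based classification metrics; undefined entries are None."""

    sensitivity: float | None
    specificity: float | None
    fpr: float | None
    fnr: float | None
    accuracy: float
    ppv: float | None


@dataclass(frozen=True)
class TrialResult:
    trial_index: int
    params: ModelParams
    selected_features: tuple[str, ...]
    auc: float | None
    metrics: ConfusionMetrics | None
    decision_probability: float | None
    valid: bool = True


@dataclass
class GridResult:
    """Averaged metrics per (cost, top) cell and the winning combination."""

    cell_means: dict[tuple[float, int], dict[str, float | None]]
    n_valid: dict[tuple[float, int], int]
    trial_results: dict[tuple[float, int], list[TrialResult]]
    best_params: ModelParams
    best_threshold: float

    def auc_frame(self) -> pd.DataFrame:
        """Heatmap-ready frame: rows are cost values, columns top values."""
        costs = sorted({c for c, _ in self.cell_means})
        tops = sorted({t for _, t in self.cell_means})
        data = [
            [self.cell_means.get((c, t), {}).get("auc") for t in tops] for c in costs
        ]
        return pd.DataFrame(data, index=costs, columns=tops)

    def best_results(self) -> list[TrialResult]:
        return self.trial_results[(self.best_params.cost, self.best_params.top)]


# ---------------------------------------------------------------------------
# Trial construction


def _derive_int(*entropy: int) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def make_balanced_trials(
    positives: Sequence[str],
    negatives: Sequence[str],
    n_trials: int = 500,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> list[TrialSplit]:
    """Draw ``n_trials`` balanced undersampling trials with 90/10 splits.

    Each trial independently samples, without replacement, as many
    majority-class compounds as there are in the minority class, then holds
    out ``ceil(test_fraction * class size)`` of each class.  Fully
    reproducible from (seed, trial index).
    """
    pos = sorted(set(positives))
    neg = sorted(set(negatives))
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(neg) < len(pos):
        logger.warning(
            "fewer negatives (%d) than positives (%d); undersampling positives",
            len(neg),
            len(pos),
        )
    k = min(len(pos), len(neg))
    splits: list[TrialSplit] = []
    for t in range(n_trials):
        trial_seed = _derive_int(seed, t)
        rng = np.random.default_rng(trial_seed)
        p = list(rng.choice(pos, size=k, replace=False)) if len(pos) > k else list(pos)
        n = list(rng.choice(neg, size=k, replace=False)) if len(neg) > k else list(neg)
        test_n = math.ceil(test_fraction * k)
        p_perm = list(rng.permutation(p))
        n_perm = list(rng.permutation(n))
        splits.append(
            TrialSplit(
                index=t,
                seed=trial_seed,
                train_pos=tuple(p_perm[test_n:]),
                train_neg=tuple(n_perm[test_n:]),
                test_pos=tuple(p_perm[:test_n]),
                test_neg=tuple(n_perm[:test_n]),
            )
        )
    return splits


# ---------------------------------------------------------------------------
# Recursive feature elimination


def default_rfe_schedule(n_features: int, top: int) -> tuple[int, ...]:
    """Halve the surviving-feature count down to 10, inserting ``top``."""
    sizes: list[int] = []
    cur = n_features
    floor = min(10, top)
    while cur > floor:
        cur = max(cur // 2, floor)
        sizes.append(cur)
    if 0 < top < n_features:
        sizes.append(top)
    return tuple(sorted({s for s in sizes if s < n_features}, reverse=True))


def _importances(
    clf: SVC, X: np.ndarray, y: np.ndarray, kernel: str, seed: int
) -> np.ndarray:
    if kernel == "linear":
        return np.asarray(clf.coef_).ravel() ** 2
    imp = permutation_importance(clf, X, y, n_repeats=5, random_state=seed)
    return imp.importances_mean


def rfe_rank(
    X: pd.DataFrame,
    y: Sequence[int],
    params: ModelParams,
    seed: int = 0,
) -> list[str]:
    """Full feature ranking, best to worst, by recursive elimination.

    Requires preprocessed (standardized) features and both classes present.
    The elimination schedule comes from ``params.rfe_schedule`` or the
    default halving schedule; a schedule entry at or above the feature count
    is dropped with a warning.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("rfe_rank requires two classes in y")
    features = list(X.columns)
    if len(features) == 1:
        return features
    schedule = params.rfe_schedule or default_rfe_schedule(len(features), params.top)
    usable = tuple(s for s in schedule if s < len(features))
    if len(usable) != len(schedule):
        logger.warning(
            "rfe schedule truncated: %d entr(ies) >= %d features",
            len(schedule) - len(usable),
            len(features),
        )
    surviving = features
    eliminated: list[str] = []  # worst first
    Xv = X.to_numpy()
    col = {f: i for i, f in enumerate(features)}

    def fit_importances(feats: list[str]) -> np.ndarray:
        sub = Xv[:, [col[f] for f in feats]]
        clf = SVC(kernel=params.kernel, C=params.cost, gamma="scale")
        clf.fit(sub, y)
        return _importances(clf, sub, y, params.kernel, seed)

    for target in usable:
        imp = fit_importances(surviving)
        order = np.argsort(imp, kind="stable")  # ascending: worst first
        n_drop = len(surviving) - target
        dropped = set(order[:n_drop])
        eliminated.extend(surviving[i] for i in order[:n_drop])
        surviving = [f for i, f in enumerate(surviving) if i not in dropped]
    final_imp = fit_importances(surviving)
    final_order = np.argsort(-final_imp, kind="stable")  # descending: best first
    ranking = [surviving[i] for i in final_order] + list(reversed(eliminated))
    return ranking


# ---------------------------------------------------------------------------
# Metrics


def confusion_metrics(
    y_true: Sequence[int], probabilities: Sequence[float], threshold: float
) -> ConfusionMetrics:
    """Classification metrics at a probability threshold (positive iff p > t).

    A metric whose denominator is empty (e.g. PPV with no predicted
    positives) is reported as None, never as 0.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise ValueError("confusion_metrics requires non-empty input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p > threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    return ConfusionMetrics(
        sensitivity=sens,
        specificity=spec,
        fpr=None if spec is None else 1.0 - spec,
        fnr=None if sens is None else 1.0 - sens,
        accuracy=(tp + tn) / y.size,
        ppv=ratio(tp, tp + fp),
    )


def youden_threshold(y_true: Sequence[int], probabilities: Sequence[float]) -> float:
    """Probability maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed probabilities plus 0; classification is
    positive iff probability strictly exceeds the threshold.  Ties go to the
    smallest threshold (highest sensitivity).
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("Youden's J requires both classes in y_true")
    best_t, best_j = 0.0, -np.inf
    for t in np.unique(np.concatenate(([0.0], p))):
        pred = p > t
        sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
        spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
        j = sens + spec - 1.0
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def positive_probability(clf: SVC, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """P(class 1) column of a fitted probabilistic classifier."""
    idx = int(np.nonzero(clf.classes_ == 1)[0][0])
    return clf.predict_proba(np.asarray(X))[:, idx]


# ---------------------------------------------------------------------------
# Trial evaluation and grid search


def _evaluate(
    split: TrialSplit,
    X: pd.DataFrame,
    y: pd.Series,
    params: ModelParams,
    ranking: Sequence[str],
    random_state: int,
) -> TrialResult:
    selected = tuple(ranking[: params.top])
    train_ids, test_ids = split.train_ids, split.test_ids
    y_train = y.loc[train_ids].to_numpy(dtype=int)
    y_test = y.loc[test_ids].to_numpy(dtype=int)
    clf = SVC(
        kernel=params.kernel,
        C=params.cost,
        gamma="scale",
        probability=True,
        random_state=random_state,
    )
    clf.fit(X.loc[train_ids, list(selected)].to_numpy(), y_train)
    if len(np.unique(y_test)) < 2:
        logger.warning("trial %d held-out set is single-class; flagged", split.index)
        return TrialResult(split.index, params, selected, None, None, None, valid=False)
    probs = positive_probability(clf, X.loc[test_ids, list(selected)])
    auc = float(roc_auc_score(y_test, probs))
    thr = youden_threshold(y_test, probs)
    metrics = confusion_metrics(y_test, probs, thr)
    return TrialResult(split.index, params, selected, auc, metrics, thr)


def fit_trial(
    split: TrialSplit,
    X: pd.DataFrame,
    y: pd.Series | Mapping[str, int],
    params: ModelParams,
    seed: int = 0,
) -> TrialResult:
    """Rank, select, fit and evaluate one balanced trial.

    Features are ranked by RFE on the trial's training rows only; the top
    ``params.top`` are retained, the SVM refitted, and probability scores on
    the held-out 10% yield ROC/AUC, the Youden-J decision probability, and
    confusion metrics at that threshold.  A single-class held-out set makes
    AUC undefined: the trial is flagged invalid and excluded from averages.
    """
    y = pd.Series(y) if not isinstance(y, pd.Series) else y
    ranking = rfe_rank(X.loc[split.train_ids], y.loc[split.train_ids], params, seed)
    return _evaluate(split, X, y, params, ranking, _derive_int(seed, split.index))


_METRIC_FIELDS = ("sensitivity", "specificity", "fpr", "fnr", "accuracy", "ppv")


def _cell_mean(results: list[TrialResult]) -> tuple[dict[str, float | None], int]:
    valid = [r for r in results if r.valid]
    if not valid:
        return {}, 0
    means: dict[str, float | None] = {
        "auc": float(np.mean([r.auc for r in valid])),
        "decision_probability": float(np.mean([r.decision_probability for r in valid])),
    }
    for name in _METRIC_FIELDS:
        vals = [getattr(r.metrics, name) for r in valid]
        vals = [v for v in vals if v is not None]
        means[name] = float(np.mean(vals)) if vals else None
    return means, len(valid)


def grid_search(
    trials: Sequence[TrialSplit],
    X: pd.DataFrame,
    y: pd.Series | Mapping[str, int],
    cost_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
    top_grid: Sequence[int] = (5, 10, 15, 20, 30, 50, 100, 200, 400),
    kernel: str = "linear",
    seed: int = 0,
) -> GridResult:
    """Evaluate every (cost, top) cell on every trial and pick the best.

    The RFE ranking is computed once per (trial, cost) — it does not depend
    on ``top`` — with an elimination schedule covering all requested top
    values, then reused across the top grid.  Cells average each metric
    arithmetically over their valid trials; a cell with no valid trial is
    marked missing and can never win.  The winner maximizes mean AUC, ties
    broken by smaller top, then smaller cost.  Bit-identical for a fixed
    seed.
    """
    if not cost_grid or not top_grid:
        raise ValueError("cost_grid and top_grid must be non-empty")
    y = pd.Series(y) if not isinstance(y, pd.Series) else y
    n_features = X.shape[1]
    tops = sorted(set(int(t) for t in top_grid))
    usable_tops = [t for t in tops if t <= n_features]
    if len(usable_tops) != len(tops):
        logger.warning(
            "dropping top values above the %d usable features: %s",
            n_features,
            [t for t in tops if t > n_features],
        )
    if not usable_tops:
        raise ValueError("no top value is <= the number of usable features")
    costs = sorted(set(float(c) for c in cost_grid))

    # one elimination schedule covering every requested top
    base = default_rfe_schedule(n_features, min(usable_tops))
    schedule = tuple(
        sorted({s for s in base} | {t for t in usable_tops if t < n_features}, reverse=True)
    )

    results: dict[tuple[float, int], list[TrialResult]] = {
        (c, t): [] for c in costs for t in usable_tops
    }
    for split in trials:
        y_train = y.loc[split.train_ids]
        X_train = X.loc[split.train_ids]
        for ci, cost in enumerate(costs):
            rank_params = ModelParams(
                cost=cost, top=min(usable_tops), kernel=kernel, rfe_schedule=schedule
            )
            ranking = rfe_rank(X_train, y_train, rank_params, _derive_int(seed, split.index, ci))
            for pi, top in enumerate(usable_tops):
                params = ModelParams(cost=cost, top=top, kernel=kernel)
                rs = _derive_int(seed, split.index, ci, pi)
                results[(cost, top)].append(_evaluate(split, X, y, params, ranking, rs))

    cell_means: dict[tuple[float, int], dict[str, float | None]] = {}
    n_valid: dict[tuple[float, int], int] = {}
    for cell, res in results.items():
        means, nv = _cell_mean(res)
        cell_means[cell] = means
        n_valid[cell] = nv
        if nv == 0:
            logger.warning("grid cell cost=%g top=%d has no valid trial", *cell)

    scored = [
        (means["auc"], cell)
        for cell, means in cell_means.items()
        if n_valid[cell] > 0
    ]
    if not scored:
        raise RuntimeError("every grid cell is missing (all trials degenerate)")
    # max AUC; ties -> smaller top, then smaller cost
    best_cell = min(scored, key=lambda s: (-s[0], s[1][1], s[1][0]))[1]
    best_params = ModelParams(cost=best_cell[0], top=best_cell[1], kernel=kernel)
    best_threshold = cell_means[best_cell]["decision_probability"]
    return GridResult(
        cell_means=cell_means,
        n_valid=n_valid,
        trial_results=results,
        best_params=best_params,
        best_threshold=float(best_threshold),
    )
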