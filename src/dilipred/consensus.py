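"""Feature-frequency consensus and the final deployable classifier.

The top features selected by each balanced trial at the winning (cost, top)
cell differ from trial to trial.  The consensus step counts, over all trials,
how often each descriptor was selected, ranks descriptors by that frequency
(ties by better mean within-trial rank, then name), and keeps the top
``top``.  The final model is then refit on the full labeled pool restricted
to the consensus descriptors, with inverse-class-frequency weighting to
approximate the balanced objective the trials optimized, and carries the
ensemble's mean Youden-J probability threshold as its positive/negative
cut-off.

The fitted SVM is exported as its mathematical parameters (weights or
support vectors, intercept, Platt sigmoid A/B) in JSON; prediction after
loading goes through a native decision-function + Platt pairwise-coupling
path that reproduces libsvm's probability output bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from .descriptors import DescriptorMatrix, ScalingParams, preprocess
from .ensemble import TrialResult

logger = logging.getLogger(__name__)

warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated", category=FutureWarning
)


@dataclass(frozen=True)
class FrequencyTable:
    """Selection counts per descriptor over the trials at one grid cell."""

    counts: Mapping[str, int]
    mean_rank: Mapping[str, float]  # mean 0-based position within selected lists
    n_trials: int

    def __post_init__(self) -> None:
        bad = [f for f, c in self.counts.items() if not 0 < c <= self.n_trials]
        if bad:
            raise ValueError(f"counts outside (0, n_trials] for {bad}")


def feature_frequency(trial_results: Sequence[TrialResult]) -> FrequencyTable:
    """Count how many trials selected each feature.

    All results must share the same (cost, top) parameters; invalid
    (degenerate held-out) trials still contribute their selected set, since
    selection happens on the training rows.
    """
    if not trial_results:
        raise ValueError("no trial results to aggregate")
    params = trial_results[0].params
    if any(r.params != params for r in trial_results):
        raise ValueError("trial results mix different (cost, top) parameters")
    counts: Counter[str] = Counter()
    rank_sums: dict[str, float] = defaultdict(float)
    for res in trial_results:
        for pos, feat in enumerate(res.selected_features):
            counts[feat] += 1
            rank_sums[feat] += pos
    mean_rank = {f: rank_sums[f] / counts[f] for f in counts}
    return FrequencyTable(dict(counts), mean_rank, n_trials=len(trial_results))


def select_consensus_features(freq: FrequencyTable, k: int) -> list[str]:
    """Top-k features by descending selection count.

    Ties are broken by ascending mean within-trial rank (better average
    position wins), then lexicographic name, so the result is deterministic.
    """
    if k > len(freq.counts):
        raise ValueError(
            f"requested {k} consensus features but only {len(freq.counts)} "
            "were ever selected"
        )
    ordered = sorted(
        freq.counts, key=lambda f: (-freq.counts[f], freq.mean_rank[f], f)
    )
    return ordered[:k]


# ---------------------------------------------------------------------------
# Native libsvm-compatible probability path


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def _platt_couple(decision: np.ndarray, prob_a: float, prob_b: float) -> np.ndarray:
    """P(class 1) via libsvm's binary Platt + pairwise-coupling iteration.

    libsvm does not return the sigmoid directly: the binary case still runs
    the Wu-Lin-Weng coupling solver with stopping tolerance 0.005/k, so the
    sigmoid is reproduced only approximately.  This mirrors that iteration
    exactly so stored models reproduce ``SVC.predict_proba`` to machine
    precision.
    """
    r01 = np.clip(_sigmoid(prob_a * decision + prob_b), 1e-7, 1 - 1e-7)
    out = np.empty_like(r01)
    for i, r in enumerate(r01):
        r10 = 1.0 - r
        q = np.array([[r10 * r10, -r10 * r], [-r10 * r, r * r]])
        p = np.array([0.5, 0.5])
        for _ in range(100):
            qp = q @ p
            pqp = p @ qp
            if np.max(np.abs(qp - pqp)) < 0.0025:
                break
            for t in range(2):
                diff = (-qp[t] + pqp) / q[t][t]
                p[t] += diff
                pqp = (pqp + diff * (2 * qp[t] + diff * q[t][t])) / (1 + diff) ** 2
                qp = (qp + diff * q[t]) / (1 + diff)
                p /= 1 + diff
        out[i] = p[1]
    return out


@dataclass
class FinalModel:
    """Consensus-feature SVM with a fixed probability threshold.

    ``decision_sign`` records the orientation of libsvm's internal decision
    value relative to the stored one (it depends on which class libsvm saw
    first during training) and is validated against sklearn at fit time.
    """

    consensus_features: list[str]
    scaling: ScalingParams
    kernel: str
    cost: float
    threshold: float
    intercept: float
    prob_a: float
    prob_b: float
    decision_sign: float
    coef: np.ndarray | None = None  # linear kernel: weight per consensus feature
    support_vectors: np.ndarray | None = None  # rbf kernel
    dual_coef: np.ndarray | None = None
    gamma: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")

    def decision_function(self, matrix: DescriptorMatrix) -> pd.Series:
        X = self.scaling.transform(matrix).values.to_numpy()
        if self.kernel == "linear":
            f = X @ self.coef + self.intercept
        else:
            K = rbf_kernel(X, self.support_vectors, gamma=self.gamma)
            f = K @ self.dual_coef + self.intercept
        return pd.Series(f, index=matrix.compound_ids)

    def predict_proba(self, matrix: DescriptorMatrix) -> pd.Series:
        """Probability of the positive (hepatotoxic) class per compound."""
        f = self.decision_function(matrix)
        probs = _platt_couple(self.decision_sign * f.to_numpy(), self.prob_a, self.prob_b)
        return pd.Series(probs, index=f.index, name="probability")

    def classify(
        self, matrix: DescriptorMatrix, threshold: float | None = None
    ) -> pd.DataFrame:
        """Per-compound probability and thresholded positive/negative label."""
        thr = self.threshold if threshold is None else threshold
        probs = self.predict_proba(matrix)
        return pd.DataFrame(
            {"probability": probs, "label": np.where(probs > thr, "positive", "negative")}
        )

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write model.json, scaling.json and features.txt under a directory."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        payload = {
            "kernel": self.kernel,
            "cost": self.cost,
            "threshold": self.threshold,
            "intercept": self.intercept,
            "prob_a": self.prob_a,
            "prob_b": self.prob_b,
            "decision_sign": self.decision_sign,
            "coef": None if self.coef is None else self.coef.tolist(),
            "support_vectors": None
            if self.support_vectors is None
            else self.support_vectors.tolist(),
            "dual_coef": None if self.dual_coef is None else self.dual_coef.tolist(),
            "gamma": self.gamma,
            "provenance": self.provenance,
        }
        (d / "model.json").write_text(json.dumps(payload, indent=1))
        self.scaling.to_json(d / "scaling.json")
        (d / "features.txt").write_text("\n".join(self.consensus_features) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "FinalModel":
        d = Path(directory)
        payload = json.loads((d / "model.json").read_text())
        features = (d / "features.txt").read_text().splitlines()
        return cls(
            consensus_features=features,
            scaling=ScalingParams.from_json(d / "scaling.json"),
            kernel=payload["kernel"],
            cost=payload["cost"],
            threshold=payload["threshold"],
            intercept=payload["intercept"],
            prob_a=payload["prob_a"],
            prob_b=payload["prob_b"],
            decision_sign=payload["decision_sign"],
            coef=None if payload["coef"] is None else np.array(payload["coef"]),
            support_vectors=None
            if payload["support_vectors"] is None
            else np.array(payload["support_vectors"]),
            dual_coef=None if payload["dual_coef"] is None else np.array(payload["dual_coef"]),
            gamma=payload["gamma"],
            provenance=payload.get("provenance", {}),
        )


def fit_final_model(
    matrix: DescriptorMatrix,
    labels: pd.Series | Mapping[str, int],
    consensus_features: Sequence[str],
    cost: float,
    threshold: float,
    kernel: str = "linear",
    seed: int = 0,
    provenance: dict | None = None,
) -> FinalModel:
    """Refit preprocessing and classifier on the full labeled pool.

    The pool is the union of all positives and all negatives (no
    undersampling); the residual imbalance is handled with
    inverse-class-frequency weighting so the objective matches the balanced
    trials.  ``threshold`` is the ensemble's mean per-trial Youden-J
    decision probability at the winning parameters.
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    ids = list(labels.index)
    sub = matrix.subset_descriptors(list(consensus_features))
    scaled, scaling = preprocess(
        sub, fit_ids=ids, fitted_on=f"labeled pool (n={len(ids)})"
    )
    if scaling.kept != list(consensus_features):
        missing = set(consensus_features) - set(scaling.kept)
        raise ValueError(f"consensus features degenerate on the pool: {sorted(missing)}")
    X = scaled.values.loc[ids].to_numpy()
    y = labels.loc[ids].to_numpy(dtype=int)
    clf = SVC(
        kernel=kernel,
        C=cost,
        gamma="scale",
        class_weight="balanced",
        probability=True,
        random_state=int(np.random.SeedSequence([seed]).generate_state(1)[0] % 2**31),
    )
    clf.fit(X, y)

    prob_a = float(np.asarray(getattr(clf, "_probA"))[0])
    prob_b = float(np.asarray(getattr(clf, "_probB"))[0])
    model = FinalModel(
        consensus_features=list(consensus_features),
        scaling=scaling,
        kernel=kernel,
        cost=float(cost),
        threshold=float(threshold),
        intercept=float(clf.intercept_[0]),
        prob_a=prob_a,
        prob_b=prob_b,
        decision_sign=-1.0,
        coef=np.asarray(clf.coef_).ravel().copy() if kernel == "linear" else None,
        support_vectors=clf.support_vectors_.copy() if kernel != "linear" else None,
        dual_coef=np.asarray(clf.dual_coef_).ravel().copy() if kernel != "linear" else None,
        gamma=float(clf._gamma) if kernel != "linear" else None,
        provenance=provenance or {},
    )
    # libsvm's internal decision orientation depends on training label order;
    # validate against sklearn and flip if needed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ref = clf.predict_proba(X)[:, int(np.nonzero(clf.classes_ == 1)[0][0])]
    check = DescriptorMatrix(sub.values.loc[ids])
    mine = model.predict_proba(check).to_numpy()
    if np.max(np.abs(mine - ref)) > 1e-10:
        model.decision_sign = 1.0
        mine = model.predict_proba(check).to_numpy()
    if np.max(np.abs(mine - ref)) > 1e-10:
        raise RuntimeError("native probability path disagrees with fitted classifier")
    return model
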