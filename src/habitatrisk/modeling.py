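"""The six-learner model zoo and multimodal fusion strategies.

Learners: random forest (RF), gradient boosting (GBM), a small
feed-forward neural network (NN; the tabular stand-in for a CNN on
habitat feature vectors), k-nearest neighbours (KNN), logistic regression
(LR) and an RBF support-vector machine with calibrated probabilities
(SVM). Every model is wrapped in a pipeline with per-block z-scoring, so
fused blocks on different scales are handled uniformly.

Fusion strategies over per-modality feature blocks:

* **early** — concatenate the z-scored blocks and train one model;
* **late (average / weighted)** — train one model per block and average
  the predicted probabilities, optionally weighted by inner-validation
  AUC;
* **ensemble soft voting** — per-block members packaged as one model
  whose prediction is the unweighted mean of member probabilities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._types import FeatureBlock

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "FusionSpec",
    "TrainedModel",
    "make_estimator",
    "train_model",
    "early_fuse",
    "late_fuse",
    "LateFusionModel",
    "ensemble_soft_voting",
    "permutation_attribution",
]

ALGORITHMS = ("RF", "GBM", "NN", "KNN", "LR", "SVM")


@dataclass(frozen=True)
class ModelSpec:
    """One learner: algorithm name, hyperparameter overrides, seed."""

    algorithm: str = "SVM"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {ALGORITHMS}")


@dataclass(frozen=True)
class FusionSpec:
    """A fusion strategy over multimodal blocks.

    ``strategy`` is one of ``early``, ``late_average``, ``late_weighted``
    or ``ensemble_soft_voting``. For the late and ensemble strategies one
    member spec per block is used (a single spec is broadcast).
    """

    strategy: str = "ensemble_soft_voting"
    members: tuple = (ModelSpec(),)

    def __post_init__(self):
        allowed = ("early", "late_average", "late_weighted",
                   "ensemble_soft_voting")
        if self.strategy not in allowed:
            raise ValueError(f"strategy must be one of {allowed}")


def make_estimator(spec: ModelSpec) -> Pipeline:
    """Instantiate the learner behind a spec, z-scoring folded in."""
    hp = dict(spec.hyperparameters)
    s = spec.seed
    if spec.algorithm == "RF":
        est = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500), random_state=s, **hp)
    elif spec.algorithm == "GBM":
        est = GradientBoostingClassifier(
            n_estimators=hp.pop("n_estimators", 300),
            max_depth=hp.pop("max_depth", 3),
            learning_rate=hp.pop("learning_rate", 0.1),
            random_state=s, **hp)
    elif spec.algorithm == "NN":
        # stops on training-loss plateau (tol); validation-based early
        # stopping is unreliable on desk-scale cohorts
        est = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64,)),
            early_stopping=hp.pop("early_stopping", False),
            n_iter_no_change=hp.pop("n_iter_no_change", 20),
            max_iter=hp.pop("max_iter", 500), random_state=s, **hp)
    elif spec.algorithm == "KNN":
        est = KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 7), **hp)
    elif spec.algorithm == "LR":
        est = LogisticRegression(max_iter=hp.pop("max_iter", 2000),
                                 random_state=s, **hp)
    else:  # SVM with probability calibration built in
        est = SVC(kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0),
                  probability=True, random_state=s, **hp)
    return Pipeline([("scale", StandardScaler()), ("model", est)])


@dataclass
class TrainedModel:
    """A fitted estimator bound to the feature schema it was trained on."""

    estimator: object
    feature_names: tuple
    spec: object

    def predict_proba(self, block: FeatureBlock) -> np.ndarray:
        x = block.data[list(self.feature_names)].to_numpy(dtype=float)
        p = self.estimator.predict_proba(x)[:, 1]
        return np.clip(p, 0.0, 1.0)


def train_model(spec: ModelSpec, block: FeatureBlock, labels) -> TrainedModel:
    """Fit one learner on one feature block."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    if block.n_subjects < 20:
        raise ValueError("need at least 20 subjects to train")
    est = make_estimator(spec)
    est.fit(block.data.to_numpy(dtype=float), y)
    return TrainedModel(estimator=est,
                        feature_names=tuple(block.data.columns), spec=spec)


def early_fuse(blocks) -> FeatureBlock:
    """Concatenate blocks column-wise after per-block z-scoring.

    Subject ids and order must match exactly across blocks; misalignment
    raises instead of silently reindexing. Provenance is preserved in the
    column names as a ``modality__feature`` prefix.
    """
    if len(blocks) == 0:
        raise ValueError("no blocks to fuse")
    if len(blocks) == 1:
        return blocks[0]
    index = blocks[0].data.index
    frames = []
    for b in blocks:
        if not b.data.index.equals(index):
            raise ValueError("subject ids/order differ across blocks; "
                             "align explicitly before fusing")
        z = (b.data - b.data.mean()) / b.data.std(ddof=0).replace(0.0, 1.0)
        z.columns = [f"{b.modality}__{c}" for c in b.data.columns]
        frames.append(z)
    fused = pd.concat(frames, axis=1)
    return FeatureBlock(fused, modality="fused_early")


def late_fuse(member_probs, mode: str = "average", weights=None) -> np.ndarray:
    """Combine per-model probability vectors.

    ``average`` takes the arithmetic mean; ``weighted`` a convex
    combination with the given weights (normalized to sum 1; the default
    convention derives them from held-out member AUCs upstream).
    """
    probs = [np.asarray(p, dtype=float) for p in member_probs]
    n = len(probs[0])
    if any(len(p) != n for p in probs):
        raise ValueError("member probability vectors differ in length")
    mat = np.vstack(probs)
    if mode == "average":
        return mat.mean(axis=0)
    if mode != "weighted":
        raise ValueError("mode must be 'average' or 'weighted'")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(probs),) or np.any(w < 0):
        raise ValueError("weights must be nonnegative, one per member")
    w = w / w.sum()
    return w @ mat


@dataclass
class LateFusionModel:
    """Per-block trained members combined at prediction time."""

    members: list                 # TrainedModel per block
    mode: str = "average"         # average | weighted
    weights: np.ndarray | None = None

    def predict_proba(self, blocks) -> np.ndarray:
        probs = [m.predict_proba(b) for m, b in zip(self.members, blocks)]
        return late_fuse(probs, mode=self.mode, weights=self.weights)


def _broadcast(members, n):
    mem = list(members)
    if len(mem) == 1:
        mem = mem * n
    if len(mem) != n:
        raise ValueError("one member spec per block required")
    return mem


def fit_late_fusion(blocks, labels, members=(ModelSpec(),),
                    mode: str = "average", n_inner: int = 5,
                    seed: int = 0) -> LateFusionModel:
    """Train per-block members; for weighted mode, weights are the inner
    cross-validated AUC of each member, normalized to sum 1."""
    from .evaluation import rank_auc

    y = np.asarray(labels)
    mem_specs = _broadcast(members, len(blocks))
    trained = [train_model(s, b, y) for s, b in zip(mem_specs, blocks)]
    weights = None
    if mode == "weighted":
        aucs = []
        cv = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
        for s, b in zip(mem_specs, blocks):
            p = cross_val_predict(make_estimator(s),
                                  b.data.to_numpy(dtype=float), y,
                                  cv=cv, method="predict_proba")[:, 1]
            aucs.append(rank_auc(p, y))
        weights = np.asarray(aucs) / np.sum(aucs)
    return LateFusionModel(members=trained, mode=mode, weights=weights)


@dataclass
class SoftVotingModel:
    """Unweighted mean of member probabilities, packaged as one model."""

    members: list

    def predict_proba(self, blocks) -> np.ndarray:
        probs = [m.predict_proba(b) for m, b in zip(self.members, blocks)]
        return np.vstack(probs).mean(axis=0)


def ensemble_soft_voting(members, blocks, labels) -> SoftVotingModel:
    """Train members on their assigned blocks; predict by soft voting."""
    if len(blocks) < 1:
        raise ValueError("no blocks")
    mem_specs = _broadcast(members, len(blocks))
    if len(mem_specs) < 2 and len(blocks) < 2:
        raise ValueError("soft voting needs at least 2 members")
    y = np.asarray(labels)
    trained = [train_model(s, b, y) for s, b in zip(mem_specs, blocks)]
    return SoftVotingModel(members=trained)


def permutation_attribution(model: TrainedModel, block: FeatureBlock, labels,
                            n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Permutation feature attribution: mean AUC drop per feature.

    Each column is shuffled ``n_repeats`` times; the importance is the mean
    drop in AUC relative to the unpermuted predictions, with its SD. A
    model-agnostic stand-in for Shapley-value attribution.
    """
    from .evaluation import rank_auc

    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    base = rank_auc(model.predict_proba(block), y)
    rows = []
    for col in block.data.columns:
        drops = []
        for _ in range(n_repeats):
            shuffled = block.data.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            p = model.predict_proba(
                FeatureBlock(shuffled, block.modality, dict(block.provenance)))
            drops.append(base - rank_auc(p, y))
        rows.append((col, float(np.mean(drops)), float(np.std(drops))))
    return pd.DataFrame(rows, columns=["feature", "auc_drop", "sd"]) \
        .set_index("feature").sort_values("auc_drop", ascending=False)
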