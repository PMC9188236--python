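"""Per-view random forests and the multi-view stacking model (MVRF).

One random forest (default 500 trees, 15 candidate features per split) is
trained per anatomical view.  Each forest yields, for an image, a vote
profile: the relative frequency with which its trees vote for each of the q
species — a proxy for the class posterior.  The multi-view model concatenates
the three per-view profiles into a 3q meta-feature vector and trains a
multinomial logistic regression on top.

The crucial detail is how meta-training features are built: for a training
observation only the trees whose bootstrap sample *excluded* it (its
out-of-bag trees, about T/e of them) are allowed to vote.  This keeps the
meta-features honest — an in-bag tree has effectively memorised the
observation — so the meta-learner sees vote profiles distributed like those
of genuinely unseen images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .taxonomy_io import VIEWS


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters: 500 trees, mtry 15 by default."""

    n_trees: int = 500
    mtry: int = 15
    seed: int = 0
    meta_l2: float = 1.0  # ridge strength of the multinomial meta-learner

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class ViewForest:
    """A fitted forest for one view plus what OOB voting needs."""

    view: str
    forest: RandomForestClassifier
    classes: np.ndarray                  # ordered species labels, length q
    oob_mask: np.ndarray                 # (n, T) True where obs i is OOB for tree t
    tree_votes: np.ndarray               # (n, T) class index voted by tree t for obs i
    n_train: int

    @property
    def n_trees(self) -> int:
        return self.oob_mask.shape[1]


def train_view_forest(
    features: np.ndarray, labels, cfg: ForestConfig, view: str = "transverse"
) -> ViewForest:
    """Fit one per-view forest, retaining bootstrap membership for OOB votes."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if cfg.mtry > X.shape[1]:
        raise ValueError(
            f"mtry={cfg.mtry} exceeds the feature dimension {X.shape[1]}"
        )
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.mtry,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    clf.fit(X, y)

    n = X.shape[0]
    oob = np.ones((n, cfg.n_trees), dtype=bool)
    for t, sample_idx in enumerate(clf.estimators_samples_):
        oob[np.unique(sample_idx), t] = False
    # stacking-leakage guard: no observation may be in-bag for every tree
    if cfg.n_trees > 1 and not (oob.sum(axis=1) < cfg.n_trees).all():
        raise AssertionError("an observation was in-bag for every tree")

    votes = np.empty((n, cfg.n_trees), dtype=np.int32)
    for t, tree in enumerate(clf.estimators_):
        # sub-trees predict label-encoded class indices into clf.classes_
        votes[:, t] = tree.predict(X).astype(np.int32)
    return ViewForest(
        view=view, forest=clf, classes=clf.classes_,
        oob_mask=oob, tree_votes=votes, n_train=n,
    )


def oob_vote_profile(forest: ViewForest, training_index: int) -> np.ndarray:
    """Relative vote frequencies over the trees that did NOT train on the obs.

    If the observation happens to be in-bag for every tree (probability
    vanishingly small at T=500) the uniform profile is returned.
    """
    if not (0 <= training_index < forest.n_train):
        raise ValueError(f"training_index {training_index} out of range")
    return oob_vote_profiles(forest)[training_index]


def oob_vote_profiles(forest: ViewForest) -> np.ndarray:
    """OOB vote profiles for all training observations, shape (n, q)."""
    n, q = forest.n_train, len(forest.classes)
    counts = np.zeros((n, q))
    rows = np.arange(n)
    for t in range(forest.n_trees):
        mask = forest.oob_mask[:, t]
        np.add.at(counts, (rows[mask], forest.tree_votes[mask, t]), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    profiles = np.full((n, q), 1.0 / q)
    nonzero = totals[:, 0] > 0
    profiles[nonzero] = counts[nonzero] / totals[nonzero]
    return profiles


def test_vote_profile(forest: ViewForest, feature: np.ndarray) -> np.ndarray:
    """Vote profile for a new image: every tree in the forest votes."""
    feature = np.asarray(feature, dtype=np.float64)
    if feature.ndim == 1:
        return test_vote_profiles(forest, feature[None, :])[0]
    raise ValueError("expected a single feature vector; use test_vote_profiles")


def test_vote_profiles(forest: ViewForest, X: np.ndarray) -> np.ndarray:
    """Vote profiles for a batch of images, shape (m, q)."""
    X = np.asarray(X, dtype=np.float64)
    d_expected = forest.forest.n_features_in_
    if X.ndim != 2 or X.shape[1] != d_expected:
        raise ValueError(
            f"feature dimension mismatch: expected {d_expected}, got {X.shape}"
        )
    m, q = X.shape[0], len(forest.classes)
    counts = np.zeros((m, q))
    rows = np.arange(m)
    for tree in forest.forest.estimators_:
        idx = tree.predict(X).astype(np.int32)
        np.add.at(counts, (rows, idx), 1.0)
    return counts / forest.forest.n_estimators


@dataclass
class MVRFModel:
    """Three per-view forests plus the multinomial meta-learner."""

    forests: dict = field(default_factory=dict)  # view -> ViewForest
    meta: LogisticRegression | None = None
    classes: np.ndarray | None = None
    version: str = "mvrf-1"

    def meta_dim(self) -> int:
        return 3 * len(self.classes)


def train_mvrf(
    features_by_view: dict, labels, cfg: ForestConfig
) -> MVRFModel:
    """Train the multi-view stacked model.

    ``features_by_view`` maps each of the three views to an (n, d) matrix
    whose rows are aligned across views (row i of every view belongs to the
    same specimen piece).  The per-view forests are trained independently
    (with view-specific seeds derived from ``cfg.seed``); the meta-learner is
    a multinomial logistic regression with a small L2 penalty fitted on the
    concatenated out-of-bag vote profiles.
    """
    missing = [v for v in VIEWS if v not in features_by_view]
    if missing:
        raise ValueError(f"missing view(s) {missing} in training data")
    y = np.asarray(labels)
    n = len(y)
    for v in VIEWS:
        if np.asarray(features_by_view[v]).shape[0] != n:
            raise ValueError(f"view {v!r} has a different number of specimens")

    forests = {}
    meta_parts = []
    for k, v in enumerate(VIEWS):
        vf = train_view_forest(
            features_by_view[v], y,
            ForestConfig(cfg.n_trees, cfg.mtry, cfg.seed + 101 * (k + 1), cfg.meta_l2),
            view=v,
        )
        forests[v] = vf
        meta_parts.append(oob_vote_profiles(vf))
    classes = forests["transverse"].classes
    for v in VIEWS:
        if not np.array_equal(forests[v].classes, classes):
            raise AssertionError("class lists differ across views")

    meta_X = np.hstack(meta_parts)
    meta = LogisticRegression(
        C=1.0 / cfg.meta_l2, max_iter=2000, random_state=cfg.seed
    )
    meta.fit(meta_X, y)
    return MVRFModel(forests=forests, meta=meta, classes=classes)


def mvrf_posteriors(model: MVRFModel, features_by_view: dict) -> np.ndarray:
    """Meta-learner class probabilities for a batch of complete specimens."""
    missing = [v for v in VIEWS if v not in features_by_view]
    if missing:
        raise ValueError(f"missing view(s) {missing} at prediction time")
    profiles = [
        test_vote_profiles(model.forests[v], np.atleast_2d(features_by_view[v]))
        for v in VIEWS
    ]
    meta_X = np.hstack(profiles)
    proba = model.meta.predict_proba(meta_X)
    # meta classes may be a subset ordering; align to model.classes
    if not np.array_equal(model.meta.classes_, model.classes):
        aligned = np.zeros((proba.shape[0], len(model.classes)))
        idx = np.searchsorted(model.classes, model.meta.classes_)
        aligned[:, idx] = proba
        proba = aligned
    return proba


def predict_mvrf(model: MVRFModel, features_by_view: dict):
    """Predict species for one specimen given its three view features.

    Returns ``(label, posterior)``; the label is the argmax of the
    meta-learner posterior, ties broken by class-list order.
    """
    proba = mvrf_posteriors(model, features_by_view)
    if proba.shape[0] != 1:
        raise ValueError("predict_mvrf expects a single specimen; "
                         "use mvrf_posteriors for batches")
    post = proba[0]
    return model.classes[int(np.argmax(post))], post


def concat_features(*views: np.ndarray) -> np.ndarray:
    """Concatenate per-view descriptors (2 or 3 views, order TS, TLS, RLS)."""
    if len(views) not in (2, 3):
        raise ValueError("expected 2 or 3 view feature vectors")
    arrs = [np.asarray(v, dtype=np.float64) for v in views]
    dims = {a.shape[-1] for a in arrs}
    if len(dims) != 1:
        raise ValueError(f"view feature lengths differ: {sorted(dims)}")
    return np.concatenate(arrs, axis=-1)


__all__ = [
    "ForestConfig", "ViewForest", "MVRFModel",
    "train_view_forest", "oob_vote_profile", "oob_vote_profiles",
    "test_vote_profile", "test_vote_profiles",
    "train_mvrf", "predict_mvrf", "mvrf_posteriors", "concat_features",
]
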