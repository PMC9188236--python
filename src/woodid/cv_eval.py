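"""Cross-validation protocols and evaluation metrics.

Two protocols are implemented.  Naive stratified k-fold assigns specimen
pieces (one piece = its three linked views, kept together) to folds at
random within each species, so images from the same physical tree can sit on
both sides of a split.  The grouped protocol (leave-k-trees-out) holds out
one whole tree per species: every image from a held-out tree is test, every
image from the remaining trees is training, and no tree ever straddles the
split.  When within-tree images are more alike than between-tree images —
the normal situation for micrographs cut from one wood block — the naive
protocol leaks and its accuracy estimate is optimistic; comparing the two
quantifies that optimism.

Reports carry accuracy at species, genus and family level (a genus-level hit
means truth and prediction map to the same genus), the mean hierarchical
cost (H-Loss), per-species accuracy and a species-by-species confusion
matrix ordered by family, then genus, then species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forest_views import (
    ForestConfig,
    concat_features,
    mvrf_posteriors,
    test_vote_profiles,
    train_mvrf,
    train_view_forest,
)
from .hierarchy_cost import CostSpec, bayes_decide_batch, h_loss
from .lpq import FEATURE_COLUMNS
from .taxonomy_io import VIEWS, DatasetIndex, TaxonomyTable

MODELS = ("single:transverse", "single:tangential", "single:radial",
          "concat2", "concat3", "mvrf")
PROTOCOLS = ("kfold", "grouped")


# ---------------------------------------------------------------------------
# specimen table: one row per piece, three aligned feature matrices

@dataclass
class SpecimenTable:
    """Feature matrices of linked views, row-aligned with specimen metadata."""

    meta: pd.DataFrame                     # columns: group_id, species, tree_id
    features: dict                         # view -> (n, d) ndarray

    def __post_init__(self) -> None:
        n = len(self.meta)
        for v, X in self.features.items():
            if X.shape[0] != n:
                raise ValueError(f"view {v!r} has {X.shape[0]} rows, expected {n}")

    def __len__(self) -> int:
        return len(self.meta)

    def take(self, idx) -> "SpecimenTable":
        idx = np.asarray(idx)
        return SpecimenTable(
            self.meta.iloc[idx].reset_index(drop=True),
            {v: X[idx] for v, X in self.features.items()},
        )


def build_specimen_table(feature_df: pd.DataFrame) -> SpecimenTable:
    """Assemble a :class:`SpecimenTable` from a per-image feature table.

    The input is the output of :func:`woodid.lpq.descriptor_table`.  The
    three views of one specimen piece are linked positionally by
    ``(specimen_id, piece_index)``; a piece missing any view is an error.
    """
    feature_df = feature_df.copy()
    feature_df["group_id"] = (
        feature_df["specimen_id"].astype(str)
        + "#p" + feature_df["piece_index"].astype(str)
    )
    rows, mats = [], {v: [] for v in VIEWS}
    for gid, grp in feature_df.groupby("group_id", sort=True):
        by_view = {r["view"]: r for _, r in grp.iterrows()}
        missing = [v for v in VIEWS if v not in by_view]
        if missing:
            raise ValueError(f"specimen group {gid!r} is missing view(s) {missing}")
        first = grp.iloc[0]
        rows.append(dict(group_id=gid, species=first["species"], tree_id=first["tree_id"]))
        for v in VIEWS:
            mats[v].append(by_view[v][FEATURE_COLUMNS].to_numpy(dtype=np.float64))
    meta = pd.DataFrame(rows)
    return SpecimenTable(meta, {v: np.vstack(mats[v]) for v in VIEWS})


# ---------------------------------------------------------------------------
# fold construction

@dataclass(frozen=True)
class FoldAssignment:
    fold_of: dict          # group_id -> fold index
    k: int


def _stratified_folds(species: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Species-stratified fold indices; per-species sizes differ by <= 1."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(species), dtype=int)
    for sp in np.unique(species):
        idx = np.flatnonzero(species == sp)
        rng.shuffle(idx)
        start = rng.integers(k)
        folds[idx] = (start + np.arange(len(idx))) % k
    return folds


def stratified_kfold(index: DatasetIndex, k: int = 4, seed: int = 0) -> FoldAssignment:
    """Naive stratified k-fold over specimen-piece groups.

    All three views of a piece share one fold, so a multi-view model never
    trains on any view of a test piece — but pieces from the same tree may
    still land in different folds (this is the leaky convention under test).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups: dict[str, str] = {}
    for r in index.records:
        groups.setdefault(r.group_id, r.species)
    gids = sorted(groups)
    species = np.array([groups[g] for g in gids])
    folds = _stratified_folds(species, k, seed)
    return FoldAssignment({g: int(f) for g, f in zip(gids, folds)}, k)


@dataclass(frozen=True)
class GroupedSplit:
    train_ids: tuple       # image_ids (or group row indices) in training
    test_ids: tuple
    untestable_species: tuple = ()


def _grouped_split_core(species: np.ndarray, tree_ids: np.ndarray, seed: int):
    """Per species, pick one tree whose items all become test."""
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(species), dtype=bool)
    untestable = []
    for sp in np.unique(species):
        sp_mask = species == sp
        trees = np.unique(tree_ids[sp_mask])
        if len(trees) < 2:
            untestable.append(str(sp))
            continue
        held = trees[rng.integers(len(trees))]
        test_mask |= sp_mask & (tree_ids == held)
    return test_mask, untestable


def leave_k_trees_out_split(index: DatasetIndex, seed: int = 0) -> GroupedSplit:
    """One-tree-per-species held-out split over a dataset index.

    Returns image_id lists; a species with a single tree goes wholly to
    training and is reported as untestable.
    """
    if not index.records:
        raise ValueError("cannot split an empty dataset")
    species = np.array([r.species for r in index.records])
    trees = np.array([r.tree_id for r in index.records])
    test_mask, untestable = _grouped_split_core(species, trees, seed)
    ids = np.array([r.image_id for r in index.records])
    return GroupedSplit(
        tuple(ids[~test_mask]), tuple(ids[test_mask]), tuple(untestable)
    )


# ---------------------------------------------------------------------------
# metrics

@dataclass
class EvalReport:
    accuracy_species: float
    accuracy_genus: float
    accuracy_family: float
    h_loss: float
    per_species_accuracy: dict
    confusion: pd.DataFrame
    fold_accuracies: list = field(default_factory=list)
    untestable_species: tuple = ()

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracies)) if self.fold_accuracies else self.accuracy_species

    @property
    def accuracy_std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def to_dict(self) -> dict:
        return dict(
            accuracy_species=self.accuracy_species,
            accuracy_genus=self.accuracy_genus,
            accuracy_family=self.accuracy_family,
            h_loss=self.h_loss,
            per_species_accuracy=self.per_species_accuracy,
            fold_accuracies=list(map(float, self.fold_accuracies)),
            accuracy_mean=self.accuracy_mean,
            accuracy_std=self.accuracy_std,
            untestable_species=list(self.untestable_species),
        )


def evaluate(
    truth, predicted, tax: TaxonomyTable, spec: CostSpec | None = None
) -> EvalReport:
    """Multi-level accuracies, H-Loss and confusion matrix for paired labels."""
    truth, predicted = list(truth), list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lists differ in length")
    for lab in set(truth) | set(predicted):
        if lab not in tax:
            raise ValueError(f"label {lab!r} not in taxonomy")
    t = np.array(truth)
    p = np.array(predicted)
    acc_sp = float(np.mean(t == p))
    acc_ge = float(np.mean([tax.genus(a) == tax.genus(b) for a, b in zip(t, p)]))
    acc_fa = float(np.mean([tax.family(a) == tax.family(b) for a, b in zip(t, p)]))
    order = tax.taxonomy_order()
    conf = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for a, b in zip(t, p):
        conf.loc[a, b] += 1
    per_sp = {
        sp: float(np.mean(p[t == sp] == sp)) for sp in np.unique(t)
    }
    return EvalReport(
        accuracy_species=acc_sp,
        accuracy_genus=acc_ge,
        accuracy_family=acc_fa,
        h_loss=h_loss(truth, predicted, tax, spec),
        per_species_accuracy=per_sp,
        confusion=conf,
    )


# ---------------------------------------------------------------------------
# experiment driver

def _fit_predict(
    train: SpecimenTable,
    test: SpecimenTable,
    model: str,
    cfg: ForestConfig,
    tax: TaxonomyTable,
    cost_spec: CostSpec | None,
    decision: str,
):
    """Train one model on ``train``, return predicted labels for ``test``."""
    y_train = train.meta["species"].to_numpy()
    if model.startswith("single:"):
        view = model.split(":", 1)[1]
        vf = train_view_forest(train.features[view], y_train, cfg, view=view)
        post = test_vote_profiles(vf, test.features[view])
        classes = vf.classes
    elif model in ("concat2", "concat3"):
        views = VIEWS[:2] if model == "concat2" else VIEWS
        Xtr = concat_features(*[train.features[v] for v in views])
        Xte = concat_features(*[test.features[v] for v in views])
        vf = train_view_forest(Xtr, y_train, cfg, view="+".join(views))
        post = test_vote_profiles(vf, Xte)
        classes = vf.classes
    elif model == "mvrf":
        mv = train_mvrf(train.features, y_train, cfg)
        post = mvrf_posteriors(mv, test.features)
        classes = mv.classes
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")

    if decision == "bayes":
        # renormalise against round-off before the expected-cost argmin
        post = post / post.sum(axis=1, keepdims=True)
        labels = bayes_decide_batch(post, list(classes), tax, cost_spec)
    elif decision == "argmax":
        labels = [classes[int(j)] for j in np.argmax(post, axis=1)]
    else:
        raise ValueError(f"unknown decision rule {decision!r}")
    return list(labels), post


def run_experiment(
    table: SpecimenTable,
    tax: TaxonomyTable,
    model: str = "mvrf",
    protocol: str = "kfold",
    k: int = 4,
    seed: int = 0,
    forest_cfg: ForestConfig | None = None,
    cost_spec: CostSpec | None = None,
    decision: str = "argmax",
    n_repeats: int = 5,
) -> EvalReport:
    """Cross-validated evaluation of one model under one protocol.

    ``kfold``: species-stratified k-fold over specimen pieces; predictions
    pooled over folds, fold-wise accuracies kept for the mean +- std.
    ``grouped``: the leave-one-tree-per-species split repeated ``n_repeats``
    times with derived seeds; each repeat contributes one accuracy.
    All fitting happens inside the training side of each split.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    cfg = forest_cfg or ForestConfig()
    species = table.meta["species"].to_numpy()
    tree_ids = table.meta["tree_id"].to_numpy()

    all_truth: list[str] = []
    all_pred: list[str] = []
    fold_accs: list[float] = []
    untestable: tuple = ()

    if protocol == "kfold":
        if k < 2:
            raise ValueError("k must be >= 2")
        folds = _stratified_folds(species, k, seed)
        splits = [
            (np.flatnonzero(folds != f), np.flatnonzero(folds == f))
            for f in range(k)
        ]
    else:
        splits = []
        for r in range(n_repeats):
            test_mask, unt = _grouped_split_core(species, tree_ids, seed + 9973 * r)
            untestable = tuple(unt)
            if not test_mask.any():
                raise ValueError("no species has two trees; grouped CV impossible")
            splits.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))

    for i, (tr_idx, te_idx) in enumerate(splits):
        train, test = table.take(tr_idx), table.take(te_idx)
        if protocol == "grouped":
            assert not set(train.meta["tree_id"]) & set(test.meta["tree_id"])
        labels, _ = _fit_predict(
            train, test, model, replace(cfg, seed=cfg.seed + 31 * i),
            tax, cost_spec, decision,
        )
        truth = list(test.meta["species"])
        all_truth.extend(truth)
        all_pred.extend(labels)
        fold_accs.append(float(np.mean(np.array(labels) == np.array(truth))))

    report = evaluate(all_truth, all_pred, tax, cost_spec)
    report.fold_accuracies = fold_accs
    report.untestable_species = untestable
    return report


__all__ = [
    "MODELS", "PROTOCOLS",
    "SpecimenTable", "build_specimen_table",
    "FoldAssignment", "stratified_kfold",
    "GroupedSplit", "leave_k_trees_out_split",
    "EvalReport", "evaluate", "run_experiment",
]
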