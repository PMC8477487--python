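"""Bagged classification-tree ensemble.

The classifier used throughout the pipeline is bootstrap aggregation
(bagging) of decision trees: each tree is fit on a bootstrap resample of the
training samples, considering a random subset of genes at every split, and a
sample's **probability score** is the fraction of trees voting the positive
class. A sample is called positive iff its score is strictly greater than
the threshold (default 0.5).

The tree learner is scikit-learn's :class:`RandomForestClassifier`; this
module adds the vote-fraction score, out-of-bag (OOB) accuracy, OOB
permutation importance (mean decrease in OOB accuracy when one gene's values
are permuted among a tree's out-of-bag samples), and a human-readable text
serialization of the fitted trees.

Determinism: everything is a pure function of (data, config, seed); trees
are always fit single-threaded so results do not depend on thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .io_core import (
    POSITIVE_CLASS,
    ClassificationResult,
    CohortError,
    ExpressionCohort,
    read_json_doc,
    write_json_doc,
)


@dataclass
class ForestConfig:
    """Ensemble hyperparameters.

    ``features_per_split`` is the number of candidate genes per split:
    ``"sqrt"``/``"log2"`` of the gene universe, ``"all"``, or an integer.
    ``importance_method`` selects OOB permutation importance (default) or the
    impurity-based alternative.
    """

    n_trees: int = 500
    features_per_split: str | int = "sqrt"
    min_leaf: int = 1
    bootstrap: bool = True
    importance_method: str = "impurity"  # or "oob_permutation"
    threshold: float = 0.5
    seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        if self.n_trees < 1:
            raise CohortError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise CohortError("min_leaf must be >= 1")
        if isinstance(self.features_per_split, str):
            if self.features_per_split not in ("sqrt", "log2", "all"):
                raise CohortError(
                    f"features_per_split rule {self.features_per_split!r} unknown"
                )
        elif n_features is not None and not 1 <= self.features_per_split <= n_features:
            raise CohortError(
                f"features_per_split={self.features_per_split} outside 1..{n_features}"
            )
        if self.importance_method not in ("oob_permutation", "impurity"):
            raise CohortError(f"unknown importance_method {self.importance_method!r}")

    def _sklearn_max_features(self):
        if self.features_per_split == "all":
            return None
        return self.features_per_split


@dataclass
class ImportanceRanking:
    """Genes ordered by non-increasing importance (non-negative scores)."""

    genes: list[str]
    importance: list[float]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.importance):
            raise CohortError("genes and importance lengths differ")
        if any(v < 0 for v in self.importance):
            raise CohortError("importance must be non-negative")
        if any(a < b for a, b in zip(self.importance, self.importance[1:])):
            raise CohortError("importance must be sorted non-increasing")

    def top(self, k: int) -> tuple[list[str], list[float]]:
        return self.genes[:k], self.importance[:k]


class _ArrayTree:
    """A decision tree flattened to plain arrays (the serialized form)."""

    __slots__ = ("children_left", "children_right", "feature", "threshold", "leaf_class")

    def __init__(self, children_left, children_right, feature, threshold, leaf_class):
        self.children_left = np.asarray(children_left, dtype=np.int64)
        self.children_right = np.asarray(children_right, dtype=np.int64)
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=float)
        self.leaf_class = np.asarray(leaf_class, dtype=np.int64)

    @classmethod
    def from_sklearn(cls, tree) -> "_ArrayTree":
        t = tree.tree_
        leaf_class = np.argmax(t.value[:, 0, :], axis=1)
        return cls(t.children_left, t.children_right, t.feature, t.threshold, leaf_class)

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.children_left[node] != -1
        while active.any():
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.children_left[nd], self.children_right[nd])
            active = self.children_left[node] != -1
        return self.leaf_class[node]

    def to_doc(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": [float(x) for x in self.threshold],
            "leaf_class": self.leaf_class.tolist(),
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "_ArrayTree":
        return cls(
            doc["children_left"],
            doc["children_right"],
            doc["feature"],
            doc["threshold"],
            doc["leaf_class"],
        )


@dataclass
class ForestModel:
    """A fitted ensemble restricted to an ordered gene set.

    ``class_order`` is (negative label, positive label); the probability
    score is the fraction of trees voting the positive class. In-session
    models keep the sklearn estimator (and training data, for OOB
    importance); deserialized models carry only the flattened trees, which
    reproduce the original votes exactly.
    """

    config: ForestConfig
    gene_set: list[str]
    class_order: tuple[str, str]
    _sk: RandomForestClassifier | None = None
    _trees: list[_ArrayTree] = field(default_factory=list)
    _X_train: np.ndarray | None = None
    _y_train: np.ndarray | None = None

    # -- prediction ---------------------------------------------------------

    def votes(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting the positive class, one value per row."""
        if X.shape[1] != len(self.gene_set):
            raise CohortError(
                f"model expects {len(self.gene_set)} genes, got {X.shape[1]}"
            )
        if not self._trees:
            raise CohortError("model is not fitted")
        counts = np.zeros(X.shape[0], dtype=float)
        for tree in self._trees:
            counts += tree.predict(X) == 1
        return counts / len(self._trees)

    def training_accuracy(self) -> float:
        if self._X_train is None:
            raise CohortError("training data unavailable on a deserialized model")
        scores = self.votes(self._X_train)
        return float(np.mean((scores > self.config.threshold) == (self._y_train == 1)))

    # -- out-of-bag machinery ----------------------------------------------

    def _oob_masks(self) -> list[np.ndarray]:
        if self._sk is None or self._X_train is None:
            raise CohortError("OOB statistics need an in-session fitted model")
        n = self._X_train.shape[0]
        masks = []
        for sampled in self._sk.estimators_samples_:
            mask = np.ones(n, dtype=bool)
            mask[sampled] = False
            masks.append(mask)
        return masks

    def oob_accuracy(self) -> float:
        """Accuracy of the per-sample majority vote over trees for which the
        sample is out-of-bag. Under label permutation this calibrates to
        chance (~0.5)."""
        if not self.config.bootstrap:
            raise CohortError("OOB accuracy undefined without bootstrap")
        X, y = self._X_train, self._y_train
        votes = np.zeros(X.shape[0])
        counts = np.zeros(X.shape[0])
        for tree, mask in zip(self._trees, self._oob_masks(), strict=True):
            if not mask.any():
                continue
            votes[mask] += tree.predict(X[mask]) == 1
            counts[mask] += 1
        seen = counts > 0
        pred = votes[seen] / counts[seen] > self.config.threshold
        return float(np.mean(pred == (y[seen] == 1)))

    # -- serialization ------------------------------------------------------

    def save(self, path: str) -> None:
        doc = {
            "format": "ibcsig-forest/1",
            "config": {
                "n_trees": self.config.n_trees,
                "features_per_split": self.config.features_per_split,
                "min_leaf": self.config.min_leaf,
                "bootstrap": self.config.bootstrap,
                "importance_method": self.config.importance_method,
                "threshold": self.config.threshold,
                "seed": self.config.seed,
            },
            "gene_set": self.gene_set,
            "class_order": list(self.class_order),
            "trees": [t.to_doc() for t in self._trees],
        }
        write_json_doc(doc, path)

    @classmethod
    def load(cls, path: str) -> "ForestModel":
        doc = read_json_doc(path)
        if doc.get("format") != "ibcsig-forest/1":
            raise CohortError(f"{path}: not an ibcsig forest model file")
        cfg = ForestConfig(**doc["config"])
        return cls(
            config=cfg,
            gene_set=list(doc["gene_set"]),
            class_order=tuple(doc["class_order"]),
            _trees=[_ArrayTree.from_doc(d) for d in doc["trees"]],
        )


# ---------------------------------------------------------------------------
# training / importance / prediction entry points


def _binary_labels(cohort: ExpressionCohort, sample_ids, positive_label: str):
    y = np.empty(len(sample_ids), dtype=np.int64)
    for i, sid in enumerate(sample_ids):
        label = cohort.class_of(sid)
        if label is None:
            raise CohortError(f"training sample {sid!r} has no class label")
        y[i] = 1 if label == positive_label else 0
    return y


def train_forest(
    cohort: ExpressionCohort,
    sample_ids,
    gene_set,
    cfg: ForestConfig,
    positive_label: str = POSITIVE_CLASS,
    labels: np.ndarray | None = None,
) -> ForestModel:
    """Fit the bagged ensemble on the given samples and gene set.

    ``labels`` overrides the cohort annotations (used for permutation
    checks); otherwise a sample is positive iff its class equals
    ``positive_label``. Pure function of (data, cfg).
    """
    gene_set = list(gene_set)
    cfg.validate(n_features=len(gene_set))
    X = cohort.submatrix(gene_set, sample_ids)
    y = (
        np.asarray(labels, dtype=np.int64)
        if labels is not None
        else _binary_labels(cohort, sample_ids, positive_label)
    )
    if len(np.unique(y)) < 2:
        raise CohortError("training set contains a single class")

    sk = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg._sklearn_max_features(),
        min_samples_leaf=cfg.min_leaf,
        bootstrap=cfg.bootstrap,
        criterion="gini",
        random_state=int(cfg.seed) % (2**32),
        n_jobs=1,
    )
    sk.fit(X, y)
    # sklearn orders classes_ ascending, so index 1 is the positive class
    assert list(sk.classes_) == [0, 1]
    trees = [_ArrayTree.from_sklearn(t) for t in sk.estimators_]
    return ForestModel(
        config=cfg,
        gene_set=gene_set,
        class_order=(f"non{positive_label}", positive_label),
        _sk=sk,
        _trees=trees,
        _X_train=X,
        _y_train=y,
    )


def importance(model: ForestModel, n_repeats: int = 3) -> ImportanceRanking:
    """Rank the model's genes by predictor importance.

    Two measures are available via ``config.importance_method``:

    * ``"impurity"`` (default) — mean decrease in Gini impurity over all
      splits, as accumulated by the tree learner;
    * ``"oob_permutation"`` — for each tree, each gene actually used by that
      tree has its values permuted among the tree's OOB samples (``n_repeats``
      independent permutations, averaged) and the mean decrease in OOB
      accuracy is recorded; trees not using a gene contribute zero, negative
      averages are clipped to zero.

    Deterministic for a fixed model seed; ranking ties break by gene order.
    """
    if not model._trees:
        raise CohortError("importance of an unfitted model")
    n_features = len(model.gene_set)
    if model.config.importance_method == "impurity":
        if model._sk is None:
            raise CohortError("impurity importance needs an in-session model")
        scores = np.asarray(model._sk.feature_importances_, dtype=float)
    else:
        if model._sk is None or model._X_train is None:
            raise CohortError("OOB permutation importance needs an in-session model")
        X, y = model._X_train, model._y_train
        rng = np.random.default_rng(np.random.SeedSequence([int(model.config.seed), 20]))
        totals = np.zeros(n_features)
        for tree, sk_tree, mask in zip(
            model._trees, model._sk.estimators_, model._oob_masks(), strict=True
        ):
            if not mask.any():
                continue
            Xo, yo = X[mask], y[mask]
            base_acc = np.mean(tree.predict(Xo) == yo)
            used = np.unique(sk_tree.tree_.feature)
            used = used[used >= 0]
            for f in used:
                dec = 0.0
                for _ in range(n_repeats):
                    Xp = Xo.copy()
                    Xp[:, f] = Xp[rng.permutation(Xo.shape[0]), f]
                    dec += base_acc - np.mean(tree.predict(Xp) == yo)
                totals[f] += dec / n_repeats
        scores = np.clip(totals / len(model._trees), 0.0, None)

    order = np.lexsort((np.arange(n_features), -scores))
    return ImportanceRanking(
        genes=[model.gene_set[i] for i in order],
        importance=[float(scores[i]) for i in order],
    )


def predict_proba(
    model: ForestModel, cohort: ExpressionCohort, sample_ids=None
) -> ClassificationResult:
    """Score samples with the ensemble vote fraction.

    Scores lie on the grid k/n_trees; a sample is labelled positive iff its
    score is strictly above the threshold.
    """
    if sample_ids is None:
        sample_ids = list(cohort.sample_ids)
    X = cohort.submatrix(model.gene_set, sample_ids)
    scores = model.votes(X)
    return ClassificationResult(
        sample_ids=list(sample_ids),
        prob_score=[float(s) for s in scores],
        threshold=model.config.threshold,
    )
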