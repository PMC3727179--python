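"""Subnetwork-activity feature matrices and cross-validated classification.

Each selected subnetwork contributes one feature per sample: its activity,
the mean z-score of its measured members.  Plain gene lists (e.g. a top-k
differential-expression signature) contribute one per-gene z-score feature
each.  Accuracy is estimated by k-fold cross-validation (default 10 folds,
unstratified) with two dissimilar classifiers — an entropy-split decision
tree and a radial-basis-function network (k-means centers, Gaussian
activations, logistic output) — and by train-on-one-half / test-on-the-other
cross-testing where the z-scoring parameters are learned on the training set
only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .consensus import ConsensusResult
from .data_io import CASE, ExpressionDataset, Subnetwork
from .errors import ConfigError, ContractError, FeatureError, FoldError
from .search import zscore_stats

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("tree", "rbf")


@dataclass(frozen=True)
class FeatureMatrix:
    """features x samples real matrix with per-sample class labels."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # (n_features, n_samples)
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", dict(self.labels))
        if len(self.feature_ids) < 1:
            raise FeatureError("need at least one feature")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ContractError("feature matrix shape mismatch")
        if values.size and not np.all(np.isfinite(values)):
            raise ContractError("feature matrix contains non-finite values")
        classes = {self.labels[s] for s in self.sample_ids}
        if len(classes) != 2:
            raise ContractError("both classes must be present")

    @property
    def X(self) -> np.ndarray:
        """samples x features design matrix (scikit-learn orientation)."""
        return self.values.T

    @property
    def y(self) -> np.ndarray:
        return np.array(
            [1 if self.labels[s] == CASE else 0 for s in self.sample_ids], dtype=int
        )


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------


def _member_sets_from(subnets) -> list[tuple[str, frozenset[str]]]:
    """Normalize the accepted subnetwork arguments to (feature_id, members)."""
    if isinstance(subnets, ConsensusResult):
        sets = subnets.selected_member_sets()
        return [(f"sub{i + 1:03d}", s) for i, s in enumerate(sets)]
    if isinstance(subnets, Sequence) and subnets and isinstance(subnets[0], str):
        # plain gene list -> one per-gene feature each
        return [(g, frozenset([g])) for g in subnets]
    out = []
    for i, item in enumerate(subnets):
        if isinstance(item, Subnetwork):
            out.append((f"sub{i + 1:03d}", item.members))
        else:
            out.append((f"sub{i + 1:03d}", frozenset(item)))
    return out


def _zscore_with_stats(
    ds: ExpressionDataset, mu: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    safe = np.where(sd == 0, 1.0, sd)
    z = (ds.values - mu[:, None]) / safe[:, None]
    z[sd == 0, :] = 0.0
    return z


def build_features(
    ds: ExpressionDataset,
    subnets,
    *,
    _stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureMatrix:
    """Build the subnetwork-activity (or per-gene z-score) feature matrix.

    Members missing from the dataset are dropped with a warning; a subnetwork
    with no measured member raises.  ``_stats`` optionally injects externally
    learned per-gene (mean, sd) so cross-testing never touches test-set
    statistics.
    """
    named = _member_sets_from(subnets)
    if not named:
        raise FeatureError("no subnetworks or genes given")
    index = ds.gene_index()
    if _stats is None:
        mu, sd, _ = zscore_stats(ds.values)
    else:
        mu, sd = _stats
    Z = _zscore_with_stats(ds, mu, sd)
    rows = []
    ids = []
    for fid, members in named:
        present = sorted(g for g in members if g in index)
        missing = sorted(set(members) - set(present))
        if not present:
            raise FeatureError(f"feature {fid!r}: no member measured in dataset")
        if missing:
            warnings.warn(
                f"feature {fid!r}: dropping unmeasured members {missing[:5]}",
                stacklevel=2,
            )
        rows.append(Z[[index[g] for g in present], :].mean(axis=0))
        ids.append(fid)
    return FeatureMatrix(
        feature_ids=tuple(ids),
        sample_ids=ds.sample_ids,
        values=np.vstack(rows),
        labels=ds.labels,
    )


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------


class RBFNetworkClassifier(BaseEstimator, ClassifierMixin):
    """Radial-basis-function network.

    Centers are placed by k-means on the training data
    (``n_centers = min(10, floor(sqrt(n_train)))`` by default), hidden units
    are Gaussian activations with a shared width set to the mean pairwise
    center distance, and the output layer is a linear-logistic model.
    """

    def __init__(self, n_centers: int | None = None, random_state: int = 0):
        self.n_centers = n_centers
        self.random_state = random_state

    def _design(self, X: np.ndarray) -> np.ndarray:
        d = pairwise_distances(X, self.centers_)
        return np.exp(-(d**2) / (2.0 * self.width_**2))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = len(X)
        k = self.n_centers or max(2, min(10, int(np.sqrt(n))))
        k = min(k, n)
        km = KMeans(n_clusters=k, random_state=self.random_state, n_init=10)
        km.fit(X)
        self.centers_ = km.cluster_centers_
        if k > 1:
            d = pairwise_distances(self.centers_)
            off = d[np.triu_indices(k, 1)]
            self.width_ = float(off.mean()) or 1.0
        else:
            self.width_ = 1.0
        self.out_ = LogisticRegression(max_iter=1000, random_state=self.random_state)
        self.out_.fit(self._design(X), y)
        self.classes_ = self.out_.classes_
        return self

    def predict(self, X):
        return self.out_.predict(self._design(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        return self.out_.predict_proba(self._design(np.asarray(X, dtype=float)))


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the two evaluation classifiers by name."""
    if name == "tree":
        return DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, random_state=seed
        )
    if name == "rbf":
        return RBFNetworkClassifier(random_state=seed)
    raise ConfigError(f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVResult:
    classifier_name: str
    fold_accuracies: tuple[float, ...]  # percent, one per fold
    mean_accuracy_pct: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fold_accuracies", tuple(self.fold_accuracies))
        assert abs(self.mean_accuracy_pct - float(np.mean(self.fold_accuracies))) < 1e-9


def kfold_cv(
    fm: FeatureMatrix,
    classifier: str = "tree",
    k: int = 10,
    seed: int = 0,
    stratified: bool = False,
    skip_bad_folds: bool = False,
) -> CVResult:
    """k-fold cross-validated accuracy (percent), folds of near-equal size.

    Folds are shuffled but unstratified by default; a training fold missing a
    class raises unless ``skip_bad_folds``.
    """
    X, y = fm.X, fm.y
    if len(y) < k:
        raise ContractError(f"need at least {k} samples for {k}-fold CV")
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    fold_acc: list[float] = []
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            if skip_bad_folds:
                logger.warning("kfold_cv: skipping fold with a single training class")
                continue
            raise FoldError("a training fold is missing one class")
        clf = make_classifier(classifier, seed=seed)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        fold_acc.append(100.0 * float(np.mean(pred == y[test_idx])))
    if not fold_acc:
        raise FoldError("no valid folds")
    return CVResult(
        classifier_name=classifier,
        fold_accuracies=tuple(fold_acc),
        mean_accuracy_pct=float(np.mean(fold_acc)),
        seed=seed,
    )


def cross_test(
    train_ds: ExpressionDataset,
    test_ds: ExpressionDataset,
    subnets,
    classifier: str = "tree",
    seed: int = 0,
) -> float:
    """Train on all of ``train_ds`` and report accuracy (percent) on
    ``test_ds``.  Per-gene standardization parameters are learned on the
    training set only and applied unchanged to the test set."""
    named = _member_sets_from(subnets)
    needed = sorted({g for _, m in named for g in m})
    train_index = train_ds.gene_index()
    test_index = test_ds.gene_index()
    shared = [g for g in needed if g in train_index and g in test_index]
    if not shared:
        raise ContractError("train and test datasets share no subnetwork genes")
    if len({train_ds.labels[s] for s in train_ds.sample_ids}) < 2:
        raise ContractError("training set must contain both classes")
    if len({test_ds.labels[s] for s in test_ds.sample_ids}) < 2:
        raise ContractError("test set must contain both classes")

    # restrict every member set to genes measured in BOTH datasets so the
    # train and test feature definitions coincide exactly
    shared_set = set(shared)
    restricted = []
    for fid, members in named:
        kept = frozenset(members & shared_set)
        if not kept:
            raise FeatureError(f"feature {fid!r}: no member measured in both datasets")
        restricted.append(kept)

    mu, sd, _ = zscore_stats(train_ds.values)
    fm_train = build_features(train_ds, restricted, _stats=(mu, sd))
    # map training stats onto the test dataset's gene order
    mu_test = np.zeros(test_ds.n_genes)
    sd_test = np.ones(test_ds.n_genes)
    for g, i in test_index.items():
        j = train_index.get(g)
        if j is not None:
            mu_test[i] = mu[j]
            sd_test[i] = sd[j] if sd[j] != 0 else 1.0
    fm_test = build_features(test_ds, restricted, _stats=(mu_test, sd_test))

    clf = make_classifier(classifier, seed=seed)
    clf.fit(fm_train.X, fm_train.y)
    pred = clf.predict(fm_test.X)
    return 100.0 * float(np.mean(pred == fm_test.y))
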