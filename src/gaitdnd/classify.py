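"""Decision-tree ensembles under one-vs-all ECOC with stratified 10-fold CV.

The base learner is a CART binary tree grown greedily by best
Gini-impurity decrease (thresholds at midpoints of sorted feature values),
capped by a maximum number of internal splits and a minimum leaf size.
Four ensemble strategies wrap it, each in its binary realization:

``bagging``
    trees on bootstrap resamples, unweighted score averaging;
``adaboost``
    AdaBoost.M1 — exponential sample reweighting with learner weight
    α_t = ½ ln((1−ε_t)/ε_t), optionally shrunk by a learning rate;
``rusboost``
    AdaBoost.M1 where each iteration first randomly undersamples the
    majority class down to the minority count (weights renormalized) —
    suited to the ≈1:3 imbalance of one-vs-rest subproblems;
``subspace``
    trees on random feature subsets of size round(fraction × p), score
    averaging.

The four-class problem (CON/ALS/PD/HD) is handled by one-vs-all
error-correcting output codes: one binary learner per class, prediction by
argmax of the positive-class scores, ties broken toward the lowest class
index in the fixed label order.

Cross-validation uses equi-stratified folds (equal sizes ±1, per-fold
class proportions within one sample of the overall proportions).  All
randomness — bootstraps, undersampling, subspaces, folds, tuning — derives
from one master seed through a seed-sequence tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .io import CONDITIONS, FEATURE_COLUMNS
from .metrics import MetricReport, macro_report

logger = logging.getLogger(__name__)

METHODS = ("tree", "bagging", "adaboost", "rusboost", "subspace")

#: Cap on ½ln((1−ε)/ε) when a round classifies perfectly.
_ALPHA_CAP = 12.0

#: Hyperparameter search ranges (inclusive).
PARAM_RANGES = {
    "min_leaf_size": (1, 50),
    "max_splits": (1, 100),
    "n_cycles": (10, 500),
    "learning_rate": (0.1, 1.0),
    "subspace_fraction": (0.25, 1.0),
}

#: Published tuned parameters per (method, signal type).  The "learning
#: rate" reported for the random subspace model is interpreted as its
#: feature-sampling fraction (the method has no learning rate).
PAPER_PARAMS = {
    ("tree", "vgrf"): {"min_leaf_size": 1, "max_splits": 50},
    ("tree", "stride"): {"min_leaf_size": 15, "max_splits": 50},
    ("tree", "stance"): {"min_leaf_size": 6, "max_splits": 20},
    ("tree", "swing"): {"min_leaf_size": 11, "max_splits": 11},
    ("bagging", "vgrf"): {"n_cycles": 485},
    ("bagging", "stride"): {"n_cycles": 96},
    ("bagging", "stance"): {"n_cycles": 18},
    ("bagging", "swing"): {"n_cycles": 33},
    ("adaboost", "vgrf"): {"n_cycles": 485},
    ("adaboost", "stride"): {"n_cycles": 87},
    ("adaboost", "stance"): {"n_cycles": 289},
    ("adaboost", "swing"): {"n_cycles": 90},
    ("rusboost", "vgrf"): {"learning_rate": 0.434, "n_cycles": 337},
    ("rusboost", "stride"): {"learning_rate": 0.802, "n_cycles": 449},
    ("rusboost", "stance"): {"learning_rate": 0.397, "n_cycles": 48},
    ("rusboost", "swing"): {"learning_rate": 0.953, "n_cycles": 484},
    ("subspace", "vgrf"): {"subspace_fraction": 0.5, "n_cycles": 150},
    ("subspace", "stride"): {"subspace_fraction": 0.9, "n_cycles": 410},
    ("subspace", "stance"): {"subspace_fraction": 0.7, "n_cycles": 220},
    ("subspace", "swing"): {"subspace_fraction": 0.7, "n_cycles": 380},
}


@dataclass
class ModelSpec:
    """Method choice plus hyperparameters and the master seed."""

    method: str = "adaboost"
    min_leaf_size: int = 1
    max_splits: int = 20
    n_cycles: int = 100
    learning_rate: float = 1.0
    subspace_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")
        if self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")
        if not 0.0 < self.subspace_fraction <= 1.0:
            raise ValueError("subspace_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "min_leaf_size": self.min_leaf_size,
            "max_splits": self.max_splits,
            "n_cycles": self.n_cycles,
            "learning_rate": self.learning_rate,
            "subspace_fraction": self.subspace_fraction,
            "seed": self.seed,
        }


def paper_params(method: str, signal_type: str) -> dict:
    """The published tuned hyperparameters for one method/signal pairing."""
    key = (method, signal_type)
    if key not in PAPER_PARAMS:
        raise ValueError(f"no published parameters for {key}")
    return dict(PAPER_PARAMS[key])


# ---------------------------------------------------------------------------
# base learner
# ---------------------------------------------------------------------------

def train_cart(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf_size: int = 1,
    max_splits: int = 20,
    sample_weight: np.ndarray | None = None,
    random_state: int = 0,
) -> DecisionTreeClassifier:
    """Grow a Gini CART greedily, best split first, capped at ``max_splits``
    internal nodes (= max_splits + 1 leaves) and ``min_leaf_size`` samples
    per leaf.  A single-class y yields a trivial one-leaf tree (warned).

    ``random_state`` pins the feature-tie permutation so identical inputs
    give identical trees.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        logger.warning("single-class training data; trivial single-leaf tree")
    tree = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_leaf_size,
        max_leaf_nodes=max_splits + 1,
        random_state=random_state,
    )
    tree.fit(np.asarray(X, dtype=float), y, sample_weight=sample_weight)
    return tree


def _positive_proba(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """P(class 1) from a tree that may have seen only one class."""
    proba = tree.predict_proba(X)
    classes = list(tree.classes_)
    if 1 in classes:
        return proba[:, classes.index(1)]
    return np.zeros(len(X))


# ---------------------------------------------------------------------------
# binary ensembles
# ---------------------------------------------------------------------------

class BinaryEnsemble:
    """A fitted binary committee exposing a positive-class score in [0, 1]."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.trees: list[DecisionTreeClassifier] = []

    def _base(self, X, y, rng, sample_weight=None) -> DecisionTreeClassifier:
        return train_cart(
            X, y,
            min_leaf_size=self.spec.min_leaf_size,
            max_splits=self.spec.max_splits,
            sample_weight=sample_weight,
            random_state=int(rng.integers(2**31)),
        )

    def fit(self, X, y, rng: np.random.Generator):
        raise NotImplementedError

    def score(self, X) -> np.ndarray:
        raise NotImplementedError


class BaggingBinary(BinaryEnsemble):
    """Bootstrap-aggregated trees; unweighted probability averaging."""

    def __init__(self, spec: ModelSpec, bootstrap: bool = True):
        super().__init__(spec)
        self.bootstrap = bootstrap  # test hook: False degenerates to CART

    def fit(self, X, y, rng):
        n = len(y)
        for _ in range(self.spec.n_cycles):
            idx = rng.integers(0, n, size=n) if self.bootstrap else np.arange(n)
            self.trees.append(self._base(X[idx], y[idx], rng))
        return self

    def score(self, X):
        return np.mean([_positive_proba(t, X) for t in self.trees], axis=0)


class SubspaceBinary(BinaryEnsemble):
    """Each tree sees a random feature subset of size round(fraction × p)."""

    def fit(self, X, y, rng):
        p = X.shape[1]
        size = max(1, round(self.spec.subspace_fraction * p))
        self.subsets = []
        for _ in range(self.spec.n_cycles):
            cols = np.sort(rng.choice(p, size=size, replace=False))
            self.subsets.append(cols)
            self.trees.append(self._base(X[:, cols], y, rng))
        return self

    def score(self, X):
        return np.mean(
            [_positive_proba(t, X[:, cols])
             for t, cols in zip(self.trees, self.subsets)],
            axis=0,
        )


class AdaBoostBinary(BinaryEnsemble):
    """Binary AdaBoost.M1 with learning-rate shrinkage on α.

    A perfect round (ε = 0) gets a capped finite α; a round with ε ≥ ½ is
    discarded and the sample weights reset to uniform (logged).
    """

    undersample = False

    def fit(self, X, y, rng):
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.alphas: list[float] = []
        for t in range(self.spec.n_cycles):
            if self.undersample:
                idx = self._undersample_indices(y, rng)
                wi = w[idx]
                tree = self._base(X[idx], y[idx], rng,
                                  sample_weight=wi / wi.sum())
            else:
                tree = self._base(X, y, rng, sample_weight=w)
            pred = tree.predict(X)
            miss = pred != y
            eps = float(np.sum(w[miss]))
            if eps >= 0.5:
                logger.info(
                    "boosting round %d: error %.3f >= 0.5; weights reset", t, eps
                )
                w = np.full(n, 1.0 / n)
                continue
            alpha = min(
                0.5 * math.log((1.0 - eps) / max(eps, 1e-12)), _ALPHA_CAP
            ) * self.spec.learning_rate
            self.trees.append(tree)
            self.alphas.append(alpha)
            w = w * np.exp(alpha * np.where(miss, 1.0, -1.0))
            w /= w.sum()
        if not self.trees:  # every round rejected: fall back to one weak tree
            self.trees.append(self._base(X, y, rng))
            self.alphas.append(1.0)
        return self

    def _undersample_indices(self, y, rng):
        raise NotImplementedError

    def score(self, X):
        alphas = np.asarray(self.alphas)
        votes = np.stack([t.predict(X).astype(float) for t in self.trees])
        return (alphas[:, None] * votes).sum(axis=0) / alphas.sum()

    def staged_training_error(self, X, y) -> list[float]:
        """Misclassification after each round (diagnostic for the boosting
        error-decay property)."""
        alphas = np.asarray(self.alphas)
        votes = np.stack([t.predict(X).astype(float) for t in self.trees])
        errs = []
        for m in range(1, len(self.trees) + 1):
            score = (alphas[:m, None] * votes[:m]).sum(axis=0) / alphas[:m].sum()
            errs.append(float(np.mean((score >= 0.5).astype(int) != y)))
        return errs


class RUSBoostBinary(AdaBoostBinary):
    """AdaBoost.M1 over per-round random undersamples of the majority class."""

    undersample = True

    def _undersample_indices(self, y, rng):
        idx0 = np.flatnonzero(y == 0)
        idx1 = np.flatnonzero(y == 1)
        minority, majority = (idx1, idx0) if idx1.size <= idx0.size else (idx0, idx1)
        take = rng.choice(majority, size=minority.size, replace=False)
        return np.sort(np.concatenate([minority, take]))


class TreeBinary(BinaryEnsemble):
    """A single CART, exposed through the ensemble interface."""

    def fit(self, X, y, rng):
        self.trees.append(self._base(X, y, rng))
        return self

    def score(self, X):
        return _positive_proba(self.trees[0], X)


_BINARY_LEARNERS = {
    "tree": TreeBinary,
    "bagging": BaggingBinary,
    "adaboost": AdaBoostBinary,
    "rusboost": RUSBoostBinary,
    "subspace": SubspaceBinary,
}


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> BinaryEnsemble:
    """Fit one binary learner of the requested method on 0/1 labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    learner = _BINARY_LEARNERS[spec.method](spec, **kwargs)
    return learner.fit(X, y, rng)


# ---------------------------------------------------------------------------
# one-vs-all ECOC
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """One-vs-all ECOC committee: one binary learner per class."""

    method: str
    class_order: tuple
    learners: dict
    spec: ModelSpec

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack(
            [self.learners[label].score(X) for label in self.class_order]
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.scores(X)
        # argmax takes the first maximum -> lowest class index on ties
        idx = np.argmax(scores, axis=1)
        return np.asarray(self.class_order, dtype=object)[idx]


def _class_order_for(y: np.ndarray) -> tuple:
    present = set(np.unique(y).tolist())
    if present <= set(CONDITIONS):
        return tuple(c for c in CONDITIONS if c in present)
    return tuple(sorted(present))


def ecoc_one_vs_all(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    class_order: tuple | None = None,
) -> TrainedModel:
    """Train one class-vs-rest binary learner per class.

    Prediction is argmax over the per-class positive scores; the fixed
    label order (CON, ALS, PD, HD) breaks ties toward the lowest index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    order = tuple(class_order) if class_order else _class_order_for(y)
    counts = {label: int(np.sum(y == label)) for label in order}
    absent = [label for label, n in counts.items() if n == 0]
    if absent:
        raise ValueError(f"classes absent from training data: {absent}")
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 samples per class, got {counts}")
    ss = np.random.SeedSequence(spec.seed)
    learners = {}
    for label, child in zip(order, ss.spawn(len(order))):
        rng = np.random.default_rng(child)
        learners[label] = train_ensemble(X, (y == label).astype(int), spec, rng)
    return TrainedModel(
        method=spec.method, class_order=order, learners=learners, spec=spec
    )


# ---------------------------------------------------------------------------
# folds and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    folds: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds != fold)


def make_folds(y, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Equi-stratified fold assignment: per-class seeded shuffle, then
    round-robin with a running offset so fold sizes stay equal (±1)."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2 (no held-out data otherwise)")
    order = _class_order_for(y)
    rng = np.random.default_rng(seed)
    folds = np.full(y.size, -1, dtype=int)
    start = 0
    for label in order:
        idx = np.flatnonzero(y == label)
        if idx.size < k:
            raise ValueError(
                f"class {label} has {idx.size} samples, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        folds[idx] = (start + np.arange(idx.size)) % k
        start = (start + idx.size) % k
    return FoldAssignment(folds=folds, k=k)


@dataclass
class CVResult:
    """Per-fold metric reports and their mean, with the run configuration."""

    spec: ModelSpec
    k: int
    seed: int
    class_order: tuple
    per_fold: list
    mean: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_fold and not self.mean:
            from .metrics import METRIC_NAMES

            self.mean = {
                name: float(np.mean([r.macro[name] for r in self.per_fold]))
                for name in METRIC_NAMES
            }

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "k": self.k,
            "seed": self.seed,
            "class_order": list(self.class_order),
            "mean": dict(self.mean),
            "per_fold": [r.to_dict() for r in self.per_fold],
        }


def _feature_matrix(features) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) from a feature table (DataFrame) or a raw (X, y) pair."""
    if isinstance(features, tuple):
        X, y = features
        return np.asarray(X, dtype=float), np.asarray(y)
    types = features["signal_type"].unique()
    if len(types) > 1:
        raise ValueError(f"feature table mixes signal types {sorted(types)}")
    X = features[list(FEATURE_COLUMNS[4:])].to_numpy(dtype=float)
    y = features["condition"].to_numpy()
    return X, y


def cross_validate(
    features,
    spec: ModelSpec,
    k: int = 10,
    seed: int | None = None,
    class_order: tuple | None = None,
) -> CVResult:
    """Equi-stratified k-fold cross-validation of the one-vs-all model.

    Reports per-fold per-class and macro metrics plus their mean over
    folds.  Deterministic given (data, spec, seed): the fold split and
    every per-fold model seed derive from the one master seed.
    """
    X, y = _feature_matrix(features)
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    fold_seed, *model_seeds = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(k + 1)
    ]
    assignment = make_folds(y, k=k, seed=fold_seed)
    order = tuple(class_order) if class_order else _class_order_for(y)
    reports: list[MetricReport] = []
    for fold in range(k):
        tr = assignment.train_indices(fold)
        te = assignment.test_indices(fold)
        model = ecoc_one_vs_all(
            replace(spec, seed=model_seeds[fold]), X[tr], y[tr], order
        )
        reports.append(macro_report(y[te], model.predict(X[te]), order))
    return CVResult(
        spec=spec, k=k, seed=master, class_order=order, per_fold=reports
    )


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------

def _sample_params(method: str, rng: np.random.Generator) -> dict:
    p = {
        "min_leaf_size": int(rng.integers(*PARAM_RANGES["min_leaf_size"],
                                          endpoint=True)),
        "max_splits": int(rng.integers(*PARAM_RANGES["max_splits"],
                                       endpoint=True)),
    }
    if method != "tree":
        p["n_cycles"] = int(rng.integers(*PARAM_RANGES["n_cycles"],
                                         endpoint=True))
    if method in ("adaboost", "rusboost"):
        p["learning_rate"] = float(rng.uniform(*PARAM_RANGES["learning_rate"]))
    if method == "subspace":
        p["subspace_fraction"] = float(
            rng.uniform(*PARAM_RANGES["subspace_fraction"])
        )
    return p


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    budget: int = 30,
    seed: int = 0,
    subset_fraction: float = 0.1,
    cv_folds: int = 5,
    cycle_cap: int | None = None,
) -> dict:
    """Budgeted seeded random search minimizing CV misclassification on a
    stratified subset of the data.

    A ``subset_fraction`` stratified sample (at least ``cv_folds`` per
    class) stands in for the full set during the search.  ``cycle_cap``
    optionally truncates the ensemble-size range to bound runtime.
    """
    if budget < 10:
        raise ValueError("tuning budget must be >= 10 evaluations")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ss = np.random.SeedSequence(seed)
    rng_subset, rng_search, rng_eval = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    # stratified tuning subset
    keep = []
    for label in _class_order_for(y):
        idx = np.flatnonzero(y == label)
        m = min(idx.size, max(int(math.ceil(subset_fraction * idx.size)),
                              cv_folds))
        keep.append(rng_subset.choice(idx, size=m, replace=False))
    keep = np.sort(np.concatenate(keep))
    Xs, ys = X[keep], y[keep]
    eval_seed = int(rng_eval.integers(2**31))
    best_err, best_params = np.inf, None
    for b in range(budget):
        params = _sample_params(method, rng_search)
        if cycle_cap is not None and "n_cycles" in params:
            params["n_cycles"] = min(params["n_cycles"], cycle_cap)
        spec = ModelSpec(method=method, seed=eval_seed, **params)
        result = cross_validate((Xs, ys), spec, k=cv_folds, seed=eval_seed)
        err = 100.0 - result.mean["accuracy"]
        if err < best_err:
            best_err, best_params = err, params
    logger.info("tuned %s: CV misclassification %.2f%% with %s",
                method, best_err, best_params)
    return best_params
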