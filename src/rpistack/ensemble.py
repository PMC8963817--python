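"""Stacked-generalization ensemble with adaptive weight initialization.

Level 0 holds four base classifiers — gradient boosting (depth-6 trees),
an RBF-kernel SVM with calibrated probabilities, a 25-tree Gini random
forest, and extremely randomized trees at library defaults.  The training
set is split into F=4 stratified internal fractions; each classifier is
fitted F times on the complement of one fraction, producing

  * out-of-fold probability encodings tr^c of the training samples (every
    sample scored only by sub-encoders that never saw it),
  * test encodings te^c = (1/F) sum_i te_i^c averaged over the F fold
    models, and
  * held-out AUCs w_i^c per fraction, averaged into w^c.

Adaptive weights lambda^c = 1 - (1 - (w^c)^2)^N (N = number of base
classifiers) shrink weaker classifiers' encodings before the level-1
logistic decoder is fitted on the scaled columns.  Plain stacking
(lambda = 1), uniform averaging and hard majority voting (strict majority
wins, otherwise "reject" -> negative) are available as baselines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import __version__

logger = logging.getLogger(__name__)

ROLES = ("gradient_boosting", "svm_rbf", "random_forest", "extra_trees")
STRATEGIES = ("stacking_adaptive", "stacking", "averaging", "voting")

DEFAULT_INTERNAL_FOLDS = 4


def make_base_learners(seed: int = 0, booster: str = "gbtree") -> dict:
    """The four default level-0 classifiers, keyed by role.

    The boosting learner uses depth-6 trees; the SVM sits behind a
    standardizing scaler and emits sigmoid-calibrated probabilities; the
    random forest uses 25 Gini trees with a fixed random_state of 1.
    """
    return {
        "gradient_boosting": XGBClassifier(
            max_depth=6, booster=booster, random_state=seed, n_jobs=1,
            eval_metric="logloss", verbosity=0),
        "svm_rbf": make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                   method="sigmoid", cv=3)),
        "random_forest": RandomForestClassifier(
            n_estimators=25, criterion="gini", random_state=1, n_jobs=1),
        "extra_trees": ExtraTreesClassifier(random_state=seed, n_jobs=1),
    }


@dataclass
class StackingState:
    """All level-0 artefacts produced by :func:`encode_level0`."""

    roles: tuple
    n_folds: int
    train_encodings: np.ndarray          # (n_train, C) out-of-fold tr^c
    test_encodings: np.ndarray           # (n_test, C) averaged te^c
    fold_aucs: np.ndarray                # (C, F) held-out w_i^c
    mean_aucs: np.ndarray                # (C,) w^c
    fold_models: list = field(default_factory=list, repr=False)  # [C][F] fitted clones
    fold_indices: list = field(default_factory=list, repr=False)


def encode_level0(train_features, train_labels, test_features=None,
                  learners: dict = None, n_folds: int = DEFAULT_INTERNAL_FOLDS,
                  seed: int = 0) -> StackingState:
    """Out-of-fold level-0 encoding of the training (and optional test) set."""
    X = np.asarray(train_features, dtype=np.float64)
    y = np.asarray(train_labels)
    if learners is None:
        learners = make_base_learners(seed=seed)
    n = X.shape[0]
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} training samples for {n_folds} internal folds, got {n}")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < n_folds:
        raise ValueError("every internal fraction needs both classes; "
                         f"class counts {counts.tolist()} are too small for {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    roles = tuple(learners)
    C = len(roles)
    tr_enc = np.empty((n, C))
    te_enc = np.zeros((len(test_features) if test_features is not None else 0, C))
    fold_aucs = np.empty((C, n_folds))
    fold_models = []
    for c, role in enumerate(roles):
        models_c = []
        for i, (fit_idx, held_idx) in enumerate(splits):
            model = clone(learners[role])
            model.fit(X[fit_idx], y[fit_idx])
            held_probs = model.predict_proba(X[held_idx])[:, 1]
            tr_enc[held_idx, c] = held_probs
            fold_aucs[c, i] = roc_auc_score(y[held_idx], held_probs)
            if test_features is not None and len(test_features):
                te_enc[:, c] += model.predict_proba(test_features)[:, 1]
            models_c.append(model)
        fold_models.append(models_c)
    if test_features is not None and len(test_features):
        te_enc /= n_folds
    return StackingState(roles=roles, n_folds=n_folds, train_encodings=tr_enc,
                         test_encodings=te_enc, fold_aucs=fold_aucs,
                         mean_aucs=fold_aucs.mean(axis=1), fold_models=fold_models,
                         fold_indices=splits)


def adaptive_weights(mean_aucs, n_classifiers: int = None) -> np.ndarray:
    """lambda^c = 1 - (1 - (w^c)^2)^N; equals 1 at w^c = 1, monotone in w^c."""
    w = np.asarray(mean_aucs, dtype=np.float64)
    if np.any((w < 0) | (w > 1)):
        raise ValueError(f"mean AUCs must lie in [0, 1], got {w}")
    N = n_classifiers if n_classifiers is not None else w.size
    return 1.0 - (1.0 - w ** 2) ** N


def fit_meta(encodings, labels, C: float = 1.0) -> LogisticRegression:
    """Level-1 logistic decoder P(y=1|x) = 1/(1+exp(-w.x)) on the encodings."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("meta layer needs both classes in the labels")
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    model.fit(np.asarray(encodings, dtype=np.float64), y)
    return model


def average_probabilities(probs: np.ndarray, weights=None) -> np.ndarray:
    """Weighted mean of per-classifier probabilities (uniform by default)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if weights is None:
        return probs.mean(axis=1)
    weights = np.asarray(weights, dtype=np.float64)
    return probs @ (weights / weights.size)


def majority_vote(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard majority vote: strictly more than half positive wins, else reject.

    Rejections (ties included; a probability of exactly ``threshold`` votes
    negative) are mapped to the negative class and logged.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    votes = (probs > threshold).sum(axis=1)
    labels = (votes > probs.shape[1] / 2).astype(int)
    n_reject = int(np.sum((votes <= probs.shape[1] / 2) & (votes * 2 == probs.shape[1])))
    if n_reject:
        logger.info("majority vote: %d ties rejected -> negative class", n_reject)
    return labels


def predict_strategy(probs: np.ndarray, strategy: str, meta: LogisticRegression = None,
                     lambdas=None):
    """Combine per-classifier probabilities under the chosen strategy.

    ``averaging`` and the stacking variants return class-1 probabilities;
    ``voting`` returns hard labels.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if strategy == "averaging":
        return average_probabilities(probs)
    if strategy == "voting":
        return majority_vote(probs)
    if meta is None:
        raise ValueError("stacking strategies require a fitted meta model")
    scaled = probs if lambdas is None or strategy == "stacking" else probs * np.asarray(lambdas)
    return meta.predict_proba(scaled)[:, 1]


class StackingEnsemble:
    """Fit/predict wrapper over level-0 encoding plus the chosen strategy.

    For the stacking strategies the F fold models per classifier are kept
    and reused at prediction time (test encodings are their averaged
    probabilities, Fig.-3 style); for averaging/voting each classifier is
    fitted once on the full training set.
    """

    def __init__(self, strategy: str = "stacking_adaptive", learners: dict = None,
                 internal_folds: int = DEFAULT_INTERNAL_FOLDS, seed: int = 0,
                 weight_fn=adaptive_weights, meta_C: float = 1.0):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
        self.strategy = strategy
        self.learners = learners or make_base_learners(seed=seed)
        self.internal_folds = internal_folds
        self.seed = seed
        self.weight_fn = weight_fn
        self.meta_C = meta_C
        self.state: StackingState = None
        self.lambdas: np.ndarray = None
        self.meta: LogisticRegression = None
        self._full_models: dict = None

    def fit(self, X, y) -> "StackingEnsemble":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.strategy in ("averaging", "voting"):
            self._full_models = {}
            for role, est in self.learners.items():
                model = clone(est)
                model.fit(X, y)
                self._full_models[role] = model
            return self
        self.state = encode_level0(X, y, test_features=None, learners=self.learners,
                                   n_folds=self.internal_folds, seed=self.seed)
        C = len(self.state.roles)
        if self.strategy == "stacking_adaptive":
            self.lambdas = self.weight_fn(self.state.mean_aucs, C)
        else:
            self.lambdas = np.ones(C)
        self.meta = fit_meta(self.state.train_encodings * self.lambdas, y, C=self.meta_C)
        return self

    def base_probabilities(self, X) -> np.ndarray:
        """(m, C) class-1 probabilities of the base classifiers on X."""
        X = np.asarray(X, dtype=np.float64)
        if self._full_models is not None:
            cols = [self._full_models[r].predict_proba(X)[:, 1] for r in self._full_models]
        else:
            if self.state is None:
                raise RuntimeError("ensemble is not fitted")
            cols = []
            for models_c in self.state.fold_models:
                p = np.zeros(X.shape[0])
                for model in models_c:
                    p += model.predict_proba(X)[:, 1]
                cols.append(p / len(models_c))
        return np.column_stack(cols)

    def predict_proba(self, X) -> np.ndarray:
        if self.strategy == "voting":
            raise RuntimeError("the voting strategy produces hard labels only")
        probs = self.base_probabilities(X)
        if self.strategy == "averaging":
            return average_probabilities(probs)
        return self.meta.predict_proba(probs * self.lambdas)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        if self.strategy == "voting":
            return majority_vote(self.base_probabilities(X), threshold)
        return (self.predict_proba(X) >= threshold).astype(int)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_bundle(ensemble: StackingEnsemble, path, extra_manifest: dict = None) -> None:
    """Persist the fitted ensemble plus a plain-text manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(ensemble, path / "ensemble.joblib")
    manifest = {
        "format": "rpistack-bundle",
        "version": __version__,
        "strategy": ensemble.strategy,
        "seed": ensemble.seed,
        "internal_folds": ensemble.internal_folds,
        "lambdas": None if ensemble.lambdas is None else [float(v) for v in ensemble.lambdas],
        "roles": list(ensemble.learners),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_bundle(path) -> tuple:
    """Load an ensemble bundle; returns (ensemble, manifest)."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise FileNotFoundError(f"no manifest.json in bundle {path}")
    with open(manifest_file) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "rpistack-bundle":
        raise ValueError(f"{path} is not an rpistack model bundle")
    if manifest.get("version") != __version__:
        raise ValueError(f"bundle version {manifest.get('version')!r} does not match "
                         f"package version {__version__!r}")
    ensemble = joblib.load(path / "ensemble.joblib")
    return ensemble, manifest
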