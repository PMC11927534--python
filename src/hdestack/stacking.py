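"""Stacking ensemble assembly and the cross-validation objective.

The candidate pool mirrors a typical small-sample tabular cohort:
logistic regression (LR), decision tree (DT), RBF support vector machine
(SVM), k-nearest neighbours (KNN), Gaussian process (GP) and a multilayer
perceptron (MLP). Base learners feed a multinomial logistic-regression
meta-learner through out-of-fold (OOF) class-probability meta-features, so
the meta-learner never sees a prediction made by a model trained on the
same row. Per-base-learner weights are read off the meta-learner's
coefficients (mean |coefficient| over each base's probability block,
normalized to sum to one); these weights later drive the weighted Shapley
aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .containers import FeatureTable
from .diversity import DiversityReport, build_report, performance_metrics, select_base_learners
from .hde import Param, ParamSpace

logger = logging.getLogger(__name__)

CANDIDATE_NAMES = ("LR", "DT", "SVM", "KNN", "GP", "MLP")


class SubsampledClassifier(BaseEstimator, ClassifierMixin):
    """Fit a base estimator on a stratified subsample of at most ``max_n`` rows.

    Cost control for cubic-complexity learners (the Gaussian process);
    prediction uses the full fitted model.
    """

    def __init__(self, estimator, max_n: int = 400, random_state: int = 0):
        self.estimator = estimator
        self.max_n = max_n
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.shape[0] > self.max_n:
            rng = np.random.default_rng(self.random_state)
            idx = []
            classes = np.unique(y)
            per = max(2, self.max_n // classes.size)
            for k in classes:
                rows = np.flatnonzero(y == k)
                take = min(per, rows.size)
                idx.extend(rng.choice(rows, size=take, replace=False))
            idx = np.sort(np.asarray(idx))
            X, y = X[idx], y[idx]
        self.model_ = clone(self.estimator).fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


def default_candidate_pool(
    seed: int = 0, gp_max_n: int = 400
) -> dict[str, tuple[Callable[[dict], BaseEstimator], ParamSpace]]:
    """Constructors and hyperparameter spaces for the six candidates."""

    def lr(p):
        return LogisticRegression(C=p.get("C", 1.0), max_iter=1000)

    def dt(p):
        return DecisionTreeClassifier(
            max_depth=p.get("max_depth", 10), random_state=seed
        )

    def svm(p):
        return SVC(C=p.get("C", 1.0), gamma=p.get("gamma", "scale"), random_state=seed)

    def knn(p):
        return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 5))

    def gp(p):
        return SubsampledClassifier(
            GaussianProcessClassifier(
                kernel=RBF(length_scale=p.get("length_scale", 1.0)),
                optimizer=None,
                random_state=seed,
            ),
            max_n=gp_max_n,
            random_state=seed,
        )

    def mlp(p):
        return MLPClassifier(
            hidden_layer_sizes=(p.get("hidden", 64),),
            alpha=p.get("alpha", 1e-4),
            max_iter=400,
            random_state=seed,
        )

    return {
        "LR": (lr, ParamSpace([Param("C", "continuous", (1e-3, 1e2), scale="log")])),
        "DT": (dt, ParamSpace([Param("max_depth", "integer", (2, 20))])),
        "SVM": (
            svm,
            ParamSpace(
                [
                    Param("C", "continuous", (1e-2, 1e2), scale="log"),
                    Param("gamma", "continuous", (1e-4, 1e1), scale="log"),
                ]
            ),
        ),
        "KNN": (knn, ParamSpace([Param("n_neighbors", "integer", (1, 30))])),
        "GP": (
            gp,
            ParamSpace(
                [Param("length_scale", "continuous", (1e-2, 1e2), scale="log")]
            ),
        ),
        "MLP": (
            mlp,
            ParamSpace(
                [
                    Param("hidden", "integer", (8, 256)),
                    Param("alpha", "continuous", (1e-6, 1e-1), scale="log"),
                ]
            ),
        ),
    }


def joint_param_space(
    pool: dict, selection: list[str]
) -> tuple[ParamSpace, dict[str, list[str]]]:
    """Concatenate the selected candidates' spaces into one genome layout."""
    params: list[Param] = []
    layout: dict[str, list[str]] = {}
    for name in selection:
        _, space = pool[name]
        prefixed = []
        for p in space.params:
            q = Param(f"{name}.{p.name}", p.kind, p.bounds, p.choices, p.scale)
            params.append(q)
            prefixed.append(q.name)
        layout[name] = prefixed
    return ParamSpace(params), layout


def split_assignment(assignment: dict, selection: list[str]) -> dict[str, dict]:
    """Un-prefix a joint assignment back into per-candidate hyperparameters."""
    out: dict[str, dict] = {name: {} for name in selection}
    for key, val in assignment.items():
        name, pname = key.split(".", 1)
        out[name][pname] = val
    return out


def _proba_or_onehot(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Class probabilities, or one-hot predictions for probability-free models."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        full = np.zeros((X.shape[0], classes.size))
        cols = np.searchsorted(classes, model.classes_)
        full[:, cols] = proba
        return full
    logger.info("model %s lacks predict_proba; using one-hot predictions",
                type(model).__name__)
    pred = model.predict(X)
    out = np.zeros((X.shape[0], classes.size))
    out[np.arange(X.shape[0]), np.searchsorted(classes, pred)] = 1.0
    return out


def oof_meta_features(
    base_models: dict[str, BaseEstimator],
    train: FeatureTable,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Out-of-fold class-probability meta-features.

    Returns the meta matrix (one probability block per base learner, in
    ``base_models`` order), its column names, and per-base OOF hard
    predictions stacked as an (n_bases, n_samples) array.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    classes = train.classes
    n, c = train.n_samples, classes.size
    names = list(base_models)
    meta = np.zeros((n, len(names) * c))
    hard = np.zeros((len(names), n), dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(train.values, train.labels):
        for b, name in enumerate(names):
            model = clone(base_models[name])
            model.fit(train.values[tr], train.labels[tr])
            proba = _proba_or_onehot(model, train.values[te], classes)
            meta[te, b * c:(b + 1) * c] = proba
            hard[b, te] = classes[np.argmax(proba, axis=1)]
    cols = [f"{name}:p{int(k)}" for name in names for k in classes]
    return meta, cols, hard


def extract_base_weights(meta_learner, n_bases: int, n_classes: int) -> np.ndarray:
    """Per-base-learner importance from the meta-learner's coefficients.

    Mean |coefficient| over each base's probability block (all meta-learner
    classes), normalized to sum to one. A coefficient-free meta-learner
    yields uniform weights.
    """
    coef = getattr(meta_learner, "coef_", None)
    if coef is None:
        logger.info("meta-learner has no coefficients; uniform base weights")
        return np.full(n_bases, 1.0 / n_bases)
    coef = np.atleast_2d(coef)
    if coef.shape[1] != n_bases * n_classes:
        raise ValueError("coefficient matrix does not match the meta layout")
    w = np.array(
        [np.mean(np.abs(coef[:, b * n_classes:(b + 1) * n_classes]))
         for b in range(n_bases)]
    )
    total = w.sum()
    if total == 0:
        return np.full(n_bases, 1.0 / n_bases)
    return w / total


@dataclass
class StackedModel:
    """A fitted stacking ensemble."""

    base_names: list[str]
    base_models: dict[str, BaseEstimator]
    meta_learner: LogisticRegression
    classes: np.ndarray
    base_weights: np.ndarray
    n_folds: int
    seed: int
    hyperparams: dict[str, dict] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)

    def meta_features(self, X: np.ndarray) -> np.ndarray:
        blocks = [
            _proba_or_onehot(self.base_models[name], np.asarray(X), self.classes)
            for name in self.base_names
        ]
        return np.hstack(blocks)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.meta_learner.predict_proba(self.meta_features(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]

    def evaluate(self, table: FeatureTable) -> dict[str, float]:
        return performance_metrics(self.predict(table.values), table.labels)


def fit_stack(
    selection: list[str],
    hyperparams: dict[str, dict] | None,
    train: FeatureTable,
    pool: dict | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> StackedModel:
    """Fit base learners and the multinomial logistic meta-learner.

    Bases are refitted on the full training table; the meta-learner is
    trained on their out-of-fold probability features only.
    """
    if not selection:
        raise ValueError("selection must be non-empty")
    if train.classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    pool = default_candidate_pool(seed) if pool is None else pool
    hyperparams = hyperparams or {}
    bases = {
        name: pool[name][0](hyperparams.get(name, {})) for name in selection
    }
    meta_x, _, _ = oof_meta_features(bases, train, n_folds=n_folds, seed=seed)
    meta = LogisticRegression(max_iter=2000)
    meta.fit(meta_x, train.labels)
    fitted = {name: clone(m).fit(train.values, train.labels) for name, m in bases.items()}
    weights = extract_base_weights(meta, len(selection), train.classes.size)
    return StackedModel(
        base_names=list(selection),
        base_models=fitted,
        meta_learner=meta,
        classes=train.classes,
        base_weights=weights,
        n_folds=n_folds,
        seed=seed,
        hyperparams={name: dict(hyperparams.get(name, {})) for name in selection},
        feature_names=list(train.feature_names),
    )


def cv_fitness(
    selection: list[str],
    genome: np.ndarray,
    space: ParamSpace,
    train: FeatureTable,
    pool: dict | None = None,
    n_folds: int = 5,
    inner_folds: int = 3,
    seed: int = 0,
) -> float:
    """Mean stratified-CV accuracy of the stack under decoded hyperparameters.

    This is the (deterministic, seed-fixed) objective handed to the
    optimizer; a genome that fails to decode or train scores -inf.
    """
    try:
        assignment = space.decode(np.asarray(genome, dtype=float))
        params = split_assignment(assignment, selection)
    except Exception:  # noqa: BLE001
        logger.warning("cv_fitness: genome decode failed", exc_info=True)
        return -np.inf
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(train.values, train.labels):
        fold_train = train.take_rows(tr)
        model = fit_stack(
            selection, params, fold_train, pool=pool, n_folds=inner_folds, seed=seed
        )
        pred = model.predict(train.values[te])
        accs.append(float(np.mean(pred == train.labels[te])))
    return float(np.mean(accs))


def evaluate_candidates(
    train: FeatureTable,
    pool: dict | None = None,
    candidates: list[str] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    r: float = 0.5,
    scale: str = "raw",
) -> DiversityReport:
    """Score the candidate pool by its out-of-fold predictions on ``train``."""
    pool = default_candidate_pool(seed) if pool is None else pool
    candidates = list(pool) if candidates is None else list(candidates)
    bases = {name: pool[name][0]({}) for name in candidates}
    _, _, hard = oof_meta_features(bases, train, n_folds=n_folds, seed=seed)
    predictions = {name: hard[b] for b, name in enumerate(candidates)}
    return build_report(predictions, train.labels, r=r, scale=scale)


def ensemble_size_sweep(
    report: DiversityReport,
    train: FeatureTable,
    test: FeatureTable,
    hyperparams: dict[str, dict] | None = None,
    pool: dict | None = None,
    k_range: range | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Test-set performance of the top-K stack for each ensemble size K."""
    m = len(report.models)
    k_range = range(1, m + 1) if k_range is None else k_range
    rows = {}
    for k in k_range:
        selection = select_base_learners(report, k)
        model = fit_stack(
            selection, hyperparams, train, pool=pool, n_folds=n_folds, seed=seed
        )
        rows[k] = model.evaluate(test)
    df = pd.DataFrame(rows).T
    df.index.name = "K"
    return df
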