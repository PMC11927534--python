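"""Weighted Shapley explanations for stacking ensembles.

Each base learner is explained separately with an interventional Shapley
attribution of its class-probability output against a background dataset;
the per-base attributions are then combined as a weighted sum using the
base weights extracted from the meta-learner. The aggregate explains a
weight-mixture surrogate of the stack (the weighted sum of base-learner
probabilities), which is the standard procedure for attributing ensemble
decisions back to input features; it is an approximation of the exact
meta-learner composition and is documented as such.

Two attribution engines are provided, both computing interventional
Shapley values phi_j with v(S) = E_background[f(x_S, b_~S)]:

* exact coalition enumeration (2^p evaluations) — used for small feature
  counts; exact Shapley values, local accuracy to machine precision.
* permutation sampling — marginal contributions along random feature
  orderings. Each ordering's contributions telescope to
  f(x) - E[f(background)], so local accuracy holds to machine precision
  for any number of permutations; accuracy of individual phi_j improves
  with more permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import FeatureTable
from .stacking import StackedModel, _proba_or_onehot

logger = logging.getLogger(__name__)


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, FeatureTable):
        return data.values
    return np.atleast_2d(np.asarray(data, dtype=float))


def model_fn(learner, classes: np.ndarray):
    """Wrap a fitted classifier as X -> (n, n_classes) probability matrix."""
    def f(x: np.ndarray) -> np.ndarray:
        return _proba_or_onehot(learner, np.atleast_2d(x), classes)
    return f


def summarize_background(data, k: int = 50, seed: int = 0) -> np.ndarray:
    """K-means summary of a dataset, used as the Shapley background."""
    x = _as_matrix(data)
    if x.shape[0] <= k:
        return x.copy()
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    km.fit(x)
    return km.cluster_centers_


def exact_shap(f, X, background) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley values by coalition enumeration.

    Returns (values, base_values) with values of shape
    (n_samples, n_features, n_outputs). Cost grows as 2^p; guarded to
    p <= 16.
    """
    x = _as_matrix(X)
    bg = _as_matrix(background)
    n, p = x.shape
    if p > 16:
        raise ValueError("exact enumeration is limited to 16 features")
    base_out = f(bg).mean(axis=0)
    c = base_out.size
    weights = {s: factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)}
    coalitions = [frozenset(s) for r in range(p + 1) for s in combinations(range(p), r)]
    values = np.zeros((n, p, c))
    for si in range(n):
        # v(S) for every coalition, one batched model call
        stacked = np.repeat(bg, len(coalitions), axis=0).reshape(
            bg.shape[0], len(coalitions), p
        )
        for ci, s in enumerate(coalitions):
            cols = sorted(s)
            stacked[:, ci, cols] = x[si, cols]
        out = f(stacked.reshape(-1, p)).reshape(bg.shape[0], len(coalitions), c)
        v = {s: out[:, ci].mean(axis=0) for ci, s in enumerate(coalitions)}
        for j in range(p):
            phi = np.zeros(c)
            for s, vs in v.items():
                if j in s:
                    continue
                phi += weights[len(s)] * (v[s | {j}] - vs)
            values[si, j] = phi
    return values, base_out


def permutation_shap(
    f, X, background, n_perm: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled-permutation interventional Shapley values.

    Averages marginal contributions along ``n_perm`` feature orderings,
    drawn as antithetic pairs (each random ordering is followed by its
    reverse) to reduce variance; local accuracy is exact by telescoping
    regardless of ``n_perm``.
    """
    x = _as_matrix(X)
    bg = _as_matrix(background)
    n, p = x.shape
    rng = np.random.default_rng(seed)
    base_out = f(bg).mean(axis=0)
    c = base_out.size
    values = np.zeros((n, p, c))
    n_b = bg.shape[0]
    for si in range(n):
        acc = np.zeros((p, c))
        forward = None
        for k in range(n_perm):
            if k % 2 == 0:
                forward = rng.permutation(p)
                order = forward
            else:
                order = forward[::-1]
            # states 0..p: background with the first k features of the
            # ordering replaced by the sample's values
            states = np.repeat(bg[None, :, :], p + 1, axis=0)  # (p+1, n_b, p)
            for k in range(1, p + 1):
                states[k:, :, order[k - 1]] = x[si, order[k - 1]]
            out = f(states.reshape(-1, p)).reshape(p + 1, n_b, c).mean(axis=1)
            acc[order] += np.diff(out, axis=0)
        values[si] = acc / n_perm
    return values, base_out


def base_shap(
    learner,
    background,
    X,
    classes: np.ndarray | None = None,
    mode: str = "auto",
    n_perm: int = 10,
    exact_limit: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shapley tensor for one fitted base learner's probability output.

    ``mode``: "exact", "sampling", or "auto" (exact when the feature count
    is at most ``exact_limit``).
    """
    x = _as_matrix(X)
    if classes is None:
        classes = np.asarray(learner.classes_)
    f = model_fn(learner, classes)
    if mode == "auto":
        mode = "exact" if x.shape[1] <= exact_limit else "sampling"
    if mode == "exact":
        try:
            return exact_shap(f, x, background)
        except ValueError:
            logger.info("exact explainer infeasible; falling back to sampling")
            mode = "sampling"
    if mode != "sampling":
        raise ValueError(f"unknown explainer mode: {mode}")
    return permutation_shap(f, x, background, n_perm=n_perm, seed=seed)


@dataclass
class ShapExplanation:
    """Aggregated (weighted) Shapley explanation of a stacked model."""

    values: np.ndarray       # (n_samples, n_features, n_classes)
    base_values: np.ndarray  # (n_classes,)
    feature_names: list[str]
    weights: np.ndarray
    per_base: dict[str, np.ndarray] = field(default_factory=dict)
    per_base_base_values: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def aggregate_shap(
    tensors: dict[str, np.ndarray],
    base_values: dict[str, np.ndarray],
    weights,
    feature_names: list[str] | None = None,
) -> ShapExplanation:
    """Weighted sum of per-base Shapley tensors and base values."""
    names = list(tensors)
    w = np.asarray(
        [weights[n] for n in names] if isinstance(weights, dict) else weights,
        dtype=float,
    )
    if w.size != len(names):
        raise ValueError("one weight per base learner required")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    shapes = {tensors[n].shape for n in names}
    if len(shapes) != 1:
        raise ValueError("per-base tensors must be shape-aligned")
    agg = sum(wi * tensors[n] for wi, n in zip(w, names))
    agg_base = sum(wi * np.asarray(base_values[n]) for wi, n in zip(w, names))
    p = agg.shape[1]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    return ShapExplanation(
        values=agg,
        base_values=agg_base,
        feature_names=list(feature_names),
        weights=w,
        per_base={n: tensors[n] for n in names},
        per_base_base_values={n: np.asarray(base_values[n]) for n in names},
    )


def stack_shap(
    stack: StackedModel,
    background,
    X,
    mode: str = "auto",
    n_perm: int = 10,
    exact_limit: int = 10,
    seed: int = 0,
) -> ShapExplanation:
    """Weighted Shapley explanation of a fitted stack.

    Explains each base learner against the background, then aggregates
    with the meta-learner-derived base weights.
    """
    tensors, bases = {}, {}
    for name in stack.base_names:
        t, b = base_shap(
            stack.base_models[name], background, X,
            classes=stack.classes, mode=mode, n_perm=n_perm,
            exact_limit=exact_limit, seed=seed,
        )
        tensors[name] = t
        bases[name] = b
    return aggregate_shap(
        tensors, bases, stack.base_weights, feature_names=stack.feature_names
    )


def summary_export(
    e: ShapExplanation,
    X=None,
    class_index: np.ndarray | int | None = None,
    path=None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Feature ranking by mean |phi| plus per-point scatter data.

    ``class_index`` selects which class's attributions are summarized:
    an int, a per-sample array (e.g. the predicted class), or None to
    average |phi| over all classes. Returns (ranking, scatter) and
    optionally writes the ranking to CSV.
    """
    if class_index is None:
        phi = e.values.mean(axis=2)
        mag = np.abs(e.values).mean(axis=2)
    elif np.isscalar(class_index):
        phi = e.values[:, :, int(class_index)]
        mag = np.abs(phi)
    else:
        idx = np.asarray(class_index, dtype=int)
        phi = e.values[np.arange(e.n_samples), :, :][
            np.arange(e.n_samples)[:, None], np.arange(e.n_features)[None, :], idx[:, None]
        ]
        mag = np.abs(phi)
    ranking = (
        pd.DataFrame(
            {"feature": e.feature_names, "mean_abs_shap": mag.mean(axis=0)}
        )
        .sort_values("mean_abs_shap", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    scatter = None
    if X is not None:
        x = _as_matrix(X)
        rows = []
        for j, name in enumerate(e.feature_names):
            rows.append(
                pd.DataFrame(
                    {"feature": name, "shap": phi[:, j], "value": x[:, j]}
                )
            )
        scatter = pd.concat(rows, ignore_index=True)
    if path is not None:
        ranking.to_csv(path, index=False)
    return ranking, scatter


def force_export(
    e: ShapExplanation, sample: int, class_idx: int, path=None
) -> dict:
    """Single-sample force data: signed contributions, base value, f(x).

    f(x) = base_value + sum(phi) by local accuracy; contributions are
    sorted by decreasing |phi|.
    """
    if not 0 <= sample < e.n_samples:
        raise IndexError("sample index out of range")
    phi = e.values[sample, :, class_idx]
    order = np.argsort(-np.abs(phi), kind="stable")
    contrib = pd.DataFrame(
        {
            "feature": [e.feature_names[j] for j in order],
            "shap": phi[order],
            "sign": np.where(phi[order] >= 0, "+", "-"),
        }
    )
    base = float(e.base_values[class_idx])
    fx = base + float(phi.sum())
    if path is not None:
        contrib.to_csv(path, index=False)
    return {"contributions": contrib, "base_value": base, "fx": fx}
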