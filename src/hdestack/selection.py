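"""Feature selection: chemometric band selectors and morphological wrappers.

Spectral side — three classic wavelength-selection algorithms, each using
a PLS (or MLR, for SPA) inner regression on one-hot class indicators with
cross-validated RMSE (RMSECV) as the criterion:

* SPA  — successive projections: forward chains that maximize the norm of
  the candidate band projected onto the orthogonal complement of the
  already-selected set, giving minimally collinear subsets.
* CARS — competitive adaptive reweighted sampling: Monte-Carlo row
  sampling, exponentially decaying retention of high-|coefficient| bands,
  adaptive reweighted sampling, keep the subset with minimal RMSECV.
* BOSS — bootstrap soft shrinkage: bootstrap band sub-models accumulate
  normalized |coefficients| into soft weights that drive weighted random
  sampling of shrinking candidate sets.

Morphological side — thin wrappers over scikit-learn's mutual-information
ranking (MI), recursive feature elimination (RFE) and tree-importance
selection (SFM), each returning a fixed top-k.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .containers import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of one selector run."""

    method: str
    selected_indices: np.ndarray
    score_trace: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    wavelengths: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if len(np.unique(self.selected_indices)) != self.selected_indices.size:
            raise ValueError("selected indices must be unique")

    @property
    def n_selected(self) -> int:
        return self.selected_indices.size

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "params": self.params,
            "selected_indices": self.selected_indices.tolist(),
            "score_trace": [float(v) for v in self.score_trace],
        }
        if self.wavelengths is not None:
            payload["wavelengths"] = np.asarray(self.wavelengths)[
                self.selected_indices
            ].tolist()
        Path(path).write_text(json.dumps(payload, indent=2))


def _one_hot(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    out = np.zeros((y.size, classes.size))
    out[np.arange(y.size), np.searchsorted(classes, y)] = 1.0
    return out


def _pls_components(n_rows: int, n_cols: int, cap: int = 10) -> int:
    return max(1, min(cap, n_cols, n_rows - 1))


def _pls_coef_weights(x: np.ndarray, y1h: np.ndarray, cap: int = 10) -> np.ndarray:
    """Band importances: summed |PLS coefficient| across class indicators."""
    pls = PLSRegression(n_components=_pls_components(x.shape[0], x.shape[1], cap))
    pls.fit(x, y1h)
    coef = pls.coef_  # (n_targets, n_features) in modern scikit-learn
    if coef.shape[0] == x.shape[1]:
        coef = coef.T
    return np.abs(coef).sum(axis=0)


def pls_rmsecv(
    x: np.ndarray, y: np.ndarray, cv: int = 5, seed: int = 0, cap: int = 10
) -> float:
    """Cross-validated RMSE of PLS regression on one-hot class indicators."""
    y1h = _one_hot(y)
    kf = KFold(n_splits=min(cv, x.shape[0]), shuffle=True, random_state=seed)
    sq = 0.0
    n = 0
    for tr, te in kf.split(x):
        pls = PLSRegression(n_components=_pls_components(tr.size, x.shape[1], cap))
        pls.fit(x[tr], y1h[tr])
        resid = pls.predict(x[te]) - y1h[te]
        sq += float(np.sum(resid**2))
        n += resid.size
    return float(np.sqrt(sq / n))


def _mlr_rmsecv_chain(
    x: np.ndarray, y1h: np.ndarray, chain: np.ndarray, cv: int, seed: int,
    ridge: float = 1e-8,
) -> np.ndarray:
    """RMSECV of ridge-stabilized MLR for every prefix of a band chain."""
    kf = KFold(n_splits=min(cv, x.shape[0]), shuffle=True, random_state=seed)
    sq = np.zeros(chain.size)
    n_total = y1h.size
    for tr, te in kf.split(x):
        for k in range(1, chain.size + 1):
            cols = chain[:k]
            a = np.hstack([x[tr][:, cols], np.ones((tr.size, 1))])
            g = a.T @ a + ridge * np.eye(a.shape[1])
            beta = np.linalg.solve(g, a.T @ y1h[tr])
            at = np.hstack([x[te][:, cols], np.ones((te.size, 1))])
            sq[k - 1] += float(np.sum((at @ beta - y1h[te]) ** 2))
    return np.sqrt(sq / n_total)


def _spa_chain(x: np.ndarray, start: int, n_max: int, tol: float = 1e-10) -> np.ndarray:
    """Forward successive-projection chain from one starting band.

    Maintains the residual of every column after projecting out the span of
    the selected set (incremental Gram-Schmidt); each step adds the band of
    maximal residual norm, so selected columns stay linearly independent.
    """
    resid = x - x.mean(axis=0)
    chain = [start]
    u = resid[:, start]
    nu = np.linalg.norm(u)
    if nu < tol:
        return np.array(chain[:1])
    for _ in range(n_max - 1):
        u = u / np.linalg.norm(u)
        resid = resid - np.outer(u, u @ resid)
        norms = np.linalg.norm(resid, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < tol:  # remaining columns collinear with selection
            break
        chain.append(j)
        u = resid[:, j]
    return np.array(chain)


def spa_select(
    s: np.ndarray,
    y: np.ndarray,
    n_max: int = 30,
    n_starts: int | None = None,
    cv: int = 5,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> SelectionResult:
    """Successive projections algorithm for wavelength selection.

    Builds a projection chain from each candidate starting band, scores
    every chain prefix by the RMSECV of an inner one-hot regression, and
    returns the (start, size) combination with minimal RMSECV.

    ``n_starts`` limits how many starting bands are tried (all bands when
    the grid is small, a seeded random subset otherwise).
    """
    x = np.asarray(s, dtype=float)
    y1h = _one_hot(y)
    n, p = x.shape
    if not 1 <= n_max <= p:
        raise ValueError("n_max must be in [1, n_bands]")
    n_max = min(n_max, n - 2)
    rng = np.random.default_rng(seed)
    if n_starts is None:
        n_starts = p if p <= 60 else 30
    starts = (
        np.arange(p)
        if n_starts >= p
        else np.sort(rng.choice(p, size=n_starts, replace=False))
    )

    best = (np.inf, None, None)  # (rmsecv, chain prefix, trace)
    for start in starts:
        chain = _spa_chain(x, int(start), n_max)
        if chain.size == 0:
            logger.info("spa_select: start %d skipped (rank-deficient)", start)
            continue
        trace = _mlr_rmsecv_chain(x, y1h, chain, cv, seed)
        k = int(np.argmin(trace)) + 1
        if trace[k - 1] < best[0]:
            best = (float(trace[k - 1]), chain[:k], trace)
    rmse, subset, trace = best
    if subset is None:
        raise RuntimeError("SPA found no valid chain")
    return SelectionResult(
        method="SPA",
        selected_indices=np.sort(subset),
        score_trace=list(map(float, trace)),
        params={"n_max": n_max, "n_starts": int(len(starts)), "cv": cv, "seed": seed,
                "best_rmsecv": rmse},
        wavelengths=wavelengths,
    )


def _cars_ratio(i: int, n_mc: int, p: int) -> float:
    """Exponential decay retention ratio: 100% at run 1 down to 2/p at run N."""
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    a = (p / 2.0) ** (1.0 / (n_mc - 1))
    k = np.log(p / 2.0) / (n_mc - 1)
    return float(a * np.exp(-k * i))


def cars_select(
    s: np.ndarray,
    y: np.ndarray,
    n_mc: int = 50,
    row_frac: float = 0.8,
    cv: int = 5,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each Monte-Carlo run fits the inner PLS on a random row subset of the
    currently retained bands, keeps the top fraction of bands (by summed
    |coefficient|) given by an exponentially decaying schedule, then
    resamples among them with probability proportional to |coefficient|
    (adaptive reweighted sampling). The subset with minimal RMSECV over
    all runs is returned.
    """
    x = np.asarray(s, dtype=float)
    n, p = x.shape
    y1h = _one_hot(y)
    rng = np.random.default_rng(seed)
    retained = np.arange(p)
    traces: list[float] = []
    counts: list[int] = []
    subsets: list[np.ndarray] = []
    for i in range(1, n_mc + 1):
        rows = rng.choice(n, size=max(2, int(round(row_frac * n))), replace=False)
        w = _pls_coef_weights(x[rows][:, retained], y1h[rows])
        n_keep = max(2, int(round(_cars_ratio(i, n_mc, p) * p)))
        n_keep = min(n_keep, retained.size)
        top = retained[np.argsort(w)[::-1][:n_keep]]
        w_top = w[np.argsort(w)[::-1][:n_keep]]
        if w_top.sum() <= 0:
            probs = np.full(n_keep, 1.0 / n_keep)
        else:
            probs = w_top / w_top.sum()
        picked = np.unique(rng.choice(top, size=n_keep, replace=True, p=probs))
        if picked.size < 2:
            logger.info("cars_select: retained bands fell below 2; stopping early")
            break
        retained = picked
        traces.append(pls_rmsecv(x[:, retained], y, cv=cv, seed=seed))
        counts.append(retained.size)
        subsets.append(retained.copy())
    if not subsets:
        raise RuntimeError("CARS produced no subsets")
    best = int(np.argmin(traces))
    return SelectionResult(
        method="CARS",
        selected_indices=np.sort(subsets[best]),
        score_trace=traces,
        params={"n_mc": n_mc, "cv": cv, "seed": seed, "best_run": best + 1,
                "best_rmsecv": float(traces[best])},
        wavelengths=wavelengths,
        extras={"retained_counts": counts},
    )


def boss_select(
    s: np.ndarray,
    y: np.ndarray,
    n_boot: int = 20,
    max_iter: int = 20,
    shrink: float = 0.8,
    patience: int = 5,
    cv: int = 5,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> SelectionResult:
    """Bootstrap soft shrinkage band selection.

    Per iteration, ``n_boot`` bootstrap band sub-models are fitted; their
    normalized |PLS coefficients| accumulate into soft weights, which drive
    weighted random sampling of a shrinking candidate set. Iterations stop
    once RMSECV stops improving; the bands of the minimal-RMSECV sub-model
    are returned.
    """
    x = np.asarray(s, dtype=float)
    n, p = x.shape
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    y1h = _one_hot(y)
    rng = np.random.default_rng(seed)
    candidate = np.arange(p)
    traces: list[float] = []
    weight_history: list[np.ndarray] = []
    best_rmse, best_bands = np.inf, None
    since_improve = 0
    for _ in range(max_iter):
        if candidate.size < 2:
            break
        acc = np.zeros(p)
        iter_best = (np.inf, None)
        for _ in range(n_boot):
            bands = np.unique(rng.choice(candidate, size=candidate.size, replace=True))
            if bands.size < 1:
                continue
            w = _pls_coef_weights(x[:, bands], y1h)
            if w.sum() > 0:
                acc[bands] += w / w.sum()
            rmse = pls_rmsecv(x[:, bands], y, cv=cv, seed=seed)
            if rmse < iter_best[0]:
                iter_best = (rmse, bands)
        if acc.sum() <= 0:
            break
        weights = acc / acc.sum()
        weight_history.append(weights)
        traces.append(iter_best[0])
        if iter_best[0] < best_rmse:
            best_rmse, best_bands = iter_best
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= patience:
                break
        new_size = max(2, int(round(candidate.size * shrink)))
        pool = np.flatnonzero(weights > 0)
        new_size = min(new_size, pool.size)
        candidate = rng.choice(pool, size=new_size, replace=False, p=weights[pool] / weights[pool].sum())
        candidate = np.sort(candidate)
    if best_bands is None:
        raise RuntimeError("BOSS produced no sub-models")
    return SelectionResult(
        method="BOSS",
        selected_indices=np.sort(best_bands),
        score_trace=traces,
        params={"n_boot": n_boot, "cv": cv, "seed": seed,
                "best_iteration": int(np.argmin(traces)) + 1,
                "best_rmsecv": float(best_rmse)},
        wavelengths=wavelengths,
        extras={"weight_history": weight_history},
    )


def morph_select(
    t: FeatureTable, method: str, k: int = 15, seed: int = 0
) -> SelectionResult:
    """Morphological feature selection: MI ranking, RFE, or tree importance."""
    method = method.upper()
    if k > t.n_features:
        raise ValueError("k exceeds the number of features")
    x, y = t.values, t.labels
    if method == "MI":
        scores = mutual_info_classif(x, y, random_state=seed)
        idx = np.argsort(scores)[::-1][:k]
        trace = [float(scores[i]) for i in idx]
    elif method == "RFE":
        est = LogisticRegression(max_iter=2000)
        sel = RFE(est, n_features_to_select=k, step=0.2)
        # RFE assumes comparable coefficient scales; standardize internally
        xs = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        sel.fit(xs, y)
        idx = np.flatnonzero(sel.support_)
        trace = [float(r) for r in sel.ranking_[idx]]
    elif method == "SFM":
        forest = RandomForestClassifier(n_estimators=200, random_state=seed)
        forest.fit(x, y)
        idx = np.argsort(forest.feature_importances_)[::-1][:k]
        trace = [float(forest.feature_importances_[i]) for i in idx]
    else:
        raise ValueError(f"unknown morphological selector: {method}")
    return SelectionResult(
        method=method,
        selected_indices=np.sort(np.asarray(idx)),
        score_trace=trace,
        params={"k": k, "seed": seed},
    )
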