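"""Pairwise diversity metrics, composite indices and base-learner ranking.

Base learners for a stacking ensemble should be "good but different": each
candidate is scored both on how much it disagrees with the other candidates
(diversity) and on how well it classifies (performance), and the two scores
are blended into a comprehensive score used to pick the top-K.

Pairwise diversity is computed from the 2x2 correct/incorrect contingency
table of two classifiers (a = both correct, b = x correct only, c = y
correct only, d = both wrong):

* disagreement   Dis = (b + c) / n                       (bigger = more diverse)
* Q-statistic    Qs  = (ad - bc) / (ad + bc)             (smaller = more diverse)
* kappa          Ks  = (p_o - p_e) / (1 - p_e)           (smaller = more diverse)
* correlation    Cor = (ad - bc) / sqrt((a+b)(a+c)(c+d)(b+d))

with p_o = (a + d)/n the observed agreement and p_e the chance agreement
[(a+b)(a+c) + (c+d)(b+d)] / n^2 (the standard interrater kappa).

The diversity composite index of candidate x is the share-normalized sum of
its pairwise diversities over all metrics; the performance composite index
is the share-normalized sum of its accuracy / macro precision / macro
recall / F1; the comprehensive score is P_x = r*Dci_x + (1-r)*Pci_x with
r = 0.5 by default.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Dis", "Qs", "Ks", "Cor")
PERF_NAMES = ("accuracy", "precision", "recall", "f1")

#: Direction in which each pairwise metric indicates MORE diversity.
DEFAULT_DIRECTIONS = {
    "Dis": "bigger",   # more disagreement = more diverse
    "Qs": "smaller",   # association statistics: lower = more diverse
    "Ks": "smaller",
    "Cor": "smaller",
}


@dataclass
class PairCounts:
    """2x2 correct/incorrect contingency counts for a classifier pair."""

    a: int  # both correct
    b: int  # x correct, y wrong
    c: int  # x wrong, y correct
    d: int  # both wrong

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def pair_counts(pred_x, pred_y, truth) -> PairCounts:
    """Contingency counts of two prediction vectors against the truth."""
    pred_x = np.asarray(pred_x)
    pred_y = np.asarray(pred_y)
    truth = np.asarray(truth)
    if not (pred_x.shape == pred_y.shape == truth.shape):
        raise ValueError("prediction and truth vectors must have equal length")
    cx = pred_x == truth
    cy = pred_y == truth
    return PairCounts(
        a=int(np.sum(cx & cy)),
        b=int(np.sum(cx & ~cy)),
        c=int(np.sum(~cx & cy)),
        d=int(np.sum(~cx & ~cy)),
    )


def pairwise_metric(pc: PairCounts, which: str) -> float:
    """One pairwise diversity metric; NaN marks an undefined denominator."""
    a, b, c, d = float(pc.a), float(pc.b), float(pc.c), float(pc.d)
    n = a + b + c + d
    if which == "Dis":
        if n == 0:
            return math.nan
        return (b + c) / n
    if which == "Qs":
        den = a * d + b * c
        if den == 0:
            logger.info("Qs undefined (ad + bc = 0); excluded from sums")
            return math.nan
        return (a * d - b * c) / den
    if which == "Cor":
        den = (a + b) * (a + c) * (c + d) * (b + d)
        if den == 0:
            logger.info("Cor undefined (marginal product = 0); excluded")
            return math.nan
        return (a * d - b * c) / math.sqrt(den)
    if which == "Ks":
        if n == 0:
            return math.nan
        p_obs = (a + d) / n
        p_chance = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
        if p_chance == 1.0:
            logger.info("Ks undefined (chance agreement = 1); excluded")
            return math.nan
        return (p_obs - p_chance) / (1.0 - p_chance)
    raise ValueError(f"unknown pairwise metric: {which}")


def pairwise_matrices(
    predictions: dict[str, np.ndarray], truth: np.ndarray
) -> dict[str, pd.DataFrame]:
    """All four M x M pairwise metric matrices (diagonal = NaN)."""
    names = list(predictions)
    mats = {m: pd.DataFrame(np.nan, index=names, columns=names) for m in METRIC_NAMES}
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            pc = pair_counts(predictions[x], predictions[y], truth)
            for m in METRIC_NAMES:
                v = pairwise_metric(pc, m)
                mats[m].loc[x, y] = v
                mats[m].loc[y, x] = v
    return mats


def diversity_composite(
    metrics: dict[str, pd.DataFrame],
    directions: dict[str, str] | None = None,
    scale: str = "raw",
) -> pd.Series:
    """Diversity composite index per candidate.

    For each metric t, d_{x,t} sums the pairwise values of model x against
    every other model (using 1 - value for smaller-is-more-diverse metrics
    so that larger always means more diverse), and x's share
    d_{x,t} / sum_y d_{y,t} is accumulated over metrics. ``scale="raw"``
    returns the share sum (values average T/M across candidates, matching
    reported composite-index magnitudes); ``scale="normalized"`` divides by
    the number of metrics so the indices sum to 1.
    """
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    names = None
    total = None
    used = 0
    for m, mat in metrics.items():
        if names is None:
            names = list(mat.index)
            total = pd.Series(0.0, index=names)
        vals = mat.to_numpy(dtype=float).copy()
        np.fill_diagonal(vals, np.nan)
        if directions.get(m, "bigger") == "smaller":
            vals = 1.0 - vals
        d_xt = np.nansum(vals, axis=1)
        col_total = d_xt.sum()
        if col_total == 0:
            logger.warning("diversity metric %s has zero total; skipped", m)
            continue
        total = total + d_xt / col_total
        used += 1
    if names is None:
        raise ValueError("no diversity metrics supplied")
    if used == 0:
        # fully degenerate cohort (e.g. all candidates agree everywhere):
        # every model is equally (un)diverse; fall back to uniform shares
        logger.warning("all diversity metrics degenerate; uniform Dci")
        total = pd.Series(len(metrics) / len(names), index=names)
        used = len(metrics)
    if scale == "normalized":
        total = total / used
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'normalized'")
    return total


def performance_metrics(pred, truth) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1, in percent.

    Macro averages run over the classes present in the truth vector;
    F1 is computed from the macro precision and recall (2PR / (P + R)),
    the convention used when composite tables report a single P and R.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("empty prediction set")
    classes = np.unique(truth)
    precisions, recalls = [], []
    for k in classes:
        tp = np.sum((pred == k) & (truth == k))
        fp = np.sum((pred == k) & (truth != k))
        fn = np.sum((pred != k) & (truth == k))
        precisions.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
    p = float(np.mean(precisions))
    r = float(np.mean(recalls))
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return {
        "accuracy": 100.0 * float(np.mean(pred == truth)),
        "precision": 100.0 * p,
        "recall": 100.0 * r,
        "f1": 100.0 * f1,
    }


def performance_composite(perf: pd.DataFrame, scale: str = "raw") -> pd.Series:
    """Performance composite index: share-normalized sum over indicators.

    ``perf`` is candidates x indicators. Each column is divided by its
    total so every indicator contributes a share, then shares are summed
    (``scale="raw"``) or averaged (``scale="normalized"``). Zero-total
    columns are skipped.
    """
    total = pd.Series(0.0, index=perf.index)
    used = 0
    for col in perf.columns:
        col_total = perf[col].sum()
        if col_total <= 0:
            logger.warning("performance indicator %s has zero total; skipped", col)
            continue
        total = total + perf[col] / col_total
        used += 1
    if used == 0:
        raise ValueError("no usable performance indicators")
    if scale == "normalized":
        total = total / used
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'normalized'")
    return total


def comprehensive_score(
    dci: pd.Series, pci: pd.Series, r: float = 0.5
) -> tuple[pd.Series, list[str]]:
    """P_x = r*Dci + (1-r)*Pci, plus the descending ranking.

    Ties are broken by higher Pci, then lexicographic model name, so the
    ranking is deterministic.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    px = r * dci + (1.0 - r) * pci
    order = sorted(px.index, key=lambda m: (-px[m], -pci[m], m))
    return px, order


@dataclass
class DiversityReport:
    """Everything produced by candidate scoring, ready to rank and export."""

    models: list[str]
    metrics: dict[str, pd.DataFrame]
    perf: pd.DataFrame
    dci: pd.Series
    pci: pd.Series
    px: pd.Series
    ranking: list[str]
    r: float = 0.5
    scale: str = "raw"
    directions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))

    def summary_frame(self) -> pd.DataFrame:
        rank = {m: i + 1 for i, m in enumerate(self.ranking)}
        return pd.DataFrame(
            {
                "Dci": self.dci,
                "Pci": self.pci,
                "P_x": self.px,
                "rank": pd.Series(rank),
            }
        ).loc[self.models]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "models": self.models,
            "r": self.r,
            "scale": self.scale,
            "directions": self.directions,
            "metrics": {m: df.where(df.notna(), None).values.tolist()
                        for m, df in self.metrics.items()},
            "perf": self.perf.to_dict(orient="index"),
            "Dci": self.dci.to_dict(),
            "Pci": self.pci.to_dict(),
            "P_x": self.px.to_dict(),
            "ranking": self.ranking,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def matrices_to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m, df in self.metrics.items():
            df.to_csv(out / f"diversity_{m}.csv")


def build_report(
    predictions: dict[str, np.ndarray],
    truth: np.ndarray,
    r: float = 0.5,
    scale: str = "raw",
    directions: dict[str, str] | None = None,
) -> DiversityReport:
    """Score a candidate cohort from its (out-of-fold) predictions."""
    if len(predictions) < 2:
        raise ValueError("need at least two candidate models")
    mats = pairwise_matrices(predictions, truth)
    perf = pd.DataFrame(
        {name: performance_metrics(p, truth) for name, p in predictions.items()}
    ).T[list(PERF_NAMES)]
    dci = diversity_composite(mats, directions=directions, scale=scale)
    pci = performance_composite(perf, scale=scale)
    px, ranking = comprehensive_score(dci, pci, r=r)
    return DiversityReport(
        models=list(predictions),
        metrics=mats,
        perf=perf,
        dci=dci,
        pci=pci,
        px=px,
        ranking=ranking,
        r=r,
        scale=scale,
        directions=dict(DEFAULT_DIRECTIONS if directions is None else directions),
    )


def select_base_learners(report: DiversityReport, k: int) -> list[str]:
    """Top-K candidates by comprehensive score."""
    if k < 1:
        raise ValueError("K must be at least 1")
    if k > len(report.models):
        raise ValueError("K exceeds the number of candidates")
    return report.ranking[:k]
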