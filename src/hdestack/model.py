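"""Model/Results interface tying the pipeline stages together.

:class:`HDEStackingModel` is constructed from a training feature table
(typically the fused morphological + spectral block); ``fit()`` runs
candidate evaluation, diversity-aware top-K selection, optional HDE
hyperparameter optimization and the final stack fit, returning an
:class:`HDEStackingResults` that carries the diversity report, tuned
hyperparameters, base weights and a ``summary()`` table, with
``predict`` / ``evaluate`` / ``explain`` hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .diversity import DiversityReport, select_base_learners
from .explain import ShapExplanation, stack_shap, summarize_background
from .hde import HDEConfig, HDEState, optimize
from .stacking import (
    StackedModel,
    cv_fitness,
    default_candidate_pool,
    evaluate_candidates,
    fit_stack,
    joint_param_space,
    split_assignment,
)


class HDEStackingModel:
    """Diversity-selected, DE-tuned stacking classifier.

    Parameters
    ----------
    train : FeatureTable
        Training data (preprocessed / fused upstream).
    candidates : list of str, optional
        Candidate pool members; defaults to LR, DT, SVM, KNN, GP, MLP.
    k_base : int
        Number of base learners kept after comprehensive-score ranking.
    r : float
        Diversity/performance blend of the comprehensive score.
    n_folds : int
        Folds for candidate evaluation and meta-feature generation.
    hde_config : HDEConfig, optional
        Optimizer settings used when ``fit(optimize=True)``.
    seed : int
        Global seed; every stage derives its randomness from it.
    """

    def __init__(
        self,
        train: FeatureTable,
        candidates: list[str] | None = None,
        k_base: int = 3,
        r: float = 0.5,
        n_folds: int = 5,
        hde_config: HDEConfig | None = None,
        seed: int = 0,
        gp_max_n: int = 400,
    ):
        self.train = train
        self.pool = default_candidate_pool(seed, gp_max_n=gp_max_n)
        self.candidates = list(self.pool) if candidates is None else list(candidates)
        self.k_base = k_base
        self.r = r
        self.n_folds = n_folds
        self.hde_config = hde_config or HDEConfig(seed=seed)
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, modality: str = "morph", **kwargs):
        return cls(FeatureTable.from_dataframe(df, modality), **kwargs)

    def fit(self, optimize_hyperparams: bool = False) -> "HDEStackingResults":
        """Evaluate candidates, rank, (optionally) optimize, fit the stack."""
        report = evaluate_candidates(
            self.train,
            pool=self.pool,
            candidates=self.candidates,
            n_folds=self.n_folds,
            seed=self.seed,
            r=self.r,
        )
        selection = select_base_learners(report, self.k_base)
        hyperparams: dict[str, dict] = {}
        hde_state: HDEState | None = None
        if optimize_hyperparams:
            space, _ = joint_param_space(self.pool, selection)
            objective = lambda genome: cv_fitness(  # noqa: E731
                selection, genome, space, self.train,
                pool=self.pool, n_folds=self.n_folds, seed=self.seed,
            )
            assignment, hde_state = optimize(objective, space, self.hde_config)
            hyperparams = split_assignment(assignment, selection)
        stack = fit_stack(
            selection, hyperparams, self.train,
            pool=self.pool, n_folds=self.n_folds, seed=self.seed,
        )
        return HDEStackingResults(
            model=self, report=report, selection=selection,
            hyperparams=hyperparams, stack=stack, hde_state=hde_state,
        )


@dataclass
class HDEStackingResults:
    """Fitted ensemble plus every diagnostic the fit produced."""

    model: HDEStackingModel
    report: DiversityReport
    selection: list[str]
    hyperparams: dict[str, dict]
    stack: StackedModel
    hde_state: HDEState | None = None

    @property
    def base_weights(self) -> pd.Series:
        return pd.Series(self.stack.base_weights, index=self.stack.base_names)

    def predict(self, X) -> np.ndarray:
        x = X.values if isinstance(X, FeatureTable) else np.asarray(X)
        return self.stack.predict(x)

    def predict_proba(self, X) -> np.ndarray:
        x = X.values if isinstance(X, FeatureTable) else np.asarray(X)
        return self.stack.predict_proba(x)

    def evaluate(self, table: FeatureTable) -> dict[str, float]:
        return self.stack.evaluate(table)

    def explain(
        self, X, background=None, n_background: int = 50, **kwargs
    ) -> ShapExplanation:
        if background is None:
            background = summarize_background(
                self.model.train, k=n_background, seed=self.model.seed
            )
        return stack_shap(self.stack, background, X, seed=self.model.seed, **kwargs)

    def summary(self) -> str:
        lines = ["HDE-Stacking results", "=" * 60]
        lines.append("Candidate ranking (comprehensive score):")
        frame = self.report.summary_frame()
        lines.append(frame.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append(f"Selected base learners (top {len(self.selection)}): "
                     + ", ".join(self.selection))
        if self.hyperparams:
            lines.append("Tuned hyperparameters:")
            for name, params in self.hyperparams.items():
                pretty = ", ".join(
                    f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                    for k, v in params.items()
                )
                lines.append(f"  {name}: {pretty}")
        if self.hde_state is not None:
            lines.append(
                f"HDE best CV fitness: {self.hde_state.f_best:.4f} "
                f"after {self.hde_state.t} generations"
            )
        lines.append("Meta-learner base weights:")
        for name, w in self.base_weights.items():
            lines.append(f"  {name}: {w:.4f}")
        return "\n".join(lines)
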