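"""End-to-end driver: simulate -> preprocess -> select -> fuse -> rank ->
optimize -> fit -> evaluate -> explain, with every artifact written to a
run directory alongside a config snapshot so the run can be replayed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .containers import FeatureTable
from .diversity import select_base_learners
from .explain import force_export, stack_shap, summarize_background, summary_export
from .hde import HDEConfig
from .model import HDEStackingModel
from .preprocess import fuse, minmax_normalize, sg_smooth, split
from .selection import boss_select, cars_select, morph_select, spa_select
from .stacking import ensemble_size_sweep
from .synthetic import SynthConfig, make_dataset

logger = logging.getLogger(__name__)

SPECTRAL_METHODS = ("SPA", "CARS", "BOSS")
MORPH_METHODS = ("MI", "RFE", "SFM")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-serializable."""

    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    sg_window: int = 11
    sg_polyorder: int = 2
    train_frac: float = 0.7
    morph_method: str = "RFE"
    morph_k: int = 15
    spectral_method: str = "SPA"
    spa_n_max: int = 30
    spa_n_starts: int | None = 10
    cars_n_mc: int = 30
    boss_n_boot: int = 10
    normalize_spectra: bool = True
    k_base: int = 3
    r: float = 0.5
    n_folds: int = 5
    optimize_hyperparams: bool = False
    hde: HDEConfig = field(default_factory=HDEConfig)
    explain_n_samples: int = 10
    explain_n_background: int = 30
    explain_n_perm: int = 5

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["synth"]["peak_centers"] = list(payload["synth"]["peak_centers"])
        payload["synth"]["valley_centers"] = list(payload["synth"]["valley_centers"])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**{
            **raw.pop("synth", {}),
        }) if "synth" in raw or True else SynthConfig()
        hde = HDEConfig(**raw.pop("hde", {}))
        return cls(synth=synth, hde=hde, **raw)


def _preset_paper(seed: int = 0) -> RunConfig:
    """Reference workflow: RFE(15) + SPA fusion, K=3, NP=20, G_max=50."""
    return RunConfig(
        seed=seed,
        morph_method="RFE",
        morph_k=15,
        spectral_method="SPA",
        k_base=3,
        optimize_hyperparams=True,
        hde=HDEConfig(np_pop=20, g_max=50, seed=seed),
    )


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.t0 = time.time()

    def stage(self, name: str, **info) -> None:
        rec = {"stage": name, "elapsed_s": round(time.time() - self.t0, 3), **info}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")
        logger.info("stage %s: %s", name, info)


def select_spectral(x, y, method: str, cfg: RunConfig, wavelengths):
    method = method.upper()
    if method == "SPA":
        return spa_select(
            x, y, n_max=cfg.spa_n_max, n_starts=cfg.spa_n_starts,
            seed=cfg.seed, wavelengths=wavelengths,
        )
    if method == "CARS":
        return cars_select(x, y, n_mc=cfg.cars_n_mc, seed=cfg.seed,
                           wavelengths=wavelengths)
    if method == "BOSS":
        return boss_select(x, y, n_boot=cfg.boss_n_boot, seed=cfg.seed,
                           wavelengths=wavelengths)
    raise ValueError(f"unknown spectral selector: {method}")


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run the full workflow; returns the final metrics dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    log = _StageLog(out / "run.jsonl")

    morph, spectra, labels = make_dataset(cfg.synth, out_dir=out / "data")
    log.stage("simulate", n_samples=int(labels.size))

    smoothed = sg_smooth(spectra, cfg.sg_window, cfg.sg_polyorder)
    spec_table = smoothed.to_feature_table(labels)
    log.stage("preprocess")

    fused_all = fuse(morph, spec_table)
    train_all, test_all = split(fused_all, cfg.train_frac, seed=cfg.seed)
    train_norm, ranges = minmax_normalize(train_all)
    test_norm, _ = minmax_normalize(test_all, ranges=ranges)
    n_morph = morph.n_features
    log.stage("split", n_train=train_norm.n_samples, n_test=test_norm.n_samples)

    # selection runs on training rows only
    morph_train = train_norm.take_features(np.arange(n_morph))
    spec_train = train_norm.take_features(np.arange(n_morph, fused_all.n_features))
    morph_sel = morph_select(morph_train, cfg.morph_method, k=cfg.morph_k,
                             seed=cfg.seed)
    morph_sel.to_json(out / "selection_morph.json")
    spec_sel = select_spectral(
        spec_train.values, spec_train.labels, cfg.spectral_method, cfg,
        smoothed.wavelengths,
    )
    spec_sel.to_json(out / "selection_spectral.json")
    log.stage("select", morph=morph_sel.n_selected, spectral=spec_sel.n_selected)

    keep = np.concatenate([morph_sel.selected_indices,
                           n_morph + spec_sel.selected_indices])
    train = train_norm.take_features(keep)
    test = test_norm.take_features(keep)
    log.stage("fuse", n_features=train.n_features)

    model = HDEStackingModel(
        train, k_base=cfg.k_base, r=cfg.r, n_folds=cfg.n_folds,
        hde_config=cfg.hde, seed=cfg.seed,
    )
    results = model.fit(optimize_hyperparams=cfg.optimize_hyperparams)
    if results.hde_state is not None:
        st = results.hde_state
        with (out / "hde_trace.jsonl").open("w") as fh:
            for g, (fb, f_t, cr_t, strat, c_t, d_t) in enumerate(
                zip(st.trace[1:], st.f_trace, st.cr_trace,
                    st.strategy_trace, st.c_trace, st.d_trace),
                start=1,
            ):
                fh.write(json.dumps({
                    "generation": g, "best_fitness": fb, "F": f_t, "CR": cr_t,
                    "strategy": strat, "c_t": c_t, "diversity": d_t,
                }) + "\n")
    results.report.to_json(out / "diversity_report.json")
    results.report.matrices_to_csv(out / "diversity_matrices")
    results.report.summary_frame().to_csv(out / "candidate_ranking.csv")
    log.stage("rank", selection=results.selection)

    sweep = ensemble_size_sweep(
        results.report, train, test, hyperparams=results.hyperparams,
        pool=model.pool, n_folds=cfg.n_folds, seed=cfg.seed,
    )
    sweep.to_csv(out / "ensemble_size_sweep.csv")
    metrics = results.evaluate(test)
    (out / "metrics.json").write_text(json.dumps(
        {"test": metrics,
         "selection": results.selection,
         "hyperparams": results.hyperparams,
         "base_weights": {n: float(w) for n, w in results.base_weights.items()}},
        indent=2,
    ))
    (out / "summary.txt").write_text(results.summary() + "\n")
    log.stage("evaluate", **{k: round(v, 2) for k, v in metrics.items()})

    bg = summarize_background(train, k=cfg.explain_n_background, seed=cfg.seed)
    xs = test.values[: cfg.explain_n_samples]
    expl = stack_shap(results.stack, bg, xs, mode="sampling",
                      n_perm=cfg.explain_n_perm, seed=cfg.seed)
    pred = results.stack.predict(xs)
    class_idx = np.searchsorted(results.stack.classes, pred)
    ranking, _ = summary_export(expl, X=xs, class_index=class_idx,
                                path=out / "shap_summary.csv")
    force = force_export(expl, 0, int(class_idx[0]), path=out / "shap_force_s0.csv")
    log.stage("explain", top_feature=str(ranking.iloc[0]["feature"]),
              base_value=round(force["base_value"], 4), fx=round(force["fx"], 4))
    return metrics


def report(run_dir: str | Path) -> str:
    """Collate a run directory into a human-readable markdown report."""
    run = Path(run_dir)
    lines = [f"# Run report: {run}", ""]
    warn = []
    metrics_file = run / "metrics.json"
    if metrics_file.exists():
        payload = json.loads(metrics_file.read_text())
        lines.append("## Test metrics")
        for k, v in payload["test"].items():
            lines.append(f"- {k}: {v:.2f}%")
        lines.append("")
        lines.append("## Base learners: " + ", ".join(payload["selection"]))
        lines.append("")
        lines.append("## Base weights")
        for n, w in payload["base_weights"].items():
            lines.append(f"- {n}: {w:.4f}")
        lines.append("")
    else:
        warn.append("metrics.json missing — incomplete run")
    ranking_file = run / "candidate_ranking.csv"
    if ranking_file.exists():
        lines.append("## Candidate ranking")
        lines.append("")
        lines.append("```")
        lines.append(ranking_file.read_text().strip())
        lines.append("```")
        lines.append("")
    else:
        warn.append("candidate_ranking.csv missing")
    sweep_file = run / "ensemble_size_sweep.csv"
    if sweep_file.exists():
        lines.append("## Ensemble-size sweep")
        lines.append("")
        lines.append("```")
        lines.append(sweep_file.read_text().strip())
        lines.append("```")
        lines.append("")
    shap_file = run / "shap_summary.csv"
    if shap_file.exists():
        lines.append("## Top features by mean |SHAP|")
        lines.append("")
        lines.append("```")
        lines.append("\n".join(shap_file.read_text().strip().splitlines()[:11]))
        lines.append("```")
        lines.append("")
    if warn:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in warn)
    text = "\n".join(lines)
    (run / "report.md").write_text(text)
    return text
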