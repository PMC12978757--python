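"""Experiment harness: repeated 80:20 evaluation, CV model selection,
sensitivity sweep and ablation.

Per seed the protocol is: stratified 80:20 split; optional 5-fold CV on the
training side over a hyperparameter grid (subspace ratio gamma, mixing
coefficient alpha_mse, kernel weight alpha_kernel); refit of the best
configuration on the full training side; metrics on the untouched test
side.  A one-point grid skips the CV and fits exactly once.

The sensitivity sweep varies gamma and alpha_mse only — neither touches the
normalization, partitioning, selection or fusion stages — so those stages
are fitted once per seed and shared across all grid cells.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import subspace_ensemble as ens_mod
from .data_io import DataMatrix, apply_minmax, fit_minmax, stratified_split
from .metrics import MetricsReport, evaluate, macro_metrics, roc_auc
from .pipeline import ISSBECPipeline, PipelineConfig


@dataclass
class SeedResult:
    seed: int
    report: MetricsReport | None       # binary tasks
    macro: dict[str, float]
    auc: float | None
    chosen: dict[str, float]
    test_indices: np.ndarray


@dataclass
class ExperimentResult:
    per_seed: list[SeedResult]
    mean: dict[str, float]
    sd: dict[str, float]
    config: PipelineConfig

    @property
    def mean_accuracy(self) -> float:
        return self.mean["accuracy"]


@dataclass
class SensitivityGrid:
    gamma_values: list[float]
    alpha_values: list[float]
    accuracy_surface: np.ndarray   # |gamma| x |alpha|

    @property
    def spread(self) -> float:
        return float(self.accuracy_surface.max() - self.accuracy_surface.min())


def default_cv_grid() -> list[dict[str, float]]:
    return [
        {"subspace_ratio": g, "alpha_mse": a}
        for g in (0.2, 0.4, 0.6, 0.8)
        for a in (0.25, 0.5, 0.75)
    ]


def _apply_point(config: PipelineConfig, point: dict[str, float]) -> PipelineConfig:
    cfg = copy.deepcopy(config)
    ens_kwargs = {}
    for key, val in point.items():
        if key in ("subspace_ratio", "alpha_mse", "overlap_coeff"):
            ens_kwargs[key] = val
        elif key == "alpha_kernel":
            cfg.idfc.kernel = replace(cfg.idfc.kernel, alpha_kernel=val)
        elif key == "alpha_rank":
            cfg.mrfe = replace(cfg.mrfe, alpha_rank=val)
        else:
            raise ValueError(f"unknown grid parameter {key!r}")
    if ens_kwargs:
        cfg.ensemble = replace(cfg.ensemble, **ens_kwargs)
    return cfg


def _positive_label(classes: np.ndarray):
    return sorted(classes.tolist())[-1]


def _evaluate_fit(pipe: ISSBECPipeline, test: DataMatrix) -> SeedResult:
    pred, fractions = pipe.predict(test)
    classes = pipe.classes_
    macro = macro_metrics(test.labels, pred)
    report = None
    auc = None
    if classes.size == 2:
        pos = _positive_label(classes)
        report = evaluate(test.labels, pred, pos)
        pos_col = int(np.where(classes == pos)[0][0])
        if len(np.unique(test.labels)) == 2:
            _, auc = roc_auc(test.labels, fractions[:, pos_col], pos)
    return SeedResult(seed=-1, report=report, macro=macro, auc=auc,
                      chosen={}, test_indices=np.array([], int))


def _cv_select(train: DataMatrix, config: PipelineConfig,
               grid: list[dict[str, float]], folds: int,
               seed: int) -> dict[str, float]:
    if len(grid) == 1:
        return grid[0]
    from sklearn.model_selection import StratifiedKFold

    _, counts = np.unique(train.labels, return_counts=True)
    folds = min(folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_point, best_acc = grid[0], -1.0
    for point in grid:
        accs = []
        for tr, va in skf.split(train.values, train.labels):
            cfg = _apply_point(config, point).with_seed(seed)
            pipe = ISSBECPipeline(cfg).fit(train.subset_rows(tr))
            pred, _ = pipe.predict(train.subset_rows(va))
            accs.append(float(np.mean(pred == train.labels[va])))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_point = acc, point
    return best_point


def run_experiment(data: DataMatrix, config: PipelineConfig,
                   seeds: list[int],
                   cv_grid: list[dict[str, float]] | None = None,
                   cv_folds: int = 5) -> ExperimentResult:
    """Repeated 80:20 evaluation with per-seed CV hyperparameter choice."""
    if cv_grid is not None and not cv_grid:
        raise ValueError("cv_grid must not be empty")
    grid = cv_grid if cv_grid is not None else default_cv_grid()
    per_seed: list[SeedResult] = []
    for seed in seeds:
        work = data
        if config.normalize_before_split:
            work = apply_minmax(fit_minmax(data), data)
        split = stratified_split(work, ratio=0.8, seed=seed)
        train = work.subset_rows(split.train_indices)
        test = work.subset_rows(split.test_indices)
        point = _cv_select(train, config, grid, cv_folds, seed)
        cfg = _apply_point(config, point).with_seed(seed)
        pipe = ISSBECPipeline(cfg).fit(train)
        res = _evaluate_fit(pipe, test)
        res.seed = seed
        res.chosen = dict(point)
        res.test_indices = split.test_indices
        per_seed.append(res)
    keys = per_seed[0].macro.keys()
    mean = {k: float(np.mean([r.macro[k] for r in per_seed])) for k in keys}
    sd = {k: float(np.std([r.macro[k] for r in per_seed])) for k in keys}
    aucs = [r.auc for r in per_seed if r.auc is not None]
    if aucs:
        mean["auc"] = float(np.mean(aucs))
        sd["auc"] = float(np.std(aucs))
    return ExperimentResult(per_seed=per_seed, mean=mean, sd=sd, config=config)


def sensitivity_sweep(data: DataMatrix, config: PipelineConfig,
                      gamma_grid: list[float], alpha_grid: list[float],
                      seeds: list[int]) -> SensitivityGrid:
    """Mean test accuracy per (gamma, alpha_mse) cell over seeds.

    Upstream stages (normalize, partition, select, fuse) are fitted once
    per seed and shared: gamma and alpha_mse only affect the ensemble.
    """
    if not gamma_grid or not alpha_grid:
        raise ValueError("grids must be non-empty")
    surface = np.zeros((len(gamma_grid), len(alpha_grid)))
    for seed in seeds:
        split = stratified_split(data, ratio=0.8, seed=seed)
        train = data.subset_rows(split.train_indices)
        test = data.subset_rows(split.test_indices)
        base = ISSBECPipeline(config.with_seed(seed)).fit(train)
        Xtr = base.transform_inputs(train)
        Xte = base.transform_inputs(test)
        for i, g in enumerate(gamma_grid):
            for j, a in enumerate(alpha_grid):
                ecfg = replace(base.config.ensemble, subspace_ratio=g, alpha_mse=a)
                model = ens_mod.fit_ensemble(Xtr, train.labels, ecfg)
                pred, _ = ens_mod.predict(model, Xte)
                surface[i, j] += float(np.mean(pred == test.labels))
    surface /= len(seeds)
    return SensitivityGrid(gamma_values=list(gamma_grid),
                           alpha_values=list(alpha_grid),
                           accuracy_surface=surface)


ABLATION_VARIANTS = ("issbec", "conventional_dfc", "conventional_rfe")


def ablation(data: DataMatrix, config: PipelineConfig,
             seeds: list[int]) -> dict[str, ExperimentResult]:
    """Full model vs single-Gaussian-kernel partitioning vs margin-only RFE.

    All variants share identical splits and seeds for paired comparison.
    """
    variants = {
        "issbec": config,
        "conventional_dfc": _apply_point(config, {"alpha_kernel": 1.0}),
        "conventional_rfe": _apply_point(config, {"alpha_rank": 1.0}),
    }
    out = {}
    for name, cfg in variants.items():
        out[name] = run_experiment(
            data, cfg, seeds, cv_grid=[{"subspace_ratio": cfg.ensemble.subspace_ratio,
                                        "alpha_mse": cfg.ensemble.alpha_mse}]
        )
    return out
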