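"""End-to-end pipeline: normalize -> partition -> select -> fuse -> ensemble.

The distributed master/slave topology the method was designed around is
abstracted to a backend-agnostic ``parallel_map`` over independent, seeded
tasks: the per-partition feature-selection stage (the parallelizable part)
runs either serially or in a process pool, with results guaranteed
identical to sequential execution in task order.
"""

from __future__ import annotations

import concurrent.futures
import json
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from . import idfc as idfc_mod
from . import svm_mrfe as mrfe_mod
from . import subspace_ensemble as ens_mod
from .data_io import (
    DataMatrix,
    NormalizationParams,
    apply_minmax,
    fit_minmax,
)


@dataclass
class PipelineConfig:
    idfc: idfc_mod.IDFCConfig = field(default_factory=idfc_mod.IDFCConfig)
    mrfe: mrfe_mod.MRFEConfig = field(default_factory=mrfe_mod.MRFEConfig)
    ensemble: ens_mod.EnsembleConfig = field(default_factory=ens_mod.EnsembleConfig)
    normalize_before_split: bool = False
    backend: str = "serial"            # or "process_parallel"
    workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("serial", "process_parallel"):
            raise ValueError(f"unknown backend {self.backend!r}")

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-derive all module seeds deterministically from a master seed."""
        ss = np.random.SeedSequence(seed).generate_state(4) % (2**31 - 1)
        return replace(
            self,
            seed=seed,
            idfc=replace(self.idfc, seed=int(ss[0])),
            mrfe=replace(self.mrfe, seed=int(ss[1])),
            ensemble=replace(self.ensemble, seed=int(ss[2])),
        )


def _run_task(payload):
    func, args = payload
    return func(*args)


def parallel_map(func, tasks, backend: str = "serial", workers: int = 1):
    """Map ``func`` over ``tasks`` (tuples of args), preserving task order.

    Results are identical to sequential execution regardless of backend or
    worker count.  A crashed worker task is retried once, then the whole
    map aborts naming the task.
    """
    tasks = list(tasks)
    if not tasks:
        return []
    if backend == "serial" or workers <= 1:
        return [func(*args) for args in tasks]
    payloads = [(func, args) for args in tasks]
    results = [None] * len(tasks)
    with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as pool:
        futures = {pool.submit(_run_task, p): i for i, p in enumerate(payloads)}
        for fut in concurrent.futures.as_completed(futures):
            i = futures[fut]
            try:
                results[i] = fut.result()
            except Exception:
                try:  # one retry, in-process (worker may have died)
                    results[i] = _run_task(payloads[i])
                except Exception as exc:
                    raise RuntimeError(f"task {i} failed twice: {exc}") from exc
    return results


def _select_partition(values, labels, config, partition_id):
    return mrfe_mod.mrfe_select(values, labels, config, partition_id=partition_id)


class ISSBECPipeline:
    """Fitted state of the full stack; sklearn-style fit/predict."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.norm_: NormalizationParams | None = None
        self.partitions_: idfc_mod.PartitionSet | None = None
        self.fuzzy_state_: idfc_mod.FuzzyState | None = None
        self.selections_: list[mrfe_mod.SelectedFeatures] | None = None
        self.fused_: mrfe_mod.FusedFeatures | None = None
        self.ensemble_: ens_mod.EnsembleModel | None = None
        self.feature_names_: list[str] | None = None
        self.timings_: dict[str, float] = {}

    # -- fitting ---------------------------------------------------------

    def fit(self, X: DataMatrix) -> "ISSBECPipeline":
        cfg = self.config
        t0 = time.perf_counter()
        self.feature_names_ = list(X.feature_names)

        self.norm_ = fit_minmax(X)
        Xn = apply_minmax(self.norm_, X)
        self.timings_["normalize"] = time.perf_counter() - t0

        t1 = time.perf_counter()
        _, state, parts = idfc_mod.fit_idfc(Xn, cfg.idfc)
        self.fuzzy_state_ = state
        self.partitions_ = parts
        self.timings_["partition"] = time.perf_counter() - t1

        t2 = time.perf_counter()
        tasks = [
            (Xn.values[p], Xn.labels[p], cfg.mrfe, pid)
            for pid, p in enumerate(parts.partitions)
        ]
        self.selections_ = parallel_map(
            _select_partition, tasks, backend=cfg.backend, workers=cfg.workers
        )
        self.fused_ = mrfe_mod.fuse_features(self.selections_)
        self.timings_["select"] = time.perf_counter() - t2

        t3 = time.perf_counter()
        self.ensemble_ = ens_mod.fit_ensemble(
            Xn.values[:, self.fused_.indices], Xn.labels, cfg.ensemble
        )
        self.timings_["train"] = time.perf_counter() - t3
        return self

    # -- prediction ------------------------------------------------------

    def _check_fitted(self):
        if self.ensemble_ is None:
            raise RuntimeError("pipeline is not fitted")

    def transform_inputs(self, X: DataMatrix | np.ndarray) -> np.ndarray:
        self._check_fitted()
        Xn = apply_minmax(self.norm_, X)
        values = Xn.values if isinstance(Xn, DataMatrix) else Xn
        return values[:, self.fused_.indices]

    def predict(self, X: DataMatrix | np.ndarray):
        """Returns (labels, per-class vote fractions)."""
        return ens_mod.predict(self.ensemble_, self.transform_inputs(X))

    @property
    def classes_(self) -> np.ndarray:
        self._check_fitted()
        return self.ensemble_.classes

    # -- artifacts -------------------------------------------------------

    def write_artifacts(self, out_dir: str | Path, X: DataMatrix | None = None):
        """Write intermediate artifacts + a run manifest as plain text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self._check_fitted()
        self.norm_.save(out / "normalization.json")
        if X is not None:
            lines = ["sample_id\tpartition_id"] + [
                f"{sid}\t{pid}"
                for sid, pid in zip(X.sample_ids, self.partitions_.assignment)
            ]
            (out / "partitions.tsv").write_text("\n".join(lines) + "\n")
        loss = self.fuzzy_state_.loss_trajectory
        (out / "idfc_loss.csv").write_text(
            "step,loss\n" + "\n".join(f"{i},{v}" for i, v in enumerate(loss)) + "\n"
        )
        for sel in self.selections_:
            rows = ["feature_name,original_index"]
            for idx in sel.kept_indices:
                rows.append(f"{self.feature_names_[idx]},{idx}")
            (out / f"selected_partition{sel.partition_id}.csv").write_text(
                "\n".join(rows) + "\n"
            )
            trace = ["iteration,dropped_indices"]
            trace += [f"{it},{';'.join(map(str, dropped))}"
                      for it, dropped in sel.elimination_trace]
            (out / f"elimination_trace_partition{sel.partition_id}.csv").write_text(
                "\n".join(trace) + "\n"
            )
        rows = ["feature_name,original_index,partitions"]
        for idx in self.fused_.indices:
            parts = ";".join(str(p) for p in sorted(self.fused_.provenance[idx]))
            rows.append(f"{self.feature_names_[idx]},{idx},{parts}")
        (out / "fused_features.csv").write_text("\n".join(rows) + "\n")
        manifest = {
            "seed": self.config.seed,
            "backend": self.config.backend,
            "n_fused_features": len(self.fused_.indices),
            "n_partitions": len(self.partitions_.partitions),
            "timings_s": {k: round(v, 3) for k, v in self.timings_.items()},
            "config": _config_snapshot(self.config),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    return json.loads(json.dumps(snap, default=str))


def run_pipeline(data: DataMatrix, config: PipelineConfig,
                 out_dir: str | Path | None = None) -> ISSBECPipeline:
    """Fit the full stack on ``data``; optionally write artifacts."""
    pipe = ISSBECPipeline(config.with_seed(config.seed)).fit(data)
    if out_dir is not None:
        pipe.write_artifacts(out_dir, X=data)
    return pipe
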