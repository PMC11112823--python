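"""Model/Results interface over the full benchmark protocol.

:class:`MolecularPropertyModel` is built from a molecules-by-property table
and a :class:`~molfuse.data_splits.TaskSpec`; :meth:`fit` executes the whole
experimental loop — Bemis-Murcko scaffold split (80/10/10), k-fold ensemble
training on the train+validation pool, per-fold test metrics — and returns a
:class:`MolecularPropertyResults` carrying the per-fold metrics, the ensemble
mean ± std, and diagnostics. Ablation refits and significance comparisons
hang off the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_splits import (Dataset, SplitAssignment, TaskSpec,
                          kfold_ensemble_splits, read_dataset, scaffold_split)
from .evaluation import (EnsembleResult, SignificanceReport,
                         aggregate_ensemble, compute_metric, format_mean_std,
                         significance_test)
from .exceptions import ModeError
from .fusion import (ArchConfig, FusionModel, Mode, PreparedMolecule,
                     prepare_molecule)
from .molgraph import DEFAULT_SCHEMA, FeatureSchema
from .tokenization import TokenizerSpec, default_tokenizer_spec
from .training import TrainConfig, TrainResult, predict, train_model

__all__ = ["MolecularPropertyModel", "MolecularPropertyResults"]


class MolecularPropertyModel:
    """A fused language+graph property model bound to a dataset.

    Parameters
    ----------
    data
        DataFrame (or :class:`Dataset`) with the task's SMILES and label
        columns.
    task
        Task definition (regression/classification, loss, selection metric).
    mode
        "fused", "graph", or "language".
    arch
        Architecture hyperparameters; defaults are full-size, tests pass
        smaller ones.
    """

    def __init__(self, data, task: TaskSpec, mode: Mode | str = Mode.FUSED,
                 arch: ArchConfig | None = None,
                 schema: FeatureSchema = DEFAULT_SCHEMA,
                 tokenizer: TokenizerSpec | None = None):
        self.task = task
        self.mode = Mode(mode)
        self.arch = arch or ArchConfig()
        self.schema = schema
        self.tokenizer = tokenizer or default_tokenizer_spec()
        self.dataset: Dataset = (data if isinstance(data, Dataset)
                                 else read_dataset(data, task))
        self._prepared: list[PreparedMolecule] | None = None

    @classmethod
    def from_csv(cls, path, task: TaskSpec, **kwargs
                 ) -> "MolecularPropertyModel":
        return cls(read_dataset(path, task), task, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, task: TaskSpec, **kwargs
                       ) -> "MolecularPropertyModel":
        return cls(frame, task, **kwargs)

    # ------------------------------------------------------------------
    def _prepare_all(self) -> list[PreparedMolecule]:
        if self._prepared is None:
            frame = self.dataset.frame
            self._prepared = [
                prepare_molecule(smi, self.schema, self.tokenizer,
                                 label=float(lab))
                for smi, lab in zip(frame["smiles"], frame["label"])]
        return self._prepared

    def _build_net(self, seed: int) -> FusionModel:
        return FusionModel(task=self.task, d_node=self.schema.d_node,
                           mode=self.mode, arch=self.arch,
                           vocab_size=len(self.tokenizer.vocabulary),
                           d_edge=self.schema.d_edge, seed=seed,
                           max_len=self.tokenizer.max_length)

    def fit(self, k: int = 10, config: TrainConfig | None = None,
            seed: int = 0,
            fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
            split: SplitAssignment | None = None,
            folds: list | None = None) -> "MolecularPropertyResults":
        """Scaffold split, k-fold ensemble training, per-fold test metrics.

        ``split`` and ``folds`` may be supplied to reuse a previous run's
        partitioning verbatim (ablation protocol).
        """
        config = config or TrainConfig(seed=seed)
        records = self._prepare_all()
        if split is None:
            split = scaffold_split(self.dataset, fractions)
        if folds is None:
            folds = kfold_ensemble_splits(list(split.trainval), k, seed)
        if len(folds) != k:
            raise ModeError(f"supplied folds have k={len(folds)}, asked {k}")
        test_records = [records[i] for i in split.test]
        test_labels = np.asarray([r.label for r in test_records])
        pad_id = self.tokenizer.pad_id

        fold_results: list[TrainResult] = []
        per_fold_metric: list[float] = []
        per_fold_predictions: list[np.ndarray] = []
        for fold_id, (tr_idx, va_idx) in enumerate(folds):
            net = self._build_net(seed=seed + fold_id)
            fold_config = replace(config, seed=config.seed + fold_id)
            result = train_model(net,
                                 [records[i] for i in tr_idx],
                                 [records[i] for i in va_idx],
                                 fold_config, pad_id)
            preds = predict(net, test_records, pad_id,
                            target_mean=result.target_mean,
                            target_std=result.target_std)
            metric = compute_metric(preds, test_labels,
                                    self.task.selection_metric)
            fold_results.append(result)
            per_fold_metric.append(metric)
            per_fold_predictions.append(preds)

        ensemble = aggregate_ensemble(per_fold_metric,
                                      task_name=self.task.name,
                                      metric_name=self.task.selection_metric)
        return MolecularPropertyResults(
            model=self, ensemble=ensemble, fold_results=fold_results,
            split=split, folds=folds, config=config, seed=seed, k=k,
            test_predictions=np.asarray(per_fold_predictions),
            test_labels=test_labels)


@dataclass
class MolecularPropertyResults:
    """Fit results: per-fold models/metrics and the ensemble summary."""

    model: MolecularPropertyModel
    ensemble: EnsembleResult
    fold_results: list[TrainResult]
    split: SplitAssignment
    folds: list
    config: TrainConfig
    seed: int
    k: int
    test_predictions: np.ndarray      # [k, n_test]
    test_labels: np.ndarray

    @property
    def per_model_metrics(self) -> tuple[float, ...]:
        return self.ensemble.per_model_metrics

    @property
    def mean(self) -> float:
        return self.ensemble.mean

    @property
    def std(self) -> float:
        return self.ensemble.std

    def metrics_frame(self) -> pd.DataFrame:
        rows = [(i, m, r.best_epoch, r.best_metric)
                for i, (m, r) in enumerate(zip(self.per_model_metrics,
                                               self.fold_results))]
        return pd.DataFrame(rows, columns=["fold", "test_metric",
                                           "best_epoch", "valid_metric"])

    def summary(self) -> str:
        task = self.model.task
        split_sizes = (len(self.split.train), len(self.split.valid),
                       len(self.split.test))
        lines = [
            "Molecular property ensemble fit",
            "=" * 47,
            f"Task:            {task.name} ({task.task_type})",
            f"Mode:            {self.model.mode.value}",
            f"GNN:             {self.model.arch.gnn_type}",
            f"N molecules:     {len(self.model.dataset)}",
            f"Scaffold split:  {split_sizes} (train/valid/test)",
            f"Ensemble:        k={self.k}, epochs={self.config.epochs}, "
            f"batch={self.config.batch_size}",
            f"Test {task.selection_metric}: "
            f"{format_mean_std(self.mean, self.std)}",
            "-" * 47,
            "Per-fold test metrics:",
        ]
        for i, m in enumerate(self.per_model_metrics):
            lines.append(f"  fold {i}: {m:.4f}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def refit_ablated(self, mode: Mode | str) -> "MolecularPropertyResults":
        """Retrain with one branch removed, reusing splits, folds,
        hyperparameters and seeds verbatim."""
        mode = Mode(mode)
        if mode is Mode.FUSED:
            raise ModeError("ablation removes a branch; FUSED removes none")
        donor = self.model
        ablated = MolecularPropertyModel(
            donor.dataset, donor.task, mode=mode, arch=donor.arch,
            schema=donor.schema, tokenizer=donor.tokenizer)
        return ablated.fit(k=self.k, config=self.config, seed=self.seed,
                           split=self.split, folds=self.folds)

    def compare_to(self, mean: float, std: float, n: int
                   ) -> SignificanceReport:
        """Welch t-test of this ensemble against an external summary
        (mean, std, n) — e.g. a literature baseline."""
        better = self.model.task.selection_direction
        return significance_test(self.mean, self.std, self.k,
                                 mean, std, n, better=better)

    def save(self, run_dir: str | Path) -> dict:
        """Persist metrics, split manifest, histories, predictions, weights.

        Returns a manifest dict of the written paths.
        """
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"run_dir": str(run_dir)}

        metrics_path = run_dir / "fold_metrics.csv"
        self.metrics_frame().to_csv(metrics_path, index=False,
                                    float_format="%.10g")
        manifest["metrics_csv"] = str(metrics_path)

        split_path = run_dir / "split_manifest.csv"
        frame = self.split.to_frame()
        fold_of = {}
        for fold_id, (_, va) in enumerate(self.folds):
            for i in va:
                fold_of[i] = fold_id
        frame["fold"] = [fold_of.get(i, -1) for i in frame["record"]]
        frame.to_csv(split_path, index=False)
        manifest["split_csv"] = str(split_path)

        pred_path = run_dir / "test_predictions.csv"
        pred = pd.DataFrame(self.test_predictions.T,
                            columns=[f"fold{i}" for i in range(self.k)])
        pred.insert(0, "record", list(self.split.test))
        pred["label"] = self.test_labels
        pred.to_csv(pred_path, index=False, float_format="%.10g")
        manifest["predictions_csv"] = str(pred_path)

        ckpt_dir = run_dir / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        ckpts = []
        for i, r in enumerate(self.fold_results):
            path = ckpt_dir / f"fold{i}.npz"
            np.savez(path, **r.model.state_dict())
            sidecar = ckpt_dir / f"fold{i}.json"
            sidecar.write_text(json.dumps({
                "task": self.model.task.to_dict(),
                "mode": self.model.mode.value,
                "arch": self.model.arch.to_dict(),
                "schema": self.model.schema.to_dict(),
                "target_mean": r.target_mean,
                "target_std": r.target_std,
            }, indent=1))
            ckpts.append(str(path))
            hist_path = ckpt_dir / f"fold{i}_history.csv"
            r.history.to_csv(hist_path, index=False, float_format="%.10g")
        manifest["checkpoints"] = ckpts

        config_path = run_dir / "config.json"
        config_path.write_text(json.dumps({
            "task": self.model.task.to_dict(),
            "mode": self.model.mode.value,
            "arch": self.model.arch.to_dict(),
            "train": self.config.to_dict(),
            "k": self.k, "seed": self.seed,
            "ensemble": {"mean": self.mean, "std": self.std,
                         "metric": self.model.task.selection_metric},
        }, indent=1))
        manifest["config"] = str(config_path)
        (run_dir / "report.txt").write_text(self.summary() + "\n")
        manifest["report"] = str(run_dir / "report.txt")
        return manifest
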