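"""Dataset ingestion, Bemis-Murcko scaffold splitting, and k-fold ensembling.

The scaffold split groups molecules by their Bemis-Murcko scaffold (ring
systems plus linkers, side chains removed; acyclic molecules share the empty
scaffold and therefore travel together), orders groups by size descending with
a lexicographic tie-break on the scaffold SMILES, and assigns whole groups
greedily: train until its quota is reached, then validation, remainder to
test. This keeps every scaffold inside a single partition so the test set
probes generalization to unseen chemotypes. Ensembles are built by randomly
k-fold splitting the train+validation pool; the test set never enters a fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .exceptions import (DomainError, EmptyDatasetError, FormatError,
                         SplitError)
from .molgraph import parse_smiles
from .exceptions import MolfuseError

logger = logging.getLogger(__name__)

__all__ = ["TaskSpec", "Dataset", "SplitAssignment", "bemis_murcko_scaffold",
           "read_dataset", "scaffold_split", "kfold_ensemble_splits"]

_LOSS_FOR_TASK = {"regression": ("rmse", "mae"), "classification": ("bce",)}
_METRIC_DIRECTION = {"rmse": "min", "mae": "min", "roc_auc": "max"}


@dataclass(frozen=True)
class TaskSpec:
    """Task definition: columns, loss, and model-selection metric.

    Defaults follow the benchmark conventions: regression trains and selects
    on RMSE (MAE available), classification trains on BCE and selects on
    ROC-AUC (maximized).
    """

    name: str
    task_type: str                       # "regression" | "classification"
    smiles_column: str = "smiles"
    label_column: str = "label"
    training_loss: str | None = None
    selection_metric: str | None = None

    def __post_init__(self):
        if self.task_type not in ("regression", "classification"):
            raise FormatError(f"unknown task_type {self.task_type!r}")
        loss = self.training_loss or (
            "rmse" if self.task_type == "regression" else "bce")
        if loss not in _LOSS_FOR_TASK[self.task_type]:
            raise FormatError(
                f"loss {loss!r} invalid for {self.task_type} task")
        metric = self.selection_metric or (
            loss if self.task_type == "regression" else "roc_auc")
        if metric not in _METRIC_DIRECTION:
            raise FormatError(f"unknown selection metric {metric!r}")
        object.__setattr__(self, "training_loss", loss)
        object.__setattr__(self, "selection_metric", metric)

    @property
    def selection_direction(self) -> str:
        return _METRIC_DIRECTION[self.selection_metric]

    def to_dict(self) -> dict:
        return dict(name=self.name, task_type=self.task_type,
                    smiles_column=self.smiles_column,
                    label_column=self.label_column,
                    training_loss=self.training_loss,
                    selection_metric=self.selection_metric)


@dataclass(frozen=True)
class Dataset:
    """Usable records (0-based index) plus the count of dropped rows."""

    frame: pd.DataFrame                  # columns: smiles, label
    task: TaskSpec
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def smiles(self) -> list[str]:
        return self.frame["smiles"].tolist()

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=np.float64)


@dataclass(frozen=True)
class SplitAssignment:
    train: tuple[int, ...]
    valid: tuple[int, ...]
    test: tuple[int, ...]
    scaffold_of: dict[int, str] = field(default_factory=dict)

    @property
    def trainval(self) -> tuple[int, ...]:
        return self.train + self.valid

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for part, idxs in (("train", self.train), ("valid", self.valid),
                           ("test", self.test)):
            for i in idxs:
                rows.append((i, part, self.scaffold_of.get(i, "")))
        return (pd.DataFrame(rows, columns=["record", "partition", "scaffold"])
                .sort_values("record").reset_index(drop=True))


def bemis_murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES ("" for acyclic molecules)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MolfuseError(f"invalid SMILES for scaffold: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def read_dataset(source: str | Path | pd.DataFrame,
                 task: TaskSpec) -> Dataset:
    """Load a MoleculeNet-style CSV (or DataFrame) into a :class:`Dataset`.

    Rows with unparseable SMILES or missing labels are dropped (count logged);
    classification labels must lie in {0, 1}.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) \
        else pd.read_csv(source)
    for col in (task.smiles_column, task.label_column):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r}")
    frame = df[[task.smiles_column, task.label_column]].rename(
        columns={task.smiles_column: "smiles", task.label_column: "label"})
    n_before = len(frame)
    frame = frame.dropna()
    keep = []
    for smi in frame["smiles"]:
        try:
            parse_smiles(str(smi))
            keep.append(True)
        except MolfuseError:
            keep.append(False)
    frame = frame[np.asarray(keep, dtype=bool)]
    n_dropped = n_before - len(frame)
    if n_dropped:
        logger.info("dropped %d unusable rows", n_dropped)
    if len(frame) == 0:
        raise EmptyDatasetError("no usable records")
    labels = pd.to_numeric(frame["label"], errors="coerce")
    if labels.isna().any():
        raise FormatError("non-numeric labels present")
    if task.task_type == "classification":
        bad = ~labels.isin([0, 1])
        if bad.any():
            raise FormatError(
                f"classification labels outside {{0,1}}: "
                f"{sorted(labels[bad].unique().tolist())}")
    frame = frame.assign(label=labels.to_numpy(dtype=np.float64))
    frame = frame.reset_index(drop=True)
    return Dataset(frame=frame, task=task, n_dropped=n_dropped)


def scaffold_split(ds: Dataset,
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
                   ) -> SplitAssignment:
    """Deterministic greedy Bemis-Murcko scaffold split.

    Scaffold groups are ordered by (size descending, scaffold SMILES
    ascending) and assigned whole to train until |train| >= f_train*N, then to
    validation until |valid| >= f_valid*N, remainder to test.
    """
    f_train, f_valid, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError(f"fractions must be positive and sum to 1, got "
                         f"{fractions}")
    n = len(ds)
    scaffold_of = {i: bemis_murcko_scaffold(smi)
                   for i, smi in enumerate(ds.smiles)}
    groups: dict[str, list[int]] = {}
    for i, key in scaffold_of.items():
        groups.setdefault(key, []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for _, members in ordered:
        if len(train) < f_train * n:
            train.extend(members)
        elif len(valid) < f_valid * n:
            valid.extend(members)
        else:
            test.extend(members)
    if not train or not valid or not test:
        raise SplitError(
            f"empty partition: sizes {(len(train), len(valid), len(test))}")
    return SplitAssignment(train=tuple(train), valid=tuple(valid),
                           test=tuple(test), scaffold_of=scaffold_of)


def kfold_ensemble_splits(trainval: list[int] | tuple[int, ...], k: int,
                          seed: int) -> list[tuple[tuple[int, ...],
                                                   tuple[int, ...]]]:
    """k (train, valid) pairs from a seeded permutation of the pool.

    Validation folds are near-equal (sizes differ by at most one) and cover
    every pool index exactly once; pair i trains on the complement of fold i.
    """
    trainval = list(trainval)
    if k < 2:
        raise SplitError("k must be >= 2")
    if k > len(trainval):
        raise SplitError(f"k={k} exceeds pool size {len(trainval)}")
    rng = np.random.default_rng(seed)
    perm = [trainval[i] for i in rng.permutation(len(trainval))]
    folds = np.array_split(np.asarray(perm), k)
    out = []
    for i, fold in enumerate(folds):
        valid = tuple(int(x) for x in fold)
        train = tuple(x for x in perm if x not in set(valid))
        out.append((train, valid))
    return out
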