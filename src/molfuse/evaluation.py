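"""Test-set metrics, ensemble aggregation, significance testing, embeddings.

Ensemble results are reported as the sample mean ± sample standard deviation
(ddof=1) of the k per-fold test metrics. Two summaries are compared with a
Welch (unequal-variance) two-sample t-test computed from (mean, std, n) with
Welch-Satterthwaite degrees of freedom; p-values map to the conventional star
annotation (* p<0.05, ** p<0.01, *** p<0.001). Latent embeddings are the
penultimate dense-layer activations; 2-D projection goes through an external
projector interface (UMAP by default: 10 neighbors, min_dist 0.25, Chebyshev
metric for regression tasks and Jaccard for classification tasks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, MolfuseError

__all__ = ["EnsembleResult", "SignificanceReport", "ProjectionSettings",
           "compute_metric", "aggregate_ensemble", "significance_test",
           "format_mean_std", "penultimate_embeddings", "export_embeddings"]


class DegenerateLabelsError(MolfuseError):
    """ROC-AUC requested with only one class present."""


def compute_metric(predictions, labels, metric: str) -> float:
    """RMSE, MAE, or ROC-AUC.

    ROC-AUC is the probability that a random positive outranks a random
    negative, ties counted half (rank / Mann-Whitney formulation).
    """
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape or p.size == 0:
        raise DomainError(f"length mismatch: {p.shape} vs {y.shape}")
    if metric == "rmse":
        return float(np.sqrt(np.mean((p - y) ** 2)))
    if metric == "mae":
        return float(np.mean(np.abs(p - y)))
    if metric == "roc_auc":
        if len(np.unique(y)) < 2:
            raise DegenerateLabelsError(
                "ROC-AUC needs both classes present")
        from sklearn.metrics import roc_auc_score
        return float(roc_auc_score(y, p))
    raise DomainError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class EnsembleResult:
    """Mean ± std summary of k per-fold metrics."""

    per_model_metrics: tuple[float, ...]
    mean: float
    std: float
    k: int
    task_name: str = ""
    metric_name: str = ""

    def __str__(self) -> str:
        return (f"{self.task_name} {self.metric_name}: "
                f"{format_mean_std(self.mean, self.std)} (k={self.k})")


def aggregate_ensemble(per_model_metrics, task_name: str = "",
                       metric_name: str = "") -> EnsembleResult:
    """Sample mean and sample standard deviation (ddof=1) over folds."""
    vals = tuple(float(v) for v in per_model_metrics)
    if len(vals) < 2:
        raise DomainError("ensemble aggregation needs k >= 2 metrics")
    arr = np.asarray(vals, dtype=np.float64)
    return EnsembleResult(per_model_metrics=vals, mean=float(arr.mean()),
                          std=float(arr.std(ddof=1)), k=len(vals),
                          task_name=task_name, metric_name=metric_name)


def format_mean_std(mean: float, std: float, decimals: int | None = None
                    ) -> str:
    """``mean ± std`` with the std rounded to two significant digits and the
    mean to the same decimal place (benchmark-table convention)."""
    if decimals is None:
        if std > 0:
            decimals = max(0, 1 - int(math.floor(math.log10(abs(std)))))
        else:
            decimals = 2
    return f"{mean:.{decimals}f} ± {std:.{decimals}f}"


@dataclass(frozen=True)
class SignificanceReport:
    p_value: float
    stars: str                   # "ns", "*", "**", "***"
    direction: str               # "a", "b", or "tie" — which mean is better
    t_statistic: float
    dof: float


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def significance_test(mean_a: float, std_a: float, n_a: int,
                      mean_b: float, std_b: float, n_b: int,
                      better: str = "min",
                      pooled: bool = False) -> SignificanceReport:
    """Two-tailed t-test from summary statistics.

    Welch's unequal-variance form by default (``pooled=True`` for the
    classical equal-variance test). ``better`` states whether a smaller
    ("min") or larger ("max") mean wins, for the direction field.
    """
    if n_a < 2 or n_b < 2:
        raise DomainError("need n >= 2 in both groups")
    if std_a < 0 or std_b < 0:
        raise DomainError("standard deviations must be >= 0")
    va, vb = std_a ** 2, std_b ** 2
    if va == 0.0 and vb == 0.0:
        if mean_a == mean_b:
            t, dof, p = 0.0, float(n_a + n_b - 2), 1.0
        else:
            t = math.inf if mean_a > mean_b else -math.inf
            dof, p = float(n_a + n_b - 2), 0.0
    elif pooled:
        dof = float(n_a + n_b - 2)
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / dof
        se = math.sqrt(sp2 * (1 / n_a + 1 / n_b))
        t = (mean_a - mean_b) / se
        p = float(2.0 * stats.t.sf(abs(t), dof))
    else:
        se2 = va / n_a + vb / n_b
        t = (mean_a - mean_b) / math.sqrt(se2)
        dof = se2 ** 2 / (va ** 2 / (n_a ** 2 * (n_a - 1))
                          + vb ** 2 / (n_b ** 2 * (n_b - 1)))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    if mean_a == mean_b:
        direction = "tie"
    else:
        a_wins = mean_a < mean_b if better == "min" else mean_a > mean_b
        direction = "a" if a_wins else "b"
    return SignificanceReport(p_value=p, stars=_stars(p), direction=direction,
                              t_statistic=float(t), dof=float(dof))


@dataclass(frozen=True)
class ProjectionSettings:
    n_neighbors: int = 10
    min_dist: float = 0.25
    metric: str = "chebyshev"    # "jaccard" for classification tasks
    seed: int = 0


def penultimate_embeddings(model, records, pad_id: int,
                           batch_size: int = 64) -> np.ndarray:
    """Penultimate dense-layer activation per molecule (eval mode)."""
    from .fusion import collate
    was_training = model.training
    model.eval()
    out = []
    for i in range(0, len(records), batch_size):
        batch = collate(records[i:i + batch_size], pad_id, mode=model.mode,
                        readout=model.arch.readout)
        _, emb = model(batch, return_embedding=True)
        out.append(emb.data.astype(np.float64))
    if was_training:
        model.train()
    return np.concatenate(out)


def _umap_projector(settings: ProjectionSettings):
    import umap

    def project(embeddings: np.ndarray) -> np.ndarray:
        reducer = umap.UMAP(n_neighbors=settings.n_neighbors,
                            min_dist=settings.min_dist,
                            metric=settings.metric,
                            random_state=settings.seed)
        return np.asarray(reducer.fit_transform(embeddings))

    return project


def export_embeddings(models, records, pad_id: int,
                      labels=None,
                      settings: ProjectionSettings | None = None,
                      projector=None,
                      raw_path=None, projected_path=None) -> pd.DataFrame:
    """Extract latent embeddings and a 2-D projection for visualization.

    ``models`` may be a single trained model or an ensemble (averaged).
    Returns a table with id, the 2-D projection, and the label; the raw
    embedding matrix is written to ``raw_path`` when given. ``projector`` is
    any callable mapping [n, d] -> [n, 2]; UMAP with ``settings`` by default.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    mode = models[0].mode
    task = models[0].task
    if settings is None:
        metric = ("jaccard" if task.task_type == "classification"
                  else "chebyshev")
        settings = ProjectionSettings(metric=metric)
    emb = np.mean([penultimate_embeddings(m, records, pad_id)
                   for m in models], axis=0)
    if raw_path is not None:
        raw = pd.DataFrame(emb,
                           columns=[f"e{i}" for i in range(emb.shape[1])])
        raw.insert(0, "id", np.arange(len(records)))
        raw.to_csv(raw_path, index=False)
    if projector is None:
        projector = _umap_projector(settings)
    xy = projector(emb)
    out = pd.DataFrame({"id": np.arange(len(records)),
                        "dim1": xy[:, 0], "dim2": xy[:, 1]})
    if labels is not None:
        out["label"] = np.asarray(labels)
    if projected_path is not None:
        out.to_csv(projected_path, index=False)
    return out
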