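"""Training/evaluation protocol: seeded splits, cross-validation with
replicates, ablation-variant dispatch, and metric reporting.

The benchmark protocol is 0.8/0.1/0.1 train/valid/test splits (random or
Bemis-Murcko scaffold), k-fold cross-validation realized as k independently
seeded splits (fold k uses ``split_seed + k``), each fold trained
``replicates`` times from distinct initialization seeds. Classification is
reported as macro ROC-AUC in percent, regression as RMSE.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import TaskTable, export_split_csv, split
from .estimators import HGTClassifier, HGTRegressor, _macro_auc
from .metrics import UndefinedMetricError, masked_loss, rmse, roc_auc  # noqa: F401 (module surface)
from .model import VARIANT_VIEWS, ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "MetricReport",
    "make_variant",
    "make_estimator",
    "train",
    "evaluate",
    "run_cv",
    "roc_auc",
    "rmse",
    "masked_loss",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a training run."""

    model: ModelConfig = field(default_factory=ModelConfig)
    split_method: str = "scaffold"
    split_ratio: tuple[float, float, float] = (0.8, 0.1, 0.1)
    split_seed: int = 0
    folds: int = 5
    replicates: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 20
    variant: str = "full"
    output_dir: str | None = None

    def __post_init__(self):
        if self.folds < 1 or self.replicates < 1:
            raise ValueError("folds and replicates must be >= 1")


@dataclass
class MetricReport:
    """Per-(fold, replicate) metric values with sample-std aggregation."""

    metric_name: str
    values: dict[tuple[int, int], float]
    variant: str = "full"

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    @property
    def std(self) -> float:
        vals = list(self.values.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "variant": self.variant,
            "mean": self.mean,
            "std": self.std,
            "runs": [
                {"fold": f, "replicate": r, "value": v}
                for (f, r), v in sorted(self.values.items())
            ],
        }


def make_variant(base: ModelConfig, name: str) -> ModelConfig:
    """Configure one of the eight fusion variants (full + seven ablations)."""
    if name not in VARIANT_VIEWS:
        raise ValueError(f"unknown variant {name!r}; valid: {sorted(VARIANT_VIEWS)}")
    views = tuple(v for v in ("alpha", "beta", "gamma") if v in VARIANT_VIEWS[name])
    return dataclasses.replace(base, views_enabled=views, fusion_variant=name)


def make_estimator(run: RunConfig, task_type: str, seed: int | None = None):
    """Build the estimator for a run; ``seed`` overrides the model seed."""
    cfg = make_variant(run.model, run.variant)
    cls = HGTClassifier if task_type == "classification" else HGTRegressor
    return cls(
        hidden_dim=cfg.hidden_dim,
        num_heads=cfg.num_heads,
        depth=cfg.depth,
        dropout=cfg.dropout,
        sigma=cfg.sigma,
        value_source=cfg.value_source,
        variant=run.variant,
        junction_membership=cfg.junction_membership,
        learning_rate=run.learning_rate,
        batch_size=run.batch_size,
        max_epochs=run.max_epochs,
        patience=run.patience,
        random_state=cfg.seed if seed is None else seed,
    )


def evaluate(estimator, table: TaskTable, indices) -> float:
    """Test metric on a subset: macro ROC-AUC (fraction) or RMSE."""
    sub = table.subset(indices)
    scores = estimator.decision_function(sub.smiles)
    if table.task_type == "classification":
        return _macro_auc(sub.labels, sub.mask, scores)
    pred = estimator._decode(scores)
    return rmse(pred[sub.mask], sub.labels[sub.mask])


def train(run: RunConfig, table: TaskTable, seed: int | None = None):
    """Single split -> fit with early stopping -> validation report.

    Returns ``(estimator, MetricReport)`` where the report holds the
    validation metric of the one run.
    """
    spec = split(table, method=run.split_method, ratio=run.split_ratio, seed=run.split_seed)
    tr, va = spec.indices("train"), spec.indices("valid")
    if tr.size == 0:
        raise ValueError("empty training split")
    est = make_estimator(run, table.task_type, seed=seed)
    t_sub, v_sub = table.subset(tr), table.subset(va)
    y_t = np.where(t_sub.mask, t_sub.labels, np.nan)
    y_v = np.where(v_sub.mask, v_sub.labels, np.nan) if va.size else None
    est.fit(t_sub.smiles, y_t, X_valid=v_sub.smiles if va.size else None, y_valid=y_v)
    if va.size:
        value = evaluate(est, table, va)
    else:
        pred = est._decode(est.decision_function(t_sub.smiles))
        value = rmse(pred[t_sub.mask], t_sub.labels[t_sub.mask])
    name = "roc_auc_pct" if table.task_type == "classification" else "rmse"
    if table.task_type == "classification":
        value *= 100.0
    report = MetricReport(metric_name=name, values={(0, 0): value}, variant=run.variant)
    return est, report


def run_cv(run: RunConfig, table: TaskTable) -> MetricReport:
    """Cross-validation: fold k is an independent seeded split
    (seed = split_seed + k); each fold is trained ``replicates`` times with
    distinct initialization seeds and evaluated on its test set."""
    values: dict[tuple[int, int], float] = {}
    outdir = Path(run.output_dir) if run.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    for fold in range(run.folds):
        spec = split(table, method=run.split_method, ratio=run.split_ratio,
                     seed=run.split_seed + fold)
        tr, va, te = (spec.indices(p) for p in ("train", "valid", "test"))
        if te.size == 0:
            logger.warning("fold %d has an empty test split; skipping", fold)
            continue
        if outdir:
            export_split_csv(table, spec, outdir / f"fold{fold}_split.csv", fold=fold)
        t_sub, v_sub = table.subset(tr), table.subset(va)
        y_t = np.where(t_sub.mask, t_sub.labels, np.nan)
        y_v = np.where(v_sub.mask, v_sub.labels, np.nan) if va.size else None
        for rep in range(run.replicates):
            est = make_estimator(run, table.task_type,
                                 seed=run.model.seed + 1000 * fold + rep)
            est.fit(t_sub.smiles, y_t,
                    X_valid=v_sub.smiles if va.size else None, y_valid=y_v)
            try:
                value = evaluate(est, table, te)
            except UndefinedMetricError:
                logger.warning("fold %d rep %d: metric undefined on test split", fold, rep)
                continue
            if table.task_type == "classification":
                value *= 100.0
            values[(fold, rep)] = value
    if not values:
        raise ValueError("cross-validation produced no evaluable runs")
    name = "roc_auc_pct" if table.task_type == "classification" else "rmse"
    report = MetricReport(metric_name=name, values=values, variant=run.variant)
    if outdir:
        (outdir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report
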