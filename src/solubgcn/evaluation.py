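"""Cross-validation, ensembling and feature-ablation experiment grids.

The evaluation protocol is 5-fold cross-validation repeated with 5 random
seeds: for each seed the training proteins are split into five disjoint
folds, a model is trained on four folds with the fifth as validation, the
fold metrics are averaged per seed, and the final report is the mean over
seed-level means with its standard deviation (formatted like
``0.495± 0.012``).  Fold-level standard deviations are kept alongside.

Three ablation grids mirror the standard experiment designs for this model
family: a module-ablation grid (base GCN, +language-model block, +channel
gating, both), single-feature and leave-one-feature-out grids, and pairwise
combinations of the language-model block with each remaining block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ConfigError
from .io import BLOCK_ORDER, DEFAULT_BLOCK_DIMS, ProteinRecord
from .metrics import MetricRecord, binarize, evaluate_predictions
from .model import HybridGCNRegressor

ABLATION_MODES = ("module_ablation", "single_feature", "leave_one_out", "pairwise_with_ESM")


@dataclass
class CVPlan:
    """Cross-validation protocol: fold count, repeat seeds, stratification."""

    n_folds: int = 5
    seeds: Sequence[int] = (0, 1, 2, 3, 4)
    stratify: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if not self.seeds:
            raise ConfigError("at least one CV seed is required")


def make_folds(
    ids: Sequence[str],
    n_folds: int,
    seed: int,
    stratify: bool = False,
    labels: Mapping[str, float] | None = None,
) -> list[list[str]]:
    """Deterministic disjoint fold partition of protein IDs.

    IDs are sorted before shuffling, so the partition depends only on the ID
    set and the seed, not on input order.  With ``stratify`` the folds balance
    the soluble/insoluble classes at the 0.5 threshold.
    """
    ordered = sorted(set(ids))
    if len(ordered) != len(list(ids)):
        raise ConfigError("duplicate protein IDs in fold assignment")
    if stratify:
        if labels is None:
            raise ConfigError("stratified folds require labels")
        y = binarize([labels[i] for i in ordered])
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(ordered)), y)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(ordered)))
    return [[ordered[i] for i in test_idx] for _, test_idx in splits]


@dataclass
class ExperimentResult:
    """Per-fold and aggregated metrics of one cross-validated configuration."""

    label: str
    fold_metrics: dict[int, list[MetricRecord]] = field(default_factory=dict)

    def seed_means(self, metric: str) -> dict[int, float]:
        return {
            seed: float(np.nanmean([getattr(m, metric) for m in folds]))
            for seed, folds in self.fold_metrics.items()
        }

    def mean(self, metric: str) -> float:
        return float(np.mean(list(self.seed_means(metric).values())))

    def sd(self, metric: str) -> float:
        """Standard deviation across seed-level means (the reported spread)."""
        vals = list(self.seed_means(metric).values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def sd_folds(self, metric: str) -> float:
        """Standard deviation across all individual folds (logged, not headline)."""
        vals = [
            getattr(m, metric) for folds in self.fold_metrics.values() for m in folds
        ]
        return float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0

    def format_cell(self, metric: str) -> str:
        return format_mean_sd(self.mean(metric), self.sd(metric))

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in MetricRecord.NUMERIC_FIELDS:
            rows.append(
                {
                    "metric": metric,
                    "mean": self.mean(metric),
                    "sd_seeds": self.sd(metric),
                    "sd_folds": self.sd_folds(metric),
                    "formatted": self.format_cell(metric),
                }
            )
        return pd.DataFrame(rows)


def format_mean_sd(mean: float, sd: float) -> str:
    """Render ``mean ± sd`` in the three-decimal table style, e.g. ``0.495± 0.012``."""
    return f"{mean:.3f}± {sd:.3f}"


def run_cv(
    records: Sequence[ProteinRecord],
    estimator: HybridGCNRegressor,
    plan: CVPlan = CVPlan(),
    label: str = "model",
) -> ExperimentResult:
    """Repeated k-fold cross-validation of one configuration.

    For each seed, each fold in turn is the evaluation set while the others
    train the model (the held-out fold also drives early stopping).  Folds
    with a single solubility class keep their AUC flagged undefined; the run
    continues.
    """
    records = list(records)
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ConfigError("duplicate protein IDs in dataset")
    labels = {r.id: r.solubility for r in records}
    result = ExperimentResult(label=label)
    for seed in plan.seeds:
        folds = make_folds(
            list(by_id), plan.n_folds, seed, stratify=plan.stratify, labels=labels
        )
        fold_records: list[MetricRecord] = []
        for fold_ids in folds:
            held = [by_id[i] for i in fold_ids]
            train = [r for r in records if r.id not in set(fold_ids)]
            est = clone(estimator)
            est.set_params(random_state=estimator.random_state + 1000 * seed)
            est.fit(train, validation=held)
            y_hat = est.predict(held)
            y = np.array([r.solubility for r in held])
            fold_records.append(evaluate_predictions(y, y_hat))
        result.fold_metrics[seed] = fold_records
    return result


class EnsembleRegressor:
    """Arithmetic mean of the cross-validation fold models' predictions.

    A convex combination of sigmoid outputs, so ensemble predictions stay in
    ``(0, 1)``.
    """

    def __init__(self, models: Sequence[HybridGCNRegressor]):
        if not models:
            raise ConfigError("ensemble requires at least one model")
        self.models = list(models)

    def predict(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        return np.mean([m.predict(records) for m in self.models], axis=0)


def train_full_and_ensemble(
    records: Sequence[ProteinRecord],
    estimator: HybridGCNRegressor,
    plan: CVPlan = CVPlan(),
) -> tuple[HybridGCNRegressor, EnsembleRegressor]:
    """Final models after cross-validation.

    The single model is trained on the entire training set (with an internal
    early-stopping split); the ensemble averages the fold models of the
    plan's first seed.
    """
    records = list(records)
    single = clone(estimator)
    single.fit(records)

    by_id = {r.id: r for r in records}
    labels = {r.id: r.solubility for r in records}
    seed = plan.seeds[0]
    folds = make_folds(list(by_id), plan.n_folds, seed, plan.stratify, labels)
    fold_models = []
    for fold_ids in folds:
        held = [by_id[i] for i in fold_ids]
        train = [r for r in records if r.id not in set(fold_ids)]
        est = clone(estimator)
        est.set_params(random_state=estimator.random_state + 1000 * seed)
        est.fit(train, validation=held)
        fold_models.append(est)
    return single, EnsembleRegressor(fold_models)


# ---------------------------------------------------------------------------
# ablation grids
# ---------------------------------------------------------------------------


@dataclass
class AblationConfig:
    """One grid entry: which blocks are enabled and whether gating is on."""

    label: str
    blocks: tuple[str, ...]
    use_afr: bool

    def n_channels(self, block_dims: Mapping[str, int] = DEFAULT_BLOCK_DIMS) -> int:
        return sum(block_dims[b] for b in self.blocks)


def ablation_configurations(
    mode: str,
    block_dims: Mapping[str, int] = DEFAULT_BLOCK_DIMS,
) -> list[AblationConfig]:
    """Enumerate the run configurations of one ablation grid.

    ``module_ablation``: 4 runs — plain GCN on the five classic blocks,
    +language-model block, +channel gating, and the full model.
    ``single_feature``: 6 runs, one block each, gating off.
    ``leave_one_out``: 6 runs, full model minus one block.
    ``pairwise_with_ESM``: 5 runs pairing the language-model block with each
    remaining block.
    """
    if mode not in ABLATION_MODES:
        raise ConfigError(f"unknown ablation mode {mode!r}; known: {ABLATION_MODES}")
    blocks = tuple(b for b in BLOCK_ORDER if b in block_dims)
    if not blocks:
        raise ConfigError("empty feature-block set")
    classic = tuple(b for b in blocks if b != "ESM")
    configs: list[AblationConfig] = []
    if mode == "module_ablation":
        configs = [
            AblationConfig("GCN", classic, use_afr=False),
            AblationConfig("ESM+GCN", blocks, use_afr=False),
            AblationConfig("AFR+GCN", classic, use_afr=True),
            AblationConfig("ESM+AFR+GCN (HybridGCN)", blocks, use_afr=True),
        ]
    elif mode == "single_feature":
        configs = [AblationConfig(b, (b,), use_afr=False) for b in blocks]
    elif mode == "leave_one_out":
        configs = [
            AblationConfig(f"-{b}", tuple(x for x in blocks if x != b), use_afr=True)
            for b in blocks
        ]
    else:  # pairwise_with_ESM
        if "ESM" not in blocks:
            raise ConfigError("pairwise_with_ESM requires the ESM block")
        configs = [
            AblationConfig(f"ESM+{b}", ("ESM", b), use_afr=True) for b in classic
        ]
    for cfg in configs:
        if not cfg.blocks:
            raise ConfigError(f"ablation configuration {cfg.label!r} has no blocks")
    return configs


def run_ablation_grid(
    records: Sequence[ProteinRecord],
    estimator: HybridGCNRegressor,
    mode: str,
    plan: CVPlan = CVPlan(),
    block_dims: Mapping[str, int] = DEFAULT_BLOCK_DIMS,
) -> pd.DataFrame:
    """Cross-validate every configuration of one ablation grid.

    Returns a table with one row per configuration: the enabled blocks, the
    channel count, and mean ± sd for each metric.
    """
    rows = []
    for cfg in ablation_configurations(mode, block_dims):
        est = clone(estimator)
        est.set_params(blocks=cfg.blocks, use_afr=cfg.use_afr)
        result = run_cv(records, est, plan, label=cfg.label)
        row = {
            "configuration": cfg.label,
            "blocks": "+".join(cfg.blocks),
            "n_channels": cfg.n_channels(block_dims),
            "use_afr": cfg.use_afr,
        }
        for metric in MetricRecord.NUMERIC_FIELDS:
            row[metric] = result.mean(metric)
            row[f"{metric}_sd"] = result.sd(metric)
            row[f"{metric}_fmt"] = result.format_cell(metric)
        rows.append(row)
    return pd.DataFrame(rows)
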