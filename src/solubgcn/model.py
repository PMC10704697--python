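"""Scikit-learn style estimator for hybrid-feature graph solubility regression.

:class:`HybridGCNRegressor` maps protein records — per-residue feature blocks
plus a residue contact map — to a continuous solubility value in ``[0, 1]``.
The pipeline per protein is::

    stack blocks -> per-channel normalization (training statistics)
      -> adaptive feature re-weighting (optional)
      -> graph convolutions over the normalized contact adjacency
      -> tanh/softmax self-attention readout -> sigmoid head

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) and composes with :func:`sklearn.base.clone`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import io as fio
from .afr import block_importance
from .exceptions import ConfigError, DataError
from .graph import build_graph
from .io import ChannelNormalizer, HybridFeature, ProteinRecord, stack_features
from .network import (
    NetConfig,
    forward,
    pack_batch,
    predict_batch,
    train_network,
)


@dataclass
class Prediction:
    """One protein's prediction with its residue attention profile."""

    id: str
    s_hat: float
    attention: np.ndarray | None = None


class HybridGCNRegressor(RegressorMixin, BaseEstimator):
    """Graph convolutional solubility regressor with channel gating.

    Parameters
    ----------
    blocks : sequence of block names or None
        Feature blocks to use, e.g. ``("ESM", "HMM")``.  ``None`` enables
        every block present in the training records, in canonical order.
    use_afr : bool
        Apply adaptive feature re-weighting to the stacked features.
    afr_bias : bool
        Learn a bias in the AFR interaction step.
    gcn_layers, gcn_hidden : int
        Number and width of graph-convolution layers.
    attention_hidden, attention_heads : int
        Width of the attention hidden layer and number of softmax heads
        (a single head by default).
    dropout : float in [0, 1)
        Dropout on graph-convolution outputs during training.
    feature_normalization : {"none", "minmax_per_channel", "zscore_per_channel"}
        Per-channel normalization with statistics from the training set only.
    contact_threshold : float in [0, 1)
        Contact probabilities below this are dropped from the adjacency;
        0.0 keeps the full probability-weighted graph.
    adjacency_normalization : {"sym_degree", "row_stochastic", "none"}
    learning_rate, batch_size, max_epochs, patience : optimizer settings
        Adam on the batch RMSE; ``patience`` epochs without validation
        improvement stop training early (validation comes from ``fit``'s
        ``validation=`` argument or an internal split).
    validation_fraction : float
        Fraction of the training proteins held out for early stopping when no
        explicit validation set is given; 0 disables early stopping.
    random_state : int
        Seed for parameter initialization, batching, dropout and the
        internal validation split.

    Attributes
    ----------
    params_ : dict of trained parameter arrays.
    normalizer_ : fitted per-channel :class:`ChannelNormalizer`.
    enabled_blocks_ : tuple of block names used, in canonical order.
    block_spans_ : channel interval per block in the stacked feature.
    n_channels_ : total channel count C.
    channel_weights_ : training-set mean AFR gate vector (None without AFR).
    block_importance_ : mean gate weight per block (None without AFR).
    history_ : per-epoch training/validation RMSE records.
    """

    def __init__(
        self,
        *,
        blocks: Sequence[str] | None = None,
        use_afr: bool = True,
        afr_bias: bool = True,
        gcn_layers: int = 2,
        gcn_hidden: int = 256,
        attention_hidden: int = 128,
        attention_heads: int = 1,
        dropout: float = 0.2,
        feature_normalization: str = "minmax_per_channel",
        contact_threshold: float = 0.0,
        adjacency_normalization: str = "sym_degree",
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 20,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.blocks = blocks
        self.use_afr = use_afr
        self.afr_bias = afr_bias
        self.gcn_layers = gcn_layers
        self.gcn_hidden = gcn_hidden
        self.attention_hidden = attention_hidden
        self.attention_heads = attention_heads
        self.dropout = dropout
        self.feature_normalization = feature_normalization
        self.contact_threshold = contact_threshold
        self.adjacency_normalization = adjacency_normalization
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    # data preparation
    # ------------------------------------------------------------------

    def _resolve_blocks(self, record: ProteinRecord) -> tuple[str, ...]:
        if self.blocks is not None:
            enabled = tuple(fio.canonical_block_name(b) for b in self.blocks)
            if not enabled:
                raise ConfigError("empty feature-block set")
            return tuple(b for b in fio.BLOCK_ORDER if b in enabled)
        return tuple(b for b in fio.BLOCK_ORDER if b in record.blocks)

    def _stack(self, record: ProteinRecord, enabled: tuple[str, ...]) -> HybridFeature:
        missing = [b for b in enabled if b not in record.blocks]
        if missing:
            raise DataError(
                f"protein {record.id}: missing enabled block(s) {', '.join(missing)}"
            )
        return stack_features([record.blocks[b] for b in enabled])

    def _prepare(
        self, records: Sequence[ProteinRecord], fit_normalizer: bool
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Stack, normalize and graph-build each record -> (features, adjacency)."""
        hybrids = [self._stack(r, self.enabled_blocks_) for r in records]
        if fit_normalizer:
            self.normalizer_ = ChannelNormalizer(self.feature_normalization).fit(
                [h.matrix for h in hybrids]
            )
            self.block_spans_ = dict(hybrids[0].block_spans)
            self.n_channels_ = hybrids[0].C
        items = []
        for rec, hyb in zip(records, hybrids):
            X = self.normalizer_.transform(hyb.matrix)
            pg = build_graph(
                rec,
                X,
                threshold=self.contact_threshold,
                normalization=self.adjacency_normalization,
            )
            items.append((X, pg.adjacency))
        return items

    def _net_config(self) -> NetConfig:
        return NetConfig(
            n_channels=self.n_channels_,
            gcn_layers=self.gcn_layers,
            gcn_hidden=self.gcn_hidden,
            attention_hidden=self.attention_hidden,
            attention_heads=self.attention_heads,
            dropout=self.dropout,
            use_afr=self.use_afr,
            afr_bias=self.afr_bias,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.random_state,
        )

    @staticmethod
    def _labels(records: Sequence[ProteinRecord], y) -> np.ndarray:
        if y is not None:
            y = np.asarray(y, dtype=float)
            if len(y) != len(records):
                raise ConfigError("y length does not match the number of records")
            return y
        missing = [r.id for r in records if r.solubility is None]
        if missing:
            raise DataError(f"records without solubility labels: {missing[:5]}")
        return np.array([r.solubility for r in records], dtype=float)

    # ------------------------------------------------------------------
    # estimator API
    # ------------------------------------------------------------------

    def fit(
        self,
        X: Sequence[ProteinRecord],
        y=None,
        validation: Sequence[ProteinRecord] | None = None,
        validation_y=None,
    ) -> "HybridGCNRegressor":
        """Train on protein records.

        ``y`` defaults to the records' own solubility labels.  ``validation``
        supplies an explicit early-stopping set (e.g. the held-out
        cross-validation fold); otherwise ``validation_fraction`` of the
        training proteins is split off.
        """
        records = list(X)
        if not records:
            raise ConfigError("cannot fit on an empty dataset")
        labels = self._labels(records, y)
        self.enabled_blocks_ = self._resolve_blocks(records[0])

        if validation is not None:
            val_records = list(validation)
            val_labels = self._labels(val_records, validation_y)
            train_records, train_labels = records, labels
        elif self.validation_fraction > 0 and len(records) >= 10:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(records))
            n_val = max(1, int(round(self.validation_fraction * len(records))))
            val_idx, train_idx = order[:n_val], order[n_val:]
            val_records = [records[i] for i in val_idx]
            val_labels = labels[val_idx]
            train_records = [records[i] for i in train_idx]
            train_labels = labels[train_idx]
        else:
            val_records, val_labels = [], np.empty(0)
            train_records, train_labels = records, labels

        train_items = self._prepare(train_records, fit_normalizer=True)
        val_items = self._prepare(val_records, fit_normalizer=False) if val_records else []

        config = self._net_config()
        self.params_, self.history_ = train_network(
            [(f, a, lab) for (f, a), lab in zip(train_items, train_labels)],
            config,
            [(f, a, lab) for (f, a), lab in zip(val_items, val_labels)] or None,
        )
        self.n_epochs_ = sum(1 for h in self.history_ if "train_rmse" in h)

        if self.use_afr:
            batch = pack_batch(
                [f for f, _ in train_items], [a for _, a in train_items]
            )
            cache = forward(self.params_, batch, config, train=False)
            self.channel_weights_ = cache["Wc"].mean(axis=0)
            self.block_importance_ = block_importance(
                self.channel_weights_, self.block_spans_
            )
        else:
            self.channel_weights_ = None
            self.block_importance_ = None
        return self

    def predict(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        """Predict solubility for each record; values lie strictly in (0, 1)."""
        if not hasattr(self, "params_"):
            raise ConfigError("estimator is not fitted")
        records = list(X)
        if not records:
            return np.empty(0)
        items = self._prepare(records, fit_normalizer=False)
        batch = pack_batch([f for f, _ in items], [a for _, a in items])
        return predict_batch(self.params_, batch, self._net_config())

    def predict_record(self, record: ProteinRecord) -> Prediction:
        """Predict one protein, exporting its normalized residue attention."""
        items = self._prepare([record], fit_normalizer=False)
        batch = pack_batch([items[0][0]], [items[0][1]])
        cache = forward(self.params_, batch, self._net_config(), train=False)
        attention = cache["alpha"].mean(axis=1)  # average over heads
        return Prediction(
            id=record.id, s_hat=float(cache["s_hat"][0]), attention=attention
        )

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Save parameters (npz) plus a JSON sidecar of config and statistics."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params_)
        sidecar = {
            "params": self.get_params(),
            "enabled_blocks": list(self.enabled_blocks_),
            "block_spans": {k: list(v) for k, v in self.block_spans_.items()},
            "n_channels": int(self.n_channels_),
            "normalizer": self.normalizer_.to_dict(),
        }
        sidecar["params"]["blocks"] = (
            list(self.blocks) if self.blocks is not None else None
        )
        with open(directory / "model.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "HybridGCNRegressor":
        directory = Path(directory)
        with open(directory / "model.json") as fh:
            sidecar = json.load(fh)
        est = cls(**{
            k: (tuple(v) if k == "blocks" and v is not None else v)
            for k, v in sidecar["params"].items()
        })
        with np.load(directory / "params.npz") as data:
            est.params_ = {k: data[k] for k in data.files}
        est.enabled_blocks_ = tuple(sidecar["enabled_blocks"])
        est.block_spans_ = {k: tuple(v) for k, v in sidecar["block_spans"].items()}
        est.n_channels_ = sidecar["n_channels"]
        est.normalizer_ = ChannelNormalizer.from_dict(sidecar["normalizer"])
        est.history_ = []
        if est.use_afr:
            est.channel_weights_ = None
            est.block_importance_ = None
        return est
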