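"""The scTab classifier and its linear/MLP baselines.

scTab adapts the TabNet tabular attention architecture to scRNA-seq: after
size-factor/log1p normalization and an input batch-normalization layer, a
feature transformer (GLU blocks with shared weights across passes) embeds
the cell; an attentive head turns the n_a part of the embedding into a
sparse per-cell *feature attention mask* via 1.5-entmax; the masked input
is embedded again and classified from the n_d part.  A single decision
step is used.  The loss is class-weighted cross-entropy plus a small
entropy regularizer on the mask.

Models follow a statsmodels-like shape: construct a model from data, call
``fit(seed=...)``, get a :class:`FitResults` carrying the trained
parameters, the training history, prediction methods and ``summary()``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from sctab import nn
from sctab.corpus import CellByGeneMatrix, align_genes, normalize_rows
from sctab.nn import (
    AdamW,
    BatchNorm,
    Dropout,
    FeatureTransformer,
    GLUBlock,
    Linear,
    entmax15,
    entmax15_backward,
    softmax,
    weighted_cross_entropy,
)

__all__ = [
    "ScTabConfig",
    "LinearConfig",
    "MLPConfig",
    "ScTabModel",
    "LinearModel",
    "MLPModel",
    "FitResults",
    "class_weights",
    "gene_ranking",
]


# ---------------------------------------------------------------------------
# configurations (defaults are the published full-scale hyperparameters)
# ---------------------------------------------------------------------------

@dataclass
class TrainSettings:
    batch_size: int = 2048
    learning_rate: float = 0.005
    lr_decay: float = 0.9          # multiplied in per epoch
    weight_decay: float = 0.05
    max_epochs: int = 50
    patience: int = 10             # early stopping on validation macro F1
    min_delta: float = 1e-4
    augment_training_data: bool = False


@dataclass
class ScTabConfig(TrainSettings):
    n_d: int = 128
    n_a: int = 64
    n_shared: int = 3
    n_independent: int = 5
    n_steps: int = 1
    lambda_sparse: float = 1e-5
    virtual_batch_size: int = 256

    def __post_init__(self) -> None:
        if self.n_steps != 1:
            raise ValueError("only a single decision step is supported (n_steps=1)")
        if self.n_shared < 1:
            raise ValueError("need at least one shared GLU block")
        for name in ("n_d", "n_a", "n_independent", "virtual_batch_size", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LinearConfig(TrainSettings):
    learning_rate: float = 0.0005
    weight_decay: float = 0.01


@dataclass
class MLPConfig(TrainSettings):
    learning_rate: float = 0.002
    weight_decay: float = 0.05
    n_hidden: int = 8
    hidden_size: int = 128
    dropout: float = 0.1


# ---------------------------------------------------------------------------
# class weights (inverse-frequency balancing)
# ---------------------------------------------------------------------------

def class_weights(labels: Sequence[str]) -> dict[str, float]:
    """weight_c = n_samples / (n_classes * n_c).

    Balanced classes get weight 1; rare classes get up-weighted so every
    cell type contributes equally to the loss.  The identity
    sum_c weight_c * n_c = n_samples holds for any label multiset.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    counts = pd.Series(labels).value_counts()
    n, k = len(labels), len(counts)
    return {c: n / (k * int(m)) for c, m in counts.items()}


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _Network:
    """Common bookkeeping for the three architectures."""

    def __init__(self) -> None:
        self._params: list[nn.Parameter] = []
        self._bns: list[BatchNorm] = []

    def register(self, layer) -> None:
        self._params.extend(layer.parameters())
        if isinstance(layer, BatchNorm):
            self._bns.append(layer)
        elif isinstance(layer, GLUBlock):
            self._bns.append(layer.bn)
        elif isinstance(layer, FeatureTransformer):
            for b in layer.blocks:
                self._bns.append(b.bn)

    def parameters(self) -> list[nn.Parameter]:
        return self._params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.value.copy() for i, p in enumerate(self._params)}
        for i, bn in enumerate(self._bns):
            state[f"bn{i}_mean"] = bn.running_mean.copy()
            state[f"bn{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        for i, p in enumerate(self._params):
            p.value[...] = state[f"p{i}"]
        for i, bn in enumerate(self._bns):
            bn.running_mean[...] = state[f"bn{i}_mean"]
            bn.running_var[...] = state[f"bn{i}_var"]

    def recalibrate_bn(self, X: np.ndarray, batch_size: int, rng=None) -> None:
        """Recompute batch-norm running statistics with the current weights
        (precise BN): one train-mode pass over ``X`` replacing the stale
        exponential moving averages accumulated along the training
        trajectory.  Evaluation-mode predictions then match the train-mode
        behavior of the final parameters."""
        for bn in self._bns:
            bn.start_calibration()
        for lo in range(0, X.shape[0], batch_size):
            self.forward(X[lo : lo + batch_size].astype(np.float64), train=True, rng=rng)
        for bn in self._bns:
            bn.finish_calibration()

    @property
    def has_mask(self) -> bool:
        return False


class ScTabNetwork(_Network):
    def __init__(self, n_genes: int, n_classes: int, config: ScTabConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        width = config.n_d + config.n_a
        vbs = config.virtual_batch_size
        self.input_bn = BatchNorm(n_genes)
        # fully-connected weights shared between the two passes; BN is not
        self.shared_fcs = [
            Linear(n_genes if i == 0 else width, 2 * width, rng)
            for i in range(config.n_shared)
        ]
        self.ft1 = FeatureTransformer(
            n_genes, width, self.shared_fcs, config.n_independent, vbs, rng
        )
        self.ft2 = FeatureTransformer(
            n_genes, width, self.shared_fcs, config.n_independent, vbs, rng
        )
        self.mask_linear = Linear(config.n_a, n_genes, rng)
        self.mask_bn = BatchNorm(n_genes, vbs)
        self.out = Linear(config.n_d, n_classes, rng)
        self.register(self.input_bn)
        for fc in self.shared_fcs:
            self.register(fc)
        self.register(self.ft1)
        self.register(self.ft2)
        self.register(self.mask_linear)
        self.register(self.mask_bn)
        self.register(self.out)

    @property
    def has_mask(self) -> bool:
        return True

    def forward(self, x: np.ndarray, train: bool, rng=None):
        n_d = self.config.n_d
        h, c_in = self.input_bn.forward(x, train)
        f1, c_f1 = self.ft1.forward(h, train)
        a0 = f1[:, n_d:]
        ml, c_ml = self.mask_linear.forward(a0)
        mb, c_mb = self.mask_bn.forward(ml, train)
        mask = entmax15(mb)
        h2 = h * mask
        f2, c_f2 = self.ft2.forward(h2, train)
        d1 = f2[:, :n_d]
        relu = np.maximum(d1, 0.0)
        logits, c_out = self.out.forward(relu)
        cache = (c_in, c_f1, c_ml, c_mb, mask, h, c_f2, d1, relu, c_out)
        return logits, mask, d1, cache

    def backward(self, cache, dlogits: np.ndarray, dmask: np.ndarray | None) -> None:
        c_in, c_f1, c_ml, c_mb, mask, h, c_f2, d1, relu, c_out = cache
        n_d, n_a = self.config.n_d, self.config.n_a
        drelu = self.out.backward(c_out, dlogits)
        dd1 = drelu * (d1 > 0)
        df2 = np.concatenate([dd1, np.zeros((dd1.shape[0], n_a))], axis=1)
        dh2 = self.ft2.backward(c_f2, df2)
        dM = dh2 * h
        if dmask is not None:
            dM = dM + dmask
        dh = dh2 * mask
        dmb = entmax15_backward(mask, dM)
        dml = self.mask_bn.backward(c_mb, dmb)
        da0 = self.mask_linear.backward(c_ml, dml)
        df1 = np.concatenate([np.zeros((da0.shape[0], n_d)), da0], axis=1)
        dh = dh + self.ft1.backward(c_f1, df1)
        self.input_bn.backward(c_in, dh)


class LinearNetwork(_Network):
    """A single weight matrix and bias vector on normalized expression."""

    def __init__(self, n_genes: int, n_classes: int, config: LinearConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(n_genes, n_classes, rng)
        self.register(self.fc)

    def forward(self, x: np.ndarray, train: bool, rng=None):
        logits, cache = self.fc.forward(x)
        return logits, None, None, cache

    def backward(self, cache, dlogits: np.ndarray, dmask=None) -> None:
        self.fc.backward(cache, dlogits)


class MLPNetwork(_Network):
    def __init__(self, n_genes: int, n_classes: int, config: MLPConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.layers: list[Linear] = []
        self.dropouts: list[Dropout] = []
        dim = n_genes
        for _ in range(config.n_hidden):
            self.layers.append(Linear(dim, config.hidden_size, rng))
            self.dropouts.append(Dropout(config.dropout))
            dim = config.hidden_size
        self.out = Linear(dim, n_classes, rng)
        for l in self.layers:
            self.register(l)
        self.register(self.out)

    def forward(self, x: np.ndarray, train: bool, rng=None):
        caches = []
        h = x
        for fc, drop in zip(self.layers, self.dropouts):
            z, c_fc = fc.forward(h)
            a = np.maximum(z, 0.0)
            h, c_drop = drop.forward(a, train, rng)
            caches.append((c_fc, z, c_drop))
        logits, c_out = self.out.forward(h)
        return logits, None, None, (caches, c_out)

    def backward(self, cache, dlogits: np.ndarray, dmask=None) -> None:
        caches, c_out = cache
        dh = self.out.backward(c_out, dlogits)
        for (c_fc, z, c_drop), fc, drop in zip(
            reversed(caches), reversed(self.layers), reversed(self.dropouts)
        ):
            dh = drop.backward(c_drop, dh)
            dh = dh * (z > 0)
            dh = fc.backward(c_fc, dh)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResults:
    """Trained parameters plus diagnostics, returned by ``Model.fit``."""

    model_name: str
    network: _Network
    config: TrainSettings
    classes_: np.ndarray
    gene_ids: np.ndarray
    history: pd.DataFrame
    best_epoch: int
    seed: int
    class_weights_: dict[str, float]

    # -- prediction --------------------------------------------------------
    def _normalized(self, matrix: CellByGeneMatrix) -> np.ndarray:
        if not np.array_equal(matrix.gene_ids, self.gene_ids):
            matrix = align_genes(matrix, self.gene_ids)
        x = matrix.dense()
        if matrix.layer == "raw":
            x = normalize_rows(x)
        return np.asarray(x, dtype=np.float64)

    def predict_proba(self, matrix: CellByGeneMatrix, batch_size: int = 4096) -> np.ndarray:
        """Per-cell class probabilities (eval mode, running BN statistics)."""
        x = self._normalized(matrix)
        out = np.empty((x.shape[0], len(self.classes_)))
        for lo in range(0, x.shape[0], batch_size):
            logits, _, _, _ = self.network.forward(x[lo : lo + batch_size], train=False)
            out[lo : lo + batch_size] = softmax(logits)
        return out

    def predict(self, matrix: CellByGeneMatrix, batch_size: int = 4096) -> np.ndarray:
        """Argmax labels; ties break to the lowest class index."""
        if matrix.n_cells == 0:
            return np.empty(0, dtype=object)
        probs = self.predict_proba(matrix, batch_size)
        return self.classes_[np.argmax(probs, axis=1)]

    def feature_masks(self, matrix: CellByGeneMatrix, batch_size: int = 4096) -> np.ndarray:
        """Per-cell feature attention masks (scTab only)."""
        if not self.network.has_mask:
            raise AttributeError(f"{self.model_name} has no feature attention mask")
        x = self._normalized(matrix)
        out = np.empty_like(x)
        for lo in range(0, x.shape[0], batch_size):
            _, mask, _, _ = self.network.forward(x[lo : lo + batch_size], train=False)
            out[lo : lo + batch_size] = mask
        return out

    def embed(self, matrix: CellByGeneMatrix, batch_size: int = 4096) -> np.ndarray:
        if not self.network.has_mask:
            raise AttributeError(f"{self.model_name} has no embedding head")
        x = self._normalized(matrix)
        chunks = []
        for lo in range(0, x.shape[0], batch_size):
            _, _, emb, _ = self.network.forward(x[lo : lo + batch_size], train=False)
            chunks.append(emb)
        return np.concatenate(chunks)

    # -- reporting ---------------------------------------------------------
    @property
    def best_val_macro_f1(self) -> float:
        return float(self.history["val_macro_f1"].iloc[self.best_epoch])

    def summary(self) -> str:
        n_params = sum(p.value.size for p in self.network.parameters())
        buf = io.StringIO()
        buf.write(f"{self.model_name} fit results\n")
        buf.write("=" * 40 + "\n")
        buf.write(f"classes:            {len(self.classes_)}\n")
        buf.write(f"genes:              {len(self.gene_ids)}\n")
        buf.write(f"parameters:         {n_params}\n")
        buf.write(f"epochs run:         {len(self.history)}\n")
        buf.write(f"best epoch:         {self.best_epoch}\n")
        buf.write(f"val macro F1 (best): {self.best_val_macro_f1:.4f}\n")
        buf.write(f"val loss (best):     {self.history['val_loss'].iloc[self.best_epoch]:.4f}\n")
        buf.write(f"seed:               {self.seed}\n")
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters, config, vocabulary, classes,
        normalization statistics."""
        path = Path(path)
        meta = {
            "model_name": self.model_name,
            "config": asdict(self.config),
            "classes": [str(c) for c in self.classes_],
            "gene_ids": [str(g) for g in self.gene_ids],
            "best_epoch": self.best_epoch,
            "seed": self.seed,
            "class_weights": {str(k): v for k, v in self.class_weights_.items()},
            "history": self.history.to_dict(orient="list"),
        }
        np.savez_compressed(
            path,
            _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.network.state_dict(),
        )


def load_results(path: str | Path) -> FitResults:
    """Restore a :class:`FitResults` checkpoint written by ``save``."""
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    cfg_cls = {"sctab": ScTabConfig, "linear": LinearConfig, "mlp": MLPConfig}[
        meta["model_name"]
    ]
    config = cfg_cls(**meta["config"])
    net_cls = {"sctab": ScTabNetwork, "linear": LinearNetwork, "mlp": MLPNetwork}[
        meta["model_name"]
    ]
    rng = np.random.default_rng(0)
    network = net_cls(len(meta["gene_ids"]), len(meta["classes"]), config, rng)
    network.load_state_dict({k: data[k] for k in data.files if k != "_meta"})
    return FitResults(
        model_name=meta["model_name"],
        network=network,
        config=config,
        classes_=np.array(meta["classes"], dtype=object),
        gene_ids=np.array(meta["gene_ids"], dtype=object),
        history=pd.DataFrame(meta["history"]),
        best_epoch=meta["best_epoch"],
        seed=meta["seed"],
        class_weights_=meta["class_weights"],
    )


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class _BaseModel:
    """Shared fitting machinery for scTab, linear, and MLP."""

    model_name = "base"
    config_cls = TrainSettings

    def __init__(
        self,
        matrix: CellByGeneMatrix,
        records: pd.DataFrame,
        val_matrix: CellByGeneMatrix,
        val_records: pd.DataFrame,
        config=None,
        augmentation=None,
    ):
        if config is None:
            config = self.config_cls()
        self.config = config
        self.augmentation = augmentation
        train_donors = set(records["donor_id"])
        val_donors = set(val_records["donor_id"])
        if train_donors & val_donors:
            raise ValueError(
                f"train and validation share donors: {sorted(train_donors & val_donors)[:5]}"
            )
        self.gene_ids = np.asarray(matrix.gene_ids, dtype=object)
        x = matrix.dense()
        self.X = (normalize_rows(x) if matrix.layer == "raw" else x).astype(np.float32)
        xv = val_matrix.dense()
        self.X_val = (
            normalize_rows(xv) if val_matrix.layer == "raw" else xv
        ).astype(np.float32)
        labels = records["cell_type"].to_numpy(dtype=object)
        self.classes_ = np.array(sorted(set(labels)), dtype=object)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        index = {c: i for i, c in enumerate(self.classes_)}
        self.y = np.array([index[l] for l in labels])
        val_labels = val_records["cell_type"].to_numpy(dtype=object)
        # validation cells whose label the model can express
        self._val_known = np.array([l in index for l in val_labels], dtype=bool)
        self.y_val = np.array([index[l] for l in val_labels[self._val_known]])
        # class weights computed on the training split only
        self.class_weights_ = class_weights(list(labels))
        self._w = np.array([self.class_weights_[c] for c in self.classes_])

    @classmethod
    def from_split(cls, matrix, records, split, config=None, augmentation=None):
        """Build from a full corpus plus a donor :class:`SplitAssignment`."""
        tr = split.cell_indices(records, "train")
        va = split.cell_indices(records, "val")
        return cls(
            matrix.subset(tr),
            records.iloc[tr].reset_index(drop=True),
            matrix.subset(va),
            records.iloc[va].reset_index(drop=True),
            config=config,
            augmentation=augmentation,
        )

    def _build_network(self, rng: np.random.Generator) -> _Network:
        raise NotImplementedError

    def fit(self, seed: int = 0) -> FitResults:
        """Train with per-epoch learning-rate decay and early stopping on
        the validation macro F1; returns the best-epoch parameters."""
        from sctab.augmentation import augment

        cfg = self.config
        rng = np.random.default_rng(seed)
        net = self._build_network(rng)
        opt = AdamW(net.parameters(), cfg.learning_rate, cfg.weight_decay)
        use_aug = cfg.augment_training_data and self.augmentation is not None
        n = self.X.shape[0]
        rows = []
        best_f1, best_epoch, best_state, since_best = -np.inf, 0, None, 0
        for epoch in range(cfg.max_epochs):
            lr = cfg.learning_rate * cfg.lr_decay**epoch
            opt.lr = lr
            perm = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, n, cfg.batch_size):
                idx = perm[lo : lo + cfg.batch_size]
                x = self.X[idx].astype(np.float64)
                if use_aug:
                    x = augment(x, self.augmentation, rng)
                logits, mask, _, cache = net.forward(x, train=True, rng=rng)
                loss, dlogits = weighted_cross_entropy(logits, self.y[idx], self._w)
                dmask = None
                if net.has_mask and isinstance(cfg, ScTabConfig) and cfg.lambda_sparse:
                    me = mask + 1e-15
                    loss += float(cfg.lambda_sparse * (-(mask * np.log(me))).mean())
                    dmask = (
                        -cfg.lambda_sparse * (np.log(me) + mask / me) / mask.size
                    )
                opt.zero_grad()
                net.backward(cache, dlogits, dmask)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            if net._bns:
                net.recalibrate_bn(self.X, cfg.batch_size)
            val_loss, val_f1 = self._validate(net)
            rows.append(
                {
                    "epoch": epoch,
                    "lr": lr,
                    "train_loss": epoch_loss / max(n_batches, 1),
                    "val_loss": val_loss,
                    "val_macro_f1": val_f1,
                }
            )
            if val_f1 > best_f1 + cfg.min_delta:
                best_f1, best_epoch, since_best = val_f1, epoch, 0
                best_state = net.state_dict()
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if best_state is not None:
            net.load_state_dict(best_state)
        return FitResults(
            model_name=self.model_name,
            network=net,
            config=cfg,
            classes_=self.classes_,
            gene_ids=self.gene_ids,
            history=pd.DataFrame(rows),
            best_epoch=best_epoch,
            seed=seed,
            class_weights_=self.class_weights_,
        )

    def _validate(self, net: _Network, batch_size: int = 4096) -> tuple[float, float]:
        xv = self.X_val[self._val_known]
        losses, preds = [], []
        for lo in range(0, xv.shape[0], batch_size):
            x = xv[lo : lo + batch_size].astype(np.float64)
            logits, _, _, _ = net.forward(x, train=False)
            loss, _ = weighted_cross_entropy(
                logits, self.y_val[lo : lo + batch_size], self._w
            )
            losses.append(loss * x.shape[0])
            preds.append(np.argmax(logits, axis=1))
        preds = np.concatenate(preds)
        f1 = f1_score(
            self.y_val, preds, average="macro",
            labels=np.unique(self.y_val), zero_division=0,
        )
        return float(np.sum(losses) / xv.shape[0]), float(f1)


class ScTabModel(_BaseModel):
    """Feature-attention tabular classifier (single decision step)."""

    model_name = "sctab"
    config_cls = ScTabConfig

    def _build_network(self, rng):
        return ScTabNetwork(len(self.gene_ids), len(self.classes_), self.config, rng)


class LinearModel(_BaseModel):
    """Multinomial logistic regression on normalized expression."""

    model_name = "linear"
    config_cls = LinearConfig

    def _build_network(self, rng):
        return LinearNetwork(len(self.gene_ids), len(self.classes_), self.config, rng)


class MLPModel(_BaseModel):
    """Multi-layer perceptron baseline (ReLU + dropout hidden stack)."""

    model_name = "mlp"
    config_cls = MLPConfig

    def _build_network(self, rng):
        return MLPNetwork(len(self.gene_ids), len(self.classes_), self.config, rng)


# ---------------------------------------------------------------------------
# feature-attention gene ranking
# ---------------------------------------------------------------------------

def gene_ranking(
    masks: np.ndarray,
    labels: Sequence[str],
    gene_ids: Sequence[str],
    top_k: int = 200,
) -> dict[str, np.ndarray]:
    """Per-cell-type top genes by mean feature-attention score.

    For every cell type, mask rows of its cells are averaged and genes are
    ranked by that mean attention; the ``top_k`` gene ids are returned.
    Invariant to cell order.
    """
    masks = np.asarray(masks)
    gene_ids = np.asarray(list(gene_ids), dtype=object)
    if top_k > masks.shape[1]:
        raise ValueError(f"top_k={top_k} exceeds gene count {masks.shape[1]}")
    labels = np.asarray(list(labels), dtype=object)
    out: dict[str, np.ndarray] = {}
    for t in np.unique(labels):
        mean = masks[labels == t].mean(axis=0)
        order = np.argsort(-mean, kind="stable")[:top_k]
        out[t] = gene_ids[order]
    return out
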