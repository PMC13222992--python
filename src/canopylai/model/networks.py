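"""The parallel CNN-GRU hybrid regressor and its neural baselines.

The hybrid has two branches consuming the same sample. The CNN branch
mines local association patterns: in feature mode a 1-D convolution runs
along the feature-field axis of the F x L input matrix (timesteps as
channels); in image mode 2-D convolution blocks run over the per-stage
patch stack. The GRU branch consumes the L timesteps sequentially and
encodes the phenological trajectory. A meta-learner (two dense layers)
fuses the concatenated branch representations into one LAI prediction.

Training is full numpy: Adam on mean-squared error with mini-batches,
a validation split carved from the training data, and early stopping.
Seeded runs are bit-reproducible on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from canopylai.model._autograd import Tensor, concat, maxpool1d, maxpool2d
from canopylai.model._layers import (
    Adam,
    Conv1D,
    Conv2D,
    Dense,
    GRULayer,
    LayerNorm,
    Module,
    MultiHeadAttention,
    spatial_dropout,
)

__all__ = [
    "VALID_IMAGE_SIZES",
    "ModelConfig",
    "NeuralRegressor",
    "CNNGRURegressor",
    "CNNRegressor",
    "TransformerRegressor",
    "build_cnn_gru",
    "train",
    "predict",
]

#: admissible square input sizes for image mode
VALID_IMAGE_SIZES = (16, 32, 64, 96, 128, 192, 224)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the hybrid and its neural baselines.

    Defaults: three 3x3 conv blocks with 64/128/256 filters and 2x2 max
    pooling, spatial dropout 0.2, a two-layer GRU with 128 and 64 hidden
    units, a meta-learner with 128 and 64 neurons, Adam at 0.001 with
    batch size 32 and early stopping (patience 20 on a 10% validation
    split, at most 500 epochs). ``image_size`` must come from the studied
    size ladder when in image mode.
    """

    input_mode: str = "feature"  # "feature" (F x L matrix) or "image"
    n_features: int = 18
    n_stages: int = 3
    image_size: int = 128
    image_channels: int = 9  # 3 bands x L stages stacked on channels
    sequence_dim: int | None = None  # GRU input width; feature mode: F
    cnn_filters: tuple[int, ...] = (64, 128, 256)
    kernel: int = 3
    dropout: float = 0.2
    gru_units: tuple[int, ...] = (128, 64)
    branch_head: int = 64
    meta_units: tuple[int, ...] = (128, 64)
    transformer_dim: int = 64
    transformer_heads: int = 4
    transformer_layers: int = 2
    lr: float = 0.001
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_mode not in ("feature", "image"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "image" and self.image_size not in VALID_IMAGE_SIZES:
            raise ValueError(
                f"image size {self.image_size} not in {VALID_IMAGE_SIZES}"
            )
        if any(u <= 0 for u in (*self.cnn_filters, *self.gru_units,
                                *self.meta_units, self.branch_head)):
            raise ValueError("all layer sizes must be positive")
        if self.n_stages < 1:
            raise ValueError("need at least one timestep")
        extent = (
            self.n_features if self.input_mode == "feature" else self.image_size
        )
        if extent // (2 ** len(self.cnn_filters)) < 1:
            raise ValueError(
                f"pool depth {len(self.cnn_filters)} exceeds input extent {extent}"
            )

    @property
    def gru_input_dim(self) -> int:
        if self.sequence_dim is not None:
            return self.sequence_dim
        return self.n_features if self.input_mode == "feature" else 6


# ---------------------------------------------------------------------------
# Training loop shared by all in-package networks
# ---------------------------------------------------------------------------


class NeuralRegressor(Module):
    """Shared fit/predict machinery; subclasses implement ``forward``."""

    config: ModelConfig

    def __init__(self, config: ModelConfig):
        self.config = config
        self.history: list[dict] = []
        self.final_train_mse_: float | None = None

    def forward(self, batch: dict[str, np.ndarray], training: bool,
                rng: np.random.Generator) -> Tensor:
        raise NotImplementedError

    # -- helpers --------------------------------------------------------
    @staticmethod
    def _take(inputs: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
        return {k: v[idx] for k, v in inputs.items()}

    def _eval_mse(self, inputs: dict[str, np.ndarray], y: np.ndarray) -> float:
        pred = self.predict(inputs)
        return float(np.mean((pred - y) ** 2))

    def fit(self, inputs: dict[str, np.ndarray], y: np.ndarray) -> "NeuralRegressor":
        cfg = self.config
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(cfg.seed)
        n_val = int(round(cfg.val_fraction * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:  # degenerate tiny sets train on everything
            tr_idx, val_idx = perm, perm[:0]
        tr_in, tr_y = self._take(inputs, tr_idx), y[tr_idx]
        val_in, val_y = self._take(inputs, val_idx), y[val_idx]

        opt = Adam(self.parameters(), lr=cfg.lr)
        best_loss, best_state, since_best = np.inf, self.state(), 0
        self.history = []
        m = len(tr_y)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(m)
            epoch_loss = 0.0
            for start in range(0, m, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = self._take(tr_in, idx)
                pred = self.forward(batch, training=True, rng=rng)
                err = pred - tr_y[idx]
                loss = (err**2.0).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss.data!r}"
                    )
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            train_mse = epoch_loss / m
            monitor = self._eval_mse(val_in, val_y) if len(val_y) else train_mse
            self.history.append(
                {"epoch": epoch, "train_mse": train_mse, "val_mse": monitor}
            )
            if monitor < best_loss - 1e-9:
                best_loss, best_state, since_best = monitor, self.state(), 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        self.load_state(best_state)
        self.final_train_mse_ = self._eval_mse(tr_in, tr_y)
        return self

    def predict(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        n = len(next(iter(inputs.values())))
        rng = np.random.default_rng(0)  # unused at eval; forward is deterministic
        out = []
        for start in range(0, n, 256):
            idx = np.arange(start, min(start + 256, n))
            batch = self._take(inputs, idx)
            out.append(self.forward(batch, training=False, rng=rng).data.ravel())
        return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# Branches
# ---------------------------------------------------------------------------


class _CNNBranch(Module):
    """Conv blocks + flatten + one dense head, 1-D or 2-D by mode."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.convs: list[Module] = []
        if config.input_mode == "feature":
            c_in, extent = config.n_stages, config.n_features
            make = Conv1D
        else:
            c_in, extent = config.image_channels, config.image_size
            make = Conv2D
        for c_out in config.cnn_filters:
            self.convs.append(make(c_in, c_out, config.kernel, rng))
            c_in = c_out
            extent //= 2
        if config.input_mode == "feature":
            flat = c_in * extent
        else:
            flat = c_in * extent * extent
        self.head = Dense(flat, config.branch_head, rng)

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        cfg = self.config
        pool = maxpool1d if cfg.input_mode == "feature" else maxpool2d
        for conv in self.convs:
            x = conv(x).relu()
            x = spatial_dropout(x, cfg.dropout, rng, training)
            x = pool(x, 2)
        n = x.shape[0]
        x = x.reshape(n, -1)
        return self.head(x).relu()


class _GRUBranch(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.layers: list[GRULayer] = []
        d = config.gru_input_dim
        for units in config.gru_units:
            self.layers.append(GRULayer(d, units, rng))
            d = units

    def __call__(self, xs: list[Tensor]) -> Tensor:
        for layer in self.layers:
            xs = layer(xs)
        return xs[-1]  # final hidden state of the top layer


def _sequence_tensors(seq: np.ndarray) -> list[Tensor]:
    """(N, L, D) array -> list of L (N, D) leaf tensors."""
    return [Tensor(seq[:, t, :]) for t in range(seq.shape[1])]


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class CNNGRURegressor(NeuralRegressor):
    """Parallel CNN + GRU branches fused by a dense meta-learner."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        self.cnn = _CNNBranch(config, rng)
        self.gru = _GRUBranch(config, rng)
        d = config.branch_head + config.gru_units[-1]
        self.meta: list[Dense] = []
        for units in config.meta_units:
            self.meta.append(Dense(d, units, rng))
            d = units
        self.out = Dense(d, 1, rng)
        #: multiply the GRU branch output by this at fusion; setting it to
        #: 0 ablates the temporal branch without retraining
        self.gru_gate = 1.0

    def forward(self, batch, training, rng):
        cfg = self.config
        if cfg.input_mode == "feature":
            mat = batch["matrix"]  # (N, F, L)
            cnn_in = Tensor(mat.transpose(0, 2, 1))  # timesteps as channels
            seq = mat.transpose(0, 2, 1)  # (N, L, F)
        else:
            cnn_in = Tensor(batch["image"])
            seq = batch["sequence"]
        c = self.cnn(cnn_in, training, rng)
        g = self.gru(_sequence_tensors(seq)) * self.gru_gate
        x = concat([c, g], axis=1)
        for dense in self.meta:
            x = dense(x).relu()
        return self.out(x).reshape(-1)


class CNNRegressor(NeuralRegressor):
    """The CNN branch plus dense head alone — the single-branch baseline."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        self.cnn = _CNNBranch(config, rng)
        self.out = Dense(config.branch_head, 1, rng)

    def forward(self, batch, training, rng):
        if self.config.input_mode == "feature":
            cnn_in = Tensor(batch["matrix"].transpose(0, 2, 1))
        else:
            cnn_in = Tensor(batch["image"])
        return self.out(self.cnn(cnn_in, training, rng)).reshape(-1)


class _EncoderLayer(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Dense(dim, 4 * dim, rng)
        self.ff2 = Dense(4 * dim, dim, rng)
        self.norm2 = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ff2(self.ff1(x).relu()))


class TransformerRegressor(NeuralRegressor):
    """A small encoder over the timestep tokens (or image patches).

    Two encoder layers, four heads, width 64 — the smallest credible
    encoder for a comparison slot the study names but does not specify.
    """

    PATCH = 16  # image-mode token size

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        d = config.transformer_dim
        if config.input_mode == "feature":
            token_dim, n_tokens = config.n_features, config.n_stages
        else:
            per_side = max(config.image_size // self.PATCH, 1)
            n_tokens = per_side * per_side
            token_dim = config.image_channels * min(
                self.PATCH, config.image_size
            ) ** 2
        self.embed = Dense(token_dim, d, rng)
        self.pos = Tensor(0.02 * rng.standard_normal((n_tokens, d)))
        self.layers = [
            _EncoderLayer(d, config.transformer_heads, rng)
            for _ in range(config.transformer_layers)
        ]
        self.head = Dense(d, 1, rng)

    @classmethod
    def tokenize_image(cls, images: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> (N, T, C*p*p) non-overlapping patch tokens."""
        n, c, h, w = images.shape
        p = min(cls.PATCH, h, w)
        hh, ww = h // p, w // p
        x = images[:, :, : hh * p, : ww * p]
        x = x.reshape(n, c, hh, p, ww, p).transpose(0, 2, 4, 1, 3, 5)
        return x.reshape(n, hh * ww, c * p * p)

    def forward(self, batch, training, rng):
        if self.config.input_mode == "feature":
            tokens = batch["matrix"].transpose(0, 2, 1)  # (N, L, F)
        else:
            tokens = self.tokenize_image(batch["image"])
        x = self.embed(Tensor(tokens)) + self.pos
        for layer in self.layers:
            x = layer(x)
        pooled = x.mean(axis=1)
        return self.head(pooled).reshape(-1)


def build_cnn_gru(config: ModelConfig) -> CNNGRURegressor:
    """Construct the untrained parallel hybrid from a config."""
    return CNNGRURegressor(config)


def train(model: NeuralRegressor, inputs: dict[str, np.ndarray],
          y: np.ndarray) -> NeuralRegressor:
    """Fit a network in place (Adam/MSE/early stopping); returns it."""
    return model.fit(inputs, y)


def predict(model, inputs: dict[str, np.ndarray]) -> np.ndarray:
    """One finite LAI prediction per sample, batch-order invariant."""
    out = model.predict(inputs)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite predictions; inputs likely unnormalized")
    return out
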