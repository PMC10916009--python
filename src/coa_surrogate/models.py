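"""The two surrogate architectures as scikit-learn style estimators.

``BRNNRegressor`` is the 1D sequence model: a bidirectional LSTM (200 units
per direction, concatenated), a per-timestep dense layer of 800 units with
Leaky ReLU (slope 0.3), and a per-timestep linear output layer with 8
channels -- 660,008 trainable parameters at the defaults.  It trains on
zero-padded (178 x 7) -> (178 x 8) records with the masked-RMSE loss,
Adam, an exponentially decaying learning rate and early stopping, on
unscaled data by default.

``UNet3DRegressor`` is the 3D model: a U-shaped encoder/decoder with three
blocks per side, two 3x3x3 convolutions with ReLU per block, batch
normalisation at the end of each block, 2x2x2 max pooling, and 2x2x2
transpose convolutions for upsampling.  It maps (48, 48, 80, 7) stacks to
a (48, 48, 80, 1) pressure field; the output is scaled by its standard
deviation during training, inputs stay unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .errors import ParameterError
from .features1d import lengths_to_mask
from .features3d import planes_to_centerline  # re-export: 3D -> 1D comparison path
from .nn import (
    BatchNorm,
    BiLSTM,
    Conv3D,
    ConvTranspose3D,
    Dense,
    LeakyReLU,
    MaxPool3D,
    ReLU,
    fit_model,
)
from .nn.losses import masked_rmse

__all__ = [
    "BRNNConfig",
    "CNNConfig",
    "BRNNRegressor",
    "UNet3DRegressor",
    "build_brnn",
    "build_cnn3d",
    "brnn_parameter_count",
    "cross_validate",
    "masked_rmse",
    "planes_to_centerline",
]


@dataclass(frozen=True)
class BRNNConfig:
    """Architecture of the 1D sequence model."""

    lstm_units: int = 200
    dense_units: int = 800
    leaky_slope: float = 0.3
    in_channels: int = 7
    out_channels: int = 8
    seq_len: int = 178

    def __post_init__(self):
        if min(self.lstm_units, self.dense_units, self.in_channels,
               self.out_channels, self.seq_len) <= 0:
            raise ParameterError("all BRNN dimensions must be positive")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ParameterError("leaky_slope must be in (0, 1)")


@dataclass(frozen=True)
class CNNConfig:
    """Architecture of the 3D U-Net."""

    depth: int = 3
    convs_per_block: int = 2
    kernel: int = 3
    base_filters: int = 32
    in_channels: int = 7
    out_channels: int = 1

    def __post_init__(self):
        if min(self.depth, self.convs_per_block, self.base_filters,
               self.in_channels, self.out_channels) <= 0:
            raise ParameterError("all CNN dimensions must be positive")


def brnn_parameter_count(config: BRNNConfig = BRNNConfig()) -> int:
    """Analytic trainable-parameter count of the 1D architecture.

    Standard LSTM gates (input/forget/cell/output, biases, no peepholes):
    2 directions x 4 gates x ((in + H) * H + H), plus the two dense layers
    on the concatenated 2H-wide output.
    """
    f, h, d, o = (config.in_channels, config.lstm_units,
                  config.dense_units, config.out_channels)
    lstm = 2 * 4 * ((f + h) * h + h)
    dense1 = 2 * h * d + d
    dense2 = d * o + o
    return lstm + dense1 + dense2


class _SequentialNet:
    """Plain layer stack with the model protocol used by ``fit_model``."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        return [p for layer in self.layers for p in layer.params.values()]

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def build_brnn(
    config: BRNNConfig = BRNNConfig(), seed: int = 0, dtype=np.float32
) -> _SequentialNet:
    """Instantiate the 1D network; count parameters via ``.n_parameters()``."""
    rng = np.random.default_rng(seed)
    return _SequentialNet(
        [
            BiLSTM(config.in_channels, config.lstm_units, rng, dtype),
            Dense(2 * config.lstm_units, config.dense_units, rng, dtype),
            LeakyReLU(config.leaky_slope),
            Dense(config.dense_units, config.out_channels, rng, dtype),
        ]
    )


class _UNet3DNet:
    """U-shaped encoder/decoder with skip connections."""

    def __init__(self, config: CNNConfig, rng, dtype=np.float32):
        self.config = config
        f = config.base_filters
        self.enc_blocks = []
        c = config.in_channels
        for d in range(config.depth):
            self.enc_blocks.append(self._block(c, f * 2**d, rng, dtype))
            c = f * 2**d
        self.pools = [MaxPool3D() for _ in range(config.depth)]
        self.bottleneck = self._block(c, f * 2**config.depth, rng, dtype)
        c = f * 2**config.depth
        self.upconvs = []
        self.dec_blocks = []
        for d in range(config.depth - 1, -1, -1):
            skip_c = f * 2**d
            self.upconvs.append(ConvTranspose3D(c, skip_c, rng, dtype))
            self.dec_blocks.append(self._block(2 * skip_c, skip_c, rng, dtype))
            c = skip_c
        self.head = Conv3D(c, config.out_channels, rng, k=1, dtype=dtype)
        self._all_layers = (
            [l for b in self.enc_blocks for l in b]
            + self.pools
            + list(self.bottleneck)
            + self.upconvs
            + [l for b in self.dec_blocks for l in b]
            + [self.head]
        )

    def _block(self, c_in, c_out, rng, dtype):
        layers = []
        c = c_in
        for _ in range(self.config.convs_per_block):
            layers += [Conv3D(c, c_out, rng, k=self.config.kernel, dtype=dtype), ReLU()]
            c = c_out
        layers.append(BatchNorm(c_out, dtype=dtype))
        return layers

    @staticmethod
    def _run(block, x, train):
        for layer in block:
            x = layer.forward(x, train=train)
        return x

    @staticmethod
    def _run_back(block, dout):
        for layer in reversed(block):
            dout = layer.backward(dout)
        return dout

    def forward(self, x, train=True):
        self._check_divisibility(x.shape[1:4])
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = self._run(block, x, train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self._run(self.bottleneck, x, train)
        self._skip_channels = []
        for up, block, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train=train)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = self._run(block, x, train)
        return self.head.forward(x, train=train)

    def backward(self, dout):
        dout = self.head.backward(dout)
        dskips = []
        for up, block, sc in zip(
            reversed(self.upconvs), reversed(self.dec_blocks), reversed(self._skip_channels)
        ):
            dout = self._run_back(block, dout)
            dskip, dup = dout[..., :sc], dout[..., sc:]
            dskips.append(dskip)
            dout = up.backward(dup)
        dout = self._run_back(self.bottleneck, dout)
        # dskips accumulated shallowest-first, i.e. already in encoder order
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dout = pool.backward(dout) + dskip
            dout = self._run_back(block, dout)
        return dout

    def _check_divisibility(self, spatial):
        div = 2**self.config.depth
        if any(s % div for s in spatial):
            raise ParameterError(
                f"spatial dims {spatial} must be divisible by {div} "
                f"for a depth-{self.config.depth} U-Net"
            )

    def parameters(self):
        return [p for layer in self._all_layers for p in layer.params.values()]

    def zero_grad(self):
        for layer in self._all_layers:
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def build_cnn3d(
    config: CNNConfig = CNNConfig(), seed: int = 0, dtype=np.float32
) -> _UNet3DNet:
    """Instantiate the 3D U-Net."""
    return _UNet3DNet(config, np.random.default_rng(seed), dtype)


def _split_validation(n, fraction, rng):
    if not 0.0 < fraction < 1.0:
        raise ParameterError("validation_fraction must be in (0, 1)")
    n_val = max(1, int(round(fraction * n)))
    if n_val >= n:
        raise ParameterError("validation split leaves no training cases")
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


class BRNNRegressor(RegressorMixin, BaseEstimator):
    """Bidirectional-LSTM sequence regressor for centerline hemodynamics.

    Parameters mirror the training protocol: Adam at ``lr_init`` with
    exponential decay ``lr_decay`` per epoch, batch size 50, early-stopping
    patience 20, and no input/output scaling by default (``scaling`` may be
    ``"none"``, ``"normalize"`` or ``"standardize"``).

    Fitted attributes: ``net_`` (the layer stack), ``history_`` (per-epoch
    losses and learning rates), ``n_parameters_``.
    """

    def __init__(
        self,
        lstm_units: int = 200,
        dense_units: int = 800,
        leaky_slope: float = 0.3,
        lr_init: float = 1e-3,
        lr_decay: float = 0.96,
        batch_size: int = 50,
        patience: int = 20,
        max_epochs: int = 1000,
        validation_fraction: float = 0.1,
        scaling: str = "none",
        bias_init_to_mean: bool = True,
        random_state: int = 0,
    ):
        self.lstm_units = lstm_units
        self.dense_units = dense_units
        self.leaky_slope = leaky_slope
        self.lr_init = lr_init
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.scaling = scaling
        self.bias_init_to_mean = bias_init_to_mean
        self.random_state = random_state

    def _scale_factors(self, X, y, mask):
        if self.scaling == "none":
            return None
        my = mask[..., None] & np.ones(y.shape[-1], dtype=bool)
        mx = mask[..., None] & np.ones(X.shape[-1], dtype=bool)
        stats = {}
        if self.scaling == "standardize":
            for name, arr, m in (("x", X, mx), ("y", y, my)):
                vals = np.where(m, arr, np.nan)
                mean = np.nanmean(vals, axis=(0, 1))
                sd = np.nanstd(vals, axis=(0, 1))
                stats[name] = (mean, np.where(sd > 0, sd, 1.0))
        elif self.scaling == "normalize":
            for name, arr, m in (("x", X, mx), ("y", y, my)):
                vals = np.where(m, arr, np.nan)
                lo = np.nanmin(vals, axis=(0, 1))
                hi = np.nanmax(vals, axis=(0, 1))
                span = np.where(hi > lo, hi - lo, 1.0)
                stats[name] = (lo, span)
        else:
            raise ParameterError(f"unknown scaling {self.scaling!r}")
        return stats

    @staticmethod
    def _apply(arr, stat, mask):
        loc, scale = stat
        return np.where(mask[..., None], (arr - loc) / scale, 0.0)

    def fit(self, X, y, valid_lengths=None, validation_data=None):
        """Fit on padded sequences.

        X: (C, T, 7); y: (C, T, 8); ``valid_lengths`` (C,) marks the
        unpadded span of each case (defaults to full length).
        ``validation_data`` may be a tuple (X, y, lengths); otherwise
        ``validation_fraction`` of the cases is held out.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 3 or y.ndim != 3 or X.shape[:2] != y.shape[:2]:
            raise ParameterError("X and y must be (C, T, features) with matching C, T")
        T = X.shape[1]
        if valid_lengths is None:
            valid_lengths = np.full(len(X), T)
        mask = lengths_to_mask(valid_lengths, T)

        rng = np.random.default_rng(self.random_state)
        if validation_data is not None:
            Xv, yv, lv = validation_data
            Xv = np.asarray(Xv, dtype=np.float32)
            yv = np.asarray(yv, dtype=np.float32)
            mv = lengths_to_mask(lv, T)
            Xt, yt, mt = X, y, mask
        else:
            tr, va = _split_validation(len(X), self.validation_fraction, rng)
            Xt, yt, mt = X[tr], y[tr], mask[tr]
            Xv, yv, mv = X[va], y[va], mask[va]

        self.scale_stats_ = self._scale_factors(Xt, yt, mt)
        if self.scale_stats_ is not None:
            # inputs are scaled without masking so padded rows carry the
            # same constant token at fit and predict time (predict has no
            # access to valid lengths); target padding stays zero but is
            # masked out of the loss either way
            loc_x, scale_x = self.scale_stats_["x"]
            Xt = ((Xt - loc_x) / scale_x).astype(np.float32)
            Xv = ((Xv - loc_x) / scale_x).astype(np.float32)
            yt = self._apply(yt, self.scale_stats_["y"], mt).astype(np.float32)
            yv = self._apply(yv, self.scale_stats_["y"], mv).astype(np.float32)

        config = BRNNConfig(
            lstm_units=self.lstm_units,
            dense_units=self.dense_units,
            leaky_slope=self.leaky_slope,
            in_channels=X.shape[2],
            out_channels=y.shape[2],
            seq_len=T,
        )
        net_seed = int(rng.integers(2**31))
        self.net_ = build_brnn(config, seed=net_seed)
        if self.bias_init_to_mean:
            # start the output layer at the per-channel mean of the valid
            # targets; with unscaled targets (pressure ~120 mmHg) this
            # removes the large initial offset Adam would otherwise have to
            # walk down at ~lr per step
            out_bias = self.net_.layers[-1].params["b"]
            means = yt.reshape(-1, yt.shape[-1])[mt.reshape(-1)].mean(axis=0)
            out_bias.value[...] = means.astype(out_bias.value.dtype)

        self.history_ = fit_model(
            self.net_, Xt, yt, mt, Xv, yv, mv,
            lr_init=self.lr_init, lr_decay=self.lr_decay,
            batch_size=self.batch_size, patience=self.patience,
            max_epochs=self.max_epochs, rng=rng,
        )
        self.n_parameters_ = self.net_.n_parameters()
        self.config_ = config
        return self

    def predict(self, X, batch_size: int = 64):
        X = np.asarray(X, dtype=np.float32)
        if self.scale_stats_ is not None:
            loc, scale = self.scale_stats_["x"]
            X = ((X - loc) / scale).astype(np.float32)
        preds = []
        for start in range(0, len(X), batch_size):
            preds.append(self.net_.forward(X[start : start + batch_size], train=False))
        pred = np.concatenate(preds, axis=0).astype(float)
        if self.scale_stats_ is not None:
            loc, scale = self.scale_stats_["y"]
            pred = pred * scale + loc
        return pred

    def score(self, X, y, valid_lengths=None):
        """Negative masked RMSE (higher is better, sklearn convention)."""
        T = np.asarray(X).shape[1]
        if valid_lengths is None:
            valid_lengths = np.full(len(X), T)
        mask = lengths_to_mask(valid_lengths, T)
        return -masked_rmse(self.predict(X), np.asarray(y, dtype=float), mask)


class UNet3DRegressor(RegressorMixin, BaseEstimator):
    """3D U-Net regressor mapping cross-section stacks to a pressure field.

    The output is divided by its standard deviation (over in-lumen voxels
    of the training set) during training and rescaled at prediction time;
    inputs are left unscaled.
    """

    def __init__(
        self,
        base_filters: int = 32,
        depth: int = 3,
        convs_per_block: int = 2,
        kernel: int = 3,
        lr_init: float = 1e-4,
        lr_decay: float = 0.96,
        batch_size: int = 8,
        patience: int = 20,
        max_epochs: int = 1000,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.base_filters = base_filters
        self.depth = depth
        self.convs_per_block = convs_per_block
        self.kernel = kernel
        self.lr_init = lr_init
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y, mask=None):
        """Fit on volumes X (C, D, H, W, 7), y (C, D, H, W, 1), boolean
        lumen ``mask`` (C, D, H, W)."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if mask is None:
            mask = np.ones(y.shape[:-1], dtype=bool)
        mask = np.asarray(mask, dtype=bool)

        rng = np.random.default_rng(self.random_state)
        config = CNNConfig(
            depth=self.depth,
            convs_per_block=self.convs_per_block,
            kernel=self.kernel,
            base_filters=self.base_filters,
            in_channels=X.shape[-1],
            out_channels=y.shape[-1],
        )
        self.net_ = build_cnn3d(config, seed=int(rng.integers(2**31)))

        tr, va = _split_validation(len(X), self.validation_fraction, rng)
        self.y_scale_ = float(y[tr][mask[tr]].std()) or 1.0
        ys = (y / self.y_scale_).astype(np.float32)

        self.history_ = fit_model(
            self.net_, X[tr], ys[tr], mask[tr], X[va], ys[va], mask[va],
            lr_init=self.lr_init, lr_decay=self.lr_decay,
            batch_size=self.batch_size, patience=self.patience,
            max_epochs=self.max_epochs, rng=rng,
        )
        self.n_parameters_ = self.net_.n_parameters()
        self.config_ = config
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float32)
        preds = [
            self.net_.forward(X[i : i + 1], train=False) for i in range(len(X))
        ]
        return np.concatenate(preds, axis=0).astype(float) * self.y_scale_


def cross_validate(
    X,
    y,
    valid_lengths,
    param_grid: dict[str, list],
    base_params: dict | None = None,
    k: int = 10,
    seed: int = 0,
) -> dict[str, dict]:
    """k-fold cross-validation of the 1D model, one hyperparameter at a time.

    For every ``name -> candidate values`` entry of ``param_grid`` each
    candidate is scored by the mean validation masked RMSE over ``k``
    seeded, disjoint folds (all other hyperparameters at ``base_params``).
    """
    n = len(X)
    if k > n:
        raise ParameterError(f"k={k} exceeds the {n} available cases")
    base_params = dict(base_params or {})
    results: dict[str, dict] = {}
    for name, values in param_grid.items():
        results[name] = {}
        for value in values:
            folds = []
            kf = KFold(n_splits=k, shuffle=True, random_state=seed)
            for tr, va in kf.split(X):
                params = dict(base_params, **{name: value})
                est = BRNNRegressor(**params)
                est.fit(X[tr], y[tr], valid_lengths[tr])
                folds.append(-est.score(X[va], y[va], valid_lengths[va]))
            results[name][value] = {
                "fold_scores": folds,
                "mean": float(np.mean(folds)),
            }
    return results
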