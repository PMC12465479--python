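"""The 2D-CNN motor-hotspot coordinate regressor.

The model follows the statsmodels convention: :class:`MotorHotspotCNN` is
built from data (a trials x channels x width tensor and mm targets) and a
:class:`ModelConfig`; ``fit()`` trains with Adam on an MSE loss, early
stopping on validation loss, and returns a :class:`HotspotCNNResults` object
carrying the trained weights, training history and prediction methods.

Architecture (17 weight-bearing layers): four convolution blocks of
(2, 2, 3, 3) stride-1 7x7 convolutions with 16/32/64/128 filters and
shape-preserving padding, each block followed by a 2x2 stride-2 max-pool
(ceil semantics), then flatten and three fully connected layers whose final
width is 3 (x, y, z in mm) with a linear output activation.  All hidden
activations are ReLU.

Inputs are standardized per channel with statistics from the training data
only.  Targets are internally normalized by ``coordinate_scale`` (the head
radius) during optimization so the Adam step size is well matched to the
coordinate magnitudes; losses in the history are reported in mm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .montage import HotspotLocation, HotspotSource

DEFAULT_CONV_BLOCKS = ((2, 16), (2, 32), (3, 64), (3, 128))


@dataclass(frozen=True)
class ModelConfig:
    conv_blocks: tuple[tuple[int, int], ...] = DEFAULT_CONV_BLOCKS
    kernel: tuple[int, int] = (7, 7)
    dense_hidden: tuple[int, ...] = (256, 64)
    lr: float = 0.001
    batch_size: int = 10
    max_epochs: int = 1000
    patience: int = 20
    coordinate_scale: float = 90.0  # mm; head radius
    seed: int = 0

    @property
    def dense_sizes(self) -> tuple[int, ...]:
        return (*self.dense_hidden, 3)

    @property
    def n_layers(self) -> int:
        """Weight-bearing + pooling layer count (flatten not counted)."""
        n_convs = sum(b[0] for b in self.conv_blocks)
        return n_convs + len(self.conv_blocks) + len(self.dense_sizes)

    def with_updates(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


def build_model(config: ModelConfig, input_shape: tuple[int, int]):
    """Construct the untrained network and an auditable layer report.

    ``input_shape`` is (channels, width).  Returns ``(network, report)``
    where the report lists, per layer, name / kernel / filters / stride and
    the output shape, mirroring the architecture table layout.
    """
    h, w = input_shape
    n_pools = len(config.conv_blocks)
    if h < 5 or w < 5:
        raise ValueError(
            f"input shape {input_shape} too small; need at least (5, 5) to "
            f"survive {n_pools} pooling stages"
        )
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    report = [{"name": "Input", "kernel": None, "filters": None, "stride": None,
               "output_shape": (1, h, w)}]
    c_in, cur_h, cur_w = 1, h, w
    conv_i, pool_i = 0, 0
    for n_convs, n_filters in config.conv_blocks:
        for _ in range(n_convs):
            conv_i += 1
            layers += [nn.Conv2D(c_in, n_filters, config.kernel, rng), nn.ReLU()]
            c_in = n_filters
            report.append({
                "name": f"Conv{conv_i}", "kernel": config.kernel,
                "filters": n_filters, "stride": 1,
                "output_shape": (n_filters, cur_h, cur_w),
            })
        pool_i += 1
        layers.append(nn.MaxPool2x2())
        cur_h, cur_w = -(-cur_h // 2), -(-cur_w // 2)
        report.append({
            "name": f"Max-pooling{pool_i}", "kernel": (2, 2),
            "filters": c_in, "stride": 2,
            "output_shape": (c_in, cur_h, cur_w),
        })
    layers.append(nn.Flatten())
    n_in = c_in * cur_h * cur_w
    report.append({"name": "Flatten", "kernel": None, "filters": None,
                   "stride": None, "output_shape": (n_in,)})
    for i, size in enumerate(config.dense_sizes, start=1):
        last = i == len(config.dense_sizes)
        layers.append(nn.Dense(n_in, size, rng, relu_fan=not last))
        if not last:
            layers.append(nn.ReLU())
        report.append({"name": f"Dense{i}", "kernel": None, "filters": size,
                       "stride": None, "output_shape": (size,),
                       "activation": "linear" if last else "relu"})
        n_in = size
    return nn.Network(layers), report


# ---------------------------------------------------------------------------
# input standardization


@dataclass
class ChannelScaler:
    """Per-channel z-scoring with statistics from the training data only."""

    mean: np.ndarray = field(default=None, repr=False)
    sd: np.ndarray = field(default=None, repr=False)

    def fit(self, x: np.ndarray) -> "ChannelScaler":
        x = np.asarray(x)
        self.mean = x.mean(axis=(0, 2))
        sd = x.std(axis=(0, 2))
        zero = sd == 0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} zero-variance channel(s); using unit scale",
                stacklevel=2,
            )
            sd = np.where(zero, 1.0, sd)
        self.sd = sd
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("scaler not fitted")
        return (x - self.mean[None, :, None]) / self.sd[None, :, None]


def standardize_inputs(train: np.ndarray, *apply_to: np.ndarray):
    """Z-score tensors per channel using training statistics (no leakage).

    Returns ``(train_scaled, *apply_scaled, scaler)``.
    """
    if train.shape[0] == 0:
        raise ValueError("training set is empty")
    scaler = ChannelScaler().fit(train)
    out = [scaler.transform(train)] + [scaler.transform(a) for a in apply_to]
    return (*out, scaler)


# ---------------------------------------------------------------------------
# model / results


def _as_targets(y, n):
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = np.tile(y, (n, 1))
    if y.shape != (n, 3):
        raise ValueError(f"targets must be (n, 3) mm coordinates, got {y.shape}")
    return y


class MotorHotspotCNN:
    """CNN regressor from single-trial EEG tensors to hotspot coordinates.

    Parameters
    ----------
    inputs : ndarray, trials x channels x width
        Training tensors (time series or PSD bins).
    targets : ndarray, (3,) or (trials, 3)
        Hotspot coordinates in mm (vertex-origin frame).  A single 3-vector
        is broadcast over trials.
    config : ModelConfig, optional
    """

    def __init__(self, inputs, targets, config: ModelConfig | None = None):
        self.inputs = np.asarray(inputs, dtype=float)
        if self.inputs.ndim != 3:
            raise ValueError("inputs must be trials x channels x width")
        self.targets = _as_targets(targets, self.inputs.shape[0])
        self.config = config or ModelConfig()
        self.input_shape = self.inputs.shape[1:]

    @classmethod
    def from_model_input(cls, model_input, truth, config=None):
        """Build from a preprocessing ModelInput and a HotspotLocation."""
        t = truth.to_array() if isinstance(truth, HotspotLocation) else truth
        return cls(model_input.tensor, t, config)

    def fit(self, val_inputs=None, val_targets=None, val_fraction=0.2,
            shuffle_seed=None, verbose=False) -> "HotspotCNNResults":
        """Train with Adam/MSE and early stopping on validation loss.

        If no explicit validation set is given, a seeded ``val_fraction``
        split of the training data is held out.
        """
        cfg = self.config
        rng = np.random.default_rng(
            cfg.seed if shuffle_seed is None else shuffle_seed
        )
        x, y = self.inputs, self.targets
        if val_inputs is None:
            n = x.shape[0]
            n_val = max(1, int(np.floor(n * val_fraction)))
            if n - n_val < 1:
                raise ValueError("not enough trials to hold out a validation set")
            perm = rng.permutation(n)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            val_inputs, val_targets = x[val_idx], y[val_idx]
            x, y = x[train_idx], y[train_idx]
        else:
            val_targets = _as_targets(val_targets, np.asarray(val_inputs).shape[0])

        x_s, xv_s, scaler = standardize_inputs(x, np.asarray(val_inputs))
        scale = cfg.coordinate_scale
        y_s = (y / scale).astype(nn.DTYPE)
        yv_s = (val_targets / scale).astype(nn.DTYPE)
        x_s = x_s[:, None, :, :].astype(nn.DTYPE)
        xv_s = xv_s[:, None, :, :].astype(nn.DTYPE)

        network, report = build_model(cfg, self.input_shape)
        optimizer = nn.Adam(network, lr=cfg.lr)

        n = x_s.shape[0]
        history = {"epoch": [], "train_loss": [], "val_loss": []}
        best_val, best_epoch, best_weights = np.inf, 0, network.get_weights()
        stopped_epoch = cfg.max_epochs
        mm2 = scale**2

        for ep in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                network.zero_grad()
                pred = network.forward(x_s[idx], train=True)
                loss, grad = nn.mse_loss(pred, y_s[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf training loss at epoch {ep}; check that "
                        "inputs are standardized and targets are in mm"
                    )
                network.backward(grad.astype(nn.DTYPE))
                optimizer.step()
                batch_losses.append(loss)
            val_pred = network.forward(xv_s, train=False)
            val_loss, _ = nn.mse_loss(val_pred, yv_s)
            history["epoch"].append(ep)
            history["train_loss"].append(float(np.mean(batch_losses)) * mm2)
            history["val_loss"].append(val_loss * mm2)
            if verbose:
                print(f"epoch {ep}: train {history['train_loss'][-1]:.2f} "
                      f"val {history['val_loss'][-1]:.2f} (mm^2)")
            if val_loss < best_val:
                best_val, best_epoch = val_loss, ep
                best_weights = network.get_weights()
            elif ep - best_epoch >= cfg.patience:
                stopped_epoch = ep
                break
        else:
            stopped_epoch = cfg.max_epochs

        network.set_weights(best_weights)
        return HotspotCNNResults(
            model=self, network=network, scaler=scaler, layer_report=report,
            history=history, best_epoch=best_epoch, stopped_epoch=stopped_epoch,
            best_val_loss=best_val * mm2,
        )


class HotspotCNNResults:
    """Fitted-model results: weights, history, predictions, summary."""

    def __init__(self, model, network, scaler, layer_report, history,
                 best_epoch, stopped_epoch, best_val_loss):
        self.model = model
        self.network = network
        self.scaler = scaler
        self.layer_report = layer_report
        self.history = history
        self.best_epoch = best_epoch
        self.stopped_epoch = stopped_epoch
        self.best_val_loss = best_val_loss

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def predict(self, inputs: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-trial coordinate predictions (n, 3) in mm."""
        inputs = np.asarray(inputs, dtype=float)
        if inputs.ndim == 2:
            inputs = inputs[None]
        if inputs.shape[1:] != self.model.input_shape:
            raise ValueError(
                f"input shape {inputs.shape[1:]} does not match model input "
                f"shape {self.model.input_shape}"
            )
        x = self.scaler.transform(inputs)[:, None, :, :].astype(nn.DTYPE)
        preds = [
            self.network.forward(x[i:i + batch_size], train=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(preds).astype(float) * self.config.coordinate_scale

    def predict_location(self, inputs: np.ndarray) -> HotspotLocation:
        """Subject-level prediction: mean over per-trial predictions."""
        mean = self.predict(inputs).mean(axis=0)
        return HotspotLocation.from_array(mean, HotspotSource.PREDICTED)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Motor hotspot CNN regression results",
            "=" * 44,
            f"input shape (channels x width): {self.model.input_shape}",
            f"layers: {cfg.n_layers} "
            f"({sum(b[0] for b in cfg.conv_blocks)} conv, "
            f"{len(cfg.conv_blocks)} pool, {len(cfg.dense_sizes)} dense)",
            f"optimizer: Adam(lr={cfg.lr}), loss: MSE, batch={cfg.batch_size}",
            f"epochs run: {self.stopped_epoch} (best epoch {self.best_epoch}, "
            f"patience {cfg.patience})",
            f"best val loss: {self.best_val_loss:.3f} mm^2 "
            f"(RMSE {np.sqrt(self.best_val_loss):.3f} mm)",
            "-" * 44,
            f"{'layer':<14}{'kernel':<9}{'filters':<9}{'stride':<7}out",
        ]
        for row in self.layer_report:
            k = "x".join(map(str, row["kernel"])) if row["kernel"] else "-"
            f = row["filters"] if row["filters"] is not None else "-"
            s = row["stride"] if row["stride"] is not None else "-"
            lines.append(
                f"{row['name']:<14}{k:<9}{f!s:<9}{s!s:<7}{row['output_shape']}"
            )
        return "\n".join(lines)
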