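"""The GCFN classifier: parallel GRU + CNN feature fusion, plus ablations.

Two branches extract complementary features from each trial and are fused
by concatenation before a shared classifier:

* CNN branch — the 224 x 93 grayscale scalogram passes through a single
  2-D convolution whose 224 x 1 kernels span the full image height (so the
  output height collapses to 1), ReLU, 1 x 3 max pooling with stride 1 x 3
  (93 -> 31 columns, floor semantics), and flattening;
* GRU branch — the z-scored 875 x 22 time series (time steps x channels)
  passes through two stacked gated-recurrent-unit layers (25 units
  returning the full sequence, then 50 units returning the final state).

The fused vector feeds a 128-unit ReLU layer with dropout 0.3 and a 4-way
softmax.  At the published geometry the per-layer trainable parameter
counts are 14,400 (conv), 3,675 (GRU-1), 11,550 (GRU-2), 260,480 (FC-128)
and 516 (FC-4); the GRU counts force the two-bias ("reset-after")
convention, 3*(units*(inputs+units) + 2*units) per layer.

Single-branch ablation variants (:func:`build_eeg_gru`,
:func:`build_cwt_cnn`) reuse the identical classifier head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    Adam,
    ConvFullHeight,
    Dense,
    Dropout,
    GRULayer,
    Layer,
    MaxPoolWidth,
    ReLU,
    sigmoid,
    softmax,
)

__all__ = [
    "GCFNConfig", "FusionNet",
    "build_gcfn", "build_eeg_gru", "build_cwt_cnn",
    "gru_cell_step", "gru_param_count",
]


@dataclass(frozen=True)
class GCFNConfig:
    """Architecture hyperparameters (defaults mirror the published geometry)."""

    cnn_filters: int = 64
    cnn_kernel: tuple[int, int] = (224, 1)
    cnn_stride: tuple[int, int] = (1, 1)
    pool_size: tuple[int, int] = (1, 3)
    pool_stride: tuple[int, int] = (1, 3)
    gru1_units: int = 25
    gru2_units: int = 50
    fc1_units: int = 128
    n_classes: int = 4
    dropout_p: float = 0.3
    eeg_input: tuple[int, int] = (875, 22)      # time steps x channels
    image_input: tuple[int, int, int] = (224, 93, 1)

    def __post_init__(self) -> None:
        for name in ("cnn_filters", "gru1_units", "gru2_units", "fc1_units", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p must lie in [0, 1), got {self.dropout_p}")
        if self.cnn_kernel[0] != self.image_input[0]:
            raise ValueError(
                f"kernel height {self.cnn_kernel[0]} must equal image height "
                f"{self.image_input[0]} (full-height 1-D filters)"
            )
        if self.cnn_kernel[1] != 1 or self.cnn_stride != (1, 1):
            raise ValueError("only width-1 kernels with unit stride are supported")
        if self.pool_size != self.pool_stride:
            raise ValueError("pool size must equal pool stride (non-overlapping pooling)")

    # Derived geometry -----------------------------------------------------
    @property
    def conv_out_width(self) -> int:
        return self.image_input[1]  # 'valid' width-1 kernel keeps the width

    @property
    def pool_out_width(self) -> int:
        return self.conv_out_width // self.pool_size[1]

    @property
    def flatten_len(self) -> int:
        return self.cnn_filters * self.pool_out_width

    @property
    def fused_len(self) -> int:
        return self.flatten_len + self.gru2_units


def gru_param_count(n_in: int, units: int) -> int:
    """Trainable parameters of a two-bias GRU layer."""
    return 3 * (units * (n_in + units) + 2 * units)


def gru_cell_step(x_t: np.ndarray, h_prev: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """One GRU state update in the two-bias (reset-after) convention.

    ``params`` holds ``Wx`` (n_in, 3u), ``Wh`` (u, 3u), ``bx`` (3u) and
    ``bh`` (3u), gate blocks ordered [reset, update, candidate].  Exposed as
    a standalone function so the recurrence can be checked independently of
    the batched layer implementation.
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    u = h_prev.shape[-1]
    Wx, Wh, bx, bh = params["Wx"], params["Wh"], params["bx"], params["bh"]
    if Wx.shape != (x_t.shape[-1], 3 * u) or Wh.shape != (u, 3 * u):
        raise ValueError(
            f"parameter shapes {Wx.shape}/{Wh.shape} inconsistent with "
            f"input {x_t.shape[-1]} and state {u}"
        )
    xg = x_t @ Wx + bx
    hg = h_prev @ Wh + bh
    r = sigmoid(xg[:, :u] + hg[:, :u])
    z = sigmoid(xg[:, u:2 * u] + hg[:, u:2 * u])
    g = np.tanh(xg[:, 2 * u:] + r * hg[:, 2 * u:])
    return (1.0 - z) * h_prev + z * g


class FusionNet:
    """Trainable fusion classifier; branches toggled for the ablations."""

    def __init__(self, cfg: GCFNConfig, *, use_gru: bool = True, use_cnn: bool = True,
                 seed: int = 0) -> None:
        if not (use_gru or use_cnn):
            raise ValueError("at least one branch must be enabled")
        self.cfg = cfg
        self.use_gru, self.use_cnn = use_gru, use_cnn
        rng = np.random.default_rng(seed)
        self._rng = np.random.default_rng(rng.integers(2**31))

        if use_cnn:
            self.conv = ConvFullHeight(rng, cfg.image_input[0], cfg.cnn_filters)
            self.conv_relu = ReLU()
            self.pool = MaxPoolWidth(cfg.pool_size[1], cfg.pool_stride[1])
        if use_gru:
            self.gru1 = GRULayer(rng, cfg.eeg_input[1], cfg.gru1_units, return_sequences=True)
            self.gru2 = GRULayer(rng, cfg.gru1_units, cfg.gru2_units, return_sequences=False)

        n_fused = (cfg.flatten_len if use_cnn else 0) + (cfg.gru2_units if use_gru else 0)
        self.n_fused = n_fused
        self.fc1 = Dense(rng, n_fused, cfg.fc1_units)
        self.fc1_relu = ReLU()
        self.dropout = Dropout(cfg.dropout_p)
        self.fc2 = Dense(rng, cfg.fc1_units, cfg.n_classes)

    # ------------------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        if self.use_cnn:
            out += [self.conv, self.conv_relu, self.pool]
        if self.use_gru:
            out += [self.gru1, self.gru2]
        out += [self.fc1, self.fc1_relu, self.dropout, self.fc2]
        return out

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.layers, lr=lr)

    # ------------------------------------------------------------------
    def forward(self, eeg: np.ndarray | None, images: np.ndarray | None,
                *, train: bool = False) -> np.ndarray:
        """Class probabilities, one row per trial (rows sum to 1).

        ``eeg`` is (n, T, C); ``images`` is (n, H, W) or (n, H, W, 1).
        A disabled branch ignores (and does not require) its input.
        """
        feats = []
        n = None
        if self.use_cnn:
            if images is None:
                raise ValueError("this model requires the image input")
            img = np.asarray(images, dtype=float)
            if img.ndim == 4:
                img = img[..., 0]
            if img.shape[1:] != (self.cfg.image_input[0], self.cfg.image_input[1]):
                raise ValueError(
                    f"image batch shape {img.shape[1:]} does not match configured "
                    f"input {self.cfg.image_input[:2]}"
                )
            n = img.shape[0]
            c = self.pool.forward(self.conv_relu.forward(self.conv.forward(img)))
            self._cnn_shape = c.shape
            feats.append(c.reshape(n, -1))
        if self.use_gru:
            if eeg is None:
                raise ValueError("this model requires the EEG time-series input")
            eeg = np.asarray(eeg, dtype=float)
            if eeg.shape[1:] != self.cfg.eeg_input:
                raise ValueError(
                    f"EEG batch shape {eeg.shape[1:]} does not match configured "
                    f"input {self.cfg.eeg_input}"
                )
            if n is not None and eeg.shape[0] != n:
                raise ValueError(
                    f"branch batch sizes differ: {eeg.shape[0]} EEG vs {n} images"
                )
            n = eeg.shape[0]
            feats.append(self.gru2.forward(self.gru1.forward(eeg)))
        fused = np.concatenate(feats, axis=1)
        self._fused_split = feats[0].shape[1] if len(feats) == 2 else None
        h = self.dropout.forward(self.fc1_relu.forward(self.fc1.forward(fused)),
                                 train=train, rng=self._rng)
        self._logits = self.fc2.forward(h)
        return softmax(self._logits)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc1.backward(self.fc1_relu.backward(
            self.dropout.backward(self.fc2.backward(dlogits))))
        if self.use_cnn and self.use_gru:
            d_cnn, d_gru = d[:, : self._fused_split], d[:, self._fused_split:]
        elif self.use_cnn:
            d_cnn, d_gru = d, None
        else:
            d_cnn, d_gru = None, d
        if self.use_cnn:
            dc = self.pool.backward(d_cnn.reshape(self._cnn_shape))
            self.conv.backward(self.conv_relu.backward(dc))
        if self.use_gru:
            dseq = self.gru2.backward(d_gru, need_dx=True)
            self.gru1.backward(dseq, need_dx=False)

    def predict(self, eeg: np.ndarray | None, images: np.ndarray | None) -> np.ndarray:
        return np.argmax(self.forward(eeg, images, train=False), axis=1)

    # ------------------------------------------------------------------
    def summary(self) -> list[dict]:
        """Per-layer report: name, output shape, trainable parameter count."""
        cfg = self.cfg
        rows: list[dict] = []
        if self.use_cnn:
            rows += [
                {"layer": "Conv2D", "output": (1, cfg.conv_out_width, cfg.cnn_filters),
                 "params": self.conv.n_params},
                {"layer": "MaxPool", "output": (1, cfg.pool_out_width, cfg.cnn_filters),
                 "params": 0},
                {"layer": "Flatten", "output": (cfg.flatten_len,), "params": 0},
            ]
        if self.use_gru:
            rows += [
                {"layer": "GRU1", "output": (cfg.eeg_input[0], cfg.gru1_units),
                 "params": self.gru1.n_params},
                {"layer": "GRU2", "output": (cfg.gru2_units,), "params": self.gru2.n_params},
            ]
        rows += [
            {"layer": "Concatenate", "output": (self.n_fused,), "params": 0},
            {"layer": "FC1", "output": (cfg.fc1_units,), "params": self.fc1.n_params},
            {"layer": "FC2", "output": (cfg.n_classes,), "params": self.fc2.n_params},
        ]
        return rows

    def summary_text(self) -> str:
        lines = [f"{'Layer':<14}{'Output':<18}{'Params':>10}"]
        for row in self.summary():
            shape = " x ".join(str(s) for s in row["output"])
            lines.append(f"{row['layer']:<14}{shape:<18}{row['params']:>10,}")
        total = sum(r["params"] for r in self.summary())
        lines.append(f"{'Total':<14}{'':<18}{total:>10,}")
        return "\n".join(lines)


def build_gcfn(cfg: GCFNConfig = GCFNConfig(), *, seed: int = 0) -> FusionNet:
    """The full two-branch fusion network."""
    return FusionNet(cfg, use_gru=True, use_cnn=True, seed=seed)


def build_eeg_gru(cfg: GCFNConfig = GCFNConfig(), *, seed: int = 0) -> FusionNet:
    """Ablation: GRU branch only (time-series input)."""
    return FusionNet(cfg, use_gru=True, use_cnn=False, seed=seed)


def build_cwt_cnn(cfg: GCFNConfig = GCFNConfig(), *, seed: int = 0) -> FusionNet:
    """Ablation: CNN branch only (scalogram input)."""
    return FusionNet(cfg, use_gru=False, use_cnn=True, seed=seed)
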