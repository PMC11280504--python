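"""Recurrent sequence autoencoder for standardised sit-to-stand repetitions.

The network is a bow-tie sequence-to-sequence model built from LSTM layers:
a 3-layer encoder compresses a 200-frame x 16-channel repetition down to a
4-unit latent state, the latent state is repeated across all 200 time steps,
and a mirrored 3-layer decoder plus a per-frame linear output map reconstruct
the input.  Trained only on healthy-adult repetitions with mean-square-error
loss, the model learns a representation of healthy movement; reconstruction
error of an unseen repetition then measures how far it lies from that norm.

The implementation is pure NumPy: explicit forward pass, full
backpropagation through time, Adam updates with global-norm gradient
clipping, and patience-based early stopping that restores the best
validation weights.  With a fixed seed, training is bit-reproducible within
one software environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .skeleton_io import Repetition

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "LSTMAutoencoder",
    "build_model",
    "train",
    "reconstruct",
    "reconstruction_error",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Architecture and optimisation settings.

    ``encoder_units`` ends in the latent width; ``decoder_units`` must mirror
    it reversed.  Defaults follow the bow-tie 64 → 16 → 4 → 16 → 64 with a
    linear map back to the 16 input channels.
    """

    encoder_units: tuple[int, ...] = (64, 16, 4)
    decoder_units: tuple[int, ...] = (4, 16, 64)
    latent_units: int = 4
    seq_len: int = 200
    n_channels: int = 16
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 1000
    patience_epochs: int = 50
    min_delta: float = 1e-6
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.encoder_units = tuple(int(u) for u in self.encoder_units)
        self.decoder_units = tuple(int(u) for u in self.decoder_units)
        if len(self.encoder_units) != 3 or len(self.decoder_units) != 3:
            raise ValueError("encoder and decoder must each have 3 recurrent layers")
        if any(u <= 0 for u in self.encoder_units + self.decoder_units):
            raise ValueError("layer widths must be positive")
        if self.decoder_units != tuple(reversed(self.encoder_units)):
            raise ValueError("decoder_units must mirror encoder_units reversed")
        if self.latent_units != self.encoder_units[-1]:
            raise ValueError("latent_units must equal the last encoder width")
        if self.seq_len <= 0 or self.n_channels <= 0:
            raise ValueError("input shape must be positive")


# ---------------------------------------------------------------------------
# LSTM primitives
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _orthogonal(rng: np.random.Generator, n: int, cols: int) -> np.ndarray:
    """Block-orthogonal recurrent kernel (one orthogonal block per gate)."""
    blocks = []
    for _ in range(cols // n):
        a = rng.normal(size=(n, n))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)


class _LSTMLayer:
    """Single LSTM layer over full sequences (gate order: i, f, g, o)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_units: int):
        self.n_in = n_in
        self.n_units = n_units
        self.Wx = _glorot(rng, n_in, 4 * n_units)
        self.Wh = _orthogonal(rng, n_units, 4 * n_units)
        self.b = np.zeros(4 * n_units)
        self.b[n_units: 2 * n_units] = 1.0  # forget-gate bias
        self._cache: dict[str, np.ndarray] | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """x: (batch, T, n_in) → hidden sequence (batch, T, n_units)."""
        B, T, _ = x.shape
        H = self.n_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        h_seq = np.empty((B, T, H))
        if cache:
            gates = np.empty((B, T, 4 * H))
            c_seq = np.empty((B, T, H))
            tanh_c = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            h_seq[:, t] = h
            if cache:
                gates[:, t, :H] = i
                gates[:, t, H:2 * H] = f
                gates[:, t, 2 * H:3 * H] = g
                gates[:, t, 3 * H:] = o
                c_seq[:, t] = c
                tanh_c[:, t] = tc
        if cache:
            self._cache = {"x": x, "h_seq": h_seq, "gates": gates,
                           "c_seq": c_seq, "tanh_c": tanh_c}
        return h_seq

    def backward(self, dh_seq: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backpropagate through time.

        dh_seq: gradient w.r.t. the hidden sequence, (batch, T, n_units).
        Returns (dx_seq, [dWx, dWh, db]).
        """
        assert self._cache is not None, "forward(cache=True) must precede backward"
        x = self._cache["x"]
        h_seq = self._cache["h_seq"]
        gates = self._cache["gates"]
        c_seq = self._cache["c_seq"]
        tanh_c = self._cache["tanh_c"]
        B, T, H = dh_seq.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H:2 * H]
            g = gates[:, t, 2 * H:3 * H]
            o = gates[:, t, 3 * H:]
            tc = tanh_c[:, t]
            c_prev = c_seq[:, t - 1] if t > 0 else np.zeros((B, H))
            h_prev = h_seq[:, t - 1] if t > 0 else np.zeros((B, H))

            dh = dh_seq[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = np.empty((B, 4 * H))
            dz[:, :H] = dc * g * i * (1.0 - i)             # input gate
            dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)   # forget gate
            dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)    # candidate
            dz[:, 3 * H:] = dh * tc * o * (1.0 - o)        # output gate

            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        self._cache = None
        return dx, [dWx, dWh, db]


class LSTMAutoencoder:
    """Bow-tie LSTM sequence autoencoder mapping (T, C) → (T, C)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths_in = [config.n_channels, *config.encoder_units[:-1],
                     config.latent_units, *config.decoder_units[:-1]]
        widths_out = [*config.encoder_units, *config.decoder_units]
        self.layers = [_LSTMLayer(rng, n_in, n_out)
                       for n_in, n_out in zip(widths_in, widths_out)]
        self.n_encoder = len(config.encoder_units)
        self.W_out = _glorot(rng, config.decoder_units[-1], config.n_channels)
        self.b_out = np.zeros(config.n_channels)

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend([self.W_out, self.b_out])
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """x: (batch, T, C) → reconstruction of the same shape."""
        cfg = self.config
        if x.ndim != 3 or x.shape[1:] != (cfg.seq_len, cfg.n_channels):
            raise ValueError(
                f"expected (batch, {cfg.seq_len}, {cfg.n_channels}); got {x.shape}"
            )
        h = x
        for layer in self.layers[: self.n_encoder]:
            h = layer.forward(h, cache=cache)
        latent = h[:, -1, :]                                   # (B, latent)
        h = np.repeat(latent[:, None, :], cfg.seq_len, axis=1)  # repeat-vector
        for layer in self.layers[self.n_encoder:]:
            h = layer.forward(h, cache=cache)
        y = h @ self.W_out + self.b_out
        if cache:
            self._cache_h_dec = h
        return y

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        """Gradient of the scalar loss w.r.t. every parameter, given dL/dy."""
        h_dec = self._cache_h_dec
        B, T, _ = dy.shape
        dW_out = np.einsum("btu,btc->uc", h_dec, dy)
        db_out = dy.sum(axis=(0, 1))
        dh = dy @ self.W_out.T
        grads_rev: list[list[np.ndarray]] = []
        for layer in reversed(self.layers[self.n_encoder:]):
            dh, g = layer.backward(dh)
            grads_rev.append(g)
        # dh is the gradient w.r.t. the repeated latent: sum over time, then
        # route into the encoder's final hidden state only.
        d_latent = dh.sum(axis=1)
        dh_enc = np.zeros((B, T, self.config.latent_units))
        dh_enc[:, -1, :] = d_latent
        dh = dh_enc
        for layer in reversed(self.layers[: self.n_encoder]):
            dh, g = layer.backward(dh)
            grads_rev.append(g)
        grads: list[np.ndarray] = []
        for g in reversed(grads_rev):
            grads.extend(g)
        grads.extend([dW_out, db_out])
        return grads


@dataclass
class TrainedModel:
    """A fitted autoencoder with its config and training history."""

    model: LSTMAutoencoder
    config: ModelConfig
    training_history: dict[str, list[float]] = field(default_factory=dict)
    stopped_epoch: int = 0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig | None = None) -> LSTMAutoencoder:
    """Construct an untrained autoencoder from a validated config."""
    return LSTMAutoencoder(config or ModelConfig())


def _as_array(reps: Sequence[Repetition] | np.ndarray) -> np.ndarray:
    if isinstance(reps, np.ndarray):
        return reps.astype(float)
    return np.stack([np.asarray(r.values, dtype=float) for r in reps])


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train(
    model: LSTMAutoencoder,
    train_set: Sequence[Repetition],
    val_set: Sequence[Repetition],
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Fit the autoencoder on healthy-class repetitions.

    Minimises mean-square reconstruction error with Adam; stops after
    ``patience_epochs`` consecutive epochs without a validation-loss
    improvement greater than ``min_delta`` (or at ``max_epochs``) and
    restores the best-validation weights.

    Raises if the training set is empty, contains a non-HealthyAdult sample
    (label leak), or shares a subject with the validation set.
    """
    cfg = config or model.config
    if len(train_set) == 0:
        raise ValueError("empty training set")
    bad = [r.subject_id for r in train_set if r.class_label != "HealthyAdult"]
    if bad:
        raise ValueError(
            f"label leak: non-HealthyAdult sample(s) in training set: {sorted(set(bad))}"
        )
    train_subjects = {r.subject_id for r in train_set}
    val_subjects = {r.subject_id for r in val_set}
    overlap = train_subjects & val_subjects
    if overlap:
        raise ValueError(f"subjects in both train and val sets: {sorted(overlap)}")

    x_train = _as_array(train_set)
    x_val = _as_array(val_set)
    rng = np.random.default_rng(cfg.seed)

    # Adam state
    params = model.params
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    wait = 0
    n = x_train.shape[0]
    stopped_epoch = cfg.max_epochs

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_train[idx]
            yb = model.forward(xb, cache=True)
            diff = yb - xb
            loss = float(np.mean(diff ** 2))
            epoch_loss += loss * len(idx)
            dy = (2.0 / diff.size) * diff
            grads = model.backward(dy)
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if cfg.grad_clip > 0 and gnorm > cfg.grad_clip:
                scale = cfg.grad_clip / gnorm
                grads = [g * scale for g in grads]
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                p -= lr_t * mi / (np.sqrt(vi) + eps)
        history["train_loss"].append(epoch_loss / n)
        val_loss = _mse(model.forward(x_val), x_val) if len(x_val) else history["train_loss"][-1]
        history["val_loss"].append(val_loss)

        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience_epochs:
                stopped_epoch = epoch
                break

    model.set_weights(best_weights)
    return TrainedModel(
        model=model,
        config=cfg,
        training_history=history,
        stopped_epoch=min(stopped_epoch, len(history["val_loss"])),
    )


# ---------------------------------------------------------------------------
# Inference and reconstruction error
# ---------------------------------------------------------------------------

def reconstruct(
    model: TrainedModel | LSTMAutoencoder,
    rep: Repetition | np.ndarray,
) -> np.ndarray:
    """Deterministic reconstruction of one repetition, shape (T, C)."""
    net = model.model if isinstance(model, TrainedModel) else model
    x = rep.values if isinstance(rep, Repetition) else np.asarray(rep, dtype=float)
    return net.forward(x[None, :, :])[0]


def reconstruction_error(
    original: Repetition | np.ndarray,
    reconstruction: np.ndarray,
    clip_frames: int = 30,
) -> float:
    """Euclidean distance between original and reconstruction.

    The first and last ``clip_frames`` frames are clipped before the
    distance is taken (they are padding lead-in/lead-out, not movement);
    the distance is the Frobenius norm of the remaining difference.
    """
    x = original.values if isinstance(original, Repetition) else np.asarray(original, dtype=float)
    y = np.asarray(reconstruction, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    n = x.shape[0]
    if clip_frames < 0 or 2 * clip_frames >= n:
        raise ValueError(f"clip_frames {clip_frames} too large for {n} frames")
    sl = slice(clip_frames, n - clip_frames)
    return float(np.linalg.norm(x[sl] - y[sl]))


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(trained: TrainedModel, directory: str | Path) -> Path:
    """Save weights (npz) plus a JSON sidecar of config and history."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = trained.model.get_weights()
    np.savez(directory / "weights.npz",
             **{f"w{i:03d}": w for i, w in enumerate(weights)})
    sidecar = {
        "config": asdict(trained.config),
        "training_history": trained.training_history,
        "stopped_epoch": trained.stopped_epoch,
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    cfg_dict = sidecar["config"]
    for key in ("encoder_units", "decoder_units"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    model = LSTMAutoencoder(config)
    with np.load(directory / "weights.npz") as data:
        weights = [data[k] for k in sorted(data.files)]
    model.set_weights(weights)
    return TrainedModel(
        model=model,
        config=config,
        training_history=sidecar["training_history"],
        stopped_epoch=sidecar["stopped_epoch"],
    )
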