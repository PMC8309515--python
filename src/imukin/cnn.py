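"""1D convolutional network for univariate window-to-angle regression.

The architecture is fixed: a 60-sample single-channel window passes through
four Conv1D layers (50, 50, 100, 100 filters; kernel 3, stride 1, no padding;
a 2:1 max-pool after the second), is flattened and fed through a 100-unit
dense layer into a single linear output. All hidden activations are ReLU,
weights are Glorot-normal initialized, the loss is mean squared error and the
optimizer is Adam (lr 0.001, batch 512, 50 epochs).

Implemented directly on NumPy (im2col convolutions in float32), which keeps
training bit-deterministic for a given seed on a fixed BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ModelConfig", "TrainedModel", "CNNRegressor", "build_model",
           "train", "predict", "TrainingDivergenceError"]


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training recipe; defaults are the study recipe."""

    input_len: int = 60
    conv_filters: tuple[int, ...] = (50, 50, 100, 100)
    kernel_size: int = 3
    pool_size: int = 2  # applied after the 2nd conv layer
    dense_units: int = 100
    output_units: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 512
    epochs: int = 50
    rng_seed: int = 0

    def layer_output_lengths(self) -> list[int]:
        """Temporal lengths after each conv/pool layer, e.g. [58, 56, 28, 26, 24]."""
        lengths = []
        length = self.input_len
        for i, _ in enumerate(self.conv_filters):
            length -= self.kernel_size - 1
            if length < 1:
                raise ValueError("input_len too short for the conv/pool chain")
            lengths.append(length)
            if i == 1:
                if length % self.pool_size:
                    raise ValueError("pooling requires an even feature length")
                length //= self.pool_size
                lengths.append(length)
        return lengths

    @property
    def flat_features(self) -> int:
        return self.layer_output_lengths()[-1] * self.conv_filters[-1]


def _glorot_normal(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C), tap-major to match a (k*C, F) kernel."""
    L = x.shape[1]
    return np.concatenate([x[:, i:L - k + 1 + i, :] for i in range(k)], axis=2)


class CNNRegressor:
    """The window-in, angle-out network with its own Adam state."""

    def __init__(self, config: ModelConfig):
        config.layer_output_lengths()  # validates the arithmetic
        self.config = config
        k = config.kernel_size
        rng = np.random.default_rng(config.rng_seed)
        f = config.conv_filters
        chans = (1,) + f
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(f)):
            fan_in, fan_out = k * chans[i], k * chans[i + 1]
            self.params[f"W{i}"] = _glorot_normal(
                rng, fan_in, fan_out, (k * chans[i], f[i]))
            self.params[f"b{i}"] = np.zeros(f[i], dtype=np.float32)
        self.params["Wd"] = _glorot_normal(
            rng, config.flat_features, config.dense_units,
            (config.flat_features, config.dense_units))
        self.params["bd"] = np.zeros(config.dense_units, dtype=np.float32)
        self.params["Wo"] = _glorot_normal(
            rng, config.dense_units, config.output_units,
            (config.dense_units, config.output_units))
        self.params["bo"] = np.zeros(config.output_units, dtype=np.float32)
        self._adam_m = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_v = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """Predict (B, 1) from (B, 60, 1); caches activations for backprop."""
        cfg = self.config
        if x.ndim != 3 or x.shape[1] != cfg.input_len or x.shape[2] != 1:
            raise ValueError(f"expected input of shape (N, {cfg.input_len}, 1), "
                             f"got {x.shape}")
        k, pool = cfg.kernel_size, cfg.pool_size
        cache: dict[str, np.ndarray] = {}
        h = x.astype(np.float32, copy=False)
        for i in range(len(cfg.conv_filters)):
            cols = _im2col(h, k)
            z = cols @ self.params[f"W{i}"] + self.params[f"b{i}"]
            h = np.maximum(z, 0.0)
            if keep_cache:
                cache[f"cols{i}"] = cols
                cache[f"relu{i}"] = z > 0
            if i == 1:
                B, L, C = h.shape
                hp = h.reshape(B, L // pool, pool, C)
                arg = hp.argmax(axis=2)
                h = np.take_along_axis(hp, arg[:, :, None, :], axis=2)[:, :, 0, :]
                if keep_cache:
                    cache["pool_arg"] = arg
                    cache["pool_shape"] = np.array(hp.shape)
        flat = h.reshape(h.shape[0], -1)
        zd = flat @ self.params["Wd"] + self.params["bd"]
        hd = np.maximum(zd, 0.0)
        out = hd @ self.params["Wo"] + self.params["bo"]
        if keep_cache:
            cache["flat"] = flat
            cache["relud"] = zd > 0
            cache["hd"] = hd
            cache["conv_out_shape"] = np.array(h.shape)
            self._cache = cache
        return out

    # --------------------------------------------------------------- backward
    def _backward(self, dout: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        k, pool = cfg.kernel_size, cfg.pool_size
        cache = self._cache
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = cache["hd"].T @ dout
        grads["bo"] = dout.sum(axis=0)
        dhd = dout @ self.params["Wo"].T
        dzd = dhd * cache["relud"]
        grads["Wd"] = cache["flat"].T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        dh = dflat.reshape(cache["conv_out_shape"])
        for i in reversed(range(len(cfg.conv_filters))):
            if i == 1:
                B, Lp, _, C = cache["pool_shape"]
                dhp = np.zeros((B, Lp, pool, C), dtype=dh.dtype)
                np.put_along_axis(dhp, cache["pool_arg"][:, :, None, :],
                                  dh[:, :, None, :], axis=2)
                dh = dhp.reshape(B, Lp * pool, C)
            dz = dh * cache[f"relu{i}"]
            cols = cache[f"cols{i}"]
            grads[f"W{i}"] = cols.reshape(-1, cols.shape[2]).T @ dz.reshape(-1, dz.shape[2])
            grads[f"b{i}"] = dz.sum(axis=(0, 1))
            if i > 0:
                dcols = dz @ self.params[f"W{i}"].T
                cin = dcols.shape[2] // k
                lout = dcols.shape[1]
                dh = np.zeros((dz.shape[0], lout + k - 1, cin), dtype=dz.dtype)
                for tap in range(k):
                    dh[:, tap:tap + lout, :] += dcols[:, :, tap * cin:(tap + 1) * cin]
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray],
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-7) -> None:
        self._adam_t += 1
        lr = self.config.learning_rate
        correction = (np.sqrt(1.0 - beta2 ** self._adam_t)
                      / (1.0 - beta1 ** self._adam_t))
        for name, g in grads.items():
            m = self._adam_m[name]
            v = self._adam_v[name]
            m += (1.0 - beta1) * (g - m)
            v += (1.0 - beta2) * (g * g - v)
            self.params[name] -= (lr * correction * m
                                  / (np.sqrt(v) + eps)).astype(np.float32)

    def train_step(self, x: np.ndarray, y: np.ndarray) -> float:
        """One Adam step on a mini-batch; returns the batch MSE."""
        pred = self.forward(x, keep_cache=True)
        err = pred - y.astype(np.float32, copy=False)
        loss = float(np.mean(err ** 2))
        self._adam_step(self._backward(2.0 * err / err.size))
        return loss


@dataclass
class TrainedModel:
    """A fitted network plus its training history and data provenance."""

    model: CNNRegressor
    training_history: list[float]
    provenance: dict = field(default_factory=dict)

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def save_weights(self, path) -> None:
        np.savez(path, **self.model.params,
                 _history=np.asarray(self.training_history))

    @classmethod
    def load_weights(cls, path, config: ModelConfig) -> "TrainedModel":
        data = np.load(path)
        model = CNNRegressor(config)
        for name in model.params:
            model.params[name] = data[name]
        return cls(model=model, training_history=list(data["_history"]))


def build_model(config: ModelConfig = ModelConfig()) -> CNNRegressor:
    """Instantiate the untrained network; validates the layer arithmetic."""
    return CNNRegressor(config)


def train(model: CNNRegressor, frames, config: ModelConfig | None = None,
          ) -> TrainedModel:
    """Fit the network on a FrameSet with the fixed-epoch Adam recipe.

    Runs exactly ``config.epochs`` epochs of shuffled mini-batches (the
    partial final batch is kept). Deterministic given ``config.rng_seed``.
    """
    config = config or model.config
    n = len(frames)
    if n == 0:
        raise ValueError("cannot train on an empty FrameSet")
    x = np.ascontiguousarray(frames.X, dtype=np.float32)
    y = np.ascontiguousarray(frames.Y, dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x7EA1]))
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            loss = model.train_step(x[batch], y[batch])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            total += loss * batch.size
        history.append(total / n)
    return TrainedModel(model=model, training_history=history,
                        provenance={"n_frames": n, "joint": frames.joint,
                                    "channel": frames.channel})


def predict(trained: TrainedModel | CNNRegressor, frames,
            batch_size: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Predict one angle per frame; returns (predictions, center_times)."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    if frames.X.shape[1] != model.config.input_len:
        raise ValueError(f"frame length {frames.X.shape[1]} does not match "
                         f"model input_len {model.config.input_len}")
    out = [model.forward(frames.X[i:i + batch_size])
           for i in range(0, len(frames), batch_size)]
    return np.concatenate(out)[:, 0].astype(float), np.asarray(frames.center_times)
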