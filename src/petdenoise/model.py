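"""The denoising network: a 10-layer 3D CNN applied to 5-slice blocks.

The architecture follows the residual-learning denoising-CNN lineage,
adapted to volumetric PET: 10 same-padded 3x3x3 convolution layers with 68
filters each, batch normalization on the interior layers, a rectifier
after every layer except the last, and no pooling (the full receptive
field grows linearly with depth so surrounding context informs the
denoising). The first layer takes the single-channel image block and the
last layer projects back to a single channel. Training minimizes mean
squared error with stochastic gradient descent; in the default residual
mode the network predicts the noise map, which is subtracted from the
input to give the denoised image.

`DenoisingCNN` is a scikit-learn style estimator: hyperparameters in
``__init__``, state learned by ``fit`` in trailing-underscore attributes,
``get_params``/``set_params`` inherited from ``BaseEstimator``.
"""

from __future__ import annotations

import io
import json
import zipfile
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .nn import SGD, BatchNorm3d, Conv3d, ReLU, Sequential, mse_loss
from .traindata import TrainingPair

__all__ = ["DenoisingCNN", "DivergenceError", "build_model", "load_model"]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


class DenoisingCNN(BaseEstimator):
    """3D convolutional denoiser trained on (noisy, clean) block pairs.

    Parameters
    ----------
    n_layers : int
        Total convolution layers (>= 2). Default 10.
    n_filters : int
        Channels of the interior layers. Default 68.
    kernel_size : tuple of int
        Convolution kernel, all dims odd. Default (3, 3, 3).
    residual : bool
        If True (default) the network predicts the noise map and the
        denoised image is input minus prediction; otherwise it predicts
        the clean image directly.
    learning_rate, momentum, batch_size, epochs, clip_norm
        SGD settings; clip_norm bounds the global gradient norm per step.
        Defaults 0.05, 0.9, 8, 20, 0.05.
    norm_percentile : float
        Input normalization: blocks are centered by the training-set mean
        and divided by this percentile of the centered absolute
        intensities before the network, and rescaled after, so SUV units
        are preserved end to end (centering conditions the first layer,
        which has no batch normalization). Default 99.5.
    random_state : int
        Seeds weight initialization and batch shuffling; identical seeds
        and data give identical training runs.
    """

    def __init__(
        self,
        n_layers: int = 10,
        n_filters: int = 68,
        kernel_size: Tuple[int, int, int] = (3, 3, 3),
        residual: bool = True,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        batch_size: int = 8,
        epochs: int = 20,
        clip_norm: float = 0.05,
        norm_percentile: float = 99.5,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.n_layers = n_layers
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.residual = residual
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.clip_norm = clip_norm
        self.norm_percentile = norm_percentile
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ build

    def _validate_config(self) -> None:
        if self.n_layers < 2:
            raise ValueError("need at least 2 convolution layers")
        if any(k % 2 == 0 or k < 1 for k in self.kernel_size):
            raise ValueError("kernel dims must be odd and positive")
        if self.n_filters < 1 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid model configuration")

    def build(self) -> "DenoisingCNN":
        """Initialize the (untrained) network deterministically from the seed."""
        self._validate_config()
        rng = np.random.default_rng(self.random_state)
        k = tuple(self.kernel_size)
        layers: List = [Conv3d(1, self.n_filters, k, rng), ReLU()]
        for _ in range(self.n_layers - 2):
            layers += [
                Conv3d(self.n_filters, self.n_filters, k, rng),
                BatchNorm3d(self.n_filters),
                ReLU(),
            ]
        last = Conv3d(self.n_filters, 1, k, rng)
        # zero-init the output projection: in residual mode training starts
        # from the identity mapping, which avoids the large initial transient
        # and the constant-output collapse it can cause under plain SGD
        last.w[...] = 0.0
        layers.append(last)
        self.net_ = Sequential(layers)
        self.loss_history_: List[float] = []
        self.scale_ = 1.0
        self.center_ = 0.0
        return self

    @property
    def n_parameters_(self) -> int:
        return self.net_.n_params

    # ------------------------------------------------------------------ train

    @staticmethod
    def _stack(blocks: Sequence[np.ndarray]) -> np.ndarray:
        x = np.asarray(blocks, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError("expected an array of 3-D blocks: (n, depth, rows, cols)")
        return x

    def fit(self, X: Sequence[np.ndarray], y: Sequence[np.ndarray]) -> "DenoisingCNN":
        """Train on noisy blocks X against clean targets y (same shapes)."""
        X = self._stack(X)
        y = self._stack(y)
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        if X.shape != y.shape:
            raise ValueError(f"noisy {X.shape} and clean {y.shape} shapes differ")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("training data contain non-finite values")

        self.build()
        self.center_ = float(X.mean())
        scale = float(np.percentile(np.abs(X - self.center_), self.norm_percentile))
        self.scale_ = scale if scale > 0 else 1.0

        # channel-first: (1, n, depth, rows, cols)
        xn = ((X - self.center_) / self.scale_)[None]
        if self.residual:
            target = ((X - y) / self.scale_)[None]
        else:
            target = ((y - self.center_) / self.scale_)[None]

        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 1]))
        opt = SGD(
            self.net_.params_and_grads(),
            lr=self.learning_rate,
            momentum=self.momentum,
            clip_norm=self.clip_norm,
        )
        n = xn.shape[1]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                pred = self.net_.forward(xn[:, idx], training=True)
                loss, grad = mse_loss(pred, target[:, idx])
                self.net_.backward(grad)
                opt.step()
                losses.append(loss)
            mean_loss = float(np.mean(losses))
            if not np.isfinite(mean_loss):
                raise DivergenceError(epoch)
            self.loss_history_.append(mean_loss)
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}  loss {mean_loss:.6g}")
        for layer in self.net_.layers:  # release training scratch buffers
            for attr in ("_cols", "_gcols", "_gxp", "_cache", "_mask"):
                if hasattr(layer, attr):
                    setattr(layer, attr, None)
        return self

    def fit_pairs(self, pairs: Sequence[TrainingPair]) -> "DenoisingCNN":
        """Train from TrainingPair objects (noisy -> clean)."""
        if len(pairs) == 0:
            raise ValueError("training set is empty")
        X = [p.noisy.values for p in pairs]
        y = [p.clean.values for p in pairs]
        return self.fit(X, y)

    # -------------------------------------------------------------- inference

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not built/fitted; call fit() first")

    def _forward_eval(self, blocks: np.ndarray) -> np.ndarray:
        xn = ((blocks - self.center_) / self.scale_)[None].astype(np.float32)
        out = self.net_.forward(xn, training=False)
        denorm = out[0].astype(np.float64) * self.scale_
        if self.residual:
            return blocks - denorm
        return denorm + self.center_

    def predict(self, X: Sequence[np.ndarray]) -> np.ndarray:
        """Denoise a batch of blocks; output shape equals input shape."""
        self._check_fitted()
        return self._forward_eval(self._stack(X))

    def denoise_volume(
        self, values: np.ndarray, window: int = 5, chunk: int = 8
    ) -> np.ndarray:
        """Denoise a whole volume by sliding 5-slice windows, stride 1.

        Overlapping window predictions are averaged per slice, which
        suppresses block seams; inference uses frozen batch-norm running
        statistics and is deterministic.
        """
        self._check_fitted()
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError("expected a 3-D volume (slices, rows, cols)")
        s = values.shape[0]
        if s < window:
            raise ValueError(f"volume has {s} slices; need at least {window}")
        starts = list(range(0, s - window + 1))
        acc = np.zeros_like(values)
        cnt = np.zeros(s)
        for i in range(0, len(starts), chunk):
            batch_starts = starts[i : i + chunk]
            blocks = np.stack(
                [values[t : t + window] for t in batch_starts]
            ).astype(np.float32)
            out = self._forward_eval(blocks)
            for t, block in zip(batch_starts, out):
                acc[t : t + window] += block
                cnt[t : t + window] += 1
        return acc / cnt[:, None, None]

    # ------------------------------------------------------------ persistence

    def save(self, path) -> None:
        """Save config, weights and batch-norm statistics to one archive."""
        self._check_fitted()
        arrays = {}
        for li, layer in enumerate(self.net_.layers):
            for name in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, name):
                    arrays[f"layer{li}_{name}"] = getattr(layer, name)
        meta = {
            "params": self.get_params(),
            "scale": self.scale_,
            "center": self.center_,
            "loss_history": self.loss_history_,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(meta))
            buf = io.BytesIO()
            np.savez(buf, **arrays)
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "DenoisingCNN":
        with zipfile.ZipFile(path, "r") as zf:
            meta = json.loads(zf.read("config.json"))
            with zf.open("weights.npz") as f:
                arrays = dict(np.load(io.BytesIO(f.read())))
        params = meta["params"]
        params["kernel_size"] = tuple(params["kernel_size"])
        model = cls(**params).build()
        model.scale_ = meta["scale"]
        model.center_ = meta.get("center", 0.0)
        model.loss_history_ = list(meta["loss_history"])
        for li, layer in enumerate(model.net_.layers):
            for name in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                key = f"layer{li}_{name}"
                if key in arrays:
                    getattr(layer, name)[...] = arrays[key]
        return model


def build_model(**config) -> DenoisingCNN:
    """Construct an untrained network from configuration keywords."""
    return DenoisingCNN(**config).build()


def load_model(path) -> DenoisingCNN:
    return DenoisingCNN.load(path)
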