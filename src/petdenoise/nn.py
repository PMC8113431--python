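"""Minimal 3D convolutional network engine (numpy, CPU).

Implements exactly the pieces the denoising network needs: stride-1
same-padded 3x3x3 (or any odd-sized) 3D convolution, batch normalization,
ReLU, mean-squared-error loss and SGD with momentum, each with analytic
gradients. Activations are laid out channel-first as (channels, batch,
depth, rows, cols) so each kernel offset contributes one large
channel-mixing GEMM; the gradient w.r.t. the input is itself a convolution
with the channel-transposed, spatially flipped kernel. All arrays are
float32.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Conv3d", "BatchNorm3d", "ReLU", "Sequential", "SGD", "mse_loss"]


def _offsets(kernel: Sequence[int]):
    for dz in range(kernel[0]):
        for dy in range(kernel[1]):
            for dx in range(kernel[2]):
                yield dz, dy, dx


def _pad_spatial(x: np.ndarray, pads: Tuple[int, int, int]) -> np.ndarray:
    pz, py, px = pads
    return np.pad(x, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))


def _im2col(
    xp: np.ndarray,
    kernel: Tuple[int, int, int],
    out_shape,
    buf: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Gather kernel-offset slices of the padded input into one (K*Ci, M) matrix.

    Row blocks are ordered by offset then channel, matching the kernel
    matrix produced by `_kernel_matrix`. A preallocated buffer avoids
    repeated large allocations in the training loop.
    """
    ci = xp.shape[0]
    n, d, h, wd = out_shape
    m = n * d * h * wd
    k = int(np.prod(kernel))
    if buf is None or buf.shape != (k, ci, m) or buf.dtype != xp.dtype:
        buf = np.empty((k, ci, m), dtype=xp.dtype)
    for i, (dz, dy, dx) in enumerate(_offsets(kernel)):
        buf[i] = xp[:, :, dz : dz + d, dy : dy + h, dx : dx + wd].reshape(ci, m)
    return buf


def _kernel_matrix(w: np.ndarray) -> np.ndarray:
    """(Co, Ci, kz, ky, kx) -> (Co, K*Ci) with (offset, channel) column order."""
    co, ci = w.shape[:2]
    return np.ascontiguousarray(w.reshape(co, ci, -1).transpose(0, 2, 1)).reshape(
        co, -1
    )


def _conv3d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 zero-padded convolution; x (Ci,N,D,H,W), w (Co,Ci,kz,ky,kx)."""
    kz, ky, kx = w.shape[2:]
    xp = _pad_spatial(x, (kz // 2, ky // 2, kx // 2))
    cols = _im2col(xp, (kz, ky, kx), (x.shape[1],) + x.shape[2:])
    m = x.shape[1] * x.shape[2] * x.shape[3] * x.shape[4]
    y = _kernel_matrix(w) @ cols.reshape(-1, m)
    return y.reshape((w.shape[0],) + x.shape[1:])


class Conv3d:
    """Same-padded stride-1 3D convolution with bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: Tuple[int, int, int] = (3, 3, 3),
        rng: Optional[np.random.Generator] = None,
    ):
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("kernel dims must be odd for well-defined same-padding")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * int(np.prod(kernel))
        # He initialization, appropriate for ReLU stacks
        std = np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0.0, std, (out_channels, in_channels, *kernel)).astype(
            np.float32
        )
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        # persistent scratch (im2col / col2im) reused across training steps
        self._cols: Optional[np.ndarray] = None
        self._gcols: Optional[np.ndarray] = None
        self._gxp: Optional[np.ndarray] = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params_and_grads(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        kernel = self.w.shape[2:]
        pads = tuple(k // 2 for k in kernel)
        xp = _pad_spatial(x, pads)
        cols = _im2col(xp, kernel, (x.shape[1],) + x.shape[2:], buf=self._cols)
        m = x.shape[1] * x.shape[2] * x.shape[3] * x.shape[4]
        if training:
            self._shape = x.shape
            self._cols = cols
        y = (_kernel_matrix(self.w) @ cols.reshape(-1, m)).reshape(
            (self.w.shape[0],) + x.shape[1:]
        )
        return y + self.b[:, None, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols = self._cols
        assert cols is not None, "forward(training=True) must precede backward"
        ci, n, d, h, wd = self._shape
        co = self.w.shape[0]
        kernel = self.w.shape[2:]
        kz, ky, kx = kernel
        k = kz * ky * kx
        m = n * d * h * wd

        self.gb[...] = gy.sum(axis=(1, 2, 3, 4))

        gy_flat = gy.reshape(co, m)
        # (Co, K*Ci) in (offset, channel) order, back to kernel layout
        gw_mat = gy_flat @ cols.reshape(k * ci, m).T
        self.gw[...] = gw_mat.reshape(co, k, ci).transpose(0, 2, 1).reshape(
            self.w.shape
        )

        # dL/dcols, scattered back to the padded input grid (col2im)
        if self._gcols is None or self._gcols.shape != (k * ci, m):
            self._gcols = np.empty((k * ci, m), dtype=gy.dtype)
        np.matmul(_kernel_matrix(self.w).T, gy_flat, out=self._gcols)
        gcols = self._gcols.reshape(k, ci, n, d, h, wd)
        pz, py, px = kz // 2, ky // 2, kx // 2
        pshape = (ci, n, d + 2 * pz, h + 2 * py, wd + 2 * px)
        if self._gxp is None or self._gxp.shape != pshape:
            self._gxp = np.empty(pshape, dtype=gy.dtype)
        gxp = self._gxp
        gxp.fill(0)
        for i, (dz, dy, dx) in enumerate(_offsets(kernel)):
            gxp[:, :, dz : dz + d, dy : dy + h, dx : dx + wd] += gcols[i]
        return gxp[:, :, pz : pz + d, py : py + h, px : px + wd].copy()


class BatchNorm3d:
    """Per-channel batch normalization over (batch, depth, rows, cols).

    Training uses batch statistics and updates exponential running
    statistics; inference uses the frozen running statistics only.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def params_and_grads(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v[:, None, None, None, None]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        axes = (1, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - self._bc(mean)) * self._bc(inv_std)
            self._cache = (xhat, inv_std)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                np.float32
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                np.float32
            )
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self._bc(self.running_mean)) * self._bc(inv_std)
        return self._bc(self.gamma) * xhat + self._bc(self.beta)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (1, 2, 3, 4)
        self.ggamma[...] = (gy * xhat).sum(axis=axes)
        self.gbeta[...] = gy.sum(axis=axes)
        gxhat = gy * self._bc(self.gamma)
        gx = (
            gxhat
            - self._bc(gxhat.mean(axis=axes))
            - xhat * self._bc((gxhat * xhat).mean(axis=axes))
        ) * self._bc(inv_std)
        return gx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    @property
    def n_params(self) -> int:
        return 0

    def params_and_grads(self):
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Sequential:
    def __init__(self, layers: List):
        self.layers = layers

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def params_and_grads(self):
        out = []
        for l in self.layers:
            out.extend(l.params_and_grads())
        return out

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum.

    Optionally clips the global gradient norm before each update, the usual
    safeguard for denoising-network training at aggressive learning rates.
    """

    def __init__(
        self,
        params_and_grads,
        lr: float = 1e-3,
        momentum: float = 0.9,
        clip_norm: Optional[float] = None,
    ):
        self._pg = params_and_grads
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._vel = [np.zeros_like(p) for p, _ in params_and_grads]

    def step(self) -> None:
        factor = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float(np.sum(g.astype(np.float64) ** 2)) for _, g in self._pg)
            )
            if total > self.clip_norm:
                factor = self.clip_norm / total
        for (p, g), v in zip(self._pg, self._vel):
            v *= self.momentum
            v -= self.lr * factor * g
            p += v
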