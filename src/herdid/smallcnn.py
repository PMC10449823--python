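"""A small convolutional network in plain numpy.

Three 3x3 conv blocks (conv -> ReLU -> 2x2 max-pool for the first two,
conv -> ReLU -> global average pooling for the third) followed by two
fully-connected layers with a softmax readout.  The two FC layers are the
"head": feature-extraction training updates only them, fine-tuning
unfreezes everything.  Optimized with Adam on softmax cross-entropy.

Written for desk-scale inputs (default 16x32 grayscale); im2col matmuls
keep training a few hundred images for tens of epochs in the order of a
second on one CPU.  All randomness flows through explicit generators, so
training is bit-reproducible for a fixed seed (and a fixed BLAS).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ArgumentError

_HEAD_PARAMS = ("fc1_w", "fc1_b", "fc2_w", "fc2_b")


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class SmallCNN:
    """3-conv-block CNN with a 2-layer fully-connected head."""

    def __init__(
        self,
        input_hw: tuple[int, int] = (16, 32),
        n_classes: int = 2,
        channels: tuple[int, int, int] = (6, 12, 24),
        fc_dim: int = 48,
        batch_size: int = 16,
        dtype=np.float32,
    ) -> None:
        h, w = input_hw
        if h % 4 or w % 4:
            raise ArgumentError("input height and width must be multiples of 4")
        if n_classes < 1:
            raise ArgumentError("n_classes must be >= 1")
        self.input_hw = (int(h), int(w))
        self.n_classes = int(n_classes)
        self.channels = tuple(int(c) for c in channels)
        self.fc_dim = int(fc_dim)
        self.batch_size = int(batch_size)
        self.dtype = dtype
        self.params: dict[str, np.ndarray] = {}
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        self.scope = "all"

    # ------------------------------------------------------------------ setup

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.channels
        d = self.dtype
        p = {
            "conv1_w": _he(rng, (c1, 1, 3, 3), 9, d),
            "conv1_b": np.zeros(c1, dtype=d),
            "conv2_w": _he(rng, (c2, c1, 3, 3), 9 * c1, d),
            "conv2_b": np.zeros(c2, dtype=d),
            "conv3_w": _he(rng, (c3, c2, 3, 3), 9 * c2, d),
            "conv3_b": np.zeros(c3, dtype=d),
            "fc1_w": _he(rng, (c3, self.fc_dim), c3, d),
            "fc1_b": np.zeros(self.fc_dim, dtype=d),
            "fc2_w": _he(rng, (self.fc_dim, self.n_classes), self.fc_dim, d),
            "fc2_b": np.zeros(self.n_classes, dtype=d),
        }
        self.params = p
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0
        self.scope = "all"

    def set_trainable_scope(self, scope: str) -> None:
        if scope not in ("head", "all"):
            raise ArgumentError("scope must be 'head' or 'all'")
        self.scope = scope

    def _trainable(self) -> tuple[str, ...]:
        return _HEAD_PARAMS if self.scope == "head" else tuple(self.params)

    # ---------------------------------------------------------------- layers

    @staticmethod
    def _conv_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray):
        n, c, h, ww = x.shape
        f = w.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (n,c,h,w,3,3)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * ww, c * 9
        )
        out = cols @ w.reshape(f, c * 9).T + b
        return out.reshape(n, h, ww, f).transpose(0, 3, 1, 2), cols

    @staticmethod
    def _conv_bwd(dout: np.ndarray, cols: np.ndarray, w: np.ndarray, xshape):
        n, c, h, ww = xshape
        f = w.shape[0]
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * ww, f)
        dw = (dflat.T @ cols).reshape(f, c, 3, 3)
        db = dflat.sum(axis=0)
        dcols = (dflat @ w.reshape(f, c * 9)).reshape(n, h, ww, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, ww + 2), dtype=dout.dtype)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + ww] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1 : h + 1, 1 : ww + 1], dw, db

    @staticmethod
    def _pool_fwd(x: np.ndarray):
        n, c, h, w = x.shape
        x6 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = x6.argmax(axis=-1)
        out = np.take_along_axis(x6, idx[..., None], axis=-1)[..., 0]
        return out, idx

    @staticmethod
    def _pool_bwd(dout: np.ndarray, idx: np.ndarray, xshape):
        n, c, h, w = xshape
        d6 = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(d6, idx[..., None], dout[..., None], axis=-1)
        return d6.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )

    # --------------------------------------------------------------- forward

    @staticmethod
    def standardize(x: np.ndarray) -> np.ndarray:
        """Per-image zero-mean/unit-std normalization of an (n, h, w) batch.

        Makes the network invariant to multiplicative gain (sensor
        brightness, illumination drift) up to saturation clipping.
        """
        mu = x.mean(axis=(-2, -1), keepdims=True)
        sd = x.std(axis=(-2, -1), keepdims=True)
        return (x - mu) / (sd + 1e-6)

    def _forward(self, x: np.ndarray, keep_cache: bool = False):
        p = self.params
        a1, cols1 = self._conv_fwd(x, p["conv1_w"], p["conv1_b"])
        r1 = np.maximum(a1, 0)
        p1, idx1 = self._pool_fwd(r1)
        a2, cols2 = self._conv_fwd(p1, p["conv2_w"], p["conv2_b"])
        r2 = np.maximum(a2, 0)
        p2, idx2 = self._pool_fwd(r2)
        a3, cols3 = self._conv_fwd(p2, p["conv3_w"], p["conv3_b"])
        r3 = np.maximum(a3, 0)
        g = r3.mean(axis=(2, 3))  # global average pool -> (n, c3)
        h1 = np.maximum(g @ p["fc1_w"] + p["fc1_b"], 0)
        z = h1 @ p["fc2_w"] + p["fc2_b"]
        if not keep_cache:
            return z, None
        cache = dict(
            x=x, a1=a1, cols1=cols1, idx1=idx1, p1=p1,
            a2=a2, cols2=cols2, idx2=idx2, p2=p2,
            a3=a3, cols3=cols3, r3=r3, g=g, h1=h1,
        )
        return z, cache

    def _backward(self, dz: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        h1, g = cache["h1"], cache["g"]
        grads["fc2_w"] = h1.T @ dz
        grads["fc2_b"] = dz.sum(axis=0)
        dh1 = (dz @ p["fc2_w"].T) * (h1 > 0)
        grads["fc1_w"] = g.T @ dh1
        grads["fc1_b"] = dh1.sum(axis=0)
        if self.scope == "head":
            return grads
        dg = dh1 @ p["fc1_w"].T
        r3 = cache["r3"]
        n, c3, hh, ww = r3.shape
        dr3 = np.broadcast_to(dg[:, :, None, None], r3.shape) / (hh * ww)
        da3 = (dr3 * (cache["a3"] > 0)).astype(dz.dtype)
        dp2, grads["conv3_w"], grads["conv3_b"] = self._conv_bwd(
            da3, cache["cols3"], p["conv3_w"], cache["p2"].shape
        )
        dr2 = self._pool_bwd(dp2, cache["idx2"], cache["a2"].shape)
        da2 = dr2 * (cache["a2"] > 0)
        dp1, grads["conv2_w"], grads["conv2_b"] = self._conv_bwd(
            da2, cache["cols2"], p["conv2_w"], cache["p1"].shape
        )
        dr1 = self._pool_bwd(dp1, cache["idx1"], cache["a1"].shape)
        da1 = dr1 * (cache["a1"] > 0)
        _, grads["conv1_w"], grads["conv1_b"] = self._conv_bwd(
            da1, cache["cols1"], p["conv1_w"], cache["x"].shape
        )
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name in self._trainable():
            g = grads[name]
            m = self._adam_m[name]
            v = self._adam_v[name]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[name] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(self.dtype)

    # -------------------------------------------------------------- training

    def fit_epochs(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        lr: float,
        rng: np.random.Generator,
        augment_fn=None,
    ) -> list[float]:
        """Mini-batch Adam over ``epochs`` passes; returns per-epoch mean loss.

        ``augment_fn(batch, rng) -> batch`` is applied to every mini-batch
        (fresh random draws each epoch), mirroring on-the-fly augmentation.
        """
        if not self.params:
            raise ArgumentError("initialize() must be called before fit")
        n = x.shape[0]
        x = x.astype(self.dtype, copy=False)
        losses: list[float] = []
        for _ in range(int(epochs)):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                xb = x[sel]
                if augment_fn is not None:
                    xb = augment_fn(xb, rng).astype(self.dtype, copy=False)
                xb = self.standardize(xb).astype(self.dtype, copy=False)
                yb = y[sel]
                z, cache = self._forward(xb[:, None, :, :], keep_cache=True)
                zs = z - z.max(axis=1, keepdims=True)
                expz = np.exp(zs)
                prob = expz / expz.sum(axis=1, keepdims=True)
                total += float(-np.log(prob[np.arange(len(sel)), yb] + 1e-12).sum())
                dz = prob
                dz[np.arange(len(sel)), yb] -= 1.0
                dz /= len(sel)
                grads = self._backward(dz.astype(self.dtype), cache)
                self._adam_step(grads, lr)
            losses.append(total / n)
        return losses

    def logits(self, x: np.ndarray) -> np.ndarray:
        """Raw class scores for a batch (n, h, w) -> (n, K); no augmentation."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_hw:
            raise ArgumentError(
                f"input geometry {x.shape[1:]} does not match model {self.input_hw}"
            )
        x = self.standardize(x).astype(self.dtype, copy=False)
        out = []
        for start in range(0, x.shape[0], 256):
            z, _ = self._forward(x[start : start + 256, None, :, :])
            out.append(z)
        return np.concatenate(out, axis=0) if out else np.zeros((0, self.n_classes))
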