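"""The regression CNN for cell-shape scoring.

A deliberately small network: three stages of (valid convolution, reLU,
2 x 2 stride-2 max pooling) followed by a single fully connected linear
output node.  There is no softmax head — the scalar output moves on the
8-bit-inspired scale of the class targets (slipper -127, sheared croissant
+64, croissant +127), and outlier rejection happens downstream by
thresholding that score.

The default architecture on 90 x 90 input produces the feature-map chain
70 -> 35 -> 22 -> 11 -> 6 -> 3 (conv 21, pool, conv 14, pool, conv 6,
pool), i.e. 21 x 21 kernels in the first stage.  The number of kernels in
stages 2 and 3 is a free choice (default 25, matching stage 1).

Everything is implemented directly on NumPy arrays: valid cross-correlation
evaluated in the Fourier domain (zero-padded FFTs, exact up to roundoff),
analytic backpropagation, and He-style fan-in initialization.  Forward and
backward are deterministic, so a finite-difference check against the
analytic gradient is part of the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft

__all__ = ["ModelSpec", "Model", "output_shapes", "build_model", "forward"]


@dataclass(frozen=True)
class ModelSpec:
    """Layer-chain description of the network.

    ``stages`` lists ``(kernel_px, n_kernels)`` per convolution stage; every
    stage is followed by reLU and a 2 x 2 stride-2 max pool.  The head is a
    single linear (identity-activation) output node fully connected to all
    values of the last pooled maps.
    """

    input_px: int = 90
    stages: tuple[tuple[int, int], ...] = ((21, 25), (14, 25), (6, 25))
    pool: int = 2
    pool_stride: int = 2
    # fixed affine conditioning of the input layer: (x - offset) / scale.
    # Centers the 8-bit range on zero so the stated learning rate is stable.
    input_offset: float = 127.5
    input_scale: float = 127.5

    def __post_init__(self) -> None:
        if self.input_px < 2:
            raise ValueError("input size must be >= 2")
        for k, n in self.stages:
            if k < 1 or n < 1:
                raise ValueError("kernel size and kernel count must be >= 1")

    @classmethod
    def small(cls, n_kernels: int = 8) -> "ModelSpec":
        """Desk-scale variant: same kernel sizes, fewer maps per stage."""
        return cls(stages=tuple((k, n_kernels) for k, _ in cls().stages))

    def to_dict(self) -> dict:
        return {"input_px": self.input_px,
                "stages": [list(s) for s in self.stages],
                "pool": self.pool, "pool_stride": self.pool_stride,
                "input_offset": self.input_offset,
                "input_scale": self.input_scale}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(input_px=d["input_px"],
                   stages=tuple(tuple(s) for s in d["stages"]),
                   pool=d.get("pool", 2), pool_stride=d.get("pool_stride", 2),
                   input_offset=d.get("input_offset", 127.5),
                   input_scale=d.get("input_scale", 127.5))


def output_shapes(spec: ModelSpec) -> list[tuple[int, int]]:
    """Feature-map side length and count after every conv and pool layer.

    Valid (no padding) stride-1 convolution shrinks a side by
    ``kernel - 1``; a 2 x 2 stride-2 pool halves it (floor).  On the default
    architecture this reproduces the chain
    ``[(70, 25), (35, 25), (22, 25), (11, 25), (6, 25), (3, 25)]``.

    Raises ``ValueError`` if a kernel does not fit its input.
    """
    side = spec.input_px
    shapes: list[tuple[int, int]] = []
    for k, n in spec.stages:
        side = side - k + 1
        if side <= 0:
            raise ValueError(f"kernel {k} larger than its {side + k - 1}-px input")
        shapes.append((side, n))
        side = side // spec.pool_stride
        if side <= 0:
            raise ValueError("pooling collapsed the feature map to nothing")
        shapes.append((side, n))
    return shapes


@dataclass
class Model:
    """Realized network: spec plus the free-parameter vector.

    ``weights[i]`` has shape ``(out_maps, in_maps, k, k)`` for stage ``i``;
    the head is ``fc_w`` (flattened final maps) and the scalars in
    ``biases`` / ``fc_b``.
    """

    spec: ModelSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    fc_w: np.ndarray
    fc_b: float

    # -- parameter-vector plumbing -------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, self.fc_w,
                np.atleast_1d(np.asarray(self.fc_b, float))]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def set_parameters(self, params: list[np.ndarray]) -> None:
        ns = len(self.spec.stages)
        self.weights = [np.asarray(p) for p in params[:ns]]
        self.biases = [np.asarray(p) for p in params[ns:2 * ns]]
        self.fc_w = np.asarray(params[2 * ns])
        self.fc_b = float(np.asarray(params[2 * ns + 1]).ravel()[0])

    # -- forward / backward --------------------------------------------
    @property
    def dtype(self) -> np.dtype:
        return self.weights[0].dtype

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Score a ``(N, H, W)`` stack (or one ``(H, W)`` image) of
        real-valued, windowed crops; returns ``(N,)`` scores (or a scalar)."""
        x = np.asarray(images, self.dtype)
        single = x.ndim == 2
        if single:
            x = x[None, :, :]
        elif x.ndim != 3:
            raise ValueError("expected (H, W) or (N, H, W) input")
        out, _ = self._forward_cached(x[:, None, :, :])
        return float(out[0]) if single else out

    def _forward_cached(self, x: np.ndarray):
        """Batched forward pass keeping the caches backprop needs.

        ``x`` is ``(N, C, H, W)``; returns ``(scores, cache)``.
        """
        if x.shape[2] != self.spec.input_px or x.shape[3] != self.spec.input_px:
            raise ValueError(
                f"expected {self.spec.input_px}-px square input, got "
                f"{x.shape[2]}x{x.shape[3]}")
        x = (np.asarray(x, self.dtype) - self.dtype.type(self.spec.input_offset)) \
            / self.dtype.type(self.spec.input_scale)
        cache = []
        for W, b in zip(self.weights, self.biases):
            z = _corr_valid(x, W) + b[None, :, None, None]
            a = np.maximum(z, 0.0)                      # reLU
            pooled, idx = _maxpool(a, self.spec.pool_stride)
            cache.append((x, z, a.shape, idx))
            x = pooled
        flat = x.reshape(x.shape[0], -1)
        scores = flat @ self.fc_w + self.fc_b
        cache.append((flat, x.shape))
        return scores, cache

    def _backward(self, cache, dscores: np.ndarray) -> list[np.ndarray]:
        """Gradient of a scalar loss w.r.t. every parameter.

        ``dscores`` is dL/dscore, shape ``(N,)``.  Returns gradients in the
        order of :meth:`parameters`.
        """
        flat, pooled_shape = cache[-1]
        d_fc_w = flat.T @ dscores
        d_fc_b = np.atleast_1d(dscores.sum())
        dx = (dscores[:, None] @ self.fc_w[None, :]).reshape(pooled_shape)

        dWs: list[np.ndarray] = []
        dbs: list[np.ndarray] = []
        for (x, z, a_shape, idx), W in zip(reversed(cache[:-1]),
                                           reversed(self.weights)):
            da = _maxpool_backward(dx, idx, a_shape, self.spec.pool_stride)
            dz = da * (z > 0)                           # reLU gate
            dWs.append(_corr_grad_w(x, dz, W.shape[-1]))
            dbs.append(dz.sum(axis=(0, 2, 3)))
            dx = _conv_full(dz, W)
        dWs.reverse()
        dbs.reverse()
        return [*dWs, *dbs, d_fc_w, d_fc_b]

    # -- serialization ---------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        """Write a single-file checkpoint (spec, parameters, metadata)."""
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(path, fc_w=self.fc_w, fc_b=self.fc_b,
                 spec=json.dumps(self.spec.to_dict()),
                 meta=json.dumps(extra or {}), **arrays)

    @classmethod
    def load(cls, path) -> tuple["Model", dict]:
        with np.load(path, allow_pickle=False) as z:
            spec = ModelSpec.from_dict(json.loads(str(z["spec"])))
            ns = len(spec.stages)
            model = cls(spec,
                        [z[f"w{i}"] for i in range(ns)],
                        [z[f"b{i}"] for i in range(ns)],
                        z["fc_w"], float(z["fc_b"]))
            meta = json.loads(str(z["meta"]))
        return model, meta


def _rfft2(a: np.ndarray, s: int) -> np.ndarray:
    return _fft.rfft2(a, s=(s, s), axes=(-2, -1))


def _irfft2(a: np.ndarray, s: int) -> np.ndarray:
    return _fft.irfft2(a, s=(s, s), axes=(-2, -1))


def _corr_valid(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of a batch with a kernel bank, via FFT.

    ``x`` is ``(B, C, H, H)``, ``W`` is ``(O, C, k, k)``; returns
    ``(B, O, H-k+1, H-k+1)`` with channels summed — the standard conv-layer
    forward map.  Zero-padding to a fast FFT length keeps the correlation
    linear (no wraparound), so the result is exact up to roundoff in the
    working precision of the inputs.
    """
    h = x.shape[-1]
    k = W.shape[-1]
    s = _fft.next_fast_len(h + k - 1)
    X = _rfft2(x, s)
    Kf = _rfft2(W[:, :, ::-1, ::-1], s)
    z = _irfft2(np.einsum("bcxy,ocxy->boxy", X, Kf), s)
    return np.ascontiguousarray(z[:, :, k - 1:h, k - 1:h])


def _corr_grad_w(x: np.ndarray, dz: np.ndarray, k: int) -> np.ndarray:
    """Kernel gradient: valid correlation of the inputs with the upstream
    deltas, contracted over the batch.  Returns ``(O, C, k, k)``."""
    h = x.shape[-1]
    p = dz.shape[-1]
    s = _fft.next_fast_len(h + p - 1)
    X = _rfft2(x, s)
    Df = _rfft2(dz[:, :, ::-1, ::-1], s)
    g = _irfft2(np.einsum("bcxy,boxy->ocxy", X, Df), s)
    return np.ascontiguousarray(g[:, :, p - 1:p - 1 + k, p - 1:p - 1 + k])


def _conv_full(dz: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Input gradient: full convolution of the deltas with the (unflipped)
    kernels, contracted over output maps.  Returns ``(B, C, H, H)``."""
    p = dz.shape[-1]
    k = W.shape[-1]
    s = _fft.next_fast_len(p + k - 1)
    Df = _rfft2(dz, s)
    Kf = _rfft2(W, s)
    x = _irfft2(np.einsum("boxy,ocxy->bcxy", Df, Kf), s)
    return np.ascontiguousarray(x[:, :, :p + k - 1, :p + k - 1])


def _maxpool(a: np.ndarray, s: int):
    """2 x 2 stride-2 max pool (truncating odd edges), with argmax indices."""
    b, c, h, w = a.shape
    ho, wo = h // s, w // s
    r = a[:, :, :ho * s, :wo * s].reshape(b, c, ho, s, wo, s)
    r = r.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, s * s)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, a_shape, s: int):
    b, c, h, w = a_shape
    ho, wo = h // s, w // s
    dr = np.zeros((b, c, ho, wo, s * s), dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    da = np.zeros(a_shape, dout.dtype)
    da[:, :, :ho * s, :wo * s] = (
        dr.reshape(b, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, ho * s, wo * s))
    return da


def build_model(spec: ModelSpec | None = None, init_seed: int = 0,
                dtype=np.float32) -> Model:
    """Instantiate the network with seeded He-style initialization.

    Kernel and head weights are zero-mean normal with std
    ``sqrt(2 / fan_in)``; all biases start at zero.  The same seed always
    yields parameter-identical models.  ``dtype`` sets the working
    precision (float32 default; float64 for e.g. finite-difference
    gradient checks).
    """
    if spec is None:
        spec = ModelSpec()
    shapes = output_shapes(spec)       # validates the arithmetic
    rng = np.random.default_rng(init_seed)
    weights, biases = [], []
    in_maps = 1
    for k, n in spec.stages:
        fan_in = in_maps * k * k
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  (n, in_maps, k, k)).astype(dtype))
        biases.append(np.zeros(n, dtype))
        in_maps = n
    final_side, final_maps = shapes[-1]
    fan_in = final_maps * final_side * final_side
    fc_w = rng.normal(0.0, np.sqrt(2.0 / fan_in), fan_in).astype(dtype)
    return Model(spec, weights, biases, fc_w, 0.0)


def forward(model: Model, img: np.ndarray) -> float | np.ndarray:
    """Functional alias for :meth:`Model.forward`."""
    return model.forward(img)
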