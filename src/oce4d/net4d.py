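"""4D spatiotemporal convolution and a DenseNet-style regression network.

Tensors are laid out channels-last: ``(batch, t, x, y, z, channels)``. The 4D
cross-correlation is evaluated in the frequency domain: both operands are
transformed with real FFTs padded to ``n + k - 1`` per axis (so the circular
product is the exact linear correlation), channels are contracted with a
batched matrix product per frequency bin, and the "same" window is sliced
from the inverse transform. A direct four-fold nested summation is kept in
the test suite as the numerical oracle.

The network follows the dense-connectivity pattern: a stem of four
convolutional layers, three dense blocks of three layers each with a fixed
feature growth rate, average-pooling transitions of stride 2 between blocks,
batch normalization and rectified-linear activations throughout, and a global
average pooling layer feeding a single linear regression output. Forward and
backward passes are hand-written NumPy; gradients are checked against finite
differences in the tests.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import scipy.fft as sfft

from .errors import ConfigurationError, DataError, ShapeError

# ---------------------------------------------------------------------------
# functional 4D convolution


def _as_stride4(stride: int | tuple[int, ...]) -> tuple[int, int, int, int]:
    if np.isscalar(stride):
        return (int(stride),) * 4
    s = tuple(int(v) for v in stride)
    if len(s) != 4 or any(v < 1 for v in s):
        raise ConfigurationError(f"stride must be 4 positive ints, got {stride}")
    return s


def _fft_sizes(n: tuple[int, ...], k: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(ni + ki - 1 for ni, ki in zip(n, k))


def _wrapped_take(g: np.ndarray, n: tuple[int, ...], p: list[int], s: tuple[int, ...],
                  first_axis: int) -> np.ndarray:
    """Extract indices (i - p) mod S along four consecutive axes."""
    for i, (ni, pi, si) in enumerate(zip(n, p, s)):
        if pi:
            idx = (np.arange(ni) - pi) % si
            g = np.take(g, idx, axis=first_axis + i)
        else:
            g = g[(slice(None),) * (first_axis + i) + (slice(0, ni),)]
    return g


def _corr4d_s1(
    x: np.ndarray,
    w: np.ndarray,
    cdtype: np.dtype,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stride-1 same-padded correlation of (B, n1..n4, Cin) with (k.., Cin, Cout).

    Evaluated as ``IFFT(conj(Whats) * Xhat)`` on transforms padded to
    ``n + k - 1``, which makes the circular correlation exactly linear.
    Returns ``(y, x_freq, w_freq)``; both spectra are reusable by the
    backward pass (the kernel does not change within one step).
    """
    bsz, cin = x.shape[0], x.shape[-1]
    n = x.shape[1:5]
    k = w.shape[:4]
    cout = w.shape[-1]
    p = [ki // 2 for ki in k]
    s = _fft_sizes(n, k)
    x_freq = sfft.rfftn(x, s=s, axes=(1, 2, 3, 4)).astype(cdtype, copy=False)
    w_freq = sfft.rfftn(w, s=s, axes=(0, 1, 2, 3)).astype(cdtype, copy=False)
    fshape = x_freq.shape[1:5]
    bins = int(np.prod(fshape))
    fm = x_freq.reshape(bsz, bins, cin).transpose(1, 0, 2)  # (bins, B, Cin)
    wm = np.conj(w_freq).reshape(bins, cin, cout)
    ym = fm @ wm  # (bins, B, Cout)
    y_freq = ym.transpose(1, 0, 2).reshape(bsz, *fshape, cout)
    g = sfft.irfftn(y_freq, s=s, axes=(1, 2, 3, 4))
    y = _wrapped_take(g, n, p, s, first_axis=1)
    return y, x_freq, w_freq


def _corr4d_grad_w(
    x_freq: np.ndarray,
    dy_freq: np.ndarray,
    n: tuple[int, ...],
    k: tuple[int, ...],
) -> np.ndarray:
    """Weight gradient from the cached input and output-gradient spectra.

    dW[d] = sum_{b,j} x[b, j + d - p] dy[b, j]: the cross-correlation of dy
    with x at shifts d - p, alias-free at FFT size n + k - 1.
    """
    bsz, cin = x_freq.shape[0], x_freq.shape[-1]
    cout = dy_freq.shape[-1]
    p = [ki // 2 for ki in k]
    s = _fft_sizes(n, k)
    fshape = x_freq.shape[1:5]
    bins = int(np.prod(fshape))
    fx = x_freq.reshape(bsz, bins, cin).transpose(1, 2, 0)  # (bins, Cin, B)
    fd = np.conj(dy_freq).reshape(bsz, bins, cout).transpose(1, 0, 2)  # (bins,B,Cout)
    z = fx @ fd  # (bins, Cin, Cout)
    g = sfft.irfftn(z.reshape(*fshape, cin, cout), s=s, axes=(0, 1, 2, 3))
    for axis, (ki, pi, si) in enumerate(zip(k, p, s)):
        idx = (np.arange(ki) - pi) % si
        g = np.take(g, idx, axis=axis)
    return g


def _corr4d_grad_x(
    dy_freq: np.ndarray,
    w_freq: np.ndarray,
    n: tuple[int, ...],
    k: tuple[int, ...],
) -> np.ndarray:
    """Input gradient: the (plain) convolution of dy with the kernel,
    IFFT(What * Dhat), sliced at offset +p."""
    bsz = dy_freq.shape[0]
    cin, cout = w_freq.shape[-2:]
    p = [ki // 2 for ki in k]
    s = _fft_sizes(n, k)
    fshape = dy_freq.shape[1:5]
    bins = int(np.prod(fshape))
    fd = dy_freq.reshape(bsz, bins, cout).transpose(1, 0, 2)  # (bins, B, Cout)
    wm = w_freq.reshape(bins, cin, cout).transpose(0, 2, 1)  # (bins, Cout, Cin)
    zm = fd @ wm  # (bins, B, Cin)
    z = zm.transpose(1, 0, 2).reshape(bsz, *fshape, cin)
    g = sfft.irfftn(z, s=s, axes=(1, 2, 3, 4))
    sl = (slice(None), *(slice(pi, pi + ni) for pi, ni in zip(p, n)), slice(None))
    return g[sl]


def conv4d(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None = None,
    stride: int | tuple[int, ...] = 1,
) -> np.ndarray:
    """Zero-padded ("same") 4D cross-correlation.

    Parameters
    ----------
    x : array ``(B, T, X, Y, Z, Cin)`` or ``(T, X, Y, Z, Cin)``
    w : array ``(kT, kX, kY, kZ, Cin, Cout)``; all kernel extents odd
    b : optional ``(Cout,)`` bias
    stride : scalar or per-axis ``(sT, sX, sY, sZ)``

    The input is zero-padded by ``k // 2`` on both sides of every
    spatiotemporal axis and output samples taken every ``stride`` positions,
    so stride 1 preserves the input extents exactly; stride s keeps every
    s-th sample of the stride-1 output. Computed at double precision.
    """
    squeeze = x.ndim == 5
    if squeeze:
        x = x[None]
    if x.ndim != 6 or w.ndim != 6:
        raise ShapeError(f"expected 6D input/kernel, got {x.shape} and {w.shape}")
    if x.shape[-1] != w.shape[4]:
        raise ShapeError(
            f"input channels {x.shape[-1]} != kernel input channels {w.shape[4]}"
        )
    if any(k % 2 == 0 for k in w.shape[:4]):
        raise ConfigurationError("kernel extents must be odd for symmetric padding")
    st = _as_stride4(stride)
    out_dtype = np.result_type(x, w)
    y, _, _ = _corr4d_s1(x.astype(np.float64), w.astype(np.float64), np.complex128)
    y = y[:, :: st[0], :: st[1], :: st[2], :: st[3], :]
    if b is not None:
        y = y + b
    y = y.astype(out_dtype, copy=False)
    return y[0] if squeeze else y


# ---------------------------------------------------------------------------
# layers


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv4d(Layer):
    """Stride-1, same-padded 4D convolution layer with bias.

    The forward pass caches the padded input spectrum so the weight gradient
    reuses it instead of re-transforming the input.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        rng: np.random.Generator,
        dtype: np.dtype = np.float32,
        name: str = "conv",
    ) -> None:
        fan_in = kernel**4 * cin
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(kernel,) * 4 + (cin, cout)).astype(dtype)
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self._cdtype = np.complex64 if np.dtype(dtype) == np.float32 else np.complex128
        self._x_freq: np.ndarray | None = None
        self._w_freq: np.ndarray | None = None
        self._n: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y, x_freq, w_freq = _corr4d_s1(x, self.w.value, self._cdtype)
        if training:
            self._x_freq, self._w_freq = x_freq, w_freq
            self._n = x.shape[1:5]
        return (y + self.b.value).astype(x.dtype, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x_freq is not None, "backward before forward"
        k = self.w.value.shape[:4]
        s = _fft_sizes(self._n, k)
        dy_freq = sfft.rfftn(dy, s=s, axes=(1, 2, 3, 4)).astype(
            self._cdtype, copy=False
        )
        dw = _corr4d_grad_w(self._x_freq, dy_freq, self._n, k)
        self.w.grad += dw.astype(self.w.grad.dtype, copy=False)
        self.b.grad += dy.sum(axis=(0, 1, 2, 3, 4))
        dx = _corr4d_grad_x(dy_freq, self._w_freq, self._n, k).astype(
            dy.dtype, copy=False
        )
        self._x_freq = self._w_freq = None
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes but the channel axis."""

    def __init__(
        self,
        channels: int,
        momentum: float = 0.9,
        eps: float = 1e-5,
        dtype: np.dtype = np.float32,
        name: str = "bn",
    ) -> None:
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if training:
            self._cache = (xhat, invstd.astype(x.dtype), axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, axes = self._cache
        n = np.prod([dy.shape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        dx = (
            invstd
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
            )
        )
        self._cache = None
        return dx.astype(dy.dtype)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class AvgPool4d(Layer):
    """Window-2 stride-2 average pooling over every spatiotemporal axis of
    extent >= 2; axes of extent 1 pass through; odd trailing samples are
    dropped."""

    def __init__(self) -> None:
        self._in_shape: tuple[int, ...] | None = None

    @staticmethod
    def output_shape(shape: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(n // 2 if n >= 2 else n for n in shape)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._in_shape = x.shape
        for axis in (1, 2, 3, 4):
            n = x.shape[axis]
            if n < 2:
                continue
            keep = (n // 2) * 2
            sl = [slice(None)] * x.ndim
            sl[axis] = slice(0, keep)
            x = x[tuple(sl)]
            new_shape = x.shape[:axis] + (n // 2, 2) + x.shape[axis + 1 :]
            x = x.reshape(new_shape).mean(axis=axis + 1)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        in_shape = self._in_shape
        for axis in (4, 3, 2, 1):
            n = in_shape[axis]
            if n < 2:
                continue
            dy = np.repeat(dy / 2.0, 2, axis=axis)
            if dy.shape[axis] < n:  # zero-grad for the dropped trailing sample
                pad = [(0, 0)] * dy.ndim
                pad[axis] = (0, n - dy.shape[axis])
                dy = np.pad(dy, pad)
        self._in_shape = None
        return dy


class GlobalAvgPool(Layer):
    """Mean over all spatiotemporal axes: (B, T, X, Y, Z, C) -> (B, C)."""

    def __init__(self) -> None:
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._in_shape = x.shape
        return x.mean(axis=(1, 2, 3, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, t, x_, y_, z_, c = self._in_shape
        scale = 1.0 / (t * x_ * y_ * z_)
        dx = np.broadcast_to(
            dy[:, None, None, None, None, :] * scale, self._in_shape
        ).astype(dy.dtype)
        self._in_shape = None
        return dx


class Linear(Layer):
    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        dtype: np.dtype = np.float32,
        name: str = "linear",
    ) -> None:
        std = np.sqrt(1.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cin, cout)).astype(dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value.T
        self._x = None
        return dx


class DenseLayer(Layer):
    """Pre-activation composite: batch norm -> rectifier -> 4D convolution."""

    def __init__(
        self,
        cin: int,
        growth: int,
        kernel: int,
        rng: np.random.Generator,
        dtype: np.dtype,
        name: str,
    ) -> None:
        self.bn = BatchNorm(cin, dtype=dtype, name=f"{name}.bn")
        self.act = ReLU()
        self.conv = Conv4d(cin, growth, kernel, rng, dtype=dtype, name=f"{name}.conv")

    def params(self) -> list[Param]:
        return self.bn.params() + self.conv.params()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = self.bn.forward(x, training)
        h = self.act.forward(h, training)
        return self.conv.forward(h, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.bn.backward(self.act.backward(self.conv.backward(dy)))


class DenseBlock(Layer):
    """Dense connectivity: each layer consumes the concatenation of the block
    input and every earlier layer's output, and contributes ``growth`` new
    channels; output channels = input + layers * growth."""

    def __init__(
        self,
        cin: int,
        layers: int,
        growth: int,
        kernel: int,
        rng: np.random.Generator,
        dtype: np.dtype,
        name: str,
    ) -> None:
        self.cin = cin
        self.growth = growth
        self.layers = [
            DenseLayer(cin + i * growth, growth, kernel, rng, dtype, f"{name}.l{i}")
            for i in range(layers)
        ]

    @property
    def cout(self) -> int:
        return self.cin + len(self.layers) * self.growth

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        features = x
        for layer in self.layers:
            y = layer.forward(features, training)
            features = np.concatenate([features, y], axis=-1)
        return features

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = dy
        for i in range(len(self.layers) - 1, -1, -1):
            c_in_i = self.cin + i * self.growth
            g_yi = g[..., c_in_i:]
            g = np.ascontiguousarray(g[..., :c_in_i]) + self.layers[i].backward(
                np.ascontiguousarray(g_yi)
            )
        return g


# ---------------------------------------------------------------------------
# the model


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the spatiotemporal regressor.

    Defaults follow the full-scale design: 10-volume sequences of 32^3 voxels,
    a 4-layer convolutional stem, three dense blocks of three layers with
    growth rate 8, and stride-2 average-pooling transitions. Stem width and
    kernel size are configurable (8 and 3 by default).
    """

    input_shape: tuple[int, int, int, int] = (10, 32, 32, 32)
    in_channels: int = 1
    stem_layers: int = 4
    stem_channels: int = 8
    n_blocks: int = 3
    layers_per_block: int = 3
    growth_rate: int = 8
    kernel_size: int = 3
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ConfigurationError("growth_rate must be > 0")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ConfigurationError("kernel_size must be odd and positive")
        if self.n_blocks < 1 or self.layers_per_block < 1 or self.stem_layers < 1:
            raise ConfigurationError("need >= 1 stem layer, block and block layer")
        shape = tuple(self.input_shape)
        if len(shape) != 4 or any(int(e) != e or e < 1 for e in shape):
            raise ConfigurationError(f"invalid input_shape {self.input_shape}")
        for _ in range(self.n_blocks - 1):
            shape = AvgPool4d.output_shape(shape)
            if any(e < 1 for e in shape):
                raise ConfigurationError(
                    "downsampling exhausts a spatiotemporal axis"
                )


class Model4D:
    """The stem -> dense blocks -> GAP -> linear regression network."""

    def __init__(self, spec: ModelSpec, seed: int) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        dtype = np.dtype(spec.dtype)
        k = spec.kernel_size
        self.layers: list[Layer] = []
        c = spec.in_channels
        for i in range(spec.stem_layers):
            self.layers += [
                Conv4d(c, spec.stem_channels, k, rng, dtype, name=f"stem{i}"),
                BatchNorm(spec.stem_channels, dtype=dtype, name=f"stem{i}.bn"),
                ReLU(),
            ]
            c = spec.stem_channels
        for bi in range(spec.n_blocks):
            block = DenseBlock(
                c, spec.layers_per_block, spec.growth_rate, k, rng, dtype,
                name=f"block{bi}",
            )
            self.layers.append(block)
            c = block.cout
            if bi < spec.n_blocks - 1:
                self.layers.append(AvgPool4d())
        self.layers += [
            BatchNorm(c, dtype=dtype, name="head.bn"),
            ReLU(),
            GlobalAvgPool(),
            Linear(c, 1, rng, dtype, name="head"),
        ]
        self.final_channels = c

    # -- parameters -----------------------------------------------------
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- passes ----------------------------------------------------------
    def _coerce(self, batch: np.ndarray) -> np.ndarray:
        x = np.asarray(batch, dtype=self.spec.dtype)
        if x.ndim == 5:
            x = x[..., None]
        if x.ndim != 6 or x.shape[-1] != self.spec.in_channels:
            raise ShapeError(f"expected (B, T, X, Y, Z[, C]) input, got {batch.shape}")
        if not np.all(np.isfinite(x)):
            raise DataError("non-finite values in network input")
        return x

    def forward(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        """Predict one concentration (percent) per batch item."""
        x = self._coerce(batch)
        for layer in self.layers:
            x = layer.forward(x, training)
        return x[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        """Backpropagate d(loss)/d(prediction), accumulating parameter grads."""
        g = np.asarray(dpred, dtype=self.spec.dtype)[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    __call__ = forward

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"param/{p.name}": p.value for p in self.params()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                arrays[f"bnstat/{i}/mean"] = layer.running_mean
                arrays[f"bnstat/{i}/var"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.params():
            key = f"param/{p.name}"
            if key not in arrays:
                raise ShapeError(f"checkpoint missing parameter {p.name}")
            p.value = np.array(arrays[key], dtype=p.value.dtype)
            p.grad = np.zeros_like(p.value)
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(arrays[f"bnstat/{i}/mean"])
                layer.running_var = np.array(arrays[f"bnstat/{i}/var"])

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def layer_table(self) -> list[tuple[str, str, int]]:
        """(layer kind, detail, parameter count) per layer, for summaries."""
        rows = []
        for layer in self.layers:
            n = sum(p.value.size for p in layer.params())
            kind = type(layer).__name__
            detail = ""
            if isinstance(layer, Conv4d):
                detail = "x".join(str(s) for s in layer.w.value.shape)
            elif isinstance(layer, DenseBlock):
                detail = f"{layer.cin}->{layer.cout} ch"
            rows.append((kind, detail, int(n)))
        return rows


def build_model(spec: ModelSpec, seed: int) -> Model4D:
    """Build the network with deterministic initialization from ``seed``."""
    return Model4D(spec, seed)


def save_checkpoint(path, model: Model4D, extra: dict | None = None) -> None:
    """Single-file .npz archive: spec JSON, seed, parameters, BN statistics."""
    meta = {"spec": asdict(model.spec), "seed": model.seed, "extra": extra or {}}
    arrays = model.state_arrays()
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ), **arrays)


def load_checkpoint(path) -> tuple[Model4D, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    spec_d = meta["spec"]
    spec_d["input_shape"] = tuple(spec_d["input_shape"])
    spec = ModelSpec(**spec_d)
    model = Model4D(spec, meta["seed"])
    model.load_state_arrays(arrays)
    return model, meta.get("extra", {})
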