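"""Minimal reverse-mode layer engine for the EEG block system.

Public model inputs/outputs use the conventional ``(batch, maps, channels,
time)`` layout; internally every layer works on time-major tensors
``(time, maps, batch, channels)``.  That choice makes the expensive
temporal convolutions cheap on one CPU: the real FFT runs along the
leading axis with no transposes, the per-frequency feature-map mixing is
one batched complex matmul, and 'same' padding and output alignment fold
into precomputed phase factors (circular-shift theorem), so a (1, 64)
kernel over a 720-sample epoch costs three FFT passes and two or three
small GEMMs per training step.  Forward spectra are cached and reused by
the weight-gradient pass.

Every layer implements ``forward`` (caching what backward needs) and
``backward`` (returning the input gradient, accumulating parameter
gradients).  The adjoints of the FFT convolutions are exercised against
brute-force loops and central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(shape, fan_in, fan_out, rng, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _complex_dtype(dtype) -> type:
    return np.complex64 if np.dtype(dtype) == np.float32 else np.complex128


def _phase(L: int, Lf: int, shift: int, cdtype) -> np.ndarray:
    """Spectrum multiplier rolling an irfft output right by ``shift``."""
    f = np.arange(Lf)
    return np.exp(-2j * np.pi * f * shift / L).astype(cdtype)


# ---------------------------------------------------------------------------
# layers


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _FFTConvBase(Layer):
    """Shared circular-FFT machinery for the temporal convolutions.

    Cross-correlation with 'same' padding: pad_left = (k-1)//2 zeros in
    front (even kernels weigh the future side one sample heavier).  With
    FFT length L >= T + k - 1 the circular wrap-around only ever touches
    the zero-padded tail, so the linear correlation is exact.
    """

    def __init__(self, k: int, dtype):
        self.k = int(k)
        self.pad_left = (self.k - 1) // 2
        self.dtype = np.dtype(dtype)
        self.cdtype = _complex_dtype(dtype)
        self._T = None
        self._L = None
        self._ph_fwd = None   # aligns the forward output with the input grid
        self._ph_pad = None   # spectrum of the left zero-padding shift
        self._xf = None       # cached forward input spectrum

    def _plan(self, T: int) -> None:
        if self._T == T:
            return
        L = sfft.next_fast_len(T + self.k - 1, real=True)
        Lf = L // 2 + 1
        self._T, self._L = T, L
        self._ph_fwd = _phase(L, Lf, self.pad_left, self.cdtype)
        self._ph_pad = self._ph_fwd  # same shift, used on the input spectrum


class TemporalConv(_FFTConvBase):
    """(1, k) cross-correlation mixing ``in_maps -> out_maps`` feature maps.

    No bias: every instance is followed by batch norm, and the classifier
    head has its own bias.
    """

    def __init__(self, in_maps, out_maps, k, rng, dtype=np.float64, name="tconv",
                 skip_input_grad=False):
        super().__init__(k, dtype)
        self.in_maps = in_maps
        self.out_maps = out_maps
        # the network's first block never needs dL/dx
        self.skip_input_grad = skip_input_grad
        self.w = Parameter(
            glorot_uniform((out_maps, in_maps, self.k), in_maps * self.k,
                           out_maps * self.k, rng, dtype),
            name + ".w",
        )

    def parameters(self):
        return [self.w]

    def _wf(self):
        # (Lf, out, in) spectrum of the correlation operator incl. alignment
        wf = sfft.rfft(self.w.value, self._L, axis=-1)
        return (np.conj(wf) * self._ph_fwd).transpose(2, 0, 1)

    def forward(self, x, train=False, rng=None):
        T, Fi, N, C = x.shape
        self._plan(T)
        xf = sfft.rfft(x.reshape(T, Fi, N * C), self._L, axis=0)
        self._xf = xf
        self._shape = (T, Fi, N, C)
        yf = np.matmul(self._wf(), xf)
        y = sfft.irfft(yf, self._L, axis=0)[:T]
        return y.reshape(T, self.out_maps, N, C)

    def backward(self, g):
        T, Fi, N, C = self._shape
        gf = sfft.rfft(g.reshape(T, self.out_maps, N * C), self._L, axis=0)
        # dL/dw: circular correlation of the padded input with g.
        pw = np.matmul(np.conj(gf), self._xf.transpose(0, 2, 1))
        pw *= self._ph_pad[:, None, None]
        gw = sfft.irfft(pw, self._L, axis=0)[: self.k]
        self.w.grad += gw.transpose(1, 2, 0).astype(self.w.grad.dtype)
        self._xf = None
        if self.skip_input_grad:
            return None
        # dL/dx: adjoint operator = conjugate spectrum, transposed mixing.
        gxf = np.matmul(np.conj(self._wf()).transpose(0, 2, 1), gf)
        gx = sfft.irfft(gxf, self._L, axis=0)[:T]
        return gx.reshape(T, Fi, N, C)


class DepthwiseTemporalConv(_FFTConvBase):
    """Per-map (1, k) cross-correlation (no map mixing), 'same' padding."""

    def __init__(self, maps, k, rng, dtype=np.float64, name="dwconv"):
        super().__init__(k, dtype)
        self.maps = maps
        self.w = Parameter(
            glorot_uniform((maps, self.k), self.k, self.k, rng, dtype), name + ".w"
        )

    def parameters(self):
        return [self.w]

    def _wf(self):
        wf = sfft.rfft(self.w.value, self._L, axis=-1)
        return (np.conj(wf) * self._ph_fwd).T  # (Lf, maps)

    def forward(self, x, train=False, rng=None):
        T, F, N, C = x.shape
        self._plan(T)
        xf = sfft.rfft(x.reshape(T, F, N * C), self._L, axis=0)
        self._xf = xf
        self._shape = (T, F, N, C)
        yf = xf * self._wf()[:, :, None]
        y = sfft.irfft(yf, self._L, axis=0)[:T]
        return y.reshape(T, F, N, C)

    def backward(self, g):
        T, F, N, C = self._shape
        gf = sfft.rfft(g.reshape(T, F, N * C), self._L, axis=0)
        pw = np.einsum("qfs,qfs->qf", np.conj(gf), self._xf, optimize=True)
        pw *= self._ph_pad[:, None]
        gw = sfft.irfft(pw, self._L, axis=0)[: self.k]
        self.w.grad += gw.T.astype(self.w.grad.dtype)
        gxf = gf * np.conj(self._wf())[:, :, None]
        gx = sfft.irfft(gxf, self._L, axis=0)[:T]
        self._xf = None
        return gx.reshape(T, F, N, C)


class PointwiseConv(Layer):
    """(1, 1) convolution mixing feature maps."""

    def __init__(self, in_maps, out_maps, rng, dtype=np.float64, name="pwconv"):
        self.w = Parameter(
            glorot_uniform((out_maps, in_maps), in_maps, out_maps, rng, dtype),
            name + ".w",
        )
        self._x = None

    def parameters(self):
        return [self.w]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return np.einsum("oi,tinc->tonc", self.w.value, x, optimize=True)

    def backward(self, g):
        self.w.grad += np.einsum("tonc,tinc->oi", g, self._x, optimize=True).astype(
            self.w.grad.dtype
        )
        return np.einsum("oi,tonc->tinc", self.w.value, g, optimize=True)


class SpatialConv(Layer):
    """Full-height (C, 1) convolution collapsing the electrode axis to 1.

    Carries the max-norm cap ``maxnorm_c``: each output filter's Euclidean
    norm is projected to <= c after every optimizer step.
    """

    def __init__(self, in_maps, out_maps, height, rng, dtype=np.float64,
                 maxnorm_c: float | None = 1.0, name="sconv"):
        self.height = int(height)
        self.maxnorm_c = maxnorm_c
        self.w = Parameter(
            glorot_uniform((out_maps, in_maps, self.height), in_maps * self.height,
                           out_maps, rng, dtype),
            name + ".w",
        )
        self._x = None

    def parameters(self):
        return [self.w]

    def forward(self, x, train=False, rng=None):
        if x.shape[3] != self.height:
            raise ValueError(
                f"spatial conv expects {self.height} channels, got {x.shape[3]}"
            )
        self._x = x
        y = np.einsum("oic,tinc->ton", self.w.value, x, optimize=True)
        return y[:, :, :, None]

    def backward(self, g):
        g3 = g[:, :, :, 0]
        self.w.grad += np.einsum("ton,tinc->oic", g3, self._x, optimize=True).astype(
            self.w.grad.dtype
        )
        return np.einsum("oic,ton->tinc", self.w.value, g3, optimize=True)


class BatchNorm(Layer):
    """Per-feature-map batch normalization over (time, batch, channels).

    eps = 1e-5 and running-average momentum = 0.1 (conventional defaults,
    surfaced in the layer summary).  ``set_identity`` freezes the layer to
    an exact identity in eval mode, used by the residual-identity checks.
    """

    AXES = (0, 2, 3)
    SHAPE = (1, -1, 1, 1)

    def __init__(self, maps, eps=1e-5, momentum=0.1, dtype=np.float64, name="bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(maps, dtype=dtype), name + ".gamma")
        self.beta = Parameter(np.zeros(maps, dtype=dtype), name + ".beta")
        self.running_mean = np.zeros(maps, dtype=dtype)
        self.running_var = np.ones(maps, dtype=dtype)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def set_identity(self) -> None:
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0
        self.beta.value[...] = 0.0
        self.gamma.value[...] = np.sqrt(1.0 + self.eps)

    def forward(self, x, train=False, rng=None):
        if train:
            mu = x.mean(axis=self.AXES)
            var = x.var(axis=self.AXES)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (
                var * (m / max(m - 1, 1)) - self.running_var
            )
        else:
            mu = self.running_mean
            var = self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(self.SHAPE)) * ivar.reshape(self.SHAPE)
        self._cache = (xhat, ivar, train)
        return (
            self.gamma.value.reshape(self.SHAPE) * xhat
            + self.beta.value.reshape(self.SHAPE)
        )

    def backward(self, g):
        xhat, ivar, train = self._cache
        shape, axes = self.SHAPE, self.AXES
        self.gamma.grad += np.sum(g * xhat, axis=axes).astype(self.gamma.grad.dtype)
        self.beta.grad += np.sum(g, axis=axes).astype(self.beta.grad.dtype)
        ghat = g * self.gamma.value.reshape(shape)
        if not train:
            return ghat * ivar.reshape(shape)
        m = g.shape[0] * g.shape[2] * g.shape[3]
        sum_g = ghat.sum(axis=axes).reshape(shape)
        sum_gx = (ghat * xhat).sum(axis=axes).reshape(shape)
        return (ivar.reshape(shape) / m) * (m * ghat - sum_g - xhat * sum_gx)


class ELU(Layer):
    def __init__(self, alpha=1.0):
        self.alpha = alpha
        self._cache = None

    def forward(self, x, train=False, rng=None):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._cache = (x > 0, y)
        return y

    def backward(self, g):
        pos, y = self._cache
        return g * np.where(pos, 1.0, y + self.alpha)


class AvgPoolTime(Layer):
    """Non-overlapping average pooling over time with floor division.

    A trailing remainder of fewer than ``p`` samples is dropped (and
    receives zero gradient).
    """

    def __init__(self, p):
        self.p = int(p)
        self._in_T = None

    def forward(self, x, train=False, rng=None):
        T = x.shape[0]
        T2 = T // self.p
        self._in_T = T
        return x[: T2 * self.p].reshape((T2, self.p) + x.shape[1:]).mean(axis=1)

    def backward(self, g):
        p, T = self.p, self._in_T
        rep = np.repeat(g / p, p, axis=0)
        if rep.shape[0] < T:
            pad = [(0, T - rep.shape[0])] + [(0, 0)] * (g.ndim - 1)
            rep = np.pad(rep, pad)
        return rep


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p):
        self.p = float(p)
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in train mode needs an rng")
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Residual(Layer):
    """Identity-shortcut wrapper: out = inner(x) + x (no projection)."""

    def __init__(self, inner: Layer):
        self.inner = inner

    def parameters(self):
        return self.inner.parameters()

    def forward(self, x, train=False, rng=None):
        y = self.inner.forward(x, train=train, rng=rng)
        if y.shape != x.shape:
            raise ValueError(
                f"residual shortcut needs matching shapes, got {x.shape} vs {y.shape}"
            )
        return y + x

    def backward(self, g):
        return self.inner.backward(g) + g


class TimeCollapseConv(Layer):
    """Classifier convolution with kernel (1, T) spanning the whole extent.

    Input (T, F, N, 1) -> class scores (N, n_class).  Carries a bias (no
    batch norm follows it).
    """

    def __init__(self, in_maps, n_class, T, rng, dtype=np.float64, name="cls"):
        self.T = int(T)
        self.w = Parameter(
            glorot_uniform((n_class, in_maps, self.T), in_maps * self.T, n_class,
                           rng, dtype),
            name + ".w",
        )
        self.b = Parameter(np.zeros(n_class, dtype=dtype), name + ".b")
        self._x = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        if x.shape[0] != self.T or x.shape[3] != 1:
            raise ValueError(f"classifier expects ({self.T}, F, N, 1), got {x.shape}")
        self._x = x
        y = np.einsum("cft,tfn->nc", self.w.value, x[:, :, :, 0], optimize=True)
        return y + self.b.value[None, :]

    def backward(self, g):
        self.w.grad += np.einsum(
            "nc,tfn->cft", g, self._x[:, :, :, 0], optimize=True
        ).astype(self.w.grad.dtype)
        self.b.grad += g.sum(axis=0).astype(self.b.grad.dtype)
        gx = np.einsum("cft,nc->tfn", self.w.value, g, optimize=True)
        return gx[:, :, :, None]


class LogSoftmax(Layer):
    """Log-softmax over the class axis of (N, n_class) scores."""

    def __init__(self):
        self._y = None

    def forward(self, x, train=False, rng=None):
        z = x - x.max(axis=1, keepdims=True)
        self._y = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return self._y

    def backward(self, g):
        return g - np.exp(self._y) * g.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model


def to_internal(x: np.ndarray) -> np.ndarray:
    """(N, F, C, T) -> time-major (T, F, N, C)."""
    return np.ascontiguousarray(x.transpose(3, 1, 0, 2))


def from_internal(x: np.ndarray) -> np.ndarray:
    """Time-major (T, F, N, C) -> (N, F, C, T)."""
    return np.ascontiguousarray(x.transpose(2, 1, 3, 0))


class Model:
    """An ordered list of named blocks with activation/gradient capture.

    ``forward`` takes standard-layout batches ``(N, 1, channels, time)``
    and returns ``(N, n_class)`` scores; captured activations/gradients
    are returned in standard layout ``(N, maps, channels, time)``.
    """

    def __init__(self, blocks: list[tuple[str, Layer]]):
        self.blocks = blocks
        self._acts: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}

    @property
    def block_names(self) -> list[str]:
        return [name for name, _ in self.blocks]

    def block(self, name: str) -> Layer:
        for n, layer in self.blocks:
            if n == name:
                return layer
        raise KeyError(f"unknown block {name!r}; known: {self.block_names}")

    def parameters(self) -> list[Parameter]:
        return [p for _, layer in self.blocks for p in layer.parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x, train=False, rng=None, capture=()):
        """Run all blocks; keep the outputs of blocks named in ``capture``."""
        capture = set(capture)
        unknown = capture - set(self.block_names)
        if unknown:
            raise KeyError(f"unknown block(s) {sorted(unknown)}")
        self._acts = {}
        self._grads = {}
        x = to_internal(np.asarray(x))
        for name, layer in self.blocks:
            x = layer.forward(x, train=train, rng=rng)
            if name in capture:
                self._acts[name] = from_internal(x)
        return x

    def backward(self, g, capture=()):
        """Backpropagate ``g`` (N, n_class) from the output; keep gradients
        w.r.t. the outputs of blocks named in ``capture``."""
        capture = set(capture)
        for name, layer in reversed(self.blocks):
            if name in capture:
                self._grads[name] = from_internal(g)
            g = layer.backward(g)
        return g

    def captured_activation(self, name: str) -> np.ndarray:
        return self._acts[name]

    def captured_gradient(self, name: str) -> np.ndarray:
        return self._grads[name]

    def forward_from(self, name: str, a: np.ndarray, train=False, rng=None):
        """Run the blocks strictly after ``name`` on a standard-layout
        activation ``a``; used by finite-difference gradient checks."""
        i = self.block_names.index(name)
        x = to_internal(np.asarray(a))
        for _, layer in self.blocks[i + 1 :]:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for _, layer in self.blocks:
            for sub in _iter_layers(layer):
                if isinstance(sub, BatchNorm):
                    state[sub.gamma.name + ".running_mean"] = sub.running_mean.copy()
                    state[sub.gamma.name + ".running_var"] = sub.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for _, layer in self.blocks:
            for sub in _iter_layers(layer):
                if isinstance(sub, BatchNorm):
                    sub.running_mean[...] = state[sub.gamma.name + ".running_mean"]
                    sub.running_var[...] = state[sub.gamma.name + ".running_var"]


def _iter_layers(layer: Layer):
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    elif isinstance(layer, Residual):
        yield from _iter_layers(layer.inner)


def project_maxnorm(w: np.ndarray, c: float = 1.0) -> np.ndarray:
    """Scale each leading-axis filter of ``w`` to Euclidean norm <= c."""
    if c <= 0:
        raise ValueError("max-norm cap must be positive")
    flat = w.reshape(w.shape[0], -1)
    norms = np.sqrt((flat**2).sum(axis=1))
    scale = np.where(norms > c, c / np.maximum(norms, 1e-300), 1.0)
    return w * scale.reshape((-1,) + (1,) * (w.ndim - 1)).astype(w.dtype)


def apply_maxnorm(model: Model) -> None:
    """Project every max-norm-constrained filter bank in ``model``."""
    for _, layer in model.blocks:
        for sub in _iter_layers(layer):
            if isinstance(sub, SpatialConv) and sub.maxnorm_c is not None:
                sub.w.value[...] = project_maxnorm(sub.w.value, sub.maxnorm_c)
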