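"""U-Net displacement-field regressor with hand-written backpropagation.

The registration network T_theta maps a 2-channel stack of the fixed and
moving images to a dense 2-channel displacement field of the same spatial
size. Architecture (per configured level, paper scale 32/64/128/256/512):

* encoder: 3x3 same-padded conv + activation, then 2x2 max pooling
  between levels (feature maps halve per level);
* decoder: 2x2 stride-2 deconvolution (+ activation) doubling the maps,
  concatenation with the same-depth encoder features (optionally passed
  through instance normalization), then a 3x3 conv + activation;
* head: a 1x1 conv with exactly 2 output channels, linear — the output
  is a signed displacement in pixels, so no non-negative activation is
  applied.

Weights use Kaiming (He) initialization matched to the leaky-ReLU slope.
Every layer implements an explicit ``backward`` so the whole network is
trainable with plain NumPy; gradient correctness is pinned down against
central finite differences in the test-suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["NetworkConfig", "RegistrationModel", "UNet", "Adam", "build_network", "predict_field"]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters of the displacement network.

    ``input_size`` is (H, W) and must be divisible by 2**(levels-1) so the
    pooling/up-sampling ladder closes exactly. ``filters_per_level`` must
    have one entry per level.
    """

    levels: int = 3
    filters_per_level: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 3
    activation: str = "leaky_relu"
    leaky_slope: float = 0.2
    use_instance_norm_on_skips: bool = True
    use_residual_blocks: bool = False
    input_size: tuple[int, int] = (64, 64)
    in_channels: int = 2
    field_clamp: float | None = None
    dtype: str = "float64"

    def __post_init__(self) -> None:
        self.filters_per_level = tuple(int(f) for f in self.filters_per_level)
        self.input_size = tuple(int(s) for s in self.input_size)
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.filters_per_level) != self.levels:
            raise ValueError(
                f"filters_per_level has {len(self.filters_per_level)} entries "
                f"for {self.levels} levels"
            )
        d = 2 ** (self.levels - 1)
        h, w = self.input_size
        if h % d or w % d:
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2**(levels-1) = {d}"
            )
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError("activation must be 'relu' or 'leaky_relu'")

    @property
    def slope(self) -> float:
        return 0.0 if self.activation == "relu" else self.leaky_slope

    @classmethod
    def paper_scale(cls) -> "NetworkConfig":
        """Full-resolution profile: 5 levels, 32..512 filters, 928x1408 input."""
        return cls(
            levels=5,
            filters_per_level=(32, 64, 128, 256, 512),
            input_size=(928, 1408),
            dtype="float32",
        )

    @classmethod
    def desk_scale(cls) -> "NetworkConfig":
        """Small profile used for tests and synthetic experiments.

        Residual blocks are enabled: the full-scale network is described
        as an encoder-decoder with residual connections, and at this scale
        the extra within-level conv markedly improves optimization (lower
        training loss for the same schedule).
        """
        return cls(
            levels=3,
            filters_per_level=(8, 16, 32),
            input_size=(64, 64),
            use_residual_blocks=True,
            dtype="float32",
        )

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "filters_per_level": list(self.filters_per_level),
            "kernel_size": self.kernel_size,
            "activation": self.activation,
            "leaky_slope": self.leaky_slope,
            "use_instance_norm_on_skips": self.use_instance_norm_on_skips,
            "use_residual_blocks": self.use_residual_blocks,
            "input_size": list(self.input_size),
            "in_channels": self.in_channels,
            "field_clamp": self.field_clamp,
            "dtype": self.dtype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# layers


def _kaiming(rng: np.random.Generator, shape, fan_in: int, slope: float, dtype):
    std = np.sqrt(2.0 / ((1.0 + slope**2) * fan_in))
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2D:
    """Same-padded 2D convolution (odd kernel) via im2col + einsum."""

    def __init__(self, name, c_in, c_out, k, rng, slope, dtype):
        self.name = name
        self.k = k
        self.w = _kaiming(rng, (c_out, c_in, k, k), c_in * k * k, slope, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cols = None

    def params(self):
        return [(f"{self.name}.w", self.w), (f"{self.name}.b", self.b)]

    def forward(self, x):
        k, p = self.k, (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        self._cols = cols
        y = np.einsum("nchwij,ocij->nohw", cols, self.w, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, gy, grads):
        k, p = self.k, (self.k - 1) // 2
        grads[f"{self.name}.w"] = np.einsum(
            "nohw,nchwij->ocij", gy, self._cols, optimize=True
        )
        grads[f"{self.name}.b"] = gy.sum(axis=(0, 2, 3))
        gp = np.pad(gy, ((0, 0), (0, 0), (p, p), (p, p))) if p else gy
        gcols = sliding_window_view(gp, (k, k), axis=(2, 3))
        wf = self.w[:, :, ::-1, ::-1]
        self._cols = None
        return np.einsum("nohwij,ocij->nchw", gcols, wf, optimize=True)


class Activation:
    """(Leaky) ReLU; slope 0 gives plain ReLU."""

    def __init__(self, slope):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        g = np.where(self._mask, gy, self.slope * gy)
        self._mask = None
        return g


class MaxPool2:
    """2x2 max pooling, stride 2; ties resolve to the first maximum."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._shape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return g.reshape(n, c, h, w)


class ConvTranspose2:
    """2x2 stride-2 deconvolution (doubles the spatial size)."""

    def __init__(self, name, c_in, c_out, rng, slope, dtype):
        self.name = name
        self.w = _kaiming(rng, (c_in, c_out, 2, 2), c_in, slope, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._x = None

    def params(self):
        return [(f"{self.name}.w", self.w), (f"{self.name}.b", self.b)]

    def forward(self, x):
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,coab->nohwab", x, self.w, optimize=True)
        y = y.transpose(0, 1, 2, 4, 3, 5).reshape(n, self.w.shape[1], 2 * h, 2 * w)
        return y + self.b[None, :, None, None]

    def backward(self, gy, grads):
        n, o, h2, w2 = gy.shape
        gyr = gy.reshape(n, o, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        grads[f"{self.name}.w"] = np.einsum(
            "nchw,nohwab->coab", self._x, gyr, optimize=True
        )
        grads[f"{self.name}.b"] = gy.sum(axis=(0, 2, 3))
        gx = np.einsum("nohwab,coab->nchw", gyr, self.w, optimize=True)
        self._x = None
        return gx


class InstanceNorm:
    """Per-sample, per-channel normalization over H, W (no learned affine)."""

    eps = 1e-5

    def __init__(self):
        self._xhat = None
        self._istd = None

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        self._xhat, self._istd = xhat, istd
        return xhat

    def backward(self, gy):
        xhat, istd = self._xhat, self._istd
        m = gy.mean(axis=(2, 3), keepdims=True)
        mx = (gy * xhat).mean(axis=(2, 3), keepdims=True)
        self._xhat = self._istd = None
        return istd * (gy - m - xhat * mx)


# ---------------------------------------------------------------------------
# network


class UNet:
    """Encoder-decoder displacement network (see module docstring)."""

    def __init__(self, config: NetworkConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype)
        slope = config.slope
        f = config.filters_per_level
        k = config.kernel_size
        L = config.levels

        self.enc = []
        c_in = config.in_channels
        for i in range(L):
            convs = [Conv2D(f"enc{i}a", c_in, f[i], k, rng, slope, dtype)]
            if config.use_residual_blocks:
                convs.append(Conv2D(f"enc{i}b", f[i], f[i], k, rng, slope, dtype))
            self.enc.append(convs)
            c_in = f[i]

        self.dec = []
        c_prev = f[-1]
        for i in range(L - 2, -1, -1):
            up = ConvTranspose2(f"up{i}", c_prev, f[i], rng, slope, dtype)
            conv = Conv2D(f"dec{i}", 2 * f[i], f[i], k, rng, slope, dtype)
            norm = InstanceNorm() if config.use_instance_norm_on_skips else None
            self.dec.append((i, up, conv, norm))
            c_prev = f[i]

        self.head = Conv2D("head", f[0], 2, 1, rng, slope, dtype)
        self._slope = slope

    # -- parameter plumbing -------------------------------------------------

    def _layers_with_params(self):
        for convs in self.enc:
            yield from convs
        for _, up, conv, _ in self.dec:
            yield up
            yield conv
        yield self.head

    def params(self) -> dict[str, np.ndarray]:
        return dict(p for layer in self._layers_with_params() for p in layer.params())

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        own = self.params()
        if set(own) != set(values):
            missing = sorted(set(own) ^ set(values))
            raise ValueError(f"parameter name mismatch: {missing[:4]}")
        for layer in self._layers_with_params():
            for name, arr in layer.params():
                new = np.asarray(values[name])
                if new.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: {new.shape} vs {arr.shape}"
                    )
                arr[...] = new

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params()[name]).tobytes())
        return h.hexdigest()

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, in_channels, H, W) -> field (N, 2, H, W)."""
        cfg = self.config
        d = 2 ** (cfg.levels - 1)
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise ValueError(f"expected (N, {cfg.in_channels}, H, W), got {x.shape}")
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(f"spatial size {x.shape[2:]} must be divisible by {d}")
        x = x.astype(cfg.dtype, copy=False)

        self._acts = []  # encoder blocks: list of per-conv activations
        self._pools = []
        self._residual = []
        skips = []
        for i, convs in enumerate(self.enc):
            block_acts = []
            res_in = None
            for j, conv in enumerate(convs):
                pre = conv.forward(x)
                if cfg.use_residual_blocks and j == 1:
                    res_in = x
                    pre = pre + x  # identity shortcut within the level
                act = Activation(self._slope)
                x = act.forward(pre)
                block_acts.append(act)
            self._acts.append(block_acts)
            self._residual.append(res_in is not None)
            if i < cfg.levels - 1:
                skips.append(x)
                pool = MaxPool2()
                x = pool.forward(x)
                self._pools.append(pool)

        self._dec_acts = []
        self._concat_split = []
        for idx, (i, up, conv, norm) in enumerate(self.dec):
            a_up = Activation(self._slope)
            x = a_up.forward(up.forward(x))
            s = skips[i]
            if norm is not None:
                s = norm.forward(s)
            self._concat_split.append(s.shape[1])
            x = np.concatenate([s, x], axis=1)
            a_conv = Activation(self._slope)
            x = a_conv.forward(conv.forward(x))
            self._dec_acts.append((a_up, a_conv))

        out = self.head.forward(x)
        if cfg.field_clamp is not None:
            self._clamp_mask = np.abs(out) <= cfg.field_clamp
            out = np.clip(out, -cfg.field_clamp, cfg.field_clamp)
        return out

    def backward(self, g_out: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop d loss / d field -> gradients for every parameter."""
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        g = g_out.astype(cfg.dtype, copy=False)
        if cfg.field_clamp is not None:
            g = g * self._clamp_mask
        g = self.head.backward(g, grads)

        g_skips = {}
        for idx in range(len(self.dec) - 1, -1, -1):
            i, up, conv, norm = self.dec[idx]
            a_up, a_conv = self._dec_acts[idx]
            g = conv.backward(a_conv.backward(g), grads)
            c_skip = self._concat_split[idx]
            g_s, g = g[:, :c_skip], g[:, c_skip:]
            if norm is not None:
                g_s = norm.backward(g_s)
            g_skips[i] = g_s
            g = up.backward(a_up.backward(g), grads)

        for i in range(cfg.levels - 1, -1, -1):
            if i < cfg.levels - 1:
                g = self._pools[i].backward(g)
                g = g + g_skips[i]
            convs = self.enc[i]
            block_acts = self._acts[i]
            for j in range(len(convs) - 1, -1, -1):
                g = block_acts[j].backward(g)
                gx = convs[j].backward(g, grads)
                if cfg.use_residual_blocks and j == 1:
                    gx = gx + g  # identity shortcut
                g = gx
        self._acts = self._pools = self._dec_acts = None
        return grads


# ---------------------------------------------------------------------------
# model state + optimizer


@dataclass
class RegistrationModel:
    """Network configuration plus learnable state theta, transferable
    between the unsupervised and semi-supervised training phases."""

    config: NetworkConfig
    net: UNet
    training_phase: str = "untrained"

    @property
    def theta(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.net.params().items()}

    def checksum(self) -> str:
        return self.net.checksum()

    def copy(self) -> "RegistrationModel":
        m = build_network(self.config, seed=0)
        m.net.set_params(self.net.params())
        m.training_phase = self.training_phase
        return m


def build_network(config: NetworkConfig, seed: int = 0) -> RegistrationModel:
    """Construct a registration network with seeded Kaiming initialization.

    The same (config, seed) always yields bit-identical initial parameters.
    """
    return RegistrationModel(config=config, net=UNet(config, seed))


def predict_field(model: RegistrationModel, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """One deterministic forward pass -> H x W x 2 displacement field."""
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images differ in shape")
    if tuple(fixed.shape) != tuple(model.config.input_size):
        raise ValueError(
            f"image shape {fixed.shape} != configured input size {model.config.input_size}"
        )
    x = np.stack([fixed, moving])[None]
    out = model.net.forward(x)[0]  # (2, H, W)
    return np.moveaxis(out, 0, -1).astype(float)


class Adam:
    """Adam with the conventional moments (0.9, 0.999) and eps 1e-8."""

    def __init__(self, param_names, beta1=0.9, beta2=0.999, eps=1e-8):
        self.names = list(param_names)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {n: None for n in self.names}
        self.v = {n: None for n in self.names}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for n in self.names:
            g = grads[n]
            if self.m[n] is None:
                self.m[n] = np.zeros_like(g)
                self.v[n] = np.zeros_like(g)
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * g * g
            mhat = self.m[n] / (1 - b1**self.t)
            vhat = self.v[n] / (1 - b2**self.t)
            params[n] -= lr * mhat / (np.sqrt(vhat) + self.eps)
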