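"""The U-Swin restoration network.

Architecture: a 3x3 convolution lifts the single-channel limited-angle FBP
image to a C-channel feature map; a stack of UST blocks extracts deep
features; a long residual skip re-injects the shallow features; a final 3x3
convolution maps back to one channel:

    I_out = Conv1( UST_n(...UST_1(ConvC(I_LA))) + ConvC(I_LA) )

Each UST block runs a U-Net branch and a chain of Swin-transformer layers in
parallel, fuses them with a convolution and adds a residual:

    f_out = Conv( U(f_in) + ST_k(...ST_1(f_in)) ) + f_in

A Swin-transformer layer is the standard pre-norm pair

    X = MSA(LN(X)) + X ;  X = MLP(LN(X)) + X

with multi-head self-attention restricted to non-overlapping MxM windows,
SoftMax(Q K^T / sqrt(d) + B) V per head with a learned relative position
bias B, and a cyclic M/2 shift (with boundary masking) on odd layers so
neighbouring windows communicate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from math import lcm

import numpy as np

from .autodiff import Tensor, concat, conv2d, softmax, take, upsample2x

__all__ = [
    "ModelConfig",
    "PRESETS",
    "USwin",
    "window_partition",
    "window_reverse",
    "count_parameters",
    "normalize_hu",
    "denormalize_hu",
    "save_checkpoint",
    "load_checkpoint",
]

# HU display window mapped affinely onto [0, 1] for network input and loss
HU_NORM_RANGE = (-1000.0, 2000.0)


def normalize_hu(hu: np.ndarray) -> np.ndarray:
    lo, hi = HU_NORM_RANGE
    return np.clip((np.asarray(hu, dtype=np.float64) - lo) / (hi - lo), 0.0, 1.0)


def denormalize_hu(x: np.ndarray) -> np.ndarray:
    lo, hi = HU_NORM_RANGE
    return np.asarray(x, dtype=np.float64) * (hi - lo) + lo


@dataclass(frozen=True)
class ModelConfig:
    """U-Swin hyperparameters; presets mirror the published size variants."""

    hidden_channels: int = 24
    n_ust_modules: int = 1
    st_blocks_per_ust: int = 1
    n_heads: int = 6
    window_size: int = 8
    mlp_ratio: float = 2.0
    use_unet_branch: bool = True
    use_transformer_branch: bool = True
    # the "skip connection" ablation: disables the long residual skip around
    # the UST stack and the U-Net-like encoder-decoder concatenations together
    use_long_skip: bool = True
    unet_depth: int = 2
    predict_residual: bool = False
    zero_init_residual_paths: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.use_unet_branch or self.use_transformer_branch):
            raise ValueError("at least one of the U-Net / transformer branches must be enabled")
        if self.window_size % 2 != 0:
            raise ValueError("window_size must be even (shift is M/2)")
        if self.use_transformer_branch and self.hidden_channels % self.n_heads != 0:
            raise ValueError("hidden_channels must be divisible by n_heads")
        if self.n_ust_modules < 1 or self.st_blocks_per_ust < 0 or self.unet_depth < 1:
            raise ValueError("module/block/depth counts must be positive")


PRESETS: dict[str, ModelConfig] = {
    # block-number column of the size study: (UST modules, ST blocks per UST)
    "uswin1": ModelConfig(hidden_channels=24, n_ust_modules=1, st_blocks_per_ust=1, n_heads=6),
    "light": ModelConfig(hidden_channels=24, n_ust_modules=2, st_blocks_per_ust=1, n_heads=6),
    "small": ModelConfig(hidden_channels=30, n_ust_modules=3, st_blocks_per_ust=3, n_heads=6),
    "large": ModelConfig(hidden_channels=60, n_ust_modules=6, st_blocks_per_ust=6, n_heads=6),
}


# ---------------------------------------------------------------------------
# modules


class Module:
    """Tiny container base: recursive parameter collection."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, zero_init: bool = False):
        w = np.zeros((cin, cout)) if zero_init else _trunc_normal(rng, (cin, cout))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        zero_init: bool = False,
    ):
        fan_in = cin * kernel * kernel
        w = (
            np.zeros((cout, cin, kernel, kernel))
            if zero_init
            else rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel))
        )
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.padding = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Mlp(Module):
    """Two fully connected layers with a GELU between them."""

    def __init__(self, c: int, hidden: int, rng: np.random.Generator, zero_init_out: bool = False):
        self.fc1 = Linear(c, hidden, rng)
        self.fc2 = Linear(hidden, c, rng, zero_init=zero_init_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


# ---------------------------------------------------------------------------
# window bookkeeping


def window_partition(feature: np.ndarray, M: int) -> np.ndarray:
    """Tile an (H, W, C) feature into (HW/M^2) windows of M^2 x C tokens.

    Row-major tiling; indivisible H or W are zero-padded up to the next
    multiple of M first, so token count is conserved for divisible inputs.
    """
    f = np.asarray(feature)
    H, W, C = f.shape
    ph, pw = (-H) % M, (-W) % M
    if ph or pw:
        f = np.pad(f, ((0, ph), (0, pw), (0, 0)))
        H, W = f.shape[:2]
    return (
        f.reshape(H // M, M, W // M, M, C)
        .transpose(0, 2, 1, 3, 4)
        .reshape(-1, M * M, C)
    )


def window_reverse(windows: np.ndarray, M: int, H: int, W: int) -> np.ndarray:
    """Inverse of :func:`window_partition` (crops any padding)."""
    Hp, Wp = H + (-H) % M, W + (-W) % M
    C = windows.shape[-1]
    f = (
        windows.reshape(Hp // M, Wp // M, M, M, C)
        .transpose(0, 2, 1, 3, 4)
        .reshape(Hp, Wp, C)
    )
    return f[:H, :W]


def _relative_position_index(M: int) -> np.ndarray:
    """(M^2, M^2) index into the (2M-1)^2 relative-offset bias table."""
    coords = np.stack(np.meshgrid(np.arange(M), np.arange(M), indexing="ij"))  # 2, M, M
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # 2, M^2, M^2
    rel = rel + (M - 1)
    return rel[0] * (2 * M - 1) + rel[1]


def _shift_attention_mask(Hp: int, Wp: int, M: int) -> np.ndarray:
    """Additive mask (n_windows, M^2, M^2) blocking attention across the
    wrapped boundary after an M/2 cyclic shift."""
    shift = M // 2
    img = np.zeros((Hp, Wp))
    cnt = 0
    for hs in (slice(0, -M), slice(-M, -shift), slice(-shift, None)):
        for ws in (slice(0, -M), slice(-M, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    win = window_partition(img[:, :, None], M)[:, :, 0]  # nw, M^2
    diff = win[:, :, None] - win[:, None, :]
    return np.where(diff == 0, 0.0, -1e9)


class WindowAttention(Module):
    """Multi-head self-attention within an MxM window, with relative position bias."""

    def __init__(self, c: int, n_heads: int, M: int, rng: np.random.Generator, zero_init_out: bool = False):
        self.c, self.n_heads, self.M = c, n_heads, M
        self.head_dim = c // n_heads
        self.q = Linear(c, c, rng)
        self.k = Linear(c, c, rng)
        self.v = Linear(c, c, rng)
        self.proj = Linear(c, c, rng, zero_init=zero_init_out)
        self.bias_table = Tensor(
            _trunc_normal(rng, ((2 * M - 1) ** 2, n_heads)), requires_grad=True
        )
        self._rel_index = _relative_position_index(M)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, T, C = x.shape  # B windows, T = M^2 tokens
        h, d = self.n_heads, self.head_dim

        def heads(t: Tensor) -> Tensor:  # (B, T, C) -> (B, h, T, d)
            return t.reshape(B, T, h, d).transpose(0, 2, 1, 3)

        q, k, v = heads(self.q(x)), heads(self.k(x)), heads(self.v(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))  # B, h, T, T
        bias = take(self.bias_table, self._rel_index)  # T, T, h
        logits = logits + bias.transpose(2, 0, 1).reshape(1, h, T, T)
        if mask is not None:
            logits = logits + mask[:, None, :, :]  # nw, 1, T, T broadcasts over heads
        attn = softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, C)
        return self.proj(out)


class SwinLayer(Module):
    """Pre-norm transformer layer on an (N, C, H, W) feature map.

    Even layers use the regular window partition; odd layers cyclically
    shift the feature by M/2 in both axes before partitioning (and unshift
    after), masking attention across wrapped boundaries.
    """

    def __init__(self, cfg: ModelConfig, shifted: bool, rng: np.random.Generator):
        c, M = cfg.hidden_channels, cfg.window_size
        self.M, self.shifted = M, shifted
        self.norm1 = LayerNorm(c)
        self.attn = WindowAttention(
            c, cfg.n_heads, M, rng, zero_init_out=cfg.zero_init_residual_paths
        )
        self.norm2 = LayerNorm(c)
        self.mlp = Mlp(c, int(cfg.mlp_ratio * c), rng, zero_init_out=cfg.zero_init_residual_paths)
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def _mask(self, H: int, W: int) -> np.ndarray:
        key = (H, W)
        if key not in self._mask_cache:
            self._mask_cache[key] = _shift_attention_mask(H, W, self.M)
        return self._mask_cache[key]

    def __call__(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        M = self.M
        if H % M or W % M:
            raise ValueError("feature map must be padded to a multiple of the window size")
        shift = M // 2 if self.shifted else 0

        t = x.transpose(0, 2, 3, 1)  # N, H, W, C
        y = self.norm1(t)
        if shift:
            y = y.roll((-shift, -shift), axes=(1, 2))
        # in-graph window partition (divisibility guaranteed above)
        y = (
            y.reshape(N, H // M, M, W // M, M, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(N * (H // M) * (W // M), M * M, C)
        )
        mask = None
        if shift:
            mask = np.tile(self._mask(H, W), (N, 1, 1))
        y = self.attn(y, mask=mask)
        y = (
            y.reshape(N, H // M, W // M, M, M, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(N, H, W, C)
        )
        if shift:
            y = y.roll((shift, shift), axes=(1, 2))
        t = t + y
        t = t + self.mlp(self.norm2(t))
        return t.transpose(0, 3, 1, 2)


class UNetBranch(Module):
    """Encoder-decoder branch: stride-2 downsampling, channel doubling,
    skip concatenations, output re-projected to C channels.

    ``use_skips=False`` (the "w/o skip connection" ablation) removes the
    encoder-to-decoder concatenations and with them the fusion convolutions,
    so the variant has strictly fewer parameters.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c, d = cfg.hidden_channels, cfg.unet_depth
        self.depth = d
        self.use_skips = cfg.use_long_skip
        self.enc = [Conv2d(c * 2**i, c * 2 ** (i + 1), rng, stride=2) for i in range(d)]
        self.mid = Conv2d(c * 2**d, c * 2**d, rng)
        self.dec = [
            Conv2d(c * 2 ** (i + 1), c * 2**i, rng) for i in reversed(range(d))
        ]
        self.fuse = (
            [Conv2d(2 * c * 2**i, c * 2**i, rng) for i in reversed(range(d))]
            if self.use_skips
            else []
        )
        self.out = Conv2d(c, c, rng, zero_init=cfg.zero_init_residual_paths)

    def __call__(self, x: Tensor) -> Tensor:
        H, W = x.shape[-2:]
        if H < 2**self.depth or W < 2**self.depth:
            raise ValueError(f"feature map {H}x{W} too small for unet_depth={self.depth}")
        skips = []
        t = x
        for enc in self.enc:
            skips.append(t)
            t = enc(t).relu()
        t = self.mid(t).relu()
        for i, (dec, skip) in enumerate(zip(self.dec, reversed(skips))):
            t = dec(upsample2x(t)).relu()
            if self.use_skips:
                t = self.fuse[i](concat([t, skip], axis=1)).relu()
        return self.out(t)


class USTBlock(Module):
    """Parallel U-Net + Swin-transformer chain, convolution fusion, residual."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.hidden_channels
        self.cfg = cfg
        self.unet = UNetBranch(cfg, rng) if cfg.use_unet_branch else None
        self.st_layers = (
            [SwinLayer(cfg, shifted=(i % 2 == 1), rng=rng) for i in range(cfg.st_blocks_per_ust)]
            if cfg.use_transformer_branch
            else []
        )
        self.fusion = Conv2d(c, c, rng, zero_init=cfg.zero_init_residual_paths)

    def __call__(self, x: Tensor) -> Tensor:
        branch = None
        if self.st_layers:
            t = x
            for layer in self.st_layers:
                t = layer(t)
            branch = t
        if self.unet is not None:
            u = self.unet(x)
            branch = u if branch is None else branch + u
        return self.fusion(branch) + x


class USwin(Module):
    """The full restoration network; input and output are (N, H, W) arrays in [0, 1]."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        c = config.hidden_channels
        self.conv_first = Conv2d(1, c, rng)
        self.ust_blocks = [USTBlock(config, rng) for _ in range(config.n_ust_modules)]
        # with zero-init residual paths and predict_residual the whole
        # network starts as the identity map
        self.conv_last = Conv2d(c, 1, rng, zero_init=config.zero_init_residual_paths)

    @property
    def _pad_multiple(self) -> int:
        m = self.config.window_size if self.config.use_transformer_branch else 1
        u = 2**self.config.unet_depth if self.config.use_unet_branch else 1
        return lcm(m, u)

    def forward(self, x: np.ndarray) -> Tensor:
        """Differentiable forward pass; returns the output as a graph Tensor."""
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        N, H, W = x.shape
        k = self._pad_multiple
        ph, pw = (-H) % k, (-W) % k
        xp = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect") if (ph or pw) else x

        t = Tensor(xp[:, None, :, :])
        f0 = self.conv_first(t)
        f = f0
        for block in self.ust_blocks:
            f = block(f)
        if self.config.use_long_skip:
            f = f + f0
        out = self.conv_last(f)
        if self.config.predict_residual:
            out = out + t
        out = out.reshape(out.shape[0], out.shape[2], out.shape[3])
        out = out[:, :H, :W]
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite network output")
        return out.reshape(H, W) if squeeze else out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).data

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match the model architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)


def count_parameters(config: ModelConfig) -> int:
    """Exact trainable-parameter total of a configuration."""
    return USwin(config).n_parameters()


def save_checkpoint(path, model: USwin) -> None:
    """Weights as NPZ plus a JSON sidecar holding the full configuration."""
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(asdict(model.config), fh, indent=2)


def load_checkpoint(path) -> USwin:
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
    with open(sidecar) as fh:
        config = ModelConfig(**json.load(fh))
    model = USwin(config)
    with np.load(path) as data:
        model.load_state_arrays([data[f"p{i}"] for i in range(len(data.files))])
    return model
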