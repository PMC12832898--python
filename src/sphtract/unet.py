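"""2D encoder-decoder segmentation network over fODF coefficient slices.

Classic U-Net pattern: at each of ``depth`` resolution levels two 3x3 stride-1
convolutions with leaky-ReLU activations; 2x2 max pooling between encoder
levels; the decoder mirrors the encoder with 2x2-stride-2 transposed
convolutions for upsampling and skip connections at equal resolution; dropout
after each encoder block; a 1x1 convolution head with an element-wise sigmoid.
Input channel count is 45 for full-fODF input or 9 for the 3-peak ablation;
output channels are 1 (single-class, one model per tract) or C (multi-label).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from sphtract.nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Layer,
    LeakyReLU,
    MaxPool2d,
    sigmoid,
)


@dataclass(frozen=True)
class UNetSpec:
    """Architecture description; serialized into every checkpoint."""

    in_channels: int = 45
    out_channels: int = 1
    depth: int = 5
    base_filters: int = 64
    leaky_slope: float = 0.01
    dropout: float = 0.4

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")

    @property
    def divisor(self) -> int:
        """Input H and W must be divisible by this (2**(depth-1))."""
        return 2 ** (self.depth - 1)

    def filters(self, level: int) -> int:
        return self.base_filters * 2**level

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "UNetSpec":
        return UNetSpec(**d)


def _layer_plan(spec: UNetSpec) -> list[tuple[str, int, int, int]]:
    """Trainable layers as (kind, c_in, c_out, k) in forward order.

    Shared by :func:`parameter_count` and :class:`UNet2D` so the reported
    count is by construction the count of the built network.
    """
    plan: list[tuple[str, int, int, int]] = []
    c_prev = spec.in_channels
    for lvl in range(spec.depth):
        f = spec.filters(lvl)
        plan.append(("conv", c_prev, f, 3))
        plan.append(("conv", f, f, 3))
        c_prev = f
    for lvl in range(spec.depth - 2, -1, -1):
        f = spec.filters(lvl)
        plan.append(("convT", c_prev, f, 2))
        plan.append(("conv", 2 * f, f, 3))
        plan.append(("conv", f, f, 3))
        c_prev = f
    plan.append(("conv", c_prev, spec.out_channels, 1))
    return plan


def parameter_count(spec: UNetSpec) -> int:
    """Total trainable parameters: sum over layers of k^2*c_in*c_out + c_out."""
    return sum(k * k * ci * co + co for _, ci, co, k in _layer_plan(spec))


class UNet2D:
    """Callable network: (B, H, W, in_channels) -> (B, H, W, out_channels).

    Outputs are sigmoid probabilities in (0, 1).  Evaluation mode (the
    default call) disables dropout and is deterministic; the training loop
    drives :meth:`forward_logits` / :meth:`backward` directly.
    """

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        d = spec.depth
        self.enc_blocks: list[list[Layer]] = []
        self.pools: list[MaxPool2d] = []
        c_prev = spec.in_channels
        for lvl in range(d):
            f = spec.filters(lvl)
            block: list[Layer] = [
                Conv2d(c_prev, f, 3, self.rng),
                LeakyReLU(spec.leaky_slope),
                Conv2d(f, f, 3, self.rng),
                LeakyReLU(spec.leaky_slope),
                Dropout(spec.dropout, self.rng),
            ]
            self.enc_blocks.append(block)
            if lvl < d - 1:
                self.pools.append(MaxPool2d())
            c_prev = f
        self.up_convs: list[ConvTranspose2d] = []
        self.dec_blocks: list[list[Layer]] = []
        for lvl in range(d - 2, -1, -1):
            f = spec.filters(lvl)
            self.up_convs.append(ConvTranspose2d(c_prev, f, self.rng))
            self.dec_blocks.append([
                Conv2d(2 * f, f, 3, self.rng),
                LeakyReLU(spec.leaky_slope),
                Conv2d(f, f, 3, self.rng),
                LeakyReLU(spec.leaky_slope),
            ])
            c_prev = f
        self.head = Conv2d(c_prev, spec.out_channels, 1, self.rng)

    # ------------------------------------------------------------------ #
    def _all_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        for b in self.enc_blocks:
            layers.extend(b)
        layers.extend(self.pools)
        layers.extend(self.up_convs)
        for b in self.dec_blocks:
            layers.extend(b)
        layers.append(self.head)
        return layers

    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(v.size for _, v, _ in self.params())

    # ------------------------------------------------------------------ #
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, H, W, Cin) -> logits (B, H, W, Cout); caches for backward."""
        if x.ndim != 4 or x.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"expected (B, H, W, {self.spec.in_channels}) input, got {x.shape}"
            )
        H, W = x.shape[1], x.shape[2]
        div = self.spec.divisor
        if H % div or W % div:
            raise ValueError(
                f"spatial dims ({H}, {W}) must be divisible by {div} "
                f"for depth {self.spec.depth}"
            )
        h = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32)
        skips = []
        for lvl, block in enumerate(self.enc_blocks):
            for layer in block:
                h = layer.forward(h, training)
            if lvl < self.spec.depth - 1:
                skips.append(h)
                h = self.pools[lvl].forward(h, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, (up, block) in enumerate(zip(self.up_convs, self.dec_blocks)):
            h = up.forward(h, training)
            h = np.concatenate([skips[-1 - i], h], axis=1)
            for layer in block:
                h = layer.forward(h, training)
        h = self.head.forward(h, training)
        return h.transpose(0, 2, 3, 1)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities in (0, 1)."""
        return sigmoid(self.forward_logits(x, training=False))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate gradient w.r.t. logits; accumulates into dW/db."""
        d = np.ascontiguousarray(dlogits.transpose(0, 3, 1, 2), dtype=np.float32)
        d = self.head.backward(d)
        dskips: list[np.ndarray | None] = [None] * len(self._skip_channels)
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            for layer in reversed(self.dec_blocks[i]):
                d = layer.backward(d)
            c_skip = self._skip_channels[-1 - i]
            dskips[-1 - i] = d[:, :c_skip]
            d = self.up_convs[i].backward(d[:, c_skip:])
        for lvl in range(self.spec.depth - 1, -1, -1):
            if lvl < self.spec.depth - 1:
                d = self.pools[lvl].backward(d)
                d = d + dskips[lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                d = layer.backward(d)

    # ------------------------------------------------------------------ #
    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params(), lr=lr)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": v for i, (_, v, _) in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (_, v, _) in enumerate(self.params()):
            v[...] = arrays[f"p{i}"]


def build_network(spec: UNetSpec, seed: int = 0) -> UNet2D:
    """Instantiate the network described by ``spec`` with seeded weights."""
    return UNet2D(spec, seed=seed)


# --------------------------------------------------------------------------- #
# checkpoints: architecture + weights travel together
# --------------------------------------------------------------------------- #

def save_checkpoint(path: str | Path, model: UNet2D, extra: dict | None = None) -> None:
    path = Path(path)
    meta = {"spec": model.spec.to_dict(), "extra": extra or {}}
    np.savez_compressed(path, __meta__=json.dumps(meta), **model.state_arrays())


def load_checkpoint(path: str | Path) -> tuple[UNet2D, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        model = UNet2D(UNetSpec.from_dict(meta["spec"]))
        model.load_state_arrays({k: z[k] for k in z.files if k != "__meta__"})
    return model, meta["extra"]
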