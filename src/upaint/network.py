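"""U-Net model for sparse-to-dense localization image restoration.

The network maps a sparse localization tile — optionally concatenated with a
widefield tile as a second input channel — to the dense localization tile.
The default architecture follows the widely used image-restoration U-Net:
an input double-convolution block, four downsampling stages (2x2 max pool +
double convolution, channel count doubling per stage), four upsampling
stages (2x2 transposed convolution + skip concatenation + double
convolution), and a 1x1 output convolution.  At the defaults (base 64,
depth 4) this comes to slightly more than 31 million trainable parameters.

Everything here runs on the NumPy engine in :mod:`upaint.nn`; no GPU or
deep-learning framework is required.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, ContractError, FormatError
from .nn import SGD, Adam, Conv2d, ConvTranspose2d, MaxPool2, Param, ReLU, mse_loss

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "UNet",
    "build_network",
    "count_parameters",
    "train",
    "predict",
    "stitch_tiles",
    "save_checkpoint",
    "load_checkpoint",
    "VARIANT_CHANNELS",
]

#: The published co-training schedule: 2,000 epochs on real triplets,
#: 2,000 more on simulated triplets, then a 500-epoch real-data fine-tune.
PUBLISHED_TRAINING_SCHEDULE = (2000, 2000, 500)

#: Input assembly per training variant: which triplet channels feed the net.
VARIANT_CHANNELS = {
    "3000": ("sparse",),
    "WF": ("widefield",),
    "WF+3000": ("widefield", "sparse"),
}


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyperparameters.

    ``depth`` counts downsampling stages; together with the input and output
    blocks the default spec has 4 down + 4 up + input + output = 10 stages.
    """

    in_channels: int = 1
    out_channels: int = 1
    depth: int = 4
    base_channels: int = 64
    tile_size: int = 256

    def __post_init__(self):
        if self.in_channels not in (1, 2):
            raise ConfigurationError("in_channels must be 1 or 2")
        if self.depth < 1 or self.base_channels < 1:
            raise ConfigurationError("depth and base_channels must be positive")
        if self.tile_size % (1 << self.depth) != 0:
            raise ContractError(
                f"tile_size {self.tile_size} is not divisible by 2^depth = {1 << self.depth}"
            )


@dataclass
class TrainConfig:
    """Optimization settings.

    The published protocol trains each model for 2,000 epochs on real
    triplets, then 2,000 more on simulated triplets and a final 500-epoch
    fine-tune on real data; those stage lengths are callers' choices — this
    config describes a single training stage.
    """

    epochs: int = 2000
    batch_size: int = 4
    learning_rate: float = 1e-4
    loss_name: str = "mse"
    optimizer: str = "adam"
    seed: int = 0
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be positive")
        if self.loss_name != "mse":
            raise ConfigurationError(f"unknown loss {self.loss_name!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


class _DoubleConv:
    """Two 3x3 same-padded convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.relu2 = ReLU()

    @property
    def params(self) -> list[Param]:
        return self.conv1.params + self.conv2.params

    def forward(self, x):
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, dy):
        return self.conv1.backward(self.relu1.backward(self.conv2.backward(self.relu2.backward(dy))))


class UNet:
    """Encoder-decoder with skip connections between matching resolutions."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        b = spec.base_channels
        self.inc = _DoubleConv(spec.in_channels, b, rng)
        self.inc.conv1.compute_dx = False  # no layer below consumes this gradient
        self.pools = [MaxPool2() for _ in range(spec.depth)]
        self.downs = [
            _DoubleConv(b << i, b << (i + 1), rng) for i in range(spec.depth)
        ]
        self.ups = []
        self.updcs = []
        for i in reversed(range(spec.depth)):
            cin = b << (i + 1)
            self.ups.append(ConvTranspose2d(cin, cin // 2, rng=rng))
            self.updcs.append(_DoubleConv(cin, cin // 2, rng))
        self.outc = Conv2d(b, spec.out_channels, 1, padding=0, rng=rng)

    @property
    def params(self) -> list[Param]:
        out = list(self.inc.params)
        for d in self.downs:
            out += d.params
        for u, dc in zip(self.ups, self.updcs):
            out += u.params + dc.params
        out += self.outc.params
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a (B, in_channels, H, W) batch to (B, out_channels, H, W).

        Internally the engine runs channel-major (C, B, H, W); the transpose
        happens once at each end of the pass.
        """
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ContractError(
                f"expected input of shape (B, {self.spec.in_channels}, H, W), got {x.shape}"
            )
        h, w = x.shape[2], x.shape[3]
        div = 1 << self.spec.depth
        if h % div or w % div:
            raise ContractError(f"spatial size {h}x{w} not divisible by 2^depth = {div}")
        x = np.ascontiguousarray(x.transpose(1, 0, 2, 3), dtype=np.float32)
        skips = [self.inc.forward(x)]
        for pool, down in zip(self.pools, self.downs):
            skips.append(down.forward(pool.forward(skips[-1])))
        y = skips.pop()
        for u, dc in zip(self.ups, self.updcs):
            up = u.forward(y)
            skip = skips.pop()
            y = dc.forward(np.concatenate([skip, up], axis=0))
        return self.outc.forward(y).transpose(1, 0, 2, 3)

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for a loss gradient ``dy``
        of shape (B, out_channels, H, W)."""
        # Decoder stages are undone in reverse; each contributes a gradient to
        # the encoder activation it concatenated.  dskips ends up ordered
        # [ds_0, ..., ds_{depth-1}] where ds_i is the skip grad at level i.
        dy = np.ascontiguousarray(dy.transpose(1, 0, 2, 3), dtype=np.float32)
        dy = self.outc.backward(dy)
        dskips = []
        for u, dc in zip(reversed(self.ups), reversed(self.updcs)):
            dcat = dc.backward(dy)
            nskip = dcat.shape[0] // 2
            dskips.append(dcat[:nskip])
            dy = u.backward(dcat[nskip:])
        for pool, down in zip(reversed(self.pools), reversed(self.downs)):
            dy = pool.backward(down.backward(dy)) + dskips.pop()
        self.inc.backward(dy)


def build_network(spec: UNetSpec, seed: int = 0) -> UNet:
    """Instantiate a U-Net from ``spec`` with seeded weight initialization."""
    return UNet(spec, seed=seed)


def count_parameters(model: UNet, trainable_only: bool = True) -> int:
    """Number of trainable scalar parameters in ``model``."""
    if trainable_only and getattr(model, "frozen", False):
        return 0
    return sum(p.size for p in model.params)


def _assemble_inputs(triplets, variant: str) -> tuple[np.ndarray, np.ndarray]:
    if variant not in VARIANT_CHANNELS:
        raise ContractError(f"unknown variant {variant!r}; one of {sorted(VARIANT_CHANNELS)}")
    chans = VARIANT_CHANNELS[variant]
    xs, ys = [], []
    for t in triplets:
        layers = []
        for name in chans:
            arr = getattr(t, name, None)
            if arr is None:
                raise ContractError(f"triplet lacks channel {name!r} required by variant {variant!r}")
            layers.append(np.asarray(arr, dtype=np.float32))
        xs.append(np.stack(layers))
        ys.append(np.asarray(t.dense, dtype=np.float32)[None])
    return np.stack(xs), np.stack(ys)


def train(model: UNet, train_triplets, config: TrainConfig,
          variant: str = "3000") -> tuple[UNet, list[float]]:
    """Fit ``model`` on training triplets; returns the model and per-epoch loss.

    The input channels are assembled per ``variant`` ("3000" = sparse only,
    "WF" = widefield only, "WF+3000" = widefield + sparse); the target is
    always the dense channel.  Deterministic for a fixed seed and thread
    configuration (best effort: BLAS reduction order is the only caveat).
    """
    x, y = _assemble_inputs(train_triplets, variant)
    if x.shape[1] != model.spec.in_channels:
        raise ContractError(
            f"variant {variant!r} supplies {x.shape[1]} channels but the model "
            f"expects {model.spec.in_channels}"
        )
    rng = np.random.default_rng(config.seed)
    params = model.params
    opt = (Adam if config.optimizer == "adam" else SGD)(params, lr=config.learning_rate)
    n = x.shape[0]
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            pred = model.forward(x[idx])
            loss, dldp = mse_loss(pred, y[idx])
            model.backward(dldp)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / seen)
        if (config.checkpoint_every and config.checkpoint_dir
                and (epoch + 1) % config.checkpoint_every == 0):
            path = os.path.join(config.checkpoint_dir, f"epoch{epoch + 1:05d}.npz")
            save_checkpoint(model, path, train_config=config)
    return model, history


def predict(model: UNet, sparse_tile: np.ndarray | None = None,
            widefield_tile: np.ndarray | None = None) -> np.ndarray:
    """Reconstruct a dense tile from model inputs; output clamped to [0, 1].

    Channel order for two-channel models is (widefield, sparse), matching
    the "WF+3000" training assembly.
    """
    layers = [t for t in (widefield_tile, sparse_tile) if t is not None]
    if len(layers) != model.spec.in_channels:
        raise ContractError(
            f"model expects {model.spec.in_channels} input channel(s), got {len(layers)}"
        )
    x = np.stack([np.asarray(t, dtype=np.float32) for t in layers])[None]
    y = model.forward(x)[0, 0]
    return np.clip(y, 0.0, 1.0)


def stitch_tiles(tiles) -> np.ndarray:
    """Reassemble ``(grid_index, tile)`` pairs into the full-field image.

    Inverse of grid tiling on the covered region; raises listing any missing
    grid cells if the pairs do not cover a complete rectangle.
    """
    tiles = list(tiles)
    if not tiles:
        raise ContractError("no tiles to stitch")
    index = {tuple(gi): np.asarray(t) for gi, t in tiles}
    rows = max(r for r, _ in index) + 1
    cols = max(c for _, c in index) + 1
    missing = [(r, c) for r in range(rows) for c in range(cols) if (r, c) not in index]
    if missing:
        raise ContractError(f"missing grid cells: {missing}")
    th, tw = next(iter(index.values())).shape
    out = np.empty((rows * th, cols * tw), dtype=next(iter(index.values())).dtype)
    for (r, c), t in index.items():
        if t.shape != (th, tw):
            raise ContractError("tiles have inconsistent shapes")
        out[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = t
    return out


def save_checkpoint(model: UNet, path: str, train_config: TrainConfig | None = None) -> None:
    """Serialize weights plus the JSON-encoded spec/config into one .npz file."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    meta = {"spec": asdict(model.spec)}
    if train_config is not None:
        meta["train_config"] = asdict(train_config)
    arrays = {f"param_{i:03d}": p.value for i, p in enumerate(model.params)}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str) -> UNet:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        model = UNet(UNetSpec(**meta["spec"]))
        for i, p in enumerate(model.params):
            value = data[f"param_{i:03d}"]
            if value.shape != p.value.shape:
                raise FormatError(f"checkpoint parameter {i} has shape {value.shape}, "
                                  f"expected {p.value.shape}")
            p.value[...] = value
    return model
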