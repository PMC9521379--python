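"""Configurable 2D U-Net and its Bayesian (MC-dropout) variant.

The network is a standard encoder–decoder with skip connections: two 3×3
convolutions + ReLU per resolution level, channel count doubling with
depth, 2×2 max pooling down and 2×2 transposed convolution up, and a 1×1
convolution head producing per-pixel class scores.  The Bayesian variant
inserts one dropout layer immediately before each max pooling and one
immediately after each up-convolution; keeping those dropout layers active
at inference yields Monte-Carlo samples from the approximate weight
posterior.

Weights are initialized from a zero-mean Gaussian with He scaling
(sqrt(2/fan_in)), seeded, so model construction is reproducible.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from ._nn import Adam, Conv2d, Dropout, MaxPool2, Param, ReLU, UpConv2, softmax

DropoutMode = Literal["off", "train_only", "train_and_inference"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters.

    ``dropout_rate`` is the Bernoulli drop probability θ; ``dropout_mode``
    controls when the dropout layers are active.  With θ = 0 (or mode
    "off") the network contains no dropout layers at all and is the plain
    deterministic U-Net.
    """

    in_channels: int = 2
    n_classes: int = 2
    depth: int = 3
    base_filters: int = 8
    dropout_rate: float = 0.5
    dropout_mode: DropoutMode = "train_and_inference"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.in_channels < 1:
            raise ValueError(f"in_channels must be >= 1, got {self.in_channels}")

    @property
    def has_dropout(self) -> bool:
        return self.dropout_rate > 0.0 and self.dropout_mode != "off"

    @property
    def divisor(self) -> int:
        """Required spatial divisibility of inputs: 2**(depth-1)."""
        return 2 ** (self.depth - 1)


def parameter_count(config: UNetConfig) -> int:
    """Closed-form number of learnable scalars for a given config.

    Per 3×3 conv c_in→c_out: c_out*(9*c_in + 1); per 2×2 up-conv:
    c_out*(4*c_in + 1); head 1×1 conv: n_classes*(base_filters + 1).
    """
    f = [config.base_filters * 2 ** i for i in range(config.depth)]

    def conv3(ci: int, co: int) -> int:
        return co * (9 * ci + 1)

    total = 0
    c_in = config.in_channels
    for i in range(config.depth):
        total += conv3(c_in, f[i]) + conv3(f[i], f[i])
        c_in = f[i]
    for i in range(config.depth - 2, -1, -1):
        total += f[i] * (4 * f[i + 1] + 1)           # up-conv
        total += conv3(2 * f[i], f[i]) + conv3(f[i], f[i])
    total += config.n_classes * (f[0] + 1)           # 1×1 head
    return total


class UNet:
    """The network graph with explicit forward/backward passes."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, f0 = config.depth, config.base_filters
        ch = [f0 * 2 ** i for i in range(d)]
        use_do = config.has_dropout

        self.enc_blocks: list[list] = []
        c_in = config.in_channels
        for i in range(d):
            self.enc_blocks.append(
                [Conv2d(rng, c_in, ch[i]), ReLU(), Conv2d(rng, ch[i], ch[i]), ReLU()]
            )
            c_in = ch[i]
        self.enc_dropouts = [Dropout(config.dropout_rate) if use_do else None for _ in range(d - 1)]
        self.pools = [MaxPool2() for _ in range(d - 1)]

        self.upconvs: list[UpConv2] = []
        self.dec_dropouts: list[Dropout | None] = []
        self.dec_blocks: list[list] = []
        for i in range(d - 2, -1, -1):
            self.upconvs.append(UpConv2(rng, ch[i + 1], ch[i]))
            self.dec_dropouts.append(Dropout(config.dropout_rate) if use_do else None)
            self.dec_blocks.append(
                [Conv2d(rng, 2 * ch[i], ch[i]), ReLU(), Conv2d(rng, ch[i], ch[i]), ReLU()]
            )
        self.head = Conv2d(rng, ch[0], config.n_classes, k=1)

    # -- introspection -------------------------------------------------
    def parameters(self) -> list[Param]:
        ps: list[Param] = []
        for blk in self.enc_blocks + self.dec_blocks:
            for layer in blk:
                ps.extend(layer.params())
        for up in self.upconvs:
            ps.extend(up.params())
        ps.extend(self.head.params())
        return ps

    def dropout_positions(self) -> list[tuple[str, int, str]]:
        """Where dropout layers sit, for auditing the architecture."""
        pos = []
        for i, dol in enumerate(self.enc_dropouts):
            if dol is not None:
                pos.append(("encoder", i, "before_pool"))
        d = self.config.depth
        for j, dol in enumerate(self.dec_dropouts):
            if dol is not None:
                pos.append(("decoder", d - 2 - j, "after_upconv"))
        return pos

    # -- forward / backward --------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, model expects {self.config.in_channels}"
            )
        dv = self.config.divisor
        if x.shape[2] % dv or x.shape[3] % dv:
            raise ValueError(
                f"spatial shape {x.shape[2]}x{x.shape[3]} must be divisible by "
                f"2**(depth-1) = {dv}"
            )

    def forward(self, x: np.ndarray, dropout_active: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return per-pixel class logits (N, n_classes, H, W)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._check_input(x)
        # channel-major internally: (C, N, H, W)
        h = np.ascontiguousarray(x.transpose(1, 0, 2, 3))
        skips = []
        for i in range(self.config.depth - 1):
            for layer in self.enc_blocks[i]:
                h = layer.forward(h)
            skips.append(h)
            if self.enc_dropouts[i] is not None:
                h = self.enc_dropouts[i].forward(h, dropout_active, rng)
            h = self.pools[i].forward(h)
        for layer in self.enc_blocks[-1]:
            h = layer.forward(h)
        self._skip_channels = []
        for j in range(len(self.upconvs)):
            h = self.upconvs[j].forward(h)
            if self.dec_dropouts[j] is not None:
                h = self.dec_dropouts[j].forward(h, dropout_active, rng)
            skip = skips.pop()
            self._skip_channels.append(skip.shape[0])
            h = np.concatenate([skip, h], axis=0)
            for layer in self.dec_blocks[j]:
                h = layer.forward(h)
        logits = self.head.forward(h)
        return np.ascontiguousarray(logits.transpose(1, 0, 2, 3))

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given dL/dlogits (N, classes, H, W)."""
        dl = np.ascontiguousarray(
            np.asarray(dlogits, dtype=np.float32).transpose(1, 0, 2, 3)
        )
        dh = self.head.backward(dl)
        # decoder step j consumed the skip from encoder level d-2-j
        dskip_by_level: dict[int, np.ndarray] = {}
        for j in range(len(self.upconvs) - 1, -1, -1):
            for layer in reversed(self.dec_blocks[j]):
                dh = layer.backward(dh)
            nskip = self._skip_channels[j]
            dskip_by_level[self.config.depth - 2 - j] = dh[:nskip]
            dh = dh[nskip:]
            if self.dec_dropouts[j] is not None:
                dh = self.dec_dropouts[j].backward(dh)
            dh = self.upconvs[j].backward(dh)
        for layer in reversed(self.enc_blocks[-1]):
            dh = layer.backward(dh)
        for i in range(self.config.depth - 2, -1, -1):
            dh = self.pools[i].backward(dh)
            if self.enc_dropouts[i] is not None:
                dh = self.enc_dropouts[i].backward(dh)
            # the skip tensor was the same activation fed to dropout+pool
            dh = dh + dskip_by_level[i]
            for layer in reversed(self.enc_blocks[i]):
                dh = layer.backward(dh)


@dataclass
class TrainedModel:
    """A network plus the provenance of how it was (or is to be) trained."""

    net: UNet
    config: UNetConfig
    fingerprint: dict = field(default_factory=dict)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.net.parameters()]


def build_model(config: UNetConfig, seed: int = 0) -> TrainedModel:
    """Construct an untrained model (Gaussian-initialized, seeded)."""
    return TrainedModel(net=UNet(config, seed=seed), config=config,
                        fingerprint={"lambda": None, "seed": seed, "epochs": 0})


def predict_probabilities(model: TrainedModel, image: np.ndarray,
                          stochastic: bool = False, seed: int = 0) -> np.ndarray:
    """Per-pixel softmax probabilities for one image or a batch.

    With ``stochastic=False`` every dropout layer is disabled and the
    output is deterministic.  With ``stochastic=True`` dropout stays
    active (one Monte-Carlo draw), reproducible for a fixed seed; this
    requires ``dropout_mode == 'train_and_inference'`` and θ > 0 to have
    any effect.
    """
    single = image.ndim == 3
    x = image[None] if single else image
    if x.shape[1] != model.config.in_channels:
        raise ValueError(
            f"image has {x.shape[1]} channels, model expects {model.config.in_channels}"
        )
    active = (stochastic and model.config.dropout_rate > 0.0
              and model.config.dropout_mode == "train_and_inference")
    rng = np.random.default_rng(seed) if active else None
    logits = model.net.forward(x, dropout_active=active, rng=rng)
    probs = softmax(logits, axis=1).astype(np.float64)
    return probs[0] if single else probs


# -- serialization -----------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Write weights + config + fingerprint to a single .npz checkpoint."""
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(model.net.parameters())}
    meta = json.dumps({"config": asdict(model.config), "fingerprint": model.fingerprint})
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        config = UNetConfig(**meta["config"])
        model = build_model(config, seed=meta["fingerprint"].get("seed") or 0)
        model.fingerprint = meta["fingerprint"]
        keys = sorted(k for k in data.files if k.startswith("p"))
        params = model.net.parameters()
        if len(keys) != len(params):
            raise ValueError(f"checkpoint has {len(keys)} arrays, model needs {len(params)}")
        for k, p in zip(keys, params):
            if data[k].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {k}: {data[k].shape} vs {p.value.shape}")
            p.value[...] = data[k]
    return model


def make_optimizer(model: TrainedModel, lr: float = 1e-4,
                   weight_decay: float = 1e-5) -> Adam:
    return Adam(model.net.parameters(), lr=lr, weight_decay=weight_decay)
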