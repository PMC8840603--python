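"""The multi-feature-fusion reconstruction network.

Three parallel feature extractors downsample the dual-channel input by 2×,
each built around one signature mechanism of a classic deep architecture:

* **residual** — stacked convolutions with identity skip connections;
* **attention** — channel-attention weighting (global pooling → bottleneck
  → sigmoid gate);
* **dense** — dense connectivity (each convolution's output concatenated
  with everything before it).

Their feature maps are merged by *cascade feature fusion* — plain channel
concatenation, so the fused channel count is the sum of the branch channel
counts and every branch value appears exactly once — and a pre-upsampling
head (convolution + pixel recombination, each stage doubling the spatial
size) restores full resolution and emits the two output channels.

When an optional deep-learning framework is installed, the named pretrained
backbones (resnet50 / xception / densenet121) can stand in for the toy
branches; without it, requesting them raises ``CapabilityError``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from ..errors import CapabilityError, InputError, TrainingDivergedError
from ..synthesis import DualChannelInput
from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "FusionSpec",
    "TrainConfig",
    "fuse_features",
    "upsample_stage",
    "assemble_model",
    "DMFTN",
    "train",
    "predict",
]


@dataclass(frozen=True)
class FusionSpec:
    """Shape contract of the fusion point: three branch maps of equal
    spatial size whose channel counts sum to the fused count."""

    h: int
    w: int
    d_a: int
    d_b: int
    d_c: int

    @property
    def d_out(self) -> int:
        return self.d_a + self.d_b + self.d_c


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters: Adam at learning rate 4e-5 with MSE loss
    and batch size 4 by default."""

    learning_rate: float = 4e-5
    batch_size: int = 4
    epochs: int = 10
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise InputError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise InputError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.loss != "mse":
            raise InputError(f"only the 'mse' loss is supported, got {self.loss!r}")


def _channel_axis(arrs):
    ndims = {a.ndim for a in arrs}
    if ndims == {3}:
        return 0
    if ndims == {4}:
        return 1
    raise InputError("feature maps must all be (C, H, W) or all (N, C, H, W)")


def fuse_features(x_a: np.ndarray, x_b: np.ndarray, x_c: np.ndarray) -> np.ndarray:
    """Cascade feature fusion: channel concatenation [x_a ‖ x_b ‖ x_c].

    Output channels = d_a + d_b + d_c; every input value appears exactly
    once.  Accepts (C, H, W) or (N, C, H, W) maps; a zero-channel branch is
    allowed and contributes nothing.
    """
    arrs = [np.asarray(x) for x in (x_a, x_b, x_c)]
    axis = _channel_axis(arrs)
    spatial = {a.shape[axis + 1 :] for a in arrs}
    if len(spatial) != 1:
        raise InputError(f"branch spatial sizes differ: {sorted(spatial)}")
    return np.concatenate(arrs, axis=axis)


def upsample_stage(features: np.ndarray, conv=None) -> np.ndarray:
    """One pre-upsampling stage: (optional) convolution, then pixel
    recombination that turns each 4-channel group into a 2×2 spatial block.

    The output is exactly 2× the input height and width with C/4 channels;
    the recombination itself conserves the element count.  ``conv`` may be
    a callable applied before the shuffle (identity if omitted); the
    channel count entering the shuffle must be divisible by 4.
    """
    x = np.asarray(features, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.ndim != 4:
        raise InputError(f"expected a (C, H, W) or (N, C, H, W) map, got shape {features.shape}")
    if conv is not None:
        x = np.asarray(conv(x), dtype=float)
    if x.shape[1] % 4 != 0:
        raise InputError(
            f"channel count {x.shape[1]} entering pixel recombination is not divisible by 4"
        )
    out = ad.pixel_shuffle(Tensor(x), r=2).data
    return out[0] if squeeze else out


class _Conv:
    """Convolution layer with He-initialised weights."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1, pad=None):
        pad = (k // 2) if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    @property
    def params(self):
        return [self.w, self.b]


class _ResidualBranch:
    """Stem (stride-2) + one residual block."""

    def __init__(self, rng, c_in, width):
        self.stem = _Conv(rng, c_in, width, stride=2)
        self.c1 = _Conv(rng, width, width)
        self.c2 = _Conv(rng, width, width)

    def __call__(self, x):
        h = ad.relu(self.stem(x))
        r = self.c2(ad.relu(self.c1(h)))
        return ad.relu(ad.add(h, r))

    @property
    def params(self):
        return self.stem.params + self.c1.params + self.c2.params


class _AttentionBranch:
    """Stem (stride-2) + convolution gated by channel attention."""

    def __init__(self, rng, c_in, width):
        self.stem = _Conv(rng, c_in, width, stride=2)
        self.body = _Conv(rng, width, width)
        self.gate = _Conv(rng, width, width, k=1, pad=0)

    def __call__(self, x):
        h = ad.relu(self.stem(x))
        f = self.body(h)
        att = ad.sigmoid(self.gate(ad.global_avg_pool(f)))
        return ad.relu(ad.mul(f, att))

    @property
    def params(self):
        return self.stem.params + self.body.params + self.gate.params


class _DenseBranch:
    """Stem (stride-2) + two densely connected growth convolutions."""

    def __init__(self, rng, c_in, width):
        assert width % 2 == 0, "dense branch width must be even"
        g = width // 4
        self.stem = _Conv(rng, c_in, width - 2 * g, stride=2)
        self.g1 = _Conv(rng, width - 2 * g, g)
        self.g2 = _Conv(rng, width - g, g)

    def __call__(self, x):
        h = ad.relu(self.stem(x))
        h = ad.concat([h, ad.relu(self.g1(h))], axis=1)
        h = ad.concat([h, ad.relu(self.g2(h))], axis=1)
        return h

    @property
    def params(self):
        return self.stem.params + self.g1.params + self.g2.params


class DMFTN:
    """Toy-scale multi-feature fusion network: 2-channel S×S in, 2-channel
    S×S out, for any even S.  Branches downsample by 2; the head's single
    pixel-recombination stage restores full resolution."""

    downsample = 2

    def __init__(self, width: int = 12, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.width = width
        self.res = _ResidualBranch(rng, 2, width)
        self.att = _AttentionBranch(rng, 2, width)
        self.dense = _DenseBranch(rng, 2, width)
        self.head1 = _Conv(rng, 3 * width, 32)
        self.head2 = _Conv(rng, 32, 8)  # 8 = 2 output channels x 2^2
        self.final = _Conv(rng, 2, 2)

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.data.ndim != 4 or x.data.shape[1] != 2:
            raise InputError(f"expected (N, 2, S, S) input, got shape {x.data.shape}")
        if x.data.shape[2] % self.downsample != 0:
            raise InputError(f"spatial size {x.data.shape[2]} must be even")
        a = self.res(x)
        b = self.att(x)
        c = self.dense(x)
        fused = ad.concat([a, b, c], axis=1)
        h = ad.relu(self.head1(fused))
        h = ad.pixel_shuffle(self.head2(h), r=2)
        # global residual skip: the head learns the correction to the
        # synthesized input, the standard choice in super-resolution nets
        return ad.add(self.final(h), x)

    __call__ = forward

    def parameters(self):
        return (
            self.res.params + self.att.params + self.dense.params
            + self.head1.params + self.head2.params + self.final.params
        )

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state):
        for p, s in zip(self.parameters(), state):
            p.data[...] = s


def assemble_model(branch_kind: str = "standin", *, width: int = 12, seed: int = 0) -> DMFTN:
    """Build the reconstruction network.

    ``branch_kind="standin"`` gives the self-contained toy-depth model.
    The named pretrained backbones require an optional deep-learning
    framework and raise ``CapabilityError`` when it is absent.
    """
    kinds = ("standin", "resnet50", "xception", "densenet121")
    if branch_kind not in kinds:
        raise InputError(f"branch_kind must be one of {kinds}, got {branch_kind!r}")
    if branch_kind != "standin":
        try:
            import torch  # noqa: F401
        except ImportError:
            raise CapabilityError(
                f"branch_kind={branch_kind!r} needs the optional 'torch' dependency, "
                "which is not installed; use branch_kind='standin'"
            ) from None
        raise CapabilityError(
            f"pretrained backbone {branch_kind!r} loading is not bundled; "
            "use branch_kind='standin'"
        )
    return DMFTN(width=width, seed=seed)


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start : start + batch_size]


def train(model: DMFTN, dataset, cfg: TrainConfig, val_data=None):
    """Minimise the MSE between predicted and true dual-channel images.

    ``dataset`` is a dict with ``input`` and ``truth`` arrays [N, 2, S, S]
    (``val_data`` likewise, optional).  Returns ``(model, history)`` where
    history maps ``"train"`` (and ``"val"``) to per-epoch losses.  A
    non-finite loss raises ``TrainingDivergedError`` carrying the last
    finite-loss parameters.
    """
    x = np.asarray(dataset["input"], dtype=float)
    y = np.asarray(dataset["truth"], dtype=float)
    if x.shape[0] == 0:
        raise InputError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"train": []}
    if val_data is not None:
        history["val"] = []
    checkpoint = model.state()
    for _ in range(cfg.epochs):
        losses = []
        for batch in _batches(x.shape[0], cfg.batch_size, rng):
            opt.zero_grad()
            loss = ad.mse_loss(model.forward(x[batch]), y[batch])
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    "training loss became non-finite", checkpoint=checkpoint, history=history
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train"].append(float(np.mean(losses)))
        checkpoint = model.state()
        if val_data is not None:
            vx = np.asarray(val_data["input"], dtype=float)
            vy = np.asarray(val_data["truth"], dtype=float)
            history["val"].append(float(ad.mse_loss(model.forward(vx), vy).data))
    return model, history


def predict(model: DMFTN, inp: DualChannelInput) -> DualChannelInput:
    """Evaluate the network on one dual-channel image (deterministic)."""
    x = inp.stacked()[None]
    out = model.forward(x).data[0]
    return DualChannelInput(intensity=out[0], phase=out[1])
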