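"""A compact 3D U-Net for vessel and tumor-region segmentation.

Encoder–decoder with skip connections: each level applies two 3³
convolutions with ReLU; levels are joined by 2× max-pooling on the way
down and nearest-neighbor upsampling followed by a 3³ convolution on the
way up. Channel width starts at ``base_channels`` and doubles at every
down-sampling step. Input and output are single-channel; the output
passes through a sigmoid, yielding a voxel-wise probability map.

The default configuration (8 base channels, 5 levels) counts
≈1.62 million trainable parameters. ``layer_list()`` emits every weight
tensor with its shape so the count is auditable layer by layer.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(scale=np.sqrt(2.0 / fan_in), size=shape)


class _Conv3:
    """3³ convolution + per-channel instance normalization (affine)."""

    def __init__(self, rng, cin: int, cout: int, norm: bool = True):
        self.w = Parameter(_he_init(rng, (cout, cin, 3, 3, 3), fan_in=27 * cin))
        self.b = Parameter(np.zeros(cout))
        self.norm = norm
        if norm:
            self.gamma = Parameter(np.ones(cout))
            self.beta = Parameter(np.zeros(cout))
        self.cin, self.cout = cin, cout

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.conv3d(x, self.w, self.b)
        if self.norm:
            out = ag.instance_norm(out, self.gamma, self.beta)
        return out

    def params(self):
        ps = [self.w, self.b]
        if self.norm:
            ps += [self.gamma, self.beta]
        return ps

    def describe(self, name):
        out = [
            (f"{name}.weight", self.w.data.shape, self.w.data.size),
            (f"{name}.bias", self.b.data.shape, self.b.data.size),
        ]
        if self.norm:
            out += [
                (f"{name}.norm.gamma", self.gamma.data.shape, self.gamma.data.size),
                (f"{name}.norm.beta", self.beta.data.shape, self.beta.data.size),
            ]
        return out


class _Conv1:
    def __init__(self, rng, cin: int, cout: int):
        self.w = Parameter(_he_init(rng, (cout, cin), fan_in=cin))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1x1(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]

    def describe(self, name):
        return [
            (f"{name}.weight", self.w.data.shape, self.w.data.size),
            (f"{name}.bias", self.b.data.shape, self.b.data.size),
        ]


class UNet3D:
    """3D U-Net with doubling channel widths.

    Parameters
    ----------
    base_channels
        Channel count of the first level (default 8).
    levels
        Number of hierarchy levels including the bottleneck (default 5);
        must be ≥ 2. Input volumes must have spatial extents divisible by
        ``2**(levels-1)``.
    seed
        Weight-initialization seed.
    """

    def __init__(self, base_channels: int = 8, levels: int = 5, seed: int = 0):
        if levels < 2:
            raise ValueError("levels must be ≥ 2")
        rng = np.random.default_rng(seed)
        self.base_channels = base_channels
        self.levels = levels
        self.channels = [base_channels * 2**i for i in range(levels)]

        self.enc_blocks = []
        cin = 1
        for c in self.channels:
            self.enc_blocks.append((_Conv3(rng, cin, c), _Conv3(rng, c, c)))
            cin = c

        self.up_convs = []
        self.dec_blocks = []
        for i in range(levels - 2, -1, -1):
            c_hi, c = self.channels[i + 1], self.channels[i]
            self.up_convs.append(_Conv3(rng, c_hi, c))
            self.dec_blocks.append((_Conv3(rng, 2 * c, c), _Conv3(rng, c, c)))

        self.out_conv = _Conv1(rng, self.channels[0], 1)

    # -- bookkeeping -------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for a, b in self.enc_blocks:
            params += a.params() + b.params()
        for up, (a, b) in zip(self.up_convs, self.dec_blocks):
            params += up.params() + a.params() + b.params()
        params += self.out_conv.params()
        return params

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def layer_list(self) -> list[tuple[str, tuple, int]]:
        """Every weight tensor: (name, shape, parameter count)."""
        out = []
        for i, (a, b) in enumerate(self.enc_blocks):
            out += a.describe(f"enc{i}.conv0") + b.describe(f"enc{i}.conv1")
        for j, (up, (a, b)) in enumerate(zip(self.up_convs, self.dec_blocks)):
            lvl = self.levels - 2 - j
            out += up.describe(f"up{lvl}")
            out += a.describe(f"dec{lvl}.conv0") + b.describe(f"dec{lvl}.conv1")
        out += self.out_conv.describe("out")
        return out

    # -- forward -----------------------------------------------------------
    def forward(self, x) -> Tensor:
        """Input ``(D, H, W)`` or ``(1, D, H, W)`` → probability tensor ``(D, H, W)``."""
        arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[None]
        div = 2 ** (self.levels - 1)
        if any(s % div for s in arr.shape[1:]):
            raise ValueError(
                f"spatial shape {arr.shape[1:]} not divisible by 2^(levels-1) = {div}"
            )
        t = Tensor(arr)
        skips = []
        for i, (c0, c1) in enumerate(self.enc_blocks):
            t = ag.relu(c1(ag.relu(c0(t))))
            if i < self.levels - 1:
                skips.append(t)
                t = ag.maxpool2(t)
        for up, (c0, c1) in zip(self.up_convs, self.dec_blocks):
            t = ag.relu(up(ag.upsample2(t)))
            t = ag.concat(skips.pop(), t)
            t = ag.relu(c1(ag.relu(c0(t))))
        logits = self.out_conv(t)
        prob = ag.sigmoid(logits)
        # drop the singleton channel axis
        out = ag._make(prob.data[0], (prob,), lambda g, p=prob: ag._accum(p, g[None]))
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference without graph construction."""
        with ag.no_grad():
            return self.forward(x).data

    # -- persistence (self-describing checkpoints) --------------------------
    def save(self, path: str | Path) -> None:
        state = {
            "config": {"base_channels": self.base_channels, "levels": self.levels},
            "weights": [p.data for p in self.parameters()],
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(**state["config"])
        for p, w in zip(model.parameters(), state["weights"]):
            p.data = np.asarray(w, dtype=np.float64)
        return model


def build_unet(base_channels: int = 8, levels: int = 5, seed: int = 0) -> tuple[UNet3D, int]:
    """Construct a U-Net and report its trainable-parameter count."""
    model = UNet3D(base_channels=base_channels, levels=levels, seed=seed)
    return model, model.parameter_count
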