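"""3D encoder-decoder that predicts a deformation vector field from one CT.

The network maps a single-channel volume to a 3-channel displacement field
(mm) of the same spatial size: an encoder of conv + batch-norm + PReLU
blocks with 2x average-pool downsampling and channel doubling per level, a
bottom block, and a mirror decoder with nearest-neighbour upsampling and
skip concatenations.  The 1x1x1 output head is zero-initialized so an
untrained model predicts the zero field (identity transform) -- the standard
safe start for registration networks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..grids import DisplacementField, ImageVolume
from . import autodiff as ad

__all__ = ["NetworkSpec", "DVFNet", "build_network"]

HU_WINDOW = (-1000.0, 1000.0)  # fixed normalization window for network inputs


def normalize_hu(data: np.ndarray) -> np.ndarray:
    """Clip to the HU window and rescale to [0, 1]."""
    lo, hi = HU_WINDOW
    return (np.clip(data, lo, hi) - lo) / (hi - lo)


@dataclass(frozen=True)
class NetworkSpec:
    in_channels: int = 1
    out_channels: int = 3
    levels: int = 3  # number of 2x downsamplings (and upsamplings)
    init_channels: int = 32
    kernel: int = 3
    prelu_init: float = 0.25

    def validate(self) -> None:
        if self.in_channels != 1 or self.out_channels != 3:
            raise ValueError("the DVF network takes 1 input channel and emits 3")
        if self.levels < 1 or self.init_channels < 1 or self.kernel % 2 == 0:
            raise ValueError("levels/channels must be positive, kernel odd")


class DVFNet:
    """Model handle: parameters, running BN statistics, forward pass."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.params: dict[str, ad.Tensor] = {}
        self.running: dict[str, dict] = {}
        rng = np.random.default_rng(seed)
        c = spec.init_channels
        widths = [c * 2**i for i in range(spec.levels + 1)]
        self._widths = widths
        prev = spec.in_channels
        for i, w in enumerate(widths[:-1]):
            self._add_block(f"enc{i}", prev, w, rng)
            prev = w
        self._add_block("bottom", prev, widths[-1], rng)
        prev = widths[-1]
        for i in reversed(range(spec.levels)):
            self._add_block(f"dec{i}", prev + widths[i], widths[i], rng)
            prev = widths[i]
        # zero-initialized 1x1x1 head: initial prediction is the zero field
        self.params["head.w"] = ad.Tensor(
            np.zeros((3, prev, 1, 1, 1)), requires_grad=True
        )
        self.params["head.b"] = ad.Tensor(np.zeros(3), requires_grad=True)

    def _add_block(self, name: str, cin: int, cout: int, rng) -> None:
        k = self.spec.kernel
        std = np.sqrt(2.0 / (cin * k**3))
        self.params[f"{name}.w"] = ad.Tensor(
            rng.normal(0.0, std, size=(cout, cin, k, k, k)), requires_grad=True
        )
        self.params[f"{name}.b"] = ad.Tensor(np.zeros(cout), requires_grad=True)
        self.params[f"{name}.gamma"] = ad.Tensor(np.ones(cout), requires_grad=True)
        self.params[f"{name}.beta"] = ad.Tensor(np.zeros(cout), requires_grad=True)
        self.params[f"{name}.alpha"] = ad.Tensor(
            np.full(cout, self.spec.prelu_init), requires_grad=True
        )
        self.running[name] = {"mean": np.zeros(cout), "var": np.ones(cout)}

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def _block(self, name: str, x: ad.Tensor, training: bool) -> ad.Tensor:
        p = self.params
        h = ad.conv3d(x, p[f"{name}.w"], p[f"{name}.b"])
        h = ad.batchnorm(
            h, p[f"{name}.gamma"], p[f"{name}.beta"], self.running[name], training
        )
        return ad.prelu(h, p[f"{name}.alpha"])

    def check_input(self, shape) -> None:
        div = 2**self.spec.levels
        for ax, n in zip("xyz", shape[-3:]):
            if n % div:
                raise ValueError(
                    f"spatial axis {ax} has size {n}, not divisible by {div} "
                    f"(levels={self.spec.levels})"
                )

    def forward(self, x: ad.Tensor, training: bool = False) -> ad.Tensor:
        """(N, 1, D, H, W) normalized intensities -> (N, 3, D, H, W) DVF (mm)."""
        self.check_input(x.shape)
        skips = []
        h = x
        for i in range(self.spec.levels):
            h = self._block(f"enc{i}", h, training)
            skips.append(h)
            h = ad.avgpool2(h)
        h = self._block("bottom", h, training)
        for i in reversed(range(self.spec.levels)):
            h = ad.upsample2(h)
            h = ad.concat(h, skips[i])
            h = self._block(f"dec{i}", h, training)
        return ad.conv3d(h, self.params["head.w"], self.params["head.b"])

    def predict_dvf(self, volume: ImageVolume) -> DisplacementField:
        """Run the (frozen) model on one preprocessed volume."""
        x = ad.Tensor(normalize_hu(volume.data)[None, None])
        out = self.forward(x, training=False)
        return DisplacementField(out.data[0], volume.spacing, volume.origin)

    # -- checkpointing ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {k: p.data for k, p in self.params.items()}
        for name, st in self.running.items():
            arrays[f"running.{name}.mean"] = st["mean"]
            arrays[f"running.{name}.var"] = st["var"]
        np.savez(d / "weights.npz", **arrays)
        (d / "manifest.json").write_text(
            json.dumps({"network": asdict(self.spec)}, indent=2)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "DVFNet":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        model = cls(NetworkSpec(**manifest["network"]))
        with np.load(d / "weights.npz") as z:
            for k in model.params:
                model.params[k].data = z[k]
            for name, st in model.running.items():
                st["mean"] = z[f"running.{name}.mean"]
                st["var"] = z[f"running.{name}.var"]
        return model


def build_network(spec: NetworkSpec, seed: int = 0) -> DVFNet:
    """Construct a seeded, zero-field-initialized DVF network."""
    return DVFNet(spec, seed=seed)
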