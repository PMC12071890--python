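"""Training loop (Adam) and synthetic-CT prediction.

Training minimizes the SSIM + diffusion-regularizer objective over (dCT,
pCT) pairs.  All randomness (parameter init, pair shuffling) flows from the
TrainSpec seed, and the numpy implementation is deterministic, so a repeated
run with the same data and seed reproduces the loss history bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from ..grids import DisplacementField, ImageVolume
from ..warping import resample_dvf, warp
from . import autodiff as ad
from .losses import registration_loss
from .network import DVFNet, NetworkSpec, normalize_hu

__all__ = ["TrainSpec", "train", "predict_sct"]

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 1e-5
    batch_size: int = 2
    epochs: int = 1500
    lambda_reg: float = 0.01
    ssim_window: int = 7
    random_seed: int = 0
    checkpoint_every: int = 0  # 0: only at the end
    optimizer: str = "adam"

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("regularization weight must be non-negative")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


class _Adam:
    def __init__(self, params: dict[str, ad.Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(
    pairs: list[tuple[ImageVolume, ImageVolume]],
    spec: TrainSpec,
    network: NetworkSpec | None = None,
    model: DVFNet | None = None,
    checkpoint_dir=None,
) -> tuple[DVFNet, list[float]]:
    """Fit the DVF network on (dCT, pCT) pairs; returns (model, loss history).

    The loss history holds the mean training loss per epoch.  Aborts with a
    diagnostic if the loss turns non-finite (e.g. a too-aggressive learning
    rate).
    """
    spec.validate()
    if not pairs:
        raise ValueError("need at least one (dCT, pCT) training pair")
    shape = pairs[0][0].shape
    spacing = pairs[0][0].spacing
    for d, p in pairs:
        if d.shape != shape or p.shape != shape:
            raise ValueError("all training pairs must share one grid")

    if model is None:
        model = DVFNet(network or NetworkSpec(), seed=spec.random_seed)
    model.check_input((1, 1, *shape))

    dcts = np.stack([normalize_hu(np.asarray(d.data)) for d, _ in pairs])[:, None]
    pcts = np.stack([normalize_hu(np.asarray(p.data)) for _, p in pairs])[:, None]

    rng = np.random.default_rng(spec.random_seed + 1)
    opt = _Adam(model.params, spec.learning_rate)
    history: list[float] = []
    n = len(pairs)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb = ad.Tensor(dcts[idx])
            opt.zero_grad()
            dvf = model.forward(xb, training=True)
            loss = registration_loss(
                dcts[idx], pcts[idx], dvf, spacing,
                lam=spec.lambda_reg, window=spec.ssim_window,
            )
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={spec.learning_rate}); lower the learning rate"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(val)
        history.append(float(np.mean(epoch_losses)))
        if (
            checkpoint_dir is not None
            and spec.checkpoint_every
            and (epoch + 1) % spec.checkpoint_every == 0
        ):
            model.save(checkpoint_dir)
    if checkpoint_dir is not None:
        model.save(checkpoint_dir)
    return model, history


def predict_sct(
    dct: ImageVolume, model: DVFNet
) -> tuple[ImageVolume, DisplacementField]:
    """Predict the synthetic CT and its DVF from a preprocessed diagnostic CT.

    If the input grid differs from the model's training resolution, the DVF
    is predicted on a resampled copy and upsampled (trilinearly, mm units
    unchanged) back to the native grid before warping, so the returned sCT
    lives on the input grid.  The DVF can be reused to map contours
    (nearest-neighbour warp).
    """
    div = 2**model.spec.levels
    if all(n % div == 0 for n in dct.shape):
        dvf = model.predict_dvf(dct)
    else:
        from ..preprocess import resample

        target = tuple(max(div, (n // div) * div) for n in dct.shape)
        small = resample(dct, target)
        dvf = resample_dvf(model.predict_dvf(small), dct.shape, dct.spacing)
        dvf = DisplacementField(dvf.data, dct.spacing, dct.origin)
    sct = warp(dct, dvf, interpolation="trilinear")
    return sct, dvf
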