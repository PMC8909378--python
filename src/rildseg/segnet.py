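"""2D encoder–decoder segmentation networks and logit-sum ensembling.

The backbone is a canonical 2D UNet: four reduction stages (so base
filters f grow as f, 2f, 4f, 8f, 16f at the bottleneck), two 3x3
convolutions with instance normalisation and ReLU per resolution level,
2x2 max-pool down, nearest-neighbour upsample + convolution up with skip
concatenation, and a five-channel head read through softmax. Networks in
an ensemble differ by training loss (WCE / soft Dice / Lovász-softmax)
and by base filter count; member outputs are fused by summing their
pre-softmax logit scores channel-wise and only then taking the argmax, so
each member's confidence — not just its label vote — enters the decision.
No postprocessing is applied beyond re-imposing the lung mask.

Presets mirror the two annotation-refinement stages: stage one is the
three-member {WCE·32, LV·32, LV·64} ensemble, stage two the six-member
{WCE, DC, LV} x {32, 64} grid.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._tensor import Adam, Tensor, no_grad
from .imaging_io import OUTSIDE, LabelMap
from .losses import LOSS_KINDS, compute_loss, weights_from_frequencies
from .preprocess import DEFAULT_TARGET, HUWindow, Sample, SlicePlan, make_samples

__all__ = [
    "NetConfig",
    "EnsembleConfig",
    "Hyper",
    "UNet2D",
    "build_net",
    "train",
    "predict_scores",
    "fuse_scores",
    "ensemble_predict",
    "predict_case",
    "stage_one_preset",
    "stage_two_preset",
    "save_model",
    "load_model",
]

N_CLASSES = 5
DEPTH = 4  # reduction stages


@dataclass(frozen=True)
class NetConfig:
    """One network: training loss x base filter count."""

    loss: str
    base_filters: int
    in_channels: int = 1
    input_shape: tuple[int, int] = DEFAULT_TARGET
    seed: int = 0

    def __post_init__(self):
        if self.loss not in LOSS_KINDS:
            raise ValueError(f"loss must be one of {LOSS_KINDS}, got {self.loss!r}")
        if not (isinstance(self.base_filters, int) and self.base_filters >= 1):
            raise ValueError(f"unsupported base filter count {self.base_filters!r}")
        if self.in_channels < 1:
            raise ValueError("need at least one input channel")
        h, w = self.input_shape
        if h % (2 ** DEPTH) or w % (2 ** DEPTH):
            raise ValueError(
                f"input shape {self.input_shape} not divisible by {2 ** DEPTH} "
                f"({DEPTH} reduction stages)"
            )

    @property
    def name(self) -> str:
        return f"{self.loss}{self.base_filters}"


@dataclass(frozen=True)
class EnsembleConfig:
    members: tuple[NetConfig, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")


def stage_one_preset(
    input_shape: tuple[int, int] = DEFAULT_TARGET,
    filters: tuple[int, int] = (32, 64),
    seed: int = 0,
) -> EnsembleConfig:
    """Three-member draft-stage ensemble: WCE at the small filter count,
    Lovász at both."""
    f1, f2 = filters
    return EnsembleConfig(
        tuple(
            NetConfig(loss, f, input_shape=input_shape, seed=seed + i)
            for i, (loss, f) in enumerate([("WCE", f1), ("LV", f1), ("LV", f2)])
        )
    )


def stage_two_preset(
    input_shape: tuple[int, int] = DEFAULT_TARGET,
    filters: tuple[int, int] = (32, 64),
    seed: int = 0,
) -> EnsembleConfig:
    """Six-member refined-stage ensemble: {WCE, DC, LV} x two filter counts."""
    members = []
    i = 0
    for f in filters:
        for loss in LOSS_KINDS:
            members.append(NetConfig(loss, f, input_shape=input_shape, seed=seed + i))
            i += 1
    return EnsembleConfig(tuple(members))


# ---------------------------------------------------------------- the network


class UNet2D:
    """UNet with ``DEPTH`` reduction stages and instance normalisation."""

    def __init__(self, config: NetConfig):
        self.config = config
        self.params: list[Tensor] = []
        rng = np.random.default_rng(config.seed)
        f = config.base_filters
        enc_ch = [f * 2 ** i for i in range(DEPTH)]  # f, 2f, 4f, 8f
        bott_ch = f * 2 ** DEPTH  # 16f

        self.enc_blocks = []
        cin = config.in_channels
        for ch in enc_ch:
            self.enc_blocks.append(self._block(rng, cin, ch))
            cin = ch
        self.bottleneck = self._block(rng, cin, bott_ch)
        self.up_convs = []
        self.dec_blocks = []
        cin = bott_ch
        for ch in reversed(enc_ch):
            self.up_convs.append(self._conv(rng, cin, ch, 3) + self._norm(ch))
            self.dec_blocks.append(self._block(rng, 2 * ch, ch))
            cin = ch
        self.head = self._conv(rng, cin, N_CLASSES, 1)

    # parameter constructors -------------------------------------------------
    def _conv(self, rng, cin, cout, k):
        std = np.sqrt(2.0 / (cin * k * k))
        w = Tensor(rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32), True)
        b = Tensor(np.zeros(cout, dtype=np.float32), True)
        self.params += [w, b]
        return [w, b]

    def _norm(self, ch):
        g = Tensor(np.ones((1, ch, 1, 1), dtype=np.float32), True)
        b = Tensor(np.zeros((1, ch, 1, 1), dtype=np.float32), True)
        self.params += [g, b]
        return [g, b]

    def _block(self, rng, cin, cout):
        return (
            self._conv(rng, cin, cout, 3) + self._norm(cout)
            + self._conv(rng, cout, cout, 3) + self._norm(cout)
        )

    # forward ----------------------------------------------------------------
    @staticmethod
    def _instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps=1e-5) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return gamma * (xc / ((var + eps) ** 0.5)) + beta

    @classmethod
    def _apply_block(cls, x: Tensor, p) -> Tensor:
        w1, b1, g1, be1, w2, b2, g2, be2 = p
        x = cls._instance_norm(x.conv2d(w1, b1), g1, be1).relu()
        return cls._instance_norm(x.conv2d(w2, b2), g2, be2).relu()

    def forward(self, x: Tensor) -> Tensor:
        """(N, in_channels, H, W) -> logits (N, 5, H, W)."""
        skips = []
        for p in self.enc_blocks:
            x = self._apply_block(x, p)
            skips.append(x)
            x = x.maxpool2x2()
        x = self._apply_block(x, self.bottleneck)
        for p_up, p_block, skip in zip(self.up_convs, self.dec_blocks, reversed(skips)):
            w, b, g, be = p_up
            x = self._instance_norm(x.upsample2x().conv2d(w, b), g, be).relu()
            x = Tensor.cat([skip, x], axis=1)
            x = self._apply_block(x, p_block)
        w, b = self.head
        return x.conv2d(w, b)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        if len(arrays) != len(self.params):
            raise ValueError("state does not match architecture")
        for p, a in zip(self.params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = a.astype(p.data.dtype).copy()


def build_net(config: NetConfig) -> UNet2D:
    """Deterministically initialise the network described by ``config``."""
    return UNet2D(config)


# -------------------------------------------------------------------- training


@dataclass
class Hyper:
    """Training hyperparameters (conventional defaults, all overridable)."""

    epochs: int = 10
    batch_size: int = 2
    lr: float = 1e-3
    max_steps: int | None = None
    early_stop_patience: int | None = None


def _batch_loss(model: UNet2D, batch: Sequence[Sample], weights) -> Tensor:
    images = np.stack([s.image for s in batch])[:, None, :, :].astype(np.float32)
    logits = model.forward(Tensor(images))
    flat = logits.transpose(0, 2, 3, 1).reshape(-1, N_CLASSES)
    lung = np.concatenate([s.lung.ravel() for s in batch])
    labels = np.concatenate([s.labels.ravel() for s in batch])
    idx = np.flatnonzero(lung)
    probs = flat.take(idx).softmax(axis=1)
    targets = labels[idx] - 1  # classes 1..5 -> 0..4
    return compute_loss(model.config.loss, probs, targets, weights)


def _eval_loss(model: UNet2D, samples, weights, batch_size) -> float:
    tot, n = 0.0, 0
    with no_grad():
        for i in range(0, len(samples), batch_size):
            b = samples[i : i + batch_size]
            tot += float(_batch_loss(model, b, weights).data) * len(b)
            n += len(b)
    return tot / max(n, 1)


def train(
    config: NetConfig,
    samples: Sequence[Sample],
    hyper: Hyper = Hyper(),
    seed: int | None = None,
    val_samples: Sequence[Sample] | None = None,
) -> tuple[UNet2D, list[float]]:
    """Train one network; deterministic given ``seed``.

    WCE class weights are derived from the training samples' own lung-voxel
    class frequencies. Returns the model and the per-epoch mean training
    loss history. Raises on divergence (NaN loss). With validation samples
    and a patience, stops early on stagnating validation loss and restores
    the best weights.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = build_net(replace(config, seed=int(rng.integers(2 ** 31))))
    weights = None
    if config.loss == "WCE":
        counts = np.zeros(N_CLASSES, dtype=np.int64)
        for s in samples:
            counts += np.bincount(s.labels[s.lung], minlength=6)[1:6]
        weights = weights_from_frequencies(counts / counts.sum())
    opt = Adam(model.params, lr=hyper.lr)
    history: list[float] = []
    best = (np.inf, None)
    stale = 0
    step = 0
    for epoch in range(hyper.epochs):
        order = rng.permutation(len(samples))
        epoch_losses = []
        for i in range(0, len(order), hyper.batch_size):
            if hyper.max_steps is not None and step >= hyper.max_steps:
                break
            batch = [samples[j] for j in order[i : i + hyper.batch_size]]
            opt.zero_grad()
            loss = _batch_loss(model, batch, weights)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"training diverged: {config.loss} loss became {lv} at step {step}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(lv)
            step += 1
        if epoch_losses:
            history.append(float(np.mean(epoch_losses)))
        if val_samples is not None and hyper.early_stop_patience is not None:
            vl = _eval_loss(model, val_samples, weights, hyper.batch_size)
            if vl < best[0] - 1e-6:
                best = (vl, model.state())
                stale = 0
            else:
                stale += 1
                if stale >= hyper.early_stop_patience:
                    break
        if hyper.max_steps is not None and step >= hyper.max_steps:
            break
    if best[1] is not None:
        model.load_state(best[1])
    return model, history


# ------------------------------------------------------------------- inference


def predict_scores(model: UNet2D, sample: Sample | np.ndarray) -> np.ndarray:
    """Pre-softmax class scores (5, H, W) for one slice."""
    image = sample.image if isinstance(sample, Sample) else np.asarray(sample)
    if image.shape != tuple(model.config.input_shape):
        raise ValueError(
            f"sample shape {image.shape} != network input {model.config.input_shape}"
        )
    with no_grad():
        x = Tensor(image.astype(np.float32)[None, None])
        return model.forward(x).data[0]


def fuse_scores(
    member_scores: Sequence[np.ndarray], lung_mask: np.ndarray | None = None
) -> np.ndarray:
    """Channel-wise logit summation, then per-voxel argmax (classes 1..5).

    Voxels outside ``lung_mask`` (if given) are set to the OUTSIDE
    sentinel. No other postprocessing is applied.
    """
    if not member_scores:
        raise ValueError("empty ensemble")
    total = np.sum(np.stack([np.asarray(s) for s in member_scores]), axis=0)
    labels = (total.argmax(axis=0) + 1).astype(np.int16)
    if lung_mask is not None:
        labels = np.where(lung_mask, labels, np.int16(OUTSIDE))
    return labels


def ensemble_predict(
    models: Sequence[UNet2D],
    sample: Sample | np.ndarray,
    lung_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Ensemble decision for one slice via :func:`fuse_scores`."""
    if not models:
        raise ValueError("empty ensemble")
    return fuse_scores([predict_scores(m, sample) for m in models], lung_mask)


def predict_case(
    models: Sequence[UNet2D],
    case,
    plan: SlicePlan,
    window: HUWindow = HUWindow(),
) -> LabelMap:
    """Predict a full case on its original grid.

    Inference runs on every lung-containing slice (the training-time slice
    filter is never applied here). Predictions are mapped back through the
    crop geometry; the lung mask is re-imposed at source resolution so
    every lung voxel receives a class in 1..5 and everything else the
    OUTSIDE sentinel.
    """
    if not models:
        raise ValueError("empty ensemble")
    src_shape = case.labels.shape
    out = np.full(src_shape, OUTSIDE, dtype=np.int16)
    samples = make_samples(case, plan, window, slices="all_lung")
    chunk = 8  # slices per forward pass
    for i in range(0, len(samples), chunk):
        batch = samples[i : i + chunk]
        images = np.stack([s.image for s in batch])[:, None].astype(np.float32)
        with no_grad():
            scores = models[0].forward(Tensor(images)).data
            for m in models[1:]:
                scores = scores + m.forward(Tensor(images)).data
        labels_t = (scores.argmax(axis=1) + 1).astype(np.int16)
        for s, lt in zip(batch, labels_t):
            back = plan.crop.map_back(lt, src_shape[1:], fill=1)
            z = s.slice_index
            lung = case.lung_mask.bool[z]
            out[z][lung] = back[lung]
    return LabelMap(out, case.labels.spacing, case.labels.origin)


# ----------------------------------------------------------------- persistence


def save_model(model: UNet2D, path) -> None:
    """Checkpoint: weights plus embedded config (npz)."""
    cfg = {
        "loss": model.config.loss,
        "base_filters": model.config.base_filters,
        "in_channels": model.config.in_channels,
        "input_shape": list(model.config.input_shape),
        "seed": model.config.seed,
    }
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
    np.savez(os.fspath(path), config=json.dumps(cfg), **arrays)


def load_model(path) -> UNet2D:
    with np.load(os.fspath(path), allow_pickle=False) as z:
        cfg = json.loads(str(z["config"]))
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model = UNet2D(NetConfig(**cfg))
        model.load_state([z[f"p{i}"] for i in range(len(model.params))])
    return model
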