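"""Training losses: weighted cross entropy, soft Dice, Lovász-softmax.

All three operate on flattened per-voxel class probabilities of shape
``(V, C)`` (rows on the probability simplex) with integer targets in
``0..C-1``. The caller restricts ``V`` to lung voxels — anatomy outside
the lung never enters a loss sum. Inputs may be plain numpy arrays (a
float is returned) or autodiff :class:`~rildseg._tensor.Tensor` objects
(a scalar Tensor is returned, so gradients flow to the network).

* WCE — mean over voxels of ``-w_y log p_y`` with inverse-frequency class
  weights; reduces to plain cross entropy at unit weights.
* Soft Dice — ``1 - mean_c (2 Σ p_c t_c + ε) / (Σ p_c + Σ t_c + ε)`` over
  classes present in the target, ε = 1 by convention (guards 0/0).
* Lovász-softmax — the Lovász extension of the per-class Jaccard loss
  applied to softmax outputs (Berman et al.'s surrogate), averaged over
  classes present in the batch. On hard 0/1 predictions it equals
  ``1 - IoU`` exactly, the property the unit tests pin down.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np

from ._tensor import Tensor

__all__ = [
    "LOSS_KINDS",
    "LossValue",
    "weights_from_frequencies",
    "weighted_cross_entropy",
    "soft_dice_loss",
    "lovasz_grad",
    "lovasz_softmax",
    "compute_loss",
]

LOSS_KINDS = ("WCE", "DC", "LV")

_EPS_LOG = 1e-12


class LossValue(NamedTuple):
    value: float
    kind: str


def weights_from_frequencies(
    fractions: np.ndarray, cap: float = 100.0
) -> np.ndarray:
    """Inverse-frequency class weights, normalised to mean 1 and capped.

    ``w_c ∝ 1 / fraction_c`` over classes with nonzero frequency,
    normalised so those weights average 1. A class absent from the data
    gets the cap (with a warning) rather than an infinite weight.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("class fractions must be non-negative")
    pos = f > 0
    if not pos.any():
        raise ValueError("all class fractions are zero")
    w = np.full(f.shape, cap, dtype=float)
    inv = 1.0 / f[pos]
    w[pos] = inv / inv.mean()
    if (~pos).any():
        warnings.warn(
            "classes with zero frequency received the capped weight", stacklevel=2
        )
    return np.minimum(w, cap)


def _prep(probabilities, targets):
    t = np.asarray(targets).astype(np.int64).ravel()
    is_tensor = isinstance(probabilities, Tensor)
    p = probabilities if is_tensor else Tensor(np.asarray(probabilities, dtype=float))
    if p.data.ndim != 2 or p.data.shape[0] != t.size:
        raise ValueError(
            f"expected probabilities (V, C) matching {t.size} targets, got {p.data.shape}"
        )
    if t.min(initial=0) < 0 or t.max(initial=0) >= p.data.shape[1]:
        raise ValueError("targets outside class vocabulary")
    return p, t, is_tensor


def _ret(loss: Tensor, is_tensor: bool):
    return loss if is_tensor else float(loss.data)


def weighted_cross_entropy(probabilities, targets, weights=None):
    """Mean over voxels of ``-w_y log p_y`` (plain CE at unit weights)."""
    p, t, is_tensor = _prep(probabilities, targets)
    C = p.data.shape[1]
    w = np.ones(C) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (C,) or np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive finite, one per class")
    rows = np.arange(t.size)
    p_y = p.take((rows, t)).clip_min(_EPS_LOG)
    loss = -(Tensor(w[t].astype(p.data.dtype)) * p_y.log()).mean()
    return _ret(loss, is_tensor)


def soft_dice_loss(probabilities, targets, eps: float = 1.0):
    """Multiclass soft Dice loss over classes present in the target."""
    p, t, is_tensor = _prep(probabilities, targets)
    C = p.data.shape[1]
    onehot = np.zeros((t.size, C), dtype=p.data.dtype)
    onehot[np.arange(t.size), t] = 1.0
    present = onehot.any(axis=0)
    inter = (p * Tensor(onehot)).sum(axis=0)
    denom = p.sum(axis=0) + Tensor(onehot.sum(axis=0))
    dice = (inter * Tensor(np.asarray(2.0, p.data.dtype)) + eps) / (denom + eps)
    mean_dice = (dice * Tensor(present.astype(p.data.dtype))).sum() * (1.0 / present.sum())
    return _ret(1.0 - mean_dice, is_tensor)


def lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Discrete gradient of the Lovász extension of the Jaccard loss.

    ``gt_sorted`` is the 0/1 ground-truth vector for one class, permuted
    into decreasing order of prediction error.
    """
    gt_sorted = np.asarray(gt_sorted, dtype=float).ravel()
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    if gt_sorted.size > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def lovasz_softmax(probabilities, targets):
    """Lovász-softmax loss averaged over classes present in the batch.

    Per class c: errors are ``1 - p_c`` on foreground voxels and ``p_c``
    on background; sorted descending, their inner product with the Lovász
    gradient of the Jaccard loss is the class term.
    """
    p, t, is_tensor = _prep(probabilities, targets)
    C = p.data.shape[1]
    terms = []
    for c in range(C):
        fg = (t == c).astype(p.data.dtype)
        if fg.sum() == 0:
            continue  # present-classes averaging
        sel = np.zeros(C, dtype=p.data.dtype)
        sel[c] = 1.0
        p_c = (p * Tensor(sel)).sum(axis=1)
        errors = Tensor(fg) + Tensor(1.0 - 2.0 * fg) * p_c
        perm = np.argsort(-errors.data, kind="stable")
        grad = lovasz_grad(fg[perm]).astype(p.data.dtype)
        terms.append((errors.take(perm) * Tensor(grad)).sum())
    if not terms:
        raise ValueError("no class present in target")
    loss = terms[0]
    for term in terms[1:]:
        loss = loss + term
    loss = loss * (1.0 / len(terms))
    return _ret(loss, is_tensor)


def compute_loss(kind: str, probabilities, targets, weights=None) -> "LossValue | Tensor":
    """Dispatch on loss kind; returns LossValue for numpy inputs."""
    if kind == "WCE":
        out = weighted_cross_entropy(probabilities, targets, weights)
    elif kind == "DC":
        out = soft_dice_loss(probabilities, targets)
    elif kind == "LV":
        out = lovasz_softmax(probabilities, targets)
    else:
        raise ValueError(f"unknown loss kind {kind!r}; expected one of {LOSS_KINDS}")
    if isinstance(out, Tensor):
        return out
    return LossValue(out, kind)
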