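"""Quantitative evaluation and annotation-refinement bookkeeping.

The headline metric is the *global* Dice score: true/false positives and
false negatives are pooled over every lung voxel of every scan in a set
before the ratio is formed, giving one score per class rather than a
per-scan mean. Pooling keeps scans where a rare class occupies only a
handful of voxels from distorting the score — a per-scan average lets a
single nearly-empty scan contribute an extreme value with full weight.

Also here: row-normalisable confusion matrices, patient-level K-fold
cross-validation with (mean, sd, 95% CI) summaries, voxel-wise
disagreement maps between two segmentations, and the aggregation
arithmetic for the two-stage refinement choices and ordinal qualitative
scores (the human judgements themselves are inputs, never computed).

All counts are restricted to lung voxels; the OUTSIDE sentinel never
enters any sum. A class absent from both prediction and truth across a
whole set has an *undefined* Dice, reported as missing — never as 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_io import CLASSES, OUTSIDE

__all__ = [
    "EvalReport",
    "RefinementRecord",
    "global_dice",
    "confusion_matrix",
    "dice_from_confusion",
    "evaluate_set",
    "crossval_run",
    "summarise_folds",
    "disagreement_map",
    "refinement_report",
    "qualitative_summary",
]


def _as_array(x) -> np.ndarray:
    return x.voxels if hasattr(x, "voxels") else np.asarray(x)


def _pooled_pairs(predictions, ground_truths, masks):
    if len(predictions) != len(ground_truths):
        raise ValueError("prediction/ground-truth counts differ")
    if masks is None:
        masks = [None] * len(predictions)
    for p, g, m in zip(predictions, ground_truths, masks):
        pa, ga = _as_array(p), _as_array(g)
        if pa.shape != ga.shape:
            raise ValueError(f"shape mismatch {pa.shape} vs {ga.shape}")
        lung = (_as_array(m).astype(bool)) if m is not None else (ga != OUTSIDE)
        yield pa[lung], ga[lung]


def confusion_matrix(predictions, ground_truths, masks=None) -> np.ndarray:
    """5x5 count matrix: entry (i, j) = lung voxels with truth i+1 predicted j+1."""
    M = np.zeros((5, 5), dtype=np.int64)
    for pv, gv in _pooled_pairs(predictions, ground_truths, masks):
        idx = (gv.astype(np.int64) - 1) * 5 + (pv.astype(np.int64) - 1)
        if idx.min(initial=0) < 0 or idx.max(initial=0) >= 25:
            raise ValueError("labels outside {1..5} inside the lung")
        M += np.bincount(idx, minlength=25).reshape(5, 5)
    return M


def normalise_confusion(M: np.ndarray) -> np.ndarray:
    """Row-normalised confusion matrix; all-zero rows stay zero."""
    rows = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(rows > 0, M / np.maximum(rows, 1), 0.0)


def dice_from_confusion(M: np.ndarray) -> dict[int, float | None]:
    """Per-class Dice recomputed from confusion-matrix counts."""
    out: dict[int, float | None] = {}
    for c in CLASSES:
        i = c - 1
        tp = M[i, i]
        fp = M[:, i].sum() - tp
        fn = M[i, :].sum() - tp
        out[c] = None if (2 * tp + fp + fn) == 0 else float(2 * tp / (2 * tp + fp + fn))
    return out


def global_dice(
    predictions, ground_truths, class_id: int | None = None, masks=None
):
    """Pooled (global) Dice: DSC_c = 2 TP_c / (2 TP_c + FP_c + FN_c).

    TP/FP/FN are pooled over every lung voxel of every scan in the set. A
    class absent from both sides everywhere is undefined and reported as
    None. Returns one value for ``class_id`` or a dict over all classes.
    """
    tp = np.zeros(5, dtype=np.int64)
    fp = np.zeros(5, dtype=np.int64)
    fn = np.zeros(5, dtype=np.int64)
    for pv, gv in _pooled_pairs(predictions, ground_truths, masks):
        for c in CLASSES:
            pm, gm = pv == c, gv == c
            tp[c - 1] += int(np.count_nonzero(pm & gm))
            fp[c - 1] += int(np.count_nonzero(pm & ~gm))
            fn[c - 1] += int(np.count_nonzero(~pm & gm))
    result: dict[int, float | None] = {}
    for c in CLASSES:
        denom = 2 * tp[c - 1] + fp[c - 1] + fn[c - 1]
        result[c] = None if denom == 0 else float(2 * tp[c - 1] / denom)
    if class_id is not None:
        if class_id not in CLASSES:
            raise ValueError(f"unknown class {class_id}")
        return result[class_id]
    return result


@dataclass
class EvalReport:
    """Per-class global Dice + confusion matrix for one scan set."""

    scan_set: str
    dice: dict[int, float | None]
    confusion: np.ndarray
    fold: int | None = None

    @property
    def confusion_normalised(self) -> np.ndarray:
        return normalise_confusion(self.confusion)

    @property
    def truth_counts(self) -> np.ndarray:
        return self.confusion.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scan_set": self.scan_set,
                "fold": self.fold,
                "class": list(CLASSES),
                "global_dice": [self.dice[c] for c in CLASSES],
                "truth_voxels": self.truth_counts,
            }
        )


def evaluate_set(
    predictions, ground_truths, masks=None, scan_set: str = "", fold=None
) -> EvalReport:
    M = confusion_matrix(predictions, ground_truths, masks)
    return EvalReport(scan_set, global_dice(predictions, ground_truths, masks=masks), M, fold)


# --------------------------------------------------------------- cross-validation


def summarise_folds(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Per-class mean, sd and 95% CI (mean ± 1.96 sd / sqrt(K)) over folds.

    Folds where a class is undefined are excluded from that class's
    summary, with a warning.
    """
    rows = []
    K = len(reports)
    for c in CLASSES:
        vals = [r.dice[c] for r in reports if r.dice[c] is not None]
        if len(vals) < K:
            warnings.warn(
                f"class {c} undefined in {K - len(vals)} of {K} folds; excluded",
                stacklevel=2,
            )
        if not vals:
            rows.append({"class": c, "mean": np.nan, "std": np.nan,
                         "ci95_lo": np.nan, "ci95_hi": np.nan, "n_folds": 0})
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        half = 1.96 * sd / np.sqrt(len(vals))
        rows.append({"class": c, "mean": mean, "std": sd,
                     "ci95_lo": mean - half, "ci95_hi": mean + half,
                     "n_folds": len(vals)})
    return pd.DataFrame(rows)


def crossval_run(
    cases: Sequence,
    ensemble_config,
    K: int = 5,
    seed: int = 0,
    hyper=None,
    tau: float = 0.01,
    eval_train: bool = False,
):
    """Patient-level K-fold cross-validation of an ensemble.

    Each fold's ensemble is trained from scratch on the other K-1 folds'
    filtered slices and evaluated (global Dice + confusion) on every scan
    of the held-out patients. Returns (validation reports, summary frame,
    training reports or None).
    """
    from . import segnet
    from .preprocess import make_samples, plan_case, split_patients

    patients = list(dict.fromkeys(c.patient_id for c in cases))
    split = split_patients(patients, K=K, seed=seed)
    input_shape = ensemble_config.members[0].input_shape
    plans = {id(c): plan_case(c, target=input_shape, tau=tau) for c in cases}
    hyper = segnet.Hyper() if hyper is None else hyper

    val_reports, train_reports = [], []
    rng = np.random.default_rng(seed)
    for k in range(K):
        held = set(split.fold_patients(k))
        train_cases = [c for c in cases if c.patient_id not in held]
        val_cases = [c for c in cases if c.patient_id in held]
        train_samples = []
        for c in train_cases:
            train_samples.extend(make_samples(c, plans[id(c)]))
        models = [
            segnet.train(m, train_samples, hyper, seed=int(rng.integers(2 ** 31)))[0]
            for m in ensemble_config.members
        ]

        def _report(subset, tag):
            preds = [segnet.predict_case(models, c, plans[id(c)]) for c in subset]
            gts = [c.labels for c in subset]
            masks = [c.lung_mask.bool for c in subset]
            return evaluate_set(preds, gts, masks, scan_set=tag, fold=k)

        val_reports.append(_report(val_cases, "validation"))
        if eval_train:
            train_reports.append(_report(train_cases, "training"))
    summary = summarise_folds(val_reports)
    return val_reports, summary, (train_reports if eval_train else None)


# ------------------------------------------------------- refinement comparison


def disagreement_map(seg_a, seg_b, mask=None):
    """Voxel-wise comparison of two label maps over the lung.

    Returns (binary disagreement mask, disagreeing fraction of lung
    voxels, histogram of |class_a - class_b| among disagreements).
    """
    a, b = _as_array(seg_a), _as_array(seg_b)
    if a.shape != b.shape:
        raise ValueError(f"misaligned label maps: {a.shape} vs {b.shape}")
    lung = _as_array(mask).astype(bool) if mask is not None else (a != OUTSIDE) | (b != OUTSIDE)
    dis = (a != b) & lung
    n_lung = int(lung.sum())
    fraction = float(dis.sum() / n_lung) if n_lung else 0.0
    deltas = np.abs(a[dis].astype(int) - b[dis].astype(int))
    hist = {int(d): int(n) for d, n in zip(*np.unique(deltas, return_counts=True))}
    return dis, fraction, hist


@dataclass(frozen=True)
class RefinementRecord:
    """Which segmentation (manual vs automatic) was chosen for refinement."""

    scan_id: str
    choice: str  # "manual" | "automatic"
    disagreement_fraction: float
    subset: str  # e.g. "training" | "validation"

    def __post_init__(self):
        if self.choice not in ("manual", "automatic"):
            raise ValueError(f"choice must be manual/automatic, got {self.choice!r}")
        if not 0.0 <= self.disagreement_fraction <= 1.0:
            raise ValueError("disagreement fraction outside [0, 1]")


def refinement_report(records: Sequence[RefinementRecord]) -> pd.DataFrame:
    """Per-subset percentage of scans whose manual vs automatic
    segmentation was chosen as the refinement base (rows sum to 100%)."""
    if not records:
        raise ValueError("no refinement records")
    df = pd.DataFrame([{"subset": r.subset, "choice": r.choice} for r in records])
    out = (
        df.groupby("subset")["choice"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["manual", "automatic"], fill_value=0.0)
        * 100.0
    )
    out.columns.name = None
    return out


def qualitative_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Aggregate ordinal ratings (1 acceptable / 2 minor / 3 major
    disagreement) given per scan (rows) and class (columns).

    Returns per-class percentage of scans at each score plus an AVG row
    equal to the column-wise mean over classes. Missing cells are an
    error: the grid must be complete.
    """
    if scores.isna().any().any():
        raise ValueError("qualitative score grid has missing cells")
    vals = scores.to_numpy()
    if not np.isin(vals, [1, 2, 3]).all():
        raise ValueError("scores must be 1, 2 or 3")
    rows = {}
    for col in scores.columns:
        counts = scores[col].value_counts(normalize=True).reindex([1, 2, 3], fill_value=0.0)
        rows[col] = counts * 100.0
    out = pd.DataFrame(rows).T
    out.columns = ["acceptable", "minor_disagreement", "major_disagreement"]
    out.loc["AVG"] = out.mean(axis=0)
    return out
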