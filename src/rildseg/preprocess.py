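"""Case preprocessing: lung masking, crop-and-fit, slice filtering, splits.

Turns aligned (volume, mask, labels) cases into fixed-size 2D training
samples. The pipeline is axial-slice-wise:

1. anatomy outside the lung mask is replaced by air (-1000 HU);
2. each volume gets one crop geometry — the pooled axial bounding box of
   the lung mask, padded symmetrically into the fixed network input
   (default 288 x 384). Native resolution is kept whenever the box fits;
   when it does not, a single isotropic scale factor s < 1 shrinks it,
   preserving aspect ratio and minimising downscaling;
3. for training, only slices where at least ``tau`` (default 1%) of the
   lung area carries pathology (classes 2..5) are retained — the
   class-imbalance mitigation. Inference and evaluation always use every
   lung-containing slice;
4. intensities are normalised by a fixed HU window into [0, 1]; labels are
   resampled nearest-neighbour.

Also houses pooled class-frequency accounting and leakage-free
patient-level fold splitting (all time points of a patient share a fold).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize

from .imaging_io import OUTSIDE, CLASSES, CTVolume, LabelMap, LungMask, check_aligned
from .phantom import PhantomCase

__all__ = [
    "CropGeometry",
    "SlicePlan",
    "ClassFrequencies",
    "FoldSplit",
    "HUWindow",
    "Sample",
    "mask_lungs",
    "compute_crop",
    "filter_slices",
    "plan_case",
    "make_samples",
    "class_frequencies",
    "split_patients",
    "fixed_split",
]

#: Network input size (rows = anterior-posterior, cols = left-right).
DEFAULT_TARGET = (288, 384)

#: Fill value for padding / outside-lung voxels, before windowing.
FILL_HU = -1000.0


@dataclass(frozen=True)
class HUWindow:
    """Fixed intensity window mapping HU to [0, 1]."""

    lo: float = -1000.0
    hi: float = 100.0

    def normalise(self, hu: np.ndarray) -> np.ndarray:
        return ((np.clip(hu, self.lo, self.hi) - self.lo) / (self.hi - self.lo)).astype(
            np.float32
        )


@dataclass(frozen=True)
class CropGeometry:
    """Per-volume axial crop-and-fit geometry.

    The source bounding box ``[y0, y1) x [x0, x1)`` is scaled by a single
    isotropic factor ``scale`` (1 unless the box exceeds the target) and
    placed at ``(pad_y, pad_x)`` inside the ``(out_h, out_w)`` canvas.
    At scale 1 the mapping is an exact index shift and therefore invertible.
    """

    y0: int
    y1: int
    x0: int
    x1: int
    scale: float
    pad_y: int
    pad_x: int
    out_h: int
    out_w: int

    @property
    def box_h(self) -> int:
        return self.y1 - self.y0

    @property
    def box_w(self) -> int:
        return self.x1 - self.x0

    @property
    def scaled_h(self) -> int:
        return self.box_h if self.scale == 1.0 else int(math.floor(self.box_h * self.scale + 1e-9))

    @property
    def scaled_w(self) -> int:
        return self.box_w if self.scale == 1.0 else int(math.floor(self.box_w * self.scale + 1e-9))

    # ------------------------------------------------------------- forward
    def apply_image(self, slice2d: np.ndarray, fill: float = FILL_HU) -> np.ndarray:
        crop = slice2d[self.y0 : self.y1, self.x0 : self.x1]
        if self.scale != 1.0:
            crop = resize(
                crop.astype(np.float64),
                (self.scaled_h, self.scaled_w),
                order=1,
                preserve_range=True,
                anti_aliasing=False,
            )
        out = np.full((self.out_h, self.out_w), fill, dtype=np.float32)
        out[
            self.pad_y : self.pad_y + crop.shape[0],
            self.pad_x : self.pad_x + crop.shape[1],
        ] = crop
        return out

    def apply_labels(self, slice2d: np.ndarray, fill: int = OUTSIDE) -> np.ndarray:
        crop = slice2d[self.y0 : self.y1, self.x0 : self.x1]
        if self.scale != 1.0:
            hs, ws = self.scaled_h, self.scaled_w
            ii = np.minimum(
                ((np.arange(hs) + 0.5) * crop.shape[0] / hs).astype(int),
                crop.shape[0] - 1,
            )
            jj = np.minimum(
                ((np.arange(ws) + 0.5) * crop.shape[1] / ws).astype(int),
                crop.shape[1] - 1,
            )
            crop = crop[np.ix_(ii, jj)]
        out = np.full((self.out_h, self.out_w), fill, dtype=slice2d.dtype)
        out[
            self.pad_y : self.pad_y + crop.shape[0],
            self.pad_x : self.pad_x + crop.shape[1],
        ] = crop
        return out

    # ------------------------------------------------------------- inverse
    def map_back(
        self, pred2d: np.ndarray, src_shape: tuple[int, int], fill: int = OUTSIDE
    ) -> np.ndarray:
        """Place a prediction on the source slice grid.

        Source-driven: every source voxel inside the bounding box reads
        exactly one target pixel, so full label coverage is guaranteed at
        any scale; at scale 1 the mapping inverts :meth:`apply_labels`
        index-for-index.
        """
        if pred2d.shape != (self.out_h, self.out_w):
            raise ValueError(
                f"prediction shape {pred2d.shape} != geometry target "
                f"({self.out_h}, {self.out_w})"
            )
        out = np.full(src_shape, fill, dtype=pred2d.dtype)
        h, w = self.box_h, self.box_w
        hs, ws = self.scaled_h, self.scaled_w
        ti = self.pad_y + np.minimum((np.arange(h) * hs // h), hs - 1)
        tj = self.pad_x + np.minimum((np.arange(w) * ws // w), ws - 1)
        out[self.y0 : self.y1, self.x0 : self.x1] = pred2d[np.ix_(ti, tj)]
        return out


def mask_lungs(volume: CTVolume, mask: LungMask, fill: float = FILL_HU) -> CTVolume:
    """Replace all anatomy beyond the lungs with the fill value (air)."""
    check_aligned(volume, mask, "volume", "mask")
    if not mask.voxels.any():
        raise ValueError("lung mask is empty")
    out = np.where(mask.bool, volume.voxels, np.float32(fill)).astype(np.float32)
    return CTVolume(out, volume.spacing, volume.origin, volume.orientation)


def compute_crop(mask: LungMask, target: tuple[int, int] = DEFAULT_TARGET) -> CropGeometry:
    """Pooled axial lung bounding box, fitted into the fixed target.

    The box is padded symmetrically when it fits (scale 1, native
    resolution); otherwise a single aspect-preserving scale
    ``s = min(H/h, W/w) < 1`` shrinks it, the minimal downscaling that fits.
    """
    if not mask.voxels.any():
        raise ValueError("lung mask is empty")
    ys, xs = np.nonzero(mask.voxels.any(axis=0))
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    h, w = y1 - y0, x1 - x0
    H, W = target
    s = min(1.0, H / h, W / w)
    hs = h if s == 1.0 else int(math.floor(h * s + 1e-9))
    ws = w if s == 1.0 else int(math.floor(w * s + 1e-9))
    return CropGeometry(
        y0=y0, y1=y1, x0=x0, x1=x1, scale=s,
        pad_y=(H - hs) // 2, pad_x=(W - ws) // 2, out_h=H, out_w=W,
    )


def filter_slices(
    labels: LabelMap, mask: LungMask, tau: float = 0.01
) -> tuple[list[int], np.ndarray]:
    """Retain axial slices whose lung area is at least ``tau`` pathological.

    The per-slice pathology fraction is (#lung voxels with class 2..5) /
    (#lung voxels in the slice). Slices are retained iff the fraction is
    >= tau (ties at exactly tau retained); slices without lung are never
    retained. Returns (retained slice indices, per-slice fractions).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold tau={tau} outside [0, 1]")
    check_aligned(labels, mask, "labels", "mask")
    m = mask.bool
    lung_per_slice = m.sum(axis=(1, 2))
    path_per_slice = ((labels.voxels >= 2) & m).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(lung_per_slice > 0, path_per_slice / np.maximum(lung_per_slice, 1), 0.0)
    retained = np.flatnonzero((lung_per_slice > 0) & (frac >= tau))
    return retained.tolist(), frac.astype(float)


@dataclass
class SlicePlan:
    """Training-set construction record for one case."""

    case_id: str
    crop: CropGeometry
    retained: list[int]
    fractions: list[float]
    tau: float = 0.01

    def to_dict(self) -> dict:
        d = asdict(self)
        d["crop"] = asdict(self.crop)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SlicePlan":
        d = dict(d)
        d["crop"] = CropGeometry(**d["crop"])
        return cls(**d)

    @staticmethod
    def save_many(plans: Sequence["SlicePlan"], path) -> None:
        with open(path, "w") as fh:
            json.dump([p.to_dict() for p in plans], fh, indent=1)

    @staticmethod
    def load_many(path) -> list["SlicePlan"]:
        with open(path) as fh:
            return [SlicePlan.from_dict(d) for d in json.load(fh)]


def plan_case(
    case: PhantomCase, target: tuple[int, int] = DEFAULT_TARGET, tau: float = 0.01
) -> SlicePlan:
    crop = compute_crop(case.lung_mask, target)
    retained, frac = filter_slices(case.labels, case.lung_mask, tau)
    return SlicePlan(
        case_id=f"{case.patient_id}_t{case.timepoint}",
        crop=crop,
        retained=retained,
        fractions=frac.tolist(),
        tau=tau,
    )


@dataclass
class Sample:
    """One network-ready axial slice with provenance."""

    image: np.ndarray  # (H, W) float32 in [0, 1]
    labels: np.ndarray  # (H, W) int16, {0..5}
    lung: np.ndarray  # (H, W) bool
    case_id: str
    slice_index: int


def make_samples(
    case: PhantomCase,
    plan: SlicePlan,
    window: HUWindow = HUWindow(),
    slices: Iterable[int] | str | None = None,
) -> list[Sample]:
    """Build fixed-size 2D samples for the given slices.

    ``slices`` defaults to the plan's filtered training slices; pass
    ``"all_lung"`` for inference-time samples over every lung-containing
    slice.
    """
    if f"{case.patient_id}_t{case.timepoint}" != plan.case_id:
        raise ValueError(f"plan {plan.case_id} does not match case")
    masked = mask_lungs(case.volume, case.lung_mask)
    if slices is None:
        idx = plan.retained
    elif slices == "all_lung":
        idx = np.flatnonzero(case.lung_mask.voxels.any(axis=(1, 2))).tolist()
    else:
        idx = list(slices)
    geo = plan.crop
    out = []
    for z in idx:
        img = window.normalise(geo.apply_image(masked.voxels[z]))
        lab = geo.apply_labels(case.labels.voxels[z])
        lung = geo.apply_labels(case.lung_mask.voxels[z].astype(np.int16)) > 0
        out.append(Sample(img, lab, lung, plan.case_id, int(z)))
    return out


@dataclass
class ClassFrequencies:
    """Pooled per-class voxel counts/fractions over a named slice set."""

    counts: np.ndarray  # (5,) int, classes 1..5
    slice_set: str

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def as_dict(self) -> dict:
        return {
            "slice_set": self.slice_set,
            **{f"class_{c}": int(n) for c, n in zip(CLASSES, self.counts)},
            **{
                f"class_{c}_fraction": float(f)
                for c, f in zip(CLASSES, self.fractions)
            },
        }


def class_frequencies(
    cases: Sequence[PhantomCase],
    slice_set: str = "all",
    tau: float = 0.01,
) -> ClassFrequencies:
    """Pooled lung-voxel class counts over ``"all"`` or ``"filtered"`` slices."""
    if not cases:
        raise ValueError("need at least one case")
    counts = np.zeros(5, dtype=np.int64)
    any_slice = False
    for case in cases:
        if slice_set == "all":
            zsel = np.arange(case.labels.shape[0])
        elif slice_set == "filtered":
            zsel, _ = filter_slices(case.labels, case.lung_mask, tau)
            zsel = np.asarray(zsel, dtype=int)
        else:
            raise ValueError(f"unknown slice set {slice_set!r}")
        if len(zsel) == 0:
            continue
        any_slice = True
        lab = case.labels.voxels[zsel]
        lung = case.lung_mask.bool[zsel]
        vals = lab[lung]
        counts += np.bincount(vals, minlength=6)[1:6]
    if not any_slice or counts.sum() == 0:
        raise ValueError(f"slice set {slice_set!r} is empty for this cohort")
    return ClassFrequencies(counts, slice_set)


@dataclass
class FoldSplit:
    """Patient -> fold assignment; all time points of a patient share a fold."""

    assignment: dict[str, int]
    n_folds: int

    def fold_patients(self, k: int) -> list[str]:
        return sorted(p for p, f in self.assignment.items() if f == k)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_folds": self.n_folds, "assignment": self.assignment}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "FoldSplit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["assignment"], d["n_folds"])


def split_patients(patient_ids: Sequence[str], K: int = 5, seed: int = 0) -> FoldSplit:
    """Random patient-level K-fold partition with near-equal fold sizes."""
    ids = list(dict.fromkeys(patient_ids))
    if K < 2:
        raise ValueError("need at least 2 folds")
    if K > len(ids):
        raise ValueError(f"K={K} exceeds number of patients ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return FoldSplit({ids[j]: int(i % K) for i, j in enumerate(perm)}, K)


def fixed_split(
    patient_ids: Sequence[str], test_fraction: float = 6 / 46, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Development/hold-out split by patient (test set never revisited)."""
    ids = list(dict.fromkeys(patient_ids))
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = max(1, int(round(len(ids) * test_fraction)))
    if n_test >= len(ids):
        raise ValueError("test fraction leaves no development patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test = sorted(ids[j] for j in perm[:n_test])
    dev = sorted(ids[j] for j in perm[n_test:])
    return dev, test
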