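"""Synthetic longitudinal lung-CT phantom cohorts.

Generates HU-valued volumes with two ellipsoidal lungs embedded in a denser
body, a binary lung mask, and a five-class tissue label map emulating the
statistical structure of radiation-induced lung damage (RILD) cohorts:

* five classes of incrementally increasing density, from normal aerated
  lung (Class 1) through ground-glass (2), ground-glass + reticulation (3)
  and near-solid tissue (4) to dense consolidation (5);
* severe class imbalance (by default ~94% of lung voxels are Class 1);
* damage concentrated in one lung with a smooth spatial gradient, the
  analogue of a focal radiation field;
* lesion volume growing across follow-up time points;
* heterogeneous voxel spacing drawn per volume from clinical CT ranges.

Everything is deterministic given the spec seed: the same spec yields a
bit-identical cohort. The per-class HU statistics are artifact parameters
of this generator (plausible CT physics chosen so classes are separable in
mean but overlap voxel-wise), not measurements from any clinical dataset.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .imaging_io import (
    OUTSIDE,
    CLASSES,
    CTVolume,
    LabelMap,
    LungMask,
    save_labels,
    save_mask,
    save_volume,
)

__all__ = [
    "ClassTexture",
    "PhantomSpec",
    "PhantomCase",
    "class_hu_profile",
    "generate_case",
    "generate_cohort",
    "load_cohort",
    "TIMEPOINT_MONTHS",
]

#: Follow-up schedule analogue: baseline then 3/6/12/24-month scans.
TIMEPOINT_MONTHS = (0, 3, 6, 12, 24)


class ClassTexture(NamedTuple):
    """Per-class HU density model: mean, spread, correlation, texture tag."""

    mean_hu: float
    sd_hu: float
    corr_len_vox: float
    reticulation: bool = False


#: Default density model. Means increase strictly with class id; spreads
#: overlap so neighbouring classes are not separable voxel-by-voxel.
DEFAULT_TEXTURES: dict[int, ClassTexture] = {
    1: ClassTexture(-800.0, 60.0, 1.5),
    2: ClassTexture(-550.0, 60.0, 1.5),
    3: ClassTexture(-450.0, 70.0, 1.5, reticulation=True),
    4: ClassTexture(-200.0, 60.0, 1.5),
    5: ClassTexture(40.0, 50.0, 1.5),
}

#: Lung-volume fraction targets per class, mirroring the severe imbalance
#: regime of RILD cohorts (~94% normal lung).
DEFAULT_CLASS_TARGETS = (0.937, 0.035, 0.003, 0.005, 0.020)


def class_hu_profile(class_id: int) -> ClassTexture:
    """Return the generator's configured density model for one class."""
    if class_id not in DEFAULT_TEXTURES:
        raise ValueError(f"unknown tissue class {class_id!r}; expected 1..5")
    return DEFAULT_TEXTURES[class_id]


@dataclass
class PhantomSpec:
    """Cohort-level generation parameters.

    ``class_volume_targets`` are cohort-mean lung-volume fractions for
    classes 1..5; per-case lesion load is modulated by the follow-up
    multiplier (mean 1 across time points) so the pooled cohort matches
    the targets while lesions grow over time.
    """

    n_patients: int
    timepoints_per_patient: int = 5
    grid_shape: tuple[int, int, int] = (48, 64, 96)  # (z, y, x)
    spacing_range_axial: tuple[float, float] = (0.57, 1.40)
    spacing_range_z: tuple[float, float] = (0.7, 5.0)
    class_volume_targets: tuple[float, ...] = DEFAULT_CLASS_TARGETS
    textures: dict[int, ClassTexture] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.class_volume_targets, dtype=float)
        if t.shape != (5,):
            raise ValueError("class_volume_targets must have 5 entries")
        if np.any(t < 0) or abs(t.sum() - 1.0) > 1e-6:
            raise ValueError("class_volume_targets must be >=0 and sum to 1")
        for rng_ in (self.spacing_range_axial, self.spacing_range_z):
            lo, hi = rng_
            if not (0 < lo <= hi and np.isfinite(hi)):
                raise ValueError(f"implausible spacing range {rng_}")
        if self.n_patients < 1 or self.timepoints_per_patient < 1:
            raise ValueError("need at least one patient and one timepoint")
        means = [self.textures[c].mean_hu for c in CLASSES]
        if not np.all(np.diff(means) > 0):
            raise ValueError("class mean HUs must strictly increase with class id")

    def lesion_multipliers(self) -> np.ndarray:
        """Per-timepoint lesion-load multipliers, normalised to mean 1."""
        n = self.timepoints_per_patient
        if n == 1:
            return np.ones(1)
        m = np.linspace(0.25, 1.75, n)
        return m / m.mean()

    def to_yaml(self, path) -> None:
        d = {
            "n_patients": self.n_patients,
            "timepoints_per_patient": self.timepoints_per_patient,
            "grid_shape": list(self.grid_shape),
            "spacing_range_axial": list(self.spacing_range_axial),
            "spacing_range_z": list(self.spacing_range_z),
            "class_volume_targets": list(map(float, self.class_volume_targets)),
            "textures": {c: list(t) for c, t in self.textures.items()},
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["spacing_range_axial"] = tuple(d["spacing_range_axial"])
        d["spacing_range_z"] = tuple(d["spacing_range_z"])
        d["class_volume_targets"] = tuple(d["class_volume_targets"])
        d["textures"] = {int(c): ClassTexture(*t) for c, t in d["textures"].items()}
        return cls(**d)


@dataclass
class PhantomCase:
    """One synthetic scan: volume + lung mask + label map, aligned."""

    patient_id: str
    timepoint: int
    volume: CTVolume
    lung_mask: LungMask
    labels: LabelMap

    def __post_init__(self):
        if not (
            self.volume.shape == self.lung_mask.shape == self.labels.shape
            and self.volume.spacing == self.lung_mask.spacing == self.labels.spacing
        ):
            raise ValueError("volume, mask and labels must share grid geometry")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _smooth_noise(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated Gaussian field."""
    white = rng.standard_normal(shape)
    sm = gaussian_filter(white, corr_len, mode="nearest")
    return sm / sm.std()


def _preferred_side(patient_id: str) -> int:
    # stable across runs/processes (unlike hash())
    return zlib.crc32(patient_id.encode()) % 2


def _class_counts(k_lesion: int, targets: np.ndarray) -> list[int]:
    """Split k_lesion voxels over classes 2..5 by largest remainder."""
    lesion_frac = targets[1:].sum()
    quota = targets[1:] / lesion_frac * k_lesion
    counts = np.floor(quota).astype(int)
    rem = k_lesion - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def generate_case(
    spec: PhantomSpec, patient_id: str, timepoint: int, seed
) -> PhantomCase:
    """Generate one synthetic scan.

    The lesion (classes 2..5) is painted as concentric severity shells of a
    smooth lateralised weight field — dense consolidation at the core,
    ground-glass at the rim — with total size scaled by the follow-up
    multiplier for ``timepoint``. Class 3 voxels additionally carry a
    zero-mean high-frequency line texture (reticulation analogue).
    """
    nz, ny, nx = spec.grid_shape
    rng = np.random.default_rng(seed)
    if nz < 8 or ny < 16 or nx < 24:
        raise ValueError(
            f"grid {spec.grid_shape} too small to contain two lungs"
        )
    if not 0 <= timepoint < spec.timepoints_per_patient:
        raise ValueError(f"timepoint {timepoint} outside spec schedule")
    mult = spec.lesion_multipliers()[timepoint]
    targets = np.asarray(spec.class_volume_targets, dtype=float)
    lesion_frac = targets[1:].sum() * mult
    if lesion_frac > 1.0:
        raise ValueError(
            f"infeasible targets: lesion fraction {lesion_frac:.3f} exceeds lung volume"
        )

    spacing = (
        float(rng.uniform(*spec.spacing_range_z)),
        float(rng.uniform(*spec.spacing_range_axial)),
        float(rng.uniform(*spec.spacing_range_axial)),
    )

    jit = rng.uniform(0.95, 1.05, size=6)
    body = _ellipsoid(
        spec.grid_shape, (nz / 2, ny / 2, nx / 2), (nz, ny * 0.47, nx * 0.45)
    )
    lungs = np.zeros(spec.grid_shape, dtype=bool)
    sides = []
    for i, cx in enumerate((0.28 * nx, 0.72 * nx)):
        lung = _ellipsoid(
            spec.grid_shape,
            (nz / 2, ny / 2, cx),
            (nz * 0.42 * jit[3 * i], ny * 0.35 * jit[3 * i + 1], nx * 0.17 * jit[3 * i + 2]),
        )
        sides.append(lung)
        lungs |= lung
    if not lungs.any():
        raise ValueError("grid too small: lung ellipsoids are empty")

    # ---- labels: concentric severity shells of a lateralised weight field
    labels = np.full(spec.grid_shape, OUTSIDE, dtype=np.int16)
    labels[lungs] = 1
    n_lung = int(lungs.sum())
    k_lesion = int(round(lesion_frac * n_lung))
    if k_lesion > 0:
        target_lung = sides[_preferred_side(patient_id)]
        zz, yy, xx = np.nonzero(target_lung)
        # field centre: medial-posterior part of the irradiated lung
        fz = float(zz.mean() + 0.15 * nz * rng.uniform(-1, 1))
        fy = float(yy.mean() + 0.20 * ny * rng.uniform(0, 1))
        fx = float(xx.mean())
        gz, gy, gx = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        sigma = (nz * 0.30, ny * 0.25, nx * 0.12)
        weight = np.exp(
            -0.5 * (
                ((gz - fz) / sigma[0]) ** 2
                + ((gy - fy) / sigma[1]) ** 2
                + ((gx - fx) / sigma[2]) ** 2
            )
        )
        weight = weight + 0.15 * _smooth_noise(rng, spec.grid_shape, 3.0)
        # damage stays predominantly in the irradiated lung
        weight[~target_lung] -= 0.8
        flat = np.flatnonzero(lungs)
        order = flat[np.argsort(-weight.ravel()[flat], kind="stable")]
        lesion_idx = order[:k_lesion]
        counts = _class_counts(k_lesion, targets)
        offset = 0
        for cls, k in zip((5, 4, 3, 2), reversed(counts)):
            labels.ravel()[lesion_idx[offset : offset + k]] = cls
            offset += k

    # ---- HU synthesis
    hu = np.full(spec.grid_shape, -1000.0)
    hu[body] = 30.0
    noise = _smooth_noise(rng, spec.grid_shape, DEFAULT_TEXTURES[1].corr_len_vox)
    hu += 20.0 * noise * body  # soft-tissue texture
    for cls in CLASSES:
        tex = spec.textures[cls]
        sel = labels == cls
        if not sel.any():
            continue
        hu[sel] = tex.mean_hu + tex.sd_hu * noise[sel]
        if tex.reticulation:
            gz, gy, gx = np.nonzero(sel)
            ret = 60.0 * np.sin(2 * np.pi * gy / 3.0) * np.sin(2 * np.pi * gx / 3.5)
            hu[sel] += ret
    hu = np.clip(hu, -1024.0, 400.0).astype(np.float32)

    volume = CTVolume(hu, spacing)
    mask = LungMask(lungs.astype(np.uint8), spacing)
    labelmap = LabelMap(labels, spacing)
    return PhantomCase(patient_id, timepoint, volume, mask, labelmap)


def generate_cohort(
    spec: PhantomSpec, out_dir=None
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate ``n_patients x timepoints`` cases plus a manifest table.

    Spacing is drawn independently per volume, so the cohort is
    resolution-heterogeneous. With ``out_dir`` set, volumes/masks/labels
    are written as NIfTI, the manifest as CSV and the spec as YAML.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_patients * spec.timepoints_per_patient)
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        try:
            os.makedirs(out_dir, exist_ok=True)
            probe = os.path.join(out_dir, ".write_probe")
            with open(probe, "w"):
                pass
            os.remove(probe)
        except OSError as e:
            raise OSError(f"output location {out_dir!r} not writable: {e}") from e

    cases, rows = [], []
    i = 0
    for p in range(spec.n_patients):
        patient_id = f"P{p:03d}"
        for t in range(spec.timepoints_per_patient):
            case = generate_case(spec, patient_id, t, children[i])
            i += 1
            cases.append(case)
            row = {
                "patient_id": patient_id,
                "timepoint": t,
                "timepoint_months": TIMEPOINT_MONTHS[t]
                if t < len(TIMEPOINT_MONTHS)
                else TIMEPOINT_MONTHS[-1],
                "spacing_z": case.volume.spacing[0],
                "spacing_y": case.volume.spacing[1],
                "spacing_x": case.volume.spacing[2],
                "volume_path": "",
                "mask_path": "",
                "labels_path": "",
            }
            if out_dir is not None:
                stem = f"{patient_id}_t{t}"
                vp = os.path.join(out_dir, f"{stem}_ct.nii.gz")
                mp = os.path.join(out_dir, f"{stem}_lungmask.nii.gz")
                lp = os.path.join(out_dir, f"{stem}_labels.nii.gz")
                save_volume(case.volume, vp)
                save_mask(case.lung_mask, case.volume, mp)
                save_labels(case.labels, case.volume, lp)
                row.update(volume_path=vp, mask_path=mp, labels_path=lp)
            rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        spec.to_yaml(os.path.join(out_dir, "phantom_spec.yaml"))
    return cases, manifest


def load_cohort(data_dir) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Load a written cohort back from its manifest directory."""
    from .imaging_io import load_case

    data_dir = os.fspath(data_dir)
    manifest = pd.read_csv(os.path.join(data_dir, "manifest.csv"))
    cases = []
    for row in manifest.itertuples():
        volume, mask, labels = load_case(row.volume_path, row.mask_path, row.labels_path)
        cases.append(
            PhantomCase(str(row.patient_id), int(row.timepoint), volume, mask, labels)
        )
    return cases, manifest
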