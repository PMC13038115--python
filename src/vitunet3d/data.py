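"""Multimodal MRI case handling and synthetic tumor phantoms.

A *case* is four co-registered 3D modalities (T1, T1ce, T2, FLAIR) plus an
integer label volume with the BraTS class convention {0 background,
1 necrotic/non-enhancing core, 2 peritumoral edema, 4 enhancing tumor}.
This module covers the standard preprocessing chain — modality stacking
(T1ce/T2/FLAIR channels; T1 dropped), center or tumor-centered cropping,
minimum-tumor-fraction filtering, case-level train/validation and k-fold
splitting — NIfTI round-tripping with the ``<case>_<modality>.nii.gz``
naming convention, and a phantom generator that emulates the layout with
nested ellipsoidal tumor sub-regions so every pipeline stage can be
exercised without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MODALITIES",
    "CaseRecord",
    "PhantomSpec",
    "generate_phantom",
    "generate_phantom_suite",
    "stack_modalities",
    "normalize_channels",
    "crop_volume",
    "tumor_fraction",
    "tumor_fraction_filter",
    "split_cases",
    "kfold_splits",
    "save_case",
    "load_case",
    "save_labels",
    "load_labels",
    "write_split_manifest",
    "LABEL_TO_CLASS",
    "CLASS_TO_LABEL",
    "remap_labels",
]

MODALITIES = ("t1", "t1ce", "t2", "flair")
STACK_ORDER = ("t1ce", "t2", "flair")

# BraTS labels {0,1,2,4} <-> dense class indices {0,1,2,3}
LABEL_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
CLASS_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.int16)


def remap_labels(labels: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Map {0,1,2,4} -> {0,1,2,3} (or back with ``inverse=True``)."""
    labels = np.asarray(labels)
    if inverse:
        return CLASS_TO_LABEL[labels]
    out = np.zeros_like(labels, dtype=np.int16)
    for lab, cls in LABEL_TO_CLASS.items():
        out[labels == lab] = cls
    return out


@dataclass
class CaseRecord:
    """One multimodal case sharing a single voxel geometry."""

    case_id: str
    modalities: dict[str, np.ndarray]
    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shapes = {m: v.shape for m, v in self.modalities.items()}
        shapes["labels"] = self.labels.shape
        if len(set(shapes.values())) != 1:
            raise ValueError(f"geometry mismatch across grids: {shapes}")
        missing = set(MODALITIES) - set(self.modalities)
        if missing:
            raise ValueError(f"missing modalities: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic tumor phantom: nested ellipsoids in a noisy brain volume.

    The whole tumor is an ellipsoid occupying ``tumor_fraction`` of the grid;
    inside it, the enhancing shell starts at ``shell_scale`` and the necrotic
    core ends at ``core_scale`` of the outer radii, so labels nest as
    NCR/NET core (1) ⊂ enhancing shell (4) ⊂ edema halo (2).  Modality
    intensities follow qualitative MRI contrast (edema bright on T2/FLAIR,
    enhancing rim bright on T1ce) with additive Gaussian noise.
    """

    extents: tuple[int, int, int] = (64, 64, 64)
    tumor_fraction: float = 0.05
    core_scale: float = 0.4
    shell_scale: float = 0.65
    anisotropy: tuple[float, float, float] = (1.0, 1.2, 0.85)
    noise_sigma: float = 0.1
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    # (background, NCR/NET, edema, enhancing) mean intensity per modality
    intensities: dict = field(default_factory=lambda: {
        "t1": (1.0, 0.55, 0.8, 0.9),
        "t1ce": (1.0, 0.5, 0.85, 1.8),
        "t2": (1.0, 1.2, 1.7, 1.25),
        "flair": (1.0, 1.1, 1.9, 1.3),
    })


def _ellipsoid_radii(spec: PhantomSpec) -> np.ndarray:
    target = spec.tumor_fraction * float(np.prod(spec.extents))
    aniso = np.asarray(spec.anisotropy, dtype=float)
    base = (target * 3.0 / (4.0 * np.pi * float(np.prod(aniso)))) ** (1.0 / 3.0)
    return base * aniso


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> CaseRecord:
    """Deterministic (per seed) synthetic case with BraTS-style labels."""
    rng = np.random.default_rng(spec.seed)
    radii = _ellipsoid_radii(spec)
    ext = np.asarray(spec.extents)
    if (2 * radii >= ext).any():
        raise ValueError(
            f"tumor radii {radii} do not fit grid {spec.extents}")
    lo = radii + 1
    hi = ext - radii - 1
    center = lo + rng.random(3) * (hi - lo)

    zz, yy, xx = np.meshgrid(*(np.arange(e) for e in spec.extents),
                             indexing="ij")
    rho = np.sqrt(((zz - center[0]) / radii[0]) ** 2
                  + ((yy - center[1]) / radii[1]) ** 2
                  + ((xx - center[2]) / radii[2]) ** 2)
    labels = np.zeros(spec.extents, dtype=np.int16)
    labels[rho <= 1.0] = 2                 # edema halo
    labels[rho <= spec.shell_scale] = 4    # enhancing shell
    labels[rho <= spec.core_scale] = 1     # necrotic core

    modalities = {}
    for mod in MODALITIES:
        means = spec.intensities[mod]
        vol = np.full(spec.extents, means[0], dtype=np.float64)
        vol[labels == 1] = means[1]
        vol[labels == 2] = means[2]
        vol[labels == 4] = means[3]
        vol += rng.normal(0.0, spec.noise_sigma, size=spec.extents)
        modalities[mod] = vol
    return CaseRecord(case_id=f"phantom{spec.seed:04d}", modalities=modalities,
                      labels=labels, spacing=spec.spacing)


def generate_phantom_suite(n_cases: int, seed: int = 0,
                           base: PhantomSpec = PhantomSpec()) -> list[CaseRecord]:
    """A suite of phantoms with varied tumor fraction, seeded from ``seed``."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        frac = base.tumor_fraction * float(rng.uniform(0.5, 1.5))
        spec = PhantomSpec(
            extents=base.extents, tumor_fraction=frac,
            core_scale=base.core_scale, shell_scale=base.shell_scale,
            anisotropy=base.anisotropy, noise_sigma=base.noise_sigma,
            spacing=base.spacing, seed=int(rng.integers(2 ** 31)),
            intensities=base.intensities)
        case = generate_phantom(spec)
        cases.append(CaseRecord(case_id=f"phantom{i:04d}",
                                modalities=case.modalities,
                                labels=case.labels, spacing=case.spacing))
    return cases


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def stack_modalities(case: CaseRecord) -> np.ndarray:
    """Stack (T1ce, T2, FLAIR) into a (3, D, H, W) volume; T1 is excluded."""
    return np.stack([np.asarray(case.modalities[m], dtype=np.float64)
                     for m in STACK_ORDER], axis=0)


def normalize_channels(x: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-channel z-score over nonzero voxels of a (C, D, H, W) volume."""
    x = np.asarray(x, dtype=np.float64).copy()
    for c in range(x.shape[0]):
        nz = x[c] != 0
        if nz.any():
            mu, sd = x[c][nz].mean(), x[c][nz].std()
            x[c] = (x[c] - mu) / (sd + eps)
    return x


def crop_volume(x: np.ndarray, labels: np.ndarray,
                size: tuple[int, int, int] = (128, 128, 128),
                mode: str = "center") -> tuple[np.ndarray, np.ndarray]:
    """Jointly crop an image (C, D, H, W) or (D, H, W) and its labels.

    ``center`` crops around the volume center; ``tumor`` around the tumor
    centroid (clipped so the crop stays inside the volume).
    """
    labels = np.asarray(labels)
    x = np.asarray(x)
    spatial = x.shape[-3:]
    if labels.shape != spatial:
        raise ValueError(f"label shape {labels.shape} != image spatial {spatial}")
    if any(s < c for s, c in zip(spatial, size)):
        raise ValueError(f"input extents {spatial} smaller than crop {size}")
    if mode == "center":
        centroid = [s / 2 for s in spatial]
    elif mode == "tumor":
        fg = np.argwhere(labels != 0)
        centroid = fg.mean(axis=0) + 0.5 if len(fg) else [s / 2 for s in spatial]
    else:
        raise ValueError(f"unknown crop mode: {mode}")
    starts = []
    for c, s, k in zip(centroid, spatial, size):
        start = int(round(c - k / 2))
        starts.append(min(max(start, 0), s - k))
    sl = tuple(slice(a, a + k) for a, k in zip(starts, size))
    return x[(..., *sl)], labels[sl]


def tumor_fraction(labels: np.ndarray) -> float:
    labels = np.asarray(labels)
    return float((labels != 0).sum()) / labels.size


def tumor_fraction_filter(cases: list[CaseRecord],
                          threshold: float = 0.01) -> list[CaseRecord]:
    """Keep cases whose tumor voxel fraction is >= threshold (inclusive)."""
    return [c for c in cases if tumor_fraction(c.labels) >= threshold]


def split_cases(cases: list[CaseRecord], ratio: float = 0.75,
                seed: int = 0) -> tuple[list[CaseRecord], list[CaseRecord]]:
    """Seeded, disjoint, exhaustive case-level split; |train| = round(r*n)."""
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split")
    order = np.random.default_rng(seed).permutation(len(cases))
    n_train = int(round(ratio * len(cases)))
    train_idx = set(order[:n_train].tolist())
    train = [c for i, c in enumerate(cases) if i in train_idx]
    val = [c for i, c in enumerate(cases) if i not in train_idx]
    return train, val


def kfold_splits(cases: list[CaseRecord], k: int = 4, seed: int = 0
                 ) -> list[tuple[list[CaseRecord], list[CaseRecord]]]:
    """k seeded folds; every case validates in exactly one fold."""
    if len(cases) < k:
        raise ValueError(f"need >= {k} cases for {k}-fold splitting")
    order = np.random.default_rng(seed).permutation(len(cases))
    folds = np.array_split(order, k)
    out = []
    for f in folds:
        val_idx = set(f.tolist())
        train = [c for i, c in enumerate(cases) if i not in val_idx]
        val = [c for i, c in enumerate(cases) if i in val_idx]
        out.append((train, val))
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_case(case: CaseRecord, directory: str | Path,
              compress: bool = False) -> Path:
    """Write ``<case>_<modality>.nii[.gz]`` plus ``<case>_seg`` labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    aff = _affine(case.spacing)
    for mod in MODALITIES:
        img = nib.Nifti1Image(np.asarray(case.modalities[mod],
                                         dtype=np.float32), aff)
        nib.save(img, directory / f"{case.case_id}_{mod}{ext}")
    seg = nib.Nifti1Image(np.asarray(case.labels, dtype=np.int16), aff)
    nib.save(seg, directory / f"{case.case_id}_seg{ext}")
    return directory


def _find(directory: Path, stem: str) -> Path:
    for ext in (".nii", ".nii.gz"):
        p = directory / f"{stem}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no NIfTI file for {stem} in {directory}")


def load_case(directory: str | Path, case_id: str) -> CaseRecord:
    directory = Path(directory)
    modalities = {}
    spacing = (1.0, 1.0, 1.0)
    for mod in MODALITIES:
        img = nib.load(_find(directory, f"{case_id}_{mod}"))
        modalities[mod] = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    seg = nib.load(_find(directory, f"{case_id}_seg"))
    labels = np.asarray(seg.dataobj).astype(np.int16)
    return CaseRecord(case_id=case_id, modalities=modalities, labels=labels,
                      spacing=spacing)


def save_labels(labels: np.ndarray, path: str | Path,
                spacing=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16),
                             _affine(spacing)), path)
    return path


def load_labels(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj).astype(np.int16), spacing


def write_split_manifest(splits: dict[str, list[CaseRecord]],
                         path: str | Path) -> pd.DataFrame:
    """CSV manifest mapping case id -> split name."""
    rows = [{"case_id": c.case_id, "split": name,
             "tumor_fraction": tumor_fraction(c.labels)}
            for name, cases in splits.items() for c in cases]
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df
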