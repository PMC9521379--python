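"""NIfTI I/O, per-subject intensity normalization, patch cropping, augmentation.

Arrays are channel-first, spatial axes (row, column), 0-based.  NIfTI files
store one channel per file for images (or a single file with channels in
the last dimension); the affine encodes the voxel spacing and is passed
through unchanged on write.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass
class VolumeRecord:
    image: np.ndarray           # (channels, H, W)
    label: np.ndarray           # (H, W) binary
    spacing: tuple[float, ...] = (1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape[1:] != self.label.shape:
            raise ValueError(
                f"image spatial shape {self.image.shape[1:]} != label shape {self.label.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        vals = np.unique(self.label)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"label must be binary, found values {vals}")


# -- NIfTI -------------------------------------------------------------

def write_nifti(path, array: np.ndarray, spacing=(1.0, 1.0)) -> None:
    """Write a 2D (H,W) or channel-first (C,H,W) array; channels go last."""
    arr = np.asarray(array)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, 0, -1)
    affine = np.diag(list(spacing[:2]) + [1.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float]]:
    """Read back as (C,H,W) or (H,W); returns (array, spacing)."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    zooms = img.header.get_zooms()
    return arr, (float(zooms[0]), float(zooms[1]))


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_records(manifest_path, label_col: str = "label") -> list[VolumeRecord]:
    """Load every sample referenced by a dataset manifest TSV."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    records = []
    for _, row in df.iterrows():
        image, spacing = read_nifti(root / row["image"])
        if image.ndim == 2:
            image = image[None]
        label, _ = read_nifti(root / row[label_col])
        records.append(VolumeRecord(image=image.astype(np.float32),
                                    label=label.astype(np.uint8),
                                    spacing=spacing, subject_id=str(row["sample_id"])))
    return records


# -- normalization -----------------------------------------------------

def gaussian_normalize(volume: np.ndarray) -> np.ndarray:
    """Standardize each channel to zero mean, unit SD (per subject).

    Raises on a constant channel, which cannot be standardized.
    """
    vol = np.asarray(volume, dtype=np.float64)
    single = vol.ndim == 2
    if single:
        vol = vol[None]
    out = np.empty_like(vol)
    for c in range(vol.shape[0]):
        sd = vol[c].std()
        if sd == 0:
            raise ValueError(f"channel {c} is constant and cannot be normalized")
        out[c] = (vol[c] - vol[c].mean()) / sd
    out = out.astype(np.float32)
    return out[0] if single else out


# -- cropping ----------------------------------------------------------

def random_crop(record: VolumeRecord, patch_shape: tuple[int, int], seed: int,
                mask: np.ndarray | None = None,
                lesion_biased: bool = False,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut one (image, label, supervision-mask) patch at a shared random offset.

    With ``lesion_biased`` the offset is re-drawn (up to 10 times) until the
    label patch contains foreground, when any exists.  A missing mask is
    treated as all-ones (full supervision).
    """
    ph, pw = patch_shape
    _, h, w = record.image.shape
    if ph > h or pw > w:
        raise ValueError(f"patch shape {patch_shape} exceeds image shape {(h, w)}")
    if mask is None:
        mask = np.ones_like(record.label)
    rng = np.random.default_rng(seed)
    tries = 10 if (lesion_biased and record.label.any()) else 1
    for _ in range(tries):
        oy = int(rng.integers(0, h - ph + 1))
        ox = int(rng.integers(0, w - pw + 1))
        lab = record.label[oy:oy + ph, ox:ox + pw]
        if lab.any() or tries == 1:
            break
    return (record.image[:, oy:oy + ph, ox:ox + pw],
            lab,
            mask[oy:oy + ph, ox:ox + pw])


# -- augmentation ------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    flip_prob: float = 0.5       # vertical (axis 0) flip
    mirror_prob: float = 0.5     # horizontal (axis 1) flip ("mirroring")
    rotate: bool = True          # right-angle rotation, uniform over {0,90,180,270}
    continuous_rotation: bool = False   # ±15° with nearest-neighbour labels
    max_angle: float = 15.0


def augment(image: np.ndarray, label: np.ndarray, mask: np.ndarray, seed: int,
            config: AugmentConfig = AugmentConfig(),
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one random flip/rotate/mirror transform jointly to all three arrays.

    The default right-angle mode is lossless: labels and masks stay binary
    and the multiset of label values is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    do_flip = rng.random() < config.flip_prob
    do_mirror = rng.random() < config.mirror_prob
    k = int(rng.integers(0, 4)) if config.rotate else 0
    angle = rng.uniform(-config.max_angle, config.max_angle) if config.continuous_rotation else 0.0

    def tf(a: np.ndarray, order: int) -> np.ndarray:
        spatial_from = a.ndim - 2
        if do_flip:
            a = np.flip(a, axis=spatial_from)
        if do_mirror:
            a = np.flip(a, axis=spatial_from + 1)
        if k:
            a = np.rot90(a, k=k, axes=(spatial_from, spatial_from + 1))
        if angle:
            from scipy import ndimage
            a = ndimage.rotate(a, angle, axes=(spatial_from + 1, spatial_from),
                               reshape=False, order=order, mode="nearest")
        return np.ascontiguousarray(a)

    return tf(image, 1), tf(label, 0), tf(mask, 0)
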