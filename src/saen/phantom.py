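"""Synthetic 2-channel lesion phantoms with boundary-concentrated label noise.

The generator emulates the annotation-uncertainty structure of white matter
hyperintensity data: "periventricular" lesions are bright blobs with sharp
edges placed in a central vertical band (where raters are reliable), while
"deep" lesions are placed elsewhere and get Gaussian-blurred intensity
ramps (ambiguous edges).  The observed annotation differs from the clean
label by a smooth, correlated displacement of the lesion boundary —
thresholding the clean label's signed distance transform at a clipped
Gaussian random field — so disagreements concentrate in a band around
lesion boundaries, like rater error, never as isolated pixel flips.

Channel 0 plays the role of FLAIR (full lesion contrast); channel 1 plays
T1 and carries the same lesions at half amplitude, so multi-channel input
is informative but redundant.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

LesionKind = Literal["periventricular", "deep"]


@dataclass(frozen=True)
class PhantomConfig:
    image_height: int = 64
    image_width: int = 64
    n_channels: int = 2
    n_periventricular: int = 1
    n_deep: int = 2
    lesion_radius_range: tuple[float, float] = (3.0, 7.0)
    boundary_blur_sigma: float = 1.5
    annotation_jitter_sigma: float = 1.5
    noise_sd: float = 0.3
    lesion_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_periventricular < 0 or self.n_deep < 0:
            raise ValueError("lesion counts must be >= 0")
        rmin, rmax = self.lesion_radius_range
        if rmin > rmax or rmin <= 0:
            raise ValueError(f"invalid lesion_radius_range {self.lesion_radius_range}")
        if self.boundary_blur_sigma < 0 or self.annotation_jitter_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Lesion:
    centroid: tuple[float, float]
    radius: float
    kind: LesionKind


@dataclass
class PhantomSample:
    image: np.ndarray            # (channels, H, W) float32
    clean_label: np.ndarray      # (H, W) uint8
    observed_label: np.ndarray   # (H, W) uint8
    lesion_inventory: list[Lesion] = field(default_factory=list)
    sample_id: str = ""


def _lesion_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                 angle: float, warp_amp: float, warp_freq: int,
                 warp_phase: float) -> np.ndarray:
    """Binary ellipse with a low-frequency sinusoidal boundary perturbation."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    r = np.hypot(u, v)
    phi = np.arctan2(v, u)
    boundary = 1.0 + warp_amp * np.sin(warp_freq * phi + warp_phase)
    return r <= boundary


def _max_extent(radius: float, warp_amp: float) -> float:
    return radius * (1.0 + warp_amp)


def _place_lesions(cfg: PhantomConfig, rng: np.random.Generator) -> list[dict]:
    h, w = cfg.image_height, cfg.image_width
    rmin, rmax = cfg.lesion_radius_range
    margin = 2.0  # keep lesions off the image border
    specs = []
    band_half = max(2.0, w / 8.0)
    for kind, count in (("periventricular", cfg.n_periventricular), ("deep", cfg.n_deep)):
        for _ in range(count):
            radius = rng.uniform(rmin, rmax)
            warp_amp = rng.uniform(0.0, 0.15)
            ext = _max_extent(radius, warp_amp) + margin
            if 2 * ext >= h:
                raise ValueError(
                    f"lesion of radius {radius:.1f} cannot fit image_height={h}"
                )
            if 2 * ext >= w:
                raise ValueError(
                    f"lesion of radius {radius:.1f} cannot fit image_width={w}"
                )
            cy = rng.uniform(ext, h - ext)
            if kind == "periventricular":
                lo = max(ext, w / 2.0 - band_half)
                hi = min(w - ext, w / 2.0 + band_half)
                if lo >= hi:
                    raise ValueError(
                        f"periventricular band too narrow for image_width={w}"
                    )
                cx = rng.uniform(lo, hi)
            else:
                cx = rng.uniform(ext, w - ext)
            aspect = rng.uniform(0.6, 1.0)
            specs.append(dict(
                kind=kind, cy=cy, cx=cx, ry=radius, rx=radius * aspect,
                angle=rng.uniform(0, np.pi), warp_amp=warp_amp,
                warp_freq=int(rng.integers(2, 6)), warp_phase=rng.uniform(0, 2 * np.pi),
                radius=radius,
            ))
    return specs


def _jitter_label(clean: np.ndarray, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Displace the label boundary by a smooth clipped Gaussian field.

    The signed distance to the clean boundary (negative inside) is
    re-thresholded at a correlated random field whose amplitude is clipped
    to 3*sigma - 1, which confines all label changes to a band of width
    <= 3*sigma around the clean boundary and preserves deep interior and
    far background pixels.
    """
    if sigma == 0 or not clean.any() or clean.all():
        return clean.copy()
    inside = ndimage.distance_transform_edt(clean)
    outside = ndimage.distance_transform_edt(1 - clean)
    sdt = outside - inside  # <= 0 inside the lesion
    white = rng.normal(size=clean.shape)
    smooth = ndimage.gaussian_filter(white, sigma=4.0, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return clean.copy()
    bound = max(0.0, 3.0 * sigma - 1.0)
    disp = np.clip(smooth / sd * sigma, -bound, bound)
    return (sdt <= disp).astype(np.uint8)


def generate_sample(config: PhantomConfig, seed: int) -> PhantomSample:
    """Generate one phantom; bit-identical for a fixed (config, seed)."""
    rng = np.random.default_rng(seed)
    h, w, c = config.image_height, config.image_width, config.n_channels
    specs = _place_lesions(config, rng)

    clean = np.zeros((h, w), dtype=np.uint8)
    intensity = np.zeros((h, w), dtype=np.float64)
    inventory: list[Lesion] = []
    for s in specs:
        mask = _lesion_mask(h, w, s["cy"], s["cx"], s["ry"], s["rx"],
                            s["angle"], s["warp_amp"], s["warp_freq"], s["warp_phase"])
        if s["kind"] == "deep" and config.boundary_blur_sigma > 0:
            ramp = ndimage.gaussian_filter(mask.astype(np.float64),
                                           sigma=config.boundary_blur_sigma)
            label = ramp >= 0.5
            intensity = np.maximum(intensity, ramp)
        else:
            label = mask
            intensity = np.maximum(intensity, mask.astype(np.float64))
        clean |= label.astype(np.uint8)
        inventory.append(Lesion(centroid=(s["cy"], s["cx"]), radius=s["radius"],
                                kind=s["kind"]))

    observed = _jitter_label(clean, config.annotation_jitter_sigma, rng)

    # smooth background field + channel-wise lesion contrast + sensor noise
    bg = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=12.0, mode="reflect")
    bg_sd = bg.std()
    bg = 0.2 * bg / bg_sd if bg_sd > 0 else np.zeros_like(bg)
    amp = config.lesion_amplitude
    image = np.empty((c, h, w), dtype=np.float32)
    for ch in range(c):
        contrast = amp if ch == 0 else amp / 2.0
        image[ch] = (bg + contrast * intensity
                     + config.noise_sd * rng.normal(size=(h, w))).astype(np.float32)
    return PhantomSample(image=image, clean_label=clean, observed_label=observed,
                         lesion_inventory=inventory)


def generate_dataset(config: PhantomConfig, n_samples: int, seed: int) -> list[PhantomSample]:
    """Generate n independent phantoms with per-sample seeds spawned from ``seed``."""
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_samples)
    samples = []
    for i, s in enumerate(child_seeds):
        smp = generate_sample(config, int(s))
        smp.sample_id = f"phantom_{i:04d}"
        samples.append(smp)
    return samples


def export_dataset(samples: list[PhantomSample], out_dir, spacing=(1.0, 1.0)) -> Path:
    """Write each sample as NIfTI files plus a TSV manifest; return manifest path."""
    from . import io_preprocess as iop

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for smp in samples:
        sid = smp.sample_id or f"phantom_{len(rows):04d}"
        img_path = out / f"{sid}_image.nii"
        lab_path = out / f"{sid}_label.nii"
        clean_path = out / f"{sid}_clean.nii"
        iop.write_nifti(img_path, smp.image, spacing)
        iop.write_nifti(lab_path, smp.observed_label, spacing)
        iop.write_nifti(clean_path, smp.clean_label, spacing)
        n_pv = sum(1 for l in smp.lesion_inventory if l.kind == "periventricular")
        n_deep = sum(1 for l in smp.lesion_inventory if l.kind == "deep")
        rows.append(dict(sample_id=sid, image=img_path.name, label=lab_path.name,
                         clean_label=clean_path.name, n_periventricular=n_pv,
                         n_deep=n_deep))
    import pandas as pd

    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
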