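"""Synthetic CT-like phantom slices with known liver and tumor masks.

Each phantom is a pseudo-Hounsfield-unit image containing one elliptical
"liver" (bright, ~100 HU), optionally an inset darker "tumor" (~50 HU),
a handful of confounding "organ" ellipses of liver-like intensity placed
outside the liver, a sub-zero background, and additive Gaussian pixel
noise.  Ground-truth liver/tumor masks are analytic, so every downstream
stage (windowing, superpixel embedding, graph training, metrics) can be
tested without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from skimage.draw import ellipse

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_dataset",
    "export_dataset",
]

# reference tissue sd: at liver_sd == tumor_sd == 10 the in-tissue pixel
# noise equals pixel_noise_sd exactly
_REFERENCE_SD = 10.0


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom population.

    Intensities are pseudo-HU chosen so that windowing to [0, 150] keeps
    liver and tumor visible and zeroes the background.  ``liver_sd`` /
    ``tumor_sd`` scale the in-tissue pixel noise relative to
    ``pixel_noise_sd`` (sd inside a tissue = pixel_noise_sd * tissue_sd / 10),
    so ``pixel_noise_sd = 0`` yields a noiseless piecewise-constant image.
    Axes ranges default to fractions of the image side.
    """

    height: int = 96
    width: int = 96
    liver_axes_range: tuple[float, float] | None = None
    tumor_axes_range: tuple[float, float] | None = None
    liver_mean: float = 100.0
    liver_sd: float = 10.0
    tumor_mean: float = 50.0
    tumor_sd: float = 10.0
    background_mean: float = -40.0
    organ_count: int = 3
    organ_mean: float = 110.0
    pixel_noise_sd: float = 5.0
    tumor_probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom images must be at least 32x32")
        if not 0.0 <= self.tumor_probability <= 1.0:
            raise ValueError("tumor_probability must lie in [0, 1]")
        if self.organ_count < 0:
            raise ValueError("organ_count must be >= 0")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        m = min(self.height, self.width)
        if self.liver_axes_range is None:
            object.__setattr__(self, "liver_axes_range", (0.18 * m, 0.30 * m))
        if self.tumor_axes_range is None:
            object.__setattr__(self, "tumor_axes_range", (0.06 * m, 0.11 * m))
        lo_l, hi_l = self.liver_axes_range
        lo_t, hi_t = self.tumor_axes_range
        if not (0 < lo_l <= hi_l) or not (0 < lo_t <= hi_t):
            raise ValueError("axes ranges must be positive and ordered")
        if hi_t >= lo_l:
            raise ValueError("tumor axes must be strictly smaller than liver axes")
        if 2 * hi_l > m:
            raise ValueError("liver axes do not fit within the image bounds")


@dataclass(frozen=True)
class PhantomCase:
    """One phantom slice with its analytic ground truth."""

    image: np.ndarray
    liver_mask: np.ndarray
    tumor_mask: np.ndarray
    case_id: str

    def __post_init__(self) -> None:
        if not (self.image.shape == self.liver_mask.shape == self.tumor_mask.shape):
            raise ValueError("image and masks must share one shape")
        if np.any(self.tumor_mask & ~self.liver_mask):
            raise ValueError("tumor mask must be contained in the liver mask")

    @property
    def label_mask(self) -> np.ndarray:
        """Combined integer mask: 0 background, 1 liver, 2 tumor."""
        out = np.zeros(self.image.shape, dtype=np.int16)
        out[self.liver_mask] = 1
        out[self.tumor_mask] = 2
        return out


def _ellipse_mask(shape: tuple[int, int], center, axes, angle: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = ellipse(center[0], center[1], axes[0], axes[1],
                     shape=shape, rotation=angle)
    mask[rr, cc] = True
    return mask


def generate_phantom(spec: PhantomSpec, case_seed: int) -> PhantomCase:
    """Draw one phantom deterministically from ``(spec, case_seed)``.

    The liver ellipse center, axes and rotation are sampled from the spec
    ranges; a tumor ellipse (present with ``tumor_probability``) is resampled
    until fully inside the liver; confounder organs are placed outside the
    liver.  Raises ``RuntimeError`` if a tumor cannot be fitted after a
    bounded number of retries.
    """
    rng = np.random.default_rng(case_seed)
    h, w = spec.height, spec.width
    shape = (h, w)

    lo, hi = spec.liver_axes_range
    axes = rng.uniform(lo, hi, size=2)
    margin = axes.max() + 2
    center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
    angle = rng.uniform(0, np.pi)
    liver = _ellipse_mask(shape, center, axes, angle)

    tumor = np.zeros(shape, dtype=bool)
    if rng.random() < spec.tumor_probability:
        lo_t, hi_t = spec.tumor_axes_range
        for attempt in range(50):
            t_axes = rng.uniform(lo_t, hi_t, size=2)
            # keep the tumor center well inside the liver ellipse
            u = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0, 0.45)
            off = np.array([r * axes[0] * np.sin(u), r * axes[1] * np.cos(u)])
            c = np.cos(angle), np.sin(angle)
            rot = np.array([[c[0], -c[1]], [c[1], c[0]]])
            t_center = np.asarray(center) + rot @ off
            cand = _ellipse_mask(shape, t_center, t_axes, rng.uniform(0, np.pi))
            if cand.any() and not np.any(cand & ~liver):
                tumor = cand
                break
        else:
            raise RuntimeError(
                "could not fit a tumor inside the sampled liver after 50 tries; "
                "shrink tumor_axes_range or enlarge liver_axes_range"
            )

    organs = np.zeros(shape, dtype=bool)
    m = min(h, w)
    organ_axes_range = (0.05 * m, 0.10 * m)
    placed = 0
    attempts = 0
    while placed < spec.organ_count and attempts < 50 * max(spec.organ_count, 1):
        attempts += 1
        o_axes = rng.uniform(*organ_axes_range, size=2)
        o_margin = o_axes.max() + 1
        o_center = (rng.uniform(o_margin, h - o_margin),
                    rng.uniform(o_margin, w - o_margin))
        cand = _ellipse_mask(shape, o_center, o_axes, rng.uniform(0, np.pi))
        if cand.any() and not np.any(cand & liver):
            organs |= cand
            placed += 1

    image = np.full(shape, spec.background_mean, dtype=np.float64)
    image[organs] = spec.organ_mean
    image[liver] = spec.liver_mean
    image[tumor] = spec.tumor_mean

    if spec.pixel_noise_sd > 0:
        sd = np.full(shape, spec.pixel_noise_sd)
        sd[liver] = spec.pixel_noise_sd * spec.liver_sd / _REFERENCE_SD
        sd[tumor] = spec.pixel_noise_sd * spec.tumor_sd / _REFERENCE_SD
        image = image + rng.normal(0.0, 1.0, size=shape) * sd

    return PhantomCase(image=image, liver_mask=liver, tumor_mask=tumor,
                       case_id=f"phantom-{case_seed:08d}")


def generate_dataset(spec: PhantomSpec, n_cases: int) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms with case seeds ``spec.seed + index``."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    return [generate_phantom(spec, spec.seed + i) for i in range(n_cases)]


def export_dataset(cases: Sequence[PhantomCase], directory: str | Path) -> dict:
    """Write each case as single-slice NIfTI image/mask pair plus a manifest.

    The combined mask uses the 0/1/2 background/liver/tumor convention.
    Returns the manifest (also written as ``manifest.json``) mapping
    case_id -> {image_path, mask_path}.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    affine = np.eye(4)
    for case in cases:
        img_path = directory / f"{case.case_id}_image.nii.gz"
        msk_path = directory / f"{case.case_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(case.image[..., None].astype(np.float64), affine),
                 str(img_path))
        nib.save(nib.Nifti1Image(case.label_mask[..., None].astype(np.int16), affine),
                 str(msk_path))
        manifest[case.case_id] = {"image_path": str(img_path),
                                  "mask_path": str(msk_path)}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
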