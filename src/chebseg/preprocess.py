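"""CT slice preprocessing: NIfTI reading, HU windowing, resizing, masks,
and paired geometric augmentation.

The pipeline mirrors common liver-CT practice: raw Hounsfield intensities
are windowed to the soft-tissue range [0, 150] (values outside set to 0),
normalized to [0, 1], and slices are resized with bilinear interpolation
while masks use nearest-neighbor so they stay boolean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize, rotate

__all__ = [
    "CTVolume",
    "CTSlice",
    "BinaryMask",
    "AugmentationParams",
    "read_ct_volume",
    "hu_window",
    "normalize_intensity",
    "resize_pair",
    "extract_binary_mask",
    "augment",
]

RAW_HU = "raw_hu"
WINDOWED = "windowed"
NORMALIZED = "normalized"


@dataclass(frozen=True)
class CTVolume:
    """Slice-major stack of HU values with voxel spacing in mm."""

    voxels: np.ndarray  # (slices, height, width)
    spacing: tuple[float, float, float]
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("volume must be 3-D with at least one slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")


@dataclass(frozen=True)
class CTSlice:
    pixels: np.ndarray
    intensity_domain: str = RAW_HU

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("slice must be 2-D")
        if self.intensity_domain == NORMALIZED:
            if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
                raise ValueError("normalized slice must lie in [0, 1]")


@dataclass(frozen=True)
class BinaryMask:
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.dtype != bool:
            object.__setattr__(self, "pixels", self.pixels.astype(bool))


@dataclass(frozen=True)
class AugmentationParams:
    """Shared geometric transform: rotation in [0, 20] degrees plus optional
    horizontal flip. ``rotation_degrees=None`` requests uniform sampling."""

    rotation_degrees: float | None = None
    horizontal_flip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_degrees is not None and not 0 <= self.rotation_degrees <= 20:
            raise ValueError("rotation_degrees must lie in [0, 20]")


def read_ct_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI file into a slice-major volume.

    NIfTI stores (height, width, slices); the last axis is moved first.
    2-D payloads are promoted to one-slice volumes.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several internal types
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    while len(zooms) < 3:
        zooms = zooms + (1.0,)
    if data.ndim == 2:
        voxels = data[None, ...]
    elif data.ndim == 3:
        voxels = np.moveaxis(data, -1, 0)
    else:
        raise ValueError(f"expected a 2-D or 3-D NIfTI payload, got {data.ndim}-D")
    return CTVolume(voxels=voxels, spacing=zooms, identifier=path.stem)


def hu_window(ct_slice: CTSlice, low: float = 0.0, high: float = 150.0) -> CTSlice:
    """Window raw HU values: pixels outside [low, high] are replaced by 0."""
    if low > high:
        raise ValueError("window low must not exceed high")
    if ct_slice.intensity_domain != RAW_HU:
        raise ValueError("hu_window expects a raw_hu slice")
    px = ct_slice.pixels
    out = np.where((px >= low) & (px <= high), px, 0.0)
    return CTSlice(pixels=out, intensity_domain=WINDOWED)


def normalize_intensity(ct_slice: CTSlice, divisor: float = 150.0) -> CTSlice:
    """Map windowed intensities onto [0, 1] by dividing by the window width."""
    if ct_slice.intensity_domain != WINDOWED:
        raise ValueError("normalize_intensity expects a windowed slice")
    return CTSlice(pixels=ct_slice.pixels / divisor, intensity_domain=NORMALIZED)


def resize_pair(ct_slice: CTSlice, mask: BinaryMask, target: int = 350
                ) -> tuple[CTSlice, BinaryMask]:
    """Resize a slice (bilinear) and its mask (nearest) to target x target."""
    if target < 8:
        raise ValueError("resize target must be >= 8")
    if ct_slice.pixels.shape != mask.pixels.shape:
        raise ValueError("slice and mask shapes differ")
    img = resize(ct_slice.pixels, (target, target), order=1,
                 anti_aliasing=True, preserve_range=True)
    msk = resize(mask.pixels.astype(float), (target, target), order=0,
                 anti_aliasing=False, preserve_range=True) > 0.5
    if ct_slice.intensity_domain == NORMALIZED:
        img = np.clip(img, 0.0, 1.0)
    return (CTSlice(pixels=img, intensity_domain=ct_slice.intensity_domain),
            BinaryMask(pixels=msk))


def extract_binary_mask(label_mask: np.ndarray, target_label: int) -> BinaryMask:
    """Binary mask for one label of a 0/1/2 background/liver/tumor mask.

    Liver extraction (label 1) includes tumor pixels (label 2) because tumor
    tissue lies within the liver.
    """
    label_mask = np.asarray(label_mask)
    if target_label == 1:
        px = (label_mask == 1) | (label_mask == 2)
    else:
        px = label_mask == target_label
    return BinaryMask(pixels=px)


def augment(ct_slice: CTSlice, mask: BinaryMask, params: AugmentationParams
            ) -> tuple[CTSlice, BinaryMask]:
    """Apply one shared rotation/flip to a slice and its mask.

    Rotation fills the exposed border with 0 (the windowed background value);
    the mask is re-binarized via nearest-neighbor interpolation.
    """
    if ct_slice.pixels.shape != mask.pixels.shape:
        raise ValueError("slice and mask shapes differ")
    angle = params.rotation_degrees
    if angle is None:
        angle = float(np.random.default_rng(params.seed).uniform(0.0, 20.0))
    img = ct_slice.pixels
    msk = mask.pixels
    if params.horizontal_flip:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if angle != 0.0:
        img = rotate(img, angle, resize=False, order=1, mode="constant",
                     cval=0.0, preserve_range=True)
        msk = rotate(msk.astype(float), angle, resize=False, order=0,
                     mode="constant", cval=0.0, preserve_range=True) > 0.5
    if ct_slice.intensity_domain == NORMALIZED:
        img = np.clip(img, 0.0, 1.0)
    return (CTSlice(pixels=np.ascontiguousarray(img),
                    intensity_domain=ct_slice.intensity_domain),
            BinaryMask(pixels=np.ascontiguousarray(msk)))
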