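"""Planning-CT preprocessing: from a CT volume + GTV mask to a model-ready tumor crop.

The preprocessing chain mirrors the standard transfer-learning radiomics
recipe: resample CT and mask to isotropic 1 mm voxels (nearest neighbor),
pick the axial slice with the largest tumor cross-section, cut a
100 mm x 100 mm patch centered on the in-plane tumor center of gravity
(re-centering once on the largest connected component if several tumors fall
inside the patch), blank the non-tumor background with the global minimum CT
value, apply soft-tissue windowing (level 50 HU / width 350 HU) onto [0, 1],
and finally replicate the grayscale patch into three channels resized to the
backbone's input edge length with bilinear interpolation.

Axis convention: arrays are indexed (x, y, z) with axial slices along the
third axis; ``spacing`` is mm per voxel along the same axes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize


class InvalidInputError(ValueError):
    """Raised when an input violates a preprocessing precondition."""


@dataclass(frozen=True)
class CTVolume:
    """A CT voxel grid in Hounsfield units with per-axis spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise InvalidInputError("CTVolume.voxels must be 3D")
        if not np.all(np.isfinite(vox)):
            raise InvalidInputError("CTVolume.voxels must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidInputError("spacings must be positive")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass(frozen=True)
class SegMask:
    """A binary segmentation on the same grid as its paired :class:`CTVolume`."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise InvalidInputError("SegMask.voxels must be 3D")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise InvalidInputError("SegMask values must be in {0, 1}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    ``window_level_hu``/``window_width_hu`` default to the abdominal
    soft-tissue window (50/350 HU); ``crop_size_mm`` to the 100 mm patch;
    ``model_input_px`` is the backbone-specific input edge length.
    """

    target_spacing_mm: float = 1.0
    crop_size_mm: int = 100
    window_level_hu: float = 50.0
    window_width_hu: float = 350.0
    model_input_px: int = 64

    def __post_init__(self) -> None:
        if self.crop_size_mm <= 0:
            raise InvalidInputError("crop_size_mm must be positive")
        if self.window_width_hu <= 0:
            raise InvalidInputError("window_width_hu must be positive")
        if self.target_spacing_mm <= 0:
            raise InvalidInputError("target_spacing_mm must be positive")


@dataclass(frozen=True)
class TumorCrop:
    """Model-ready 2D patch: three identical channels, values in [0, 1]."""

    pixels: np.ndarray  # (H, W, 3)
    slice_index: int
    center_mm: tuple[float, float]
    resize_px: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInputError("TumorCrop.pixels must be (H, W, 3)")
        object.__setattr__(self, "pixels", px)


def resample_isotropic(
    vol: CTVolume, mask: SegMask, cfg: PreprocessConfig | None = None
) -> tuple[CTVolume, SegMask]:
    """Resample CT and mask to an isotropic grid with nearest-neighbor sampling.

    The output grid is anchored at the input origin and covers the input
    physical extent: axis ``a`` with ``n`` voxels at spacing ``s`` maps to
    ``round(n * s / t)`` voxels at target spacing ``t``.  Output voxel
    centers at ``(j + 0.5) * t`` are filled from the input voxel whose
    cell ``[i*s, (i+1)*s)`` contains that position.
    """
    cfg = cfg or PreprocessConfig()
    if mask.voxels.shape != vol.voxels.shape:
        raise InvalidInputError("mask shape must equal volume shape")
    t = cfg.target_spacing_mm
    if tuple(vol.spacing) == (t, t, t):
        return vol, mask
    idx = []
    for n, s in zip(vol.voxels.shape, vol.spacing):
        n_out = max(1, int(round(n * s / t)))
        centers = (np.arange(n_out) + 0.5) * t
        src = np.clip(np.floor(centers / s).astype(int), 0, n - 1)
        idx.append(src)
    grid = np.ix_(*idx)
    out_vol = CTVolume(vol.voxels[grid], (t, t, t))
    out_mask = SegMask(mask.voxels[grid])
    return out_vol, out_mask


def select_max_area_slice(mask: SegMask) -> int:
    """Index of the axial slice with the largest foreground area (ties -> lowest)."""
    if mask.n_foreground == 0:
        raise InvalidInputError("mask is empty")
    areas = mask.voxels.sum(axis=(0, 1))
    return int(np.argmax(areas))  # argmax returns the first (lowest) maximizer


def _round_half_down(x: float) -> int:
    # deterministic tie policy: exact .5 rounds toward the lower index
    return int(np.ceil(x - 0.5))


def _centroid_px(mask2d: np.ndarray) -> tuple[int, int]:
    coords = np.argwhere(mask2d > 0)
    cy, cx = coords.mean(axis=0)
    return _round_half_down(cy), _round_half_down(cx)


def _extract_patch(arr: np.ndarray, center: tuple[int, int], size: int, fill: float) -> np.ndarray:
    half = size // 2
    out = np.full((size, size), fill, dtype=float)
    r0, c0 = center[0] - half, center[1] - half
    rs, re = max(r0, 0), min(r0 + size, arr.shape[0])
    cs, ce = max(c0, 0), min(c0 + size, arr.shape[1])
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = arr[rs:re, cs:ce]
    return out


def crop_centered(
    vol_slice: np.ndarray,
    mask_slice: np.ndarray,
    cfg: PreprocessConfig | None = None,
    fill: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Cut the ``crop_size_mm`` patch centered on the tumor center of gravity.

    Inputs must already be at 1 mm spacing, so mm and px coincide.  If the
    initial patch contains more than one 8-connected foreground component,
    the patch is re-centered once on the centroid of the largest component
    (largest in-patch area; ties broken by component label order).  Regions
    outside the volume are padded with ``fill``.
    """
    cfg = cfg or PreprocessConfig()
    mask_slice = np.asarray(mask_slice)
    if mask_slice.sum() == 0:
        raise InvalidInputError("slice mask is empty")
    size = int(round(cfg.crop_size_mm / cfg.target_spacing_mm))
    center = _centroid_px(mask_slice)
    crop_mask = _extract_patch(mask_slice.astype(float), center, size, 0.0)
    labels, n_comp = ndimage.label(crop_mask > 0, structure=np.ones((3, 3), int))
    if n_comp > 1:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
        largest = int(np.argmax(areas)) + 1
        comp_local = np.argwhere(labels == largest)
        half = size // 2
        cy = comp_local[:, 0].mean() + (center[0] - half)
        cx = comp_local[:, 1].mean() + (center[1] - half)
        center = (_round_half_down(cy), _round_half_down(cx))
        crop_mask = _extract_patch(mask_slice.astype(float), center, size, 0.0)
    crop_pixels = _extract_patch(np.asarray(vol_slice, dtype=float), center, size, fill)
    return crop_pixels, (crop_mask > 0).astype(np.uint8), center


def mask_background(crop_pixels: np.ndarray, crop_mask: np.ndarray, fill: float) -> np.ndarray:
    """Set non-tumor pixels to ``fill`` (the global minimum CT value)."""
    out = np.asarray(crop_pixels, dtype=float).copy()
    out[np.asarray(crop_mask) == 0] = fill
    return out


def window_intensity(crop_pixels: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Linearly map the HU window [L - W/2, L + W/2] onto [0, 1], clipping outside."""
    cfg = cfg or PreprocessConfig()
    lo = cfg.window_level_hu - cfg.window_width_hu / 2.0
    return np.clip((np.asarray(crop_pixels, dtype=float) - lo) / cfg.window_width_hu, 0.0, 1.0)


def to_model_input(
    crop_pixels: np.ndarray,
    cfg: PreprocessConfig | None = None,
    slice_index: int = 0,
    center_mm: tuple[float, float] = (0.0, 0.0),
) -> TumorCrop:
    """Bilinear-resize the windowed patch and replicate it into three channels."""
    cfg = cfg or PreprocessConfig()
    if cfg.model_input_px < 1:
        raise InvalidInputError("model_input_px must be >= 1")
    px = np.asarray(crop_pixels, dtype=float)
    resized = _sk_resize(
        px,
        (cfg.model_input_px, cfg.model_input_px),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    resized = np.clip(resized, 0.0, 1.0)
    pixels = np.repeat(resized[:, :, None], 3, axis=2)
    return TumorCrop(
        pixels=pixels,
        slice_index=int(slice_index),
        center_mm=(float(center_mm[0]), float(center_mm[1])),
        resize_px=int(cfg.model_input_px),
    )


def preprocess(vol: CTVolume, mask: SegMask, cfg: PreprocessConfig | None = None) -> TumorCrop:
    """Full chain: resample -> max-area slice -> crop -> background fill -> window -> resize."""
    cfg = cfg or PreprocessConfig()
    rvol, rmask = resample_isotropic(vol, mask, cfg)
    k = select_max_area_slice(rmask)
    fill = float(rvol.voxels.min())
    crop_px, crop_mask, center = crop_centered(rvol.voxels[:, :, k], rmask.voxels[:, :, k], cfg, fill=fill)
    crop_px = mask_background(crop_px, crop_mask, fill)
    crop_px = window_intensity(crop_px, cfg)
    return to_model_input(crop_px, cfg, slice_index=k, center_mm=center)


# ---------------------------------------------------------------------------
# NIfTI / PNG I/O

def load_nifti(path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(np.asarray(img.get_fdata(), dtype=float), spacing)


def load_nifti_mask(path) -> SegMask:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return SegMask((data > 0.5).astype(np.uint8))


def save_nifti(path, voxels: np.ndarray, spacing: tuple[float, float, float]) -> None:
    import nibabel as nib

    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(voxels), affine), str(path))


def save_crop_png(path, crop: TumorCrop) -> None:
    """8-bit PNG of the first channel (value = round(255 * pixel)) for inspection."""
    import imageio.v3 as iio

    img = np.round(255.0 * crop.pixels[:, :, 0]).astype(np.uint8)
    iio.imwrite(str(path), img)


def crop_to_dict(crop: TumorCrop) -> dict:
    return {
        "slice_index": crop.slice_index,
        "center_mm": list(crop.center_mm),
        "resize_px": crop.resize_px,
        "pixels": crop.pixels[:, :, 0].tolist(),
    }


def crop_from_dict(d: dict) -> TumorCrop:
    px = np.asarray(d["pixels"], dtype=float)
    return TumorCrop(
        pixels=np.repeat(px[:, :, None], 3, axis=2),
        slice_index=int(d["slice_index"]),
        center_mm=tuple(d["center_mm"]),
        resize_px=int(d["resize_px"]),
    )


def asdict_config(cfg: PreprocessConfig) -> dict:
    return dataclasses.asdict(cfg)
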