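"""Full-field images -> normalized single-cell crops.

Two recipes are supported, mirroring common practice for yeast screens and
for antibody-stained human cell atlases:

* ``center_based`` — cell centers are supplied externally (e.g. from a
  segmentation tool run on the structural marker); a fixed-size crop is cut
  around each center and min-max rescaled to [0, 1].  An optional area filter
  rejects crops whose object mask covers < 5% or > 95% of the crop.
* ``otsu_nucleus`` — centers are found by Otsu-binarizing the nuclear channel,
  labelling connected components and dropping objects below a minimum area
  (default 400 px); a large intermediate crop is cut, resized down to the
  working crop size, rescaled to [0, 1], and structural-channel values below
  a clip threshold (default 0.05) are zeroed to improve contrast.

Images that end up with too few surviving cells are dropped entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize

from .core import CellCrop, ContractError, DatasetManifest, MicroscopyImage, load_images


@dataclass
class PreprocessConfig:
    mode: str = "center_based"          # or "otsu_nucleus"
    crop_size: int = 64
    intermediate_crop: int = 512        # otsu_nucleus mode only
    min_object_area_px: int = 400       # otsu_nucleus mode only
    area_fraction_bounds: tuple[float, float] = (0.05, 0.95)
    min_cells_per_image: int | None = None  # default 30 center_based / 5 otsu
    clip_threshold: float = 0.05        # structural channels, otsu_nucleus mode
    nuclear_channel: int | None = None  # defaults to last structural channel

    def __post_init__(self) -> None:
        if self.mode not in ("center_based", "otsu_nucleus"):
            raise ContractError(f"unknown preprocessing mode {self.mode!r}")
        lo, hi = self.area_fraction_bounds
        if not (0 <= lo < hi <= 1):
            raise ContractError("area_fraction_bounds must satisfy 0 <= lo < hi <= 1")
        if self.crop_size < 16 or self.crop_size % 2:
            raise ContractError("crop_size must be even and >= 16")
        if self.min_cells_per_image is None:
            self.min_cells_per_image = 30 if self.mode == "center_based" else 5


# ---------------------------------------------------------------------------
# Center detection
# ---------------------------------------------------------------------------

def detect_centers_otsu(
    nuclear_channel: np.ndarray, min_object_area_px: int = 400
) -> list[tuple[float, float]]:
    """Centers of mass of Otsu-thresholded connected components.

    Components smaller than ``min_object_area_px`` are discarded.  Order is
    deterministic: row-major by each component's first pixel (the scan order
    of connected-component labelling).  A constant channel yields an empty
    list with a warning rather than an error.
    """
    chan = np.asarray(nuclear_channel, dtype=np.float64)
    if chan.ndim != 2:
        raise ContractError("nuclear channel must be a 2-D array")
    if np.ptp(chan) == 0:
        warnings.warn("constant nuclear channel; no centers detected", stacklevel=2)
        return []
    thresh = threshold_otsu(chan)
    mask = chan > thresh
    labelled = cc_label(mask)
    centers = []
    for prop in regionprops(labelled):
        if prop.area >= min_object_area_px:
            centers.append((float(prop.centroid[0]), float(prop.centroid[1])))
    return centers


# ---------------------------------------------------------------------------
# Cropping and normalization
# ---------------------------------------------------------------------------

def extract_crop(field: np.ndarray, center: tuple[int, int], crop_size: int) -> np.ndarray:
    """Cut the half-open window [r-s/2, r+s/2) x [c-s/2, c+s/2), zero-padded.

    All channels are cropped identically; the center must lie inside the
    field.
    """
    field = np.asarray(field)
    squeeze = field.ndim == 2
    if squeeze:
        field = field[..., None]
    h0, w0, z = field.shape
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < h0 and 0 <= c < w0):
        raise ContractError(f"center {center} outside field of shape {(h0, w0)}")
    half = crop_size // 2
    out = np.zeros((crop_size, crop_size, z), dtype=field.dtype)
    r0, r1 = r - half, r + half
    c0, c1 = c - half, c + half
    sr0, sr1 = max(r0, 0), min(r1, h0)
    sc0, sc1 = max(c0, 0), min(c1, w0)
    out[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = field[sr0:sr1, sc0:sc1]
    return out[..., 0] if squeeze else out


def filter_by_area(
    mask_area_px: int, crop_size: int, bounds: tuple[float, float] = (0.05, 0.95)
) -> bool:
    """Keep a crop iff its object-mask area lies within the fractional bounds
    of the crop area (boundary inclusive)."""
    if mask_area_px < 0:
        raise ContractError("mask area must be non-negative")
    total = crop_size * crop_size
    return bounds[0] * total <= mask_area_px <= bounds[1] * total


def normalize_crop(
    pixels: np.ndarray,
    mode: str = "center_based",
    clip_threshold: float = 0.05,
    structural_indices: Sequence[int] = (),
    out_size: int | None = None,
) -> np.ndarray:
    """Per-channel min-max rescale to [0, 1]; constant channels map to zero.

    In ``otsu_nucleus`` mode the crop is first resized down to ``out_size``
    (bilinear, Gaussian-prefiltered at sigma = downscale/2), then rescaled,
    then structural channels have values below ``clip_threshold`` zeroed.
    """
    pix = np.asarray(pixels, dtype=np.float64)
    if not np.all(np.isfinite(pix)):
        raise ContractError("crop contains non-finite pixels")
    squeeze = pix.ndim == 2
    if squeeze:
        pix = pix[..., None]

    if mode == "otsu_nucleus" and out_size is not None and pix.shape[0] != out_size:
        factor = pix.shape[0] / out_size
        smoothed = np.stack(
            [gaussian_filter(pix[..., z], factor / 2.0) for z in range(pix.shape[-1])],
            axis=-1,
        )
        pix = resize(
            smoothed, (out_size, out_size, pix.shape[-1]), order=1, anti_aliasing=False
        )

    lo = pix.min(axis=(0, 1), keepdims=True)
    hi = pix.max(axis=(0, 1), keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (pix - lo) / np.where(span > 0, span, 1.0), 0.0)

    if mode == "otsu_nucleus":
        for z in structural_indices:
            ch = out[..., z]
            ch[ch < clip_threshold] = 0.0
    return out[..., 0] if squeeze else out


# ---------------------------------------------------------------------------
# Whole-dataset preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ExclusionRecord:
    image_id: str
    kind: str       # "cell" or "image"
    reason: str
    detail: str = ""


@dataclass
class PreprocessResult:
    crops: list[CellCrop]
    cell_counts: dict[str, int]          # per surviving image
    exclusions: list[ExclusionRecord] = field(default_factory=list)


def preprocess_images(
    images: Sequence[MicroscopyImage],
    config: PreprocessConfig,
    centers: Mapping[tuple[str, int], Sequence[tuple[float, float]]] | None = None,
    object_areas: Mapping[tuple[str, int], Sequence[int]] | None = None,
) -> PreprocessResult:
    """Crop every image; drop images with too few surviving cells.

    ``centers`` maps (image_id, field_index) to cell centers and is required
    in ``center_based`` mode (center detection by segmentation is an external
    concern).  ``object_areas``, aligned with ``centers``, enables the
    fractional area filter; without masks the filter is skipped.
    """
    crops: list[CellCrop] = []
    counts: dict[str, int] = {}
    exclusions: list[ExclusionRecord] = []

    if config.mode == "center_based" and centers is None:
        raise ContractError("center_based mode requires precomputed centers")

    for img in images:
        layout = img.channel_layout
        nuc_ch = (
            config.nuclear_channel
            if config.nuclear_channel is not None
            else layout.structural_indices[-1]
        )
        img_crops: list[CellCrop] = []
        counter = 0
        for k, fov in enumerate(img.fields_of_view):
            if config.mode == "otsu_nucleus":
                ctrs = detect_centers_otsu(fov[..., nuc_ch], config.min_object_area_px)
                areas = None
            else:
                ctrs = list(centers.get((img.image_id, k), []))  # type: ignore[union-attr]
                areas = (
                    list(object_areas.get((img.image_id, k), []))
                    if object_areas is not None
                    else None
                )
            # reproducible cell_id assignment: order by (field, row, col)
            order = sorted(range(len(ctrs)), key=lambda j: (ctrs[j][0], ctrs[j][1]))
            for j in order:
                r, c = int(round(ctrs[j][0])), int(round(ctrs[j][1]))
                if not (0 <= r < fov.shape[0] and 0 <= c < fov.shape[1]):
                    exclusions.append(
                        ExclusionRecord(img.image_id, "cell", "center_outside_field", f"({r},{c})")
                    )
                    continue
                if areas is not None and j < len(areas):
                    if not filter_by_area(areas[j], config.crop_size, config.area_fraction_bounds):
                        exclusions.append(
                            ExclusionRecord(
                                img.image_id, "cell", "area_filter", f"area={areas[j]}"
                            )
                        )
                        continue
                size = (
                    config.intermediate_crop
                    if config.mode == "otsu_nucleus"
                    else config.crop_size
                )
                raw = extract_crop(fov, (r, c), size)
                pix = normalize_crop(
                    raw,
                    mode=config.mode,
                    clip_threshold=config.clip_threshold,
                    structural_indices=layout.structural_indices,
                    out_size=config.crop_size,
                )
                img_crops.append(
                    CellCrop(
                        pixels=pix.astype(np.float32),
                        image_id=img.image_id,
                        cell_id=f"cell_{counter:03d}",
                        center=(r, c),
                        field_index=k,
                    )
                )
                counter += 1
        if len(img_crops) < (config.min_cells_per_image or 0):
            exclusions.append(
                ExclusionRecord(
                    img.image_id,
                    "image",
                    "too_few_cells",
                    f"{len(img_crops)} < {config.min_cells_per_image}",
                )
            )
            continue
        crops.extend(img_crops)
        counts[img.image_id] = len(img_crops)

    return PreprocessResult(crops, counts, exclusions)


def preprocess_dataset(
    manifest: DatasetManifest,
    config: PreprocessConfig,
    centers: Mapping[tuple[str, int], Sequence[tuple[float, float]]] | None = None,
    base=None,
) -> PreprocessResult:
    """Manifest-driven variant of :func:`preprocess_images`."""
    images = load_images(manifest, base=base)
    return preprocess_images(images, config, centers=centers)
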