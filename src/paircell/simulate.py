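"""Synthetic multichannel fluorescence images with known localization classes.

The generator emulates the structure that the paired-cell pretext task relies
on: each image (well) holds many genetically identical cells that share one
protein-localization pattern, while structural channels are common to the
whole collection.  Cells are rotated ellipses with a concentric elliptical
nucleus; the protein channel realizes one of six canonical localization
classes or an interpolating mixture of two of them.  Nuisance variation —
per-image gain, a planar illumination ramp, per-cell brightness jitter and
additive Gaussian noise — is layered on top so that trivial intensity
statistics do not separate the classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (
    CellCrop,
    ChannelLayout,
    ContractError,
    DatasetManifest,
    MicroscopyImage,
    write_manifest,
)

PURE_CLASSES = (
    "nuclear",
    "nucleolar",
    "nucleolar_rim",
    "cytosolic",
    "punctate",
    "membrane",
)


@dataclass(frozen=True)
class Mixture:
    """Linear mixture of two pure localization classes.

    ``alpha`` is the fraction of ``class_a``; alpha=1 is pure ``class_a``.
    """

    class_a: str
    class_b: str
    alpha: float

    def __post_init__(self) -> None:
        for c in (self.class_a, self.class_b):
            if c not in PURE_CLASSES:
                raise ContractError(f"unknown pattern class {c!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ContractError("mixture fraction alpha must lie in [0, 1]")

    def __str__(self) -> str:
        return f"mixture({self.class_a},{self.class_b},{self.alpha:g})"


PatternClass = "str | Mixture"


def parse_pattern(text: str) -> "str | Mixture":
    """Parse 'nuclear' or 'mixture(nuclear,cytosolic,0.5)'."""
    text = text.strip()
    m = re.fullmatch(r"mixture\(\s*(\w+)\s*,\s*(\w+)\s*,\s*([0-9.eE+-]+)\s*\)", text)
    if m:
        return Mixture(m.group(1), m.group(2), float(m.group(3)))
    if text not in PURE_CLASSES:
        raise ContractError(f"unknown pattern class {text!r}")
    return text


@dataclass
class CellGeometry:
    center: tuple[float, float]  # (row, col) in field coordinates
    radius: float                # semi-major axis of the body, px
    eccentricity: float          # semi-major / semi-minor
    rotation: float              # radians
    nucleus_frac: float = 0.45   # nucleus semi-axes relative to body
    intensity: float = 1.0       # per-cell brightness jitter multiplier


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    Defaults define the CPU-scale benchmark used throughout the test suite:
    six localization classes, 30 images per class, 10-16 cells per 256x256
    field, sized for 32x32 crops.
    """

    pattern_classes: Sequence["str | Mixture"] = PURE_CLASSES
    images_per_class: int = 30
    cells_per_image: tuple[int, int] = (10, 16)
    field_size: tuple[int, int] = (256, 256)
    fields_per_image: int = 1
    # morphology
    cell_radius: tuple[float, float] = (7.0, 11.0)
    eccentricity: tuple[float, float] = (1.0, 1.6)
    nucleus_frac: float = 0.45
    # structural channels: 2 emulates a nucleus+body stain pair, 1 a single
    # cytosolic marker (nucleus then appears as a dimmer region of the body)
    n_structural: int = 2
    # nuisance, sized after real fluorescence screens: diffuse nonspecific
    # background in the protein channel, optical blur at this pixel scale,
    # camera/shot noise, per-image illumination and gain, per-cell brightness
    illumination_gradient: float = 0.3   # peak-to-mean planar ramp amplitude
    gain_range: tuple[float, float] = (0.6, 1.4)  # per-image multiplicative gain
    noise_sd: float = 0.05               # additive Gaussian, fraction of full scale
    cell_jitter_sd: float = 0.15         # per-cell lognormal brightness jitter
    mixing_jitter_sd: float = 0.15       # per-cell spread of the mixture fraction
    background_fluorescence: float = 0.35  # diffuse body-wide protein background
    optical_blur_sigma: float = 1.2      # Gaussian PSF, px
    center_jitter_px: int = 2            # crop-center error emulating segmentation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_image[0] < 1 or self.cells_per_image[0] > self.cells_per_image[1]:
            raise ContractError("cells_per_image range invalid")
        if self.n_structural not in (1, 2):
            raise ContractError("n_structural must be 1 or 2")
        self.pattern_classes = tuple(
            parse_pattern(p) if isinstance(p, str) else p for p in self.pattern_classes
        )

    @property
    def channel_layout(self) -> ChannelLayout:
        if self.n_structural == 2:
            return ChannelLayout(("body", "nucleus", "protein"), (0, 1), (2,))
        return ChannelLayout(("body", "protein"), (0,), (1,))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], geom: CellGeometry, scale: float) -> np.ndarray:
    """Soft [0,1] mask of an ellipse with semi-axes scale*(radius, radius/ecc)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dr = rr - geom.center[0]
    dc = cc - geom.center[1]
    ct, st = np.cos(geom.rotation), np.sin(geom.rotation)
    u = ct * dr + st * dc
    v = -st * dr + ct * dc
    a = geom.radius * scale
    b = geom.radius / geom.eccentricity * scale
    d = (u / a) ** 2 + (v / b) ** 2
    # smooth edge: ~1 inside, decaying over ~1px at the boundary
    return np.clip(1.0 - (np.sqrt(np.maximum(d, 0.0)) - 1.0) * geom.radius * 0.8, 0.0, 1.0)


def _ring(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    return np.clip(outer - inner, 0.0, 1.0)


def _render_protein(
    shape: tuple[int, int],
    geom: CellGeometry,
    pattern: "str | Mixture",
    rng: np.random.Generator,
) -> np.ndarray:
    if isinstance(pattern, Mixture):
        a = _render_protein(shape, geom, pattern.class_a, rng)
        b = _render_protein(shape, geom, pattern.class_b, rng)
        return pattern.alpha * a + (1.0 - pattern.alpha) * b

    body = _ellipse_mask(shape, geom, 1.0)
    nucleus = _ellipse_mask(shape, geom, geom.nucleus_frac)
    if pattern == "nuclear":
        img = nucleus.copy()
    elif pattern == "nucleolar":
        n_blobs = int(rng.integers(1, 4))
        img = np.zeros(shape)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        r_nuc = geom.radius * geom.nucleus_frac
        for _ in range(n_blobs):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.55) * r_nuc
            br = geom.center[0] + rad * np.cos(ang)
            bc = geom.center[1] + rad * np.sin(ang)
            sigma = max(0.8, 0.3 * r_nuc)
            img += np.exp(-((rr - br) ** 2 + (cc - bc) ** 2) / (2 * sigma**2))
        img = np.clip(img, 0, 1) * nucleus
    elif pattern == "nucleolar_rim":
        img = _ring(nucleus, _ellipse_mask(shape, geom, geom.nucleus_frac * 0.62))
    elif pattern == "cytosolic":
        img = _ring(body, nucleus)
    elif pattern == "punctate":
        n_foci = 2 + int(rng.poisson(5))
        img = np.zeros(shape)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        placed = 0
        for _ in range(50):
            if placed >= n_foci:
                break
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.2, 0.85) * geom.radius
            fr = geom.center[0] + rad * np.cos(ang)
            fc = geom.center[1] + rad * np.sin(ang) / geom.eccentricity
            img += np.exp(-((rr - fr) ** 2 + (cc - fc) ** 2) / (2 * 1.1**2))
            placed += 1
        img = np.clip(img, 0, 1) * body
    elif pattern == "membrane":
        img = _ring(body, _ellipse_mask(shape, geom, 0.78))
    else:  # pragma: no cover - guarded by parse_pattern
        raise ContractError(f"unknown pattern class {pattern!r}")
    return img


def render_cell(
    shape: tuple[int, int],
    geom: CellGeometry,
    pattern: "str | Mixture",
    rng: np.random.Generator,
    n_structural: int = 2,
    background_fluorescence: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell: (structural H x W x S, protein H x W x 1), unnormalized.

    The structural stack depicts body and nucleus; the protein channel
    realizes the localization class on top of an optional diffuse body-wide
    background (nonspecific fluorescence).  Pure-class output is
    deterministic given the rng state (stochastic classes draw blob/foci
    positions from ``rng``).
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    body = _ellipse_mask(shape, geom, 1.0)
    nucleus = _ellipse_mask(shape, geom, geom.nucleus_frac)
    if n_structural == 2:
        structural = np.stack([body, nucleus], axis=-1)
    elif n_structural == 1:
        # single cytosolic marker: nucleus shows as a dimmer interior region
        structural = (0.4 * body + 0.6 * _ring(body, nucleus))[..., None]
    else:
        raise ContractError("n_structural must be 1 or 2")
    protein = _render_protein(shape, geom, pattern, rng)
    if background_fluorescence > 0:
        protein = protein + background_fluorescence * body
    scale = geom.intensity
    return structural * scale, protein[..., None] * scale


# ---------------------------------------------------------------------------
# Field / image generation
# ---------------------------------------------------------------------------

def _sample_geometry(spec: SyntheticSpec, center, rng: np.random.Generator) -> CellGeometry:
    jitter = float(np.exp(rng.normal(0.0, spec.cell_jitter_sd)))
    return CellGeometry(
        center=center,
        radius=float(rng.uniform(*spec.cell_radius)),
        eccentricity=float(rng.uniform(*spec.eccentricity)),
        rotation=float(rng.uniform(0, np.pi)),
        nucleus_frac=spec.nucleus_frac,
        intensity=jitter,
    )


def _place_centers(
    n: int, shape: tuple[int, int], margin: float, min_sep: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    centers: list[tuple[float, float]] = []
    for _ in range(2000):
        if len(centers) >= n:
            break
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise ContractError(
            f"could not place {n} non-overlapping cells on a {shape} field after bounded retries"
        )
    return centers


def _per_cell_pattern(
    pattern: "str | Mixture", spec: SyntheticSpec, rng: np.random.Generator
) -> "str | Mixture":
    """Mixture images show cell-to-cell variability in the mixing fraction."""
    if isinstance(pattern, Mixture) and spec.mixing_jitter_sd > 0:
        a = float(np.clip(rng.normal(pattern.alpha, spec.mixing_jitter_sd), 0.0, 1.0))
        return replace(pattern, alpha=a)
    return pattern


def generate_image(
    image_id: str,
    pattern: "str | Mixture",
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> MicroscopyImage:
    """Generate one image (well): ``fields_per_image`` fields of view.

    All cells carry the image's pattern class (mixtures get a per-cell jitter
    of the mixing fraction).  Ground-truth centers, per-field, go to
    ``metadata['centers']``; the class label to ``metadata['pattern_class']``.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    shape = spec.field_size
    layout = spec.channel_layout
    gain = float(rng.uniform(*spec.gain_range))
    fovs: list[np.ndarray] = []
    all_centers: list[list[tuple[int, int]]] = []
    n_total = int(rng.integers(spec.cells_per_image[0], spec.cells_per_image[1] + 1))
    # split cells across fields as evenly as the draw allows
    base, extra = divmod(n_total, spec.fields_per_image)
    per_field = [base + (1 if k < extra else 0) for k in range(spec.fields_per_image)]

    for k in range(spec.fields_per_image):
        margin = spec.cell_radius[1] + 2.0
        min_sep = 2.0 * spec.cell_radius[1] * 0.95
        centers = _place_centers(per_field[k], shape, margin, min_sep, rng)
        field = np.zeros(shape + (layout.n_channels,), dtype=np.float64)
        for center in centers:
            geom = _sample_geometry(spec, center, rng)
            cell_pat = _per_cell_pattern(pattern, spec, rng)
            structural, protein = render_cell(
                shape, geom, cell_pat, rng, spec.n_structural,
                background_fluorescence=spec.background_fluorescence,
            )
            field[..., : layout.n_structural] += structural
            field[..., layout.n_structural :] += protein
        # optical blur (PSF)
        for z in range(field.shape[-1]):
            field[..., z] = gaussian_filter(field[..., z], spec.optical_blur_sigma)
        # per-image nuisance: gain and a planar illumination ramp on all channels
        theta = rng.uniform(0, 2 * np.pi)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        ramp = (
            (rr / shape[0] - 0.5) * np.cos(theta) + (cc / shape[1] - 0.5) * np.sin(theta)
        )
        illum = gain * (1.0 + spec.illumination_gradient * 2.0 * ramp)
        illum = np.clip(illum, 0.05, None)
        field *= illum[..., None]
        if spec.noise_sd > 0:
            field += rng.normal(0.0, spec.noise_sd * gain, size=field.shape)
        field = np.clip(field, 0.0, None)
        fovs.append(field)
        all_centers.append([(int(round(r)), int(round(c))) for r, c in centers])

    meta = {
        "pattern_class": str(pattern),
        "centers": all_centers,
        "gain": gain,
    }
    return MicroscopyImage(image_id, fovs, layout, meta)


def generate_images(spec: SyntheticSpec) -> list[MicroscopyImage]:
    """Generate the full collection in memory, deterministically from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    images = []
    for ci, pattern in enumerate(spec.pattern_classes):
        for k in range(spec.images_per_class):
            image_id = f"img_{_pattern_slug(pattern)}_{k:03d}"
            images.append(generate_image(image_id, pattern, spec, rng))
    return images


def _pattern_slug(pattern: "str | Mixture") -> str:
    if isinstance(pattern, Mixture):
        return f"mix_{pattern.class_a}_{pattern.class_b}_{int(round(pattern.alpha * 100)):03d}"
    return str(pattern)


def generate_dataset(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[DatasetManifest, pd.DataFrame]:
    """Write TIFFs + manifest.tsv (+ layout sidecar) + labels.tsv + centers.tsv.

    Regeneration from the same seed is byte-identical.  The label table is
    written beside the manifest but never consumed by training code paths.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = generate_images(spec)
    layout = spec.channel_layout

    rows = []
    label_rows = []
    center_rows = []
    for img in images:
        label_rows.append({"image_id": img.image_id, "label": img.metadata["pattern_class"]})
        for k, fov in enumerate(img.fields_of_view):
            row: dict = {"image_id": img.image_id, "field_index": k}
            # store as uint16 scaled to a fixed full-well depth
            scaled = np.clip(fov / 4.0, 0.0, 1.0)
            for zi, name in enumerate(layout.channel_names):
                fname = f"{img.image_id}_f{k}_{name}.tif"
                tifffile.imwrite(
                    out_dir / fname, (scaled[..., zi] * 65535).astype(np.uint16)
                )
                row[f"path_{name}"] = fname
            row["label"] = img.metadata["pattern_class"]
            rows.append(row)
            for r, c in img.metadata["centers"][k]:
                center_rows.append(
                    {"image_id": img.image_id, "field_index": k, "row": r, "col": c}
                )

    columns = ["image_id", "field_index"] + [f"path_{n}" for n in layout.channel_names] + ["label"]
    manifest = DatasetManifest(pd.DataFrame(rows, columns=columns), layout)
    write_manifest(manifest, out_dir / "manifest.tsv")
    pd.DataFrame(label_rows).to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    pd.DataFrame(center_rows, columns=["image_id", "field_index", "row", "col"]).to_csv(
        out_dir / "centers.tsv", sep="\t", index=False
    )
    return manifest, pd.DataFrame(label_rows)


# ---------------------------------------------------------------------------
# Direct crop generation (in-memory path used by the test benchmark)
# ---------------------------------------------------------------------------

def crops_from_images(
    images: Sequence[MicroscopyImage],
    crop_size: int = 32,
    center_jitter_px: int = 0,
    seed: int = 0,
) -> tuple[list[CellCrop], dict[str, str]]:
    """Cut normalized crops at the generator's ground-truth centers.

    ``center_jitter_px`` perturbs each crop center uniformly by up to that
    many pixels per axis, emulating center-detection error.  Returns the
    crops and an image_id -> class-label mapping.  This bypasses disk and
    center detection; the full pipeline (TIFF + manifest + Otsu) is
    exercised separately.
    """
    from .preprocess import extract_crop, normalize_crop

    jitter_rng = np.random.default_rng(np.random.SeedSequence([seed, 714]))
    crops: list[CellCrop] = []
    labels: dict[str, str] = {}
    for img in images:
        labels[img.image_id] = img.metadata["pattern_class"]
        counter = 0
        for k, fov in enumerate(img.fields_of_view):
            for r, c in sorted(img.metadata["centers"][k]):
                if center_jitter_px:
                    r = int(np.clip(r + jitter_rng.integers(-center_jitter_px, center_jitter_px + 1), 0, fov.shape[0] - 1))
                    c = int(np.clip(c + jitter_rng.integers(-center_jitter_px, center_jitter_px + 1), 0, fov.shape[1] - 1))
                raw = extract_crop(fov, (r, c), crop_size)
                pix = normalize_crop(raw, mode="center_based")
                crops.append(
                    CellCrop(
                        pixels=pix.astype(np.float32),
                        image_id=img.image_id,
                        cell_id=f"cell_{counter:03d}",
                        center=(r, c),
                        field_index=k,
                    )
                )
                counter += 1
    return crops, labels
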