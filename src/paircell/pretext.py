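"""Pair sampling, augmentation, and the inpainting loss.

A training example pairs two different cells from the same image: the source
cell contributes all of its channels, the target cell only its structural
markers, and the network must predict the target's protein channel.  One
epoch visits every eligible cell once as a source and draws its target
uniformly from the other cells of the same image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CellCrop, ChannelLayout, ContractError, group_by_image


@dataclass
class TrainingPair:
    """Source/target split of one sampled cell pair (same image, different cells)."""

    source_structural: np.ndarray  # H x W x |Z1|
    source_protein: np.ndarray     # H x W x |Z2|
    target_structural: np.ndarray
    target_protein: np.ndarray
    image_id: str
    source_cell_id: str
    target_cell_id: str

    def __post_init__(self) -> None:
        if self.source_cell_id == self.target_cell_id:
            raise ContractError("source and target must be different cells")


def eligible_images(crops: Sequence[CellCrop]) -> dict[str, list[int]]:
    """Images with >= 2 cells; singleton images are excluded with a warning."""
    groups = group_by_image(crops)
    dropped = [gid for gid, idx in groups.items() if len(idx) < 2]
    if dropped:
        warnings.warn(
            f"{len(dropped)} image(s) with <2 cells contribute no pairs: {dropped[:5]}...",
            stacklevel=2,
        )
    return {gid: idx for gid, idx in groups.items() if len(idx) >= 2}


def sample_epoch_pairs(
    crops: Sequence[CellCrop], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """One epoch of (source_index, target_index) pairs.

    Every eligible cell appears exactly once as source; its target is drawn
    uniformly from the other cells of its image; the whole list is then
    shuffled.  Identical rng state gives identical pairing.
    """
    if not crops:
        raise ContractError("crop store is empty")
    groups = eligible_images(crops)
    if not groups:
        raise ContractError("no image has >= 2 cells; cannot sample pairs")
    pairs: list[tuple[int, int]] = []
    for gid in groups:
        idx = groups[gid]
        for src in idx:
            others = [j for j in idx if j != src]
            tgt = others[int(rng.integers(len(others)))]
            pairs.append((src, tgt))
    perm = rng.permutation(len(pairs))
    return [pairs[i] for i in perm]


def make_pair(
    crops: Sequence[CellCrop], layout: ChannelLayout, src: int, tgt: int
) -> TrainingPair:
    s, t = crops[src], crops[tgt]
    z1 = list(layout.structural_indices)
    z2 = list(layout.protein_indices)
    return TrainingPair(
        source_structural=s.pixels[..., z1],
        source_protein=s.pixels[..., z2],
        target_structural=t.pixels[..., z1],
        target_protein=t.pixels[..., z2],
        image_id=s.image_id,
        source_cell_id=s.cell_id,
        target_cell_id=t.cell_id,
    )


def _flip(arr: np.ndarray, horizontal: bool, vertical: bool) -> np.ndarray:
    if vertical:
        arr = arr[::-1, :, :]
    if horizontal:
        arr = arr[:, ::-1, :]
    return arr


def augment_pair(pair: TrainingPair, rng: np.random.Generator) -> TrainingPair:
    """Random horizontal/vertical flips, drawn independently for source and
    target; the marker and protein channels of one cell always flip together."""
    sh, sv, th, tv = rng.integers(0, 2, size=4).astype(bool)
    return TrainingPair(
        source_structural=_flip(pair.source_structural, sh, sv),
        source_protein=_flip(pair.source_protein, sh, sv),
        target_structural=_flip(pair.target_structural, th, tv),
        target_protein=_flip(pair.target_protein, th, tv),
        image_id=pair.image_id,
        source_cell_id=pair.source_cell_id,
        target_cell_id=pair.target_cell_id,
    )


def inpainting_loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Pixel-wise MSE: squared error summed over h, w (and protein channels),
    divided by h*w.  Batched inputs (N, H, W, C) return the batch mean."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise ContractError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    if y_hat.ndim == 3:
        h, w = y_hat.shape[:2]
        return float(np.sum((y_hat - y) ** 2) / (h * w))
    if y_hat.ndim == 4:
        n, h, w = y_hat.shape[:3]
        return float(np.sum((y_hat - y) ** 2) / (h * w * n))
    raise ContractError("expected (H, W, C) or (N, H, W, C) arrays")


def inpainting_loss_grad(y_hat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(loss)/d(y_hat) for the batched loss above."""
    n, h, w = y_hat.shape[:3]
    return (2.0 / (h * w * n)) * (y_hat - y)
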