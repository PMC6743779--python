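"""Per-cell features from the trained source encoder.

A cell's feature vector is the spatial max over each feature map of a chosen
convolutional layer (Conv1..Conv5), taken post-batchnorm post-ReLU, running
the source encoder alone in inference mode — no target inputs are required.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core import CellCrop, ChannelLayout, ContractError, FeatureTable
from .model import LAYER_NAMES, InpaintingNet


def extract_features(
    net: InpaintingNet,
    crops: Sequence[CellCrop],
    layer: str,
    layout: ChannelLayout,
    batch_size: int = 256,
) -> FeatureTable:
    """Spatial-max-pooled activations of one source-encoder layer, per cell."""
    if layer not in LAYER_NAMES:
        raise ContractError(f"unknown layer {layer!r}; expected one of {LAYER_NAMES}")
    z = list(layout.structural_indices) + list(layout.protein_indices)
    vecs = []
    for start in range(0, len(crops), batch_size):
        chunk = crops[start : start + batch_size]
        x = np.stack([c.pixels[..., z] for c in chunk]).astype(np.float32)
        taps: dict = {}
        net.forward_source(x, train=False, taps=taps)
        vecs.append(taps[layer].max(axis=(1, 2)))
    matrix = np.concatenate(vecs, axis=0) if vecs else np.zeros((0, 0))
    return FeatureTable(
        image_ids=[c.image_id for c in crops],
        cell_ids=[c.cell_id for c in crops],
        layer_name=layer,
        matrix=np.asarray(matrix, dtype=np.float64),
    )


def average_protein_features(
    table: FeatureTable, grouping: Mapping[tuple[str, str], str]
) -> FeatureTable:
    """Protein-level vectors: unweighted mean over each protein's cells.

    ``grouping`` maps (image_id, cell_id) to a protein identifier; every cell
    in the table must be covered.
    """
    missing = [k for k in table.keys() if k not in grouping]
    if missing:
        raise ContractError(f"cells without a protein group: {missing[:5]} (+{len(missing) - 5 if len(missing) > 5 else 0} more)")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, k in enumerate(table.keys()):
        prot = grouping[k]
        if prot not in members:
            members[prot] = []
            order.append(prot)
        members[prot].append(i)
    matrix = np.stack([table.matrix[members[p]].mean(axis=0) for p in order])
    return FeatureTable(
        image_ids=order,
        cell_ids=order,
        layer_name=table.layer_name,
        matrix=matrix,
        feature_names=list(table.feature_names),
    )


def standardize_features(
    table: FeatureTable,
) -> tuple[FeatureTable, np.ndarray, np.ndarray]:
    """Column-wise zero mean / unit variance (population sd).

    Zero-variance columns are centered and left unscaled.  Returns the
    standardized table plus the fitted means and sds so callers may reuse
    train-only statistics.
    """
    if table.n_cells < 2:
        raise ContractError("standardization needs at least 2 rows")
    mean = table.matrix.mean(axis=0)
    sd = table.matrix.std(axis=0)  # population sd
    scale = np.where(sd > 0, sd, 1.0)
    out = FeatureTable(
        image_ids=list(table.image_ids),
        cell_ids=list(table.cell_ids),
        layer_name=table.layer_name,
        matrix=(table.matrix - mean) / scale,
        feature_names=list(table.feature_names),
    )
    return out, mean, sd
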