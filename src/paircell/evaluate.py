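"""Benchmarks and descriptive statistics over feature spaces.

Implements the evaluation battery used to judge feature quality:

* leave-one-out kNN balanced accuracy (and its per-layer sweep),
* the normalized same-term pairwise-distance score (negative when cells of
  images sharing a localization term sit closer than the different-term
  expectation),
* the two-compartment log-ratio score for multi-localizing proteins and its
  per-image variability statistic,
* deterministic agglomerative clustering with Newick export.

All distances are Euclidean on standardized features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist

from .core import CellCrop, ChannelLayout, ContractError, FeatureTable
from .features import extract_features, standardize_features
from .model import LAYER_NAMES, InpaintingNet


# ---------------------------------------------------------------------------
# kNN classification
# ---------------------------------------------------------------------------

@dataclass
class KnnConfig:
    k: int = 11

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ContractError("k must be >= 1")


@dataclass
class KnnReport:
    balanced_accuracy: float
    per_class: dict[str, float]
    confusion: pd.DataFrame
    predictions: list[str]


def knn_loo_balanced_accuracy(
    features: FeatureTable | np.ndarray,
    labels: Sequence[str],
    k: int = 11,
    exclude_groups: Sequence[str] | None = None,
) -> KnnReport:
    """Leave-one-out kNN with Euclidean distance and deterministic ties.

    Each cell is predicted by the majority vote of its k nearest neighbours
    (itself excluded).  Distance ties are broken by smaller row index; vote
    ties by the smallest class after sorting class names.  Balanced accuracy
    is the unweighted mean of per-class recalls.

    ``exclude_groups`` optionally assigns each row a group id (typically the
    image/well); neighbours sharing the query's group are then ineligible.
    This is the leave-one-group-out control used in morphological profiling
    when few wells per class are available, so that a feature set cannot
    score by matching well-level nuisance rather than phenotype.
    """
    X = features.matrix if isinstance(features, FeatureTable) else np.asarray(features)
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ContractError("labels and feature rows disagree in length")
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels):
        raise ContractError("labels missing for some cells")
    classes = sorted(set(labels))
    class_idx = {c: j for j, c in enumerate(classes)}
    y = np.array([class_idx[l] for l in labels])
    n = X.shape[0]
    counts = np.bincount(y, minlength=len(classes))
    if counts.min() < k + 1:
        warnings.warn(
            f"some class has fewer than k+1={k + 1} members; votes may be degenerate",
            stacklevel=2,
        )
    if exclude_groups is not None and len(exclude_groups) != n:
        raise ContractError("exclude_groups and feature rows disagree in length")

    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    if exclude_groups is not None:
        groups = np.asarray(exclude_groups)
        same = groups[:, None] == groups[None, :]
        D[same] = np.inf
    idx = np.arange(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        order = np.lexsort((idx, D[i]))
        order = order[np.isfinite(D[i][order])][: min(k, n - 1)]
        votes = np.bincount(y[order], minlength=len(classes))
        preds[i] = int(np.argmax(votes))  # argmax takes the smallest index on ties

    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y, preds):
        conf[t, p] += 1
    with np.errstate(invalid="ignore"):
        recalls = np.where(counts > 0, conf.diagonal() / np.maximum(counts, 1), np.nan)
    per_class = {c: float(recalls[j]) for j, c in enumerate(classes)}
    return KnnReport(
        balanced_accuracy=float(np.nanmean(recalls)),
        per_class=per_class,
        confusion=pd.DataFrame(conf, index=classes, columns=classes),
        predictions=[classes[p] for p in preds],
    )


def layer_sweep(
    net: InpaintingNet,
    crops: Sequence[CellCrop],
    labels: Mapping[str, str],
    layout: ChannelLayout,
    layers: Sequence[str] = LAYER_NAMES,
    k: int = 11,
) -> pd.DataFrame:
    """Balanced accuracy per layer, features freshly extracted and
    standardized for each layer.  ``labels`` maps image_id -> class."""
    rows = []
    cell_labels = [labels[c.image_id] for c in crops]
    for layer in layers:
        table = extract_features(net, crops, layer, layout)
        std, _, _ = standardize_features(table)
        report = knn_loo_balanced_accuracy(std, cell_labels, k=k)
        rows.append({"layer": layer, "balanced_accuracy": report.balanced_accuracy})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise distance statistic
# ---------------------------------------------------------------------------

@dataclass
class PairDistanceConfig:
    n_same_pairs: int = 1000
    n_diff_pairs_per_term: int = 1000
    seed: int = 0
    normalization: str = "ratio"  # or "zscore"
    # cell-line-constrained variant: unbalanced pooled expectation
    variant: str = "balanced"     # or "cell_line"
    n_pairs_unbalanced: int = 10000
    cell_line_constraint: str | None = None  # "same" or "different"

    def __post_init__(self) -> None:
        if self.n_same_pairs < 1 or self.n_diff_pairs_per_term < 1:
            raise ContractError("pair counts must be >= 1")
        if self.normalization not in ("ratio", "zscore"):
            raise ContractError("normalization must be 'ratio' or 'zscore'")
        if self.variant not in ("balanced", "cell_line"):
            raise ContractError("variant must be 'balanced' or 'cell_line'")


def image_pair_distance(cells_a: np.ndarray, cells_b: np.ndarray) -> float:
    """Mean Euclidean distance over the full cross-product of two cell sets."""
    A = np.atleast_2d(np.asarray(cells_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(cells_b, dtype=np.float64))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ContractError("both images must contain at least one cell")
    return float(cdist(A, B).mean())


def _features_by_image(table: FeatureTable) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, gid in enumerate(table.image_ids):
        groups.setdefault(gid, []).append(i)
    return {gid: table.matrix[idx] for gid, idx in groups.items()}


@dataclass
class PairDistanceReport:
    per_term: dict[str, float]
    overall: float
    seed: int
    n_pairs: int


def normalized_same_term_distance(
    features: FeatureTable,
    terms: Mapping[str, str],
    config: PairDistanceConfig | None = None,
    cell_lines: Mapping[str, str] | None = None,
) -> PairDistanceReport:
    """Same-term image distances normalized against a different-term expectation.

    For each localization term, sample image pairs sharing the term and —
    to balance the expectation — the same number of pairs against each other
    term; the score is (mean_same - mean_diff) / mean_diff (a z-score variant
    divides by the sd of the different-term distances instead).  Negative
    means same-term images are closer than expectation.

    ``variant='cell_line'`` reproduces the unbalanced protocol: pooled
    different-term pairs without per-term balancing, optionally constraining
    both images of every pair to the same or to different cell lines.
    """
    cfg = config or PairDistanceConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    by_image = _features_by_image(features)
    images = [g for g in by_image if g in terms]
    term_of = {g: terms[g] for g in images}
    term_images: dict[str, list[str]] = {}
    for g in images:
        term_images.setdefault(term_of[g], []).append(g)

    if cfg.variant == "cell_line" and cfg.cell_line_constraint is not None and cell_lines is None:
        raise ContractError("cell-line constraint requires a cell_lines mapping")

    def _pair_ok(a: str, b: str) -> bool:
        if cfg.variant != "cell_line" or cfg.cell_line_constraint is None:
            return True
        same = cell_lines[a] == cell_lines[b]  # type: ignore[index]
        return same if cfg.cell_line_constraint == "same" else not same

    def _sample_pairs(pool_a: list[str], pool_b: list[str], n: int, distinct: bool):
        out = []
        attempts = 0
        while len(out) < n and attempts < 50 * n:
            attempts += 1
            a = pool_a[int(rng.integers(len(pool_a)))]
            b = pool_b[int(rng.integers(len(pool_b)))]
            if distinct and a == b:
                continue
            if not _pair_ok(a, b):
                continue
            out.append((a, b))
        return out

    dist_cache: dict[tuple[str, str], float] = {}

    def _dist(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in dist_cache:
            dist_cache[key] = image_pair_distance(by_image[a], by_image[b])
        return dist_cache[key]

    per_term: dict[str, float] = {}
    n_sampled = 0
    eligible_terms = [t for t, gs in term_images.items() if len(gs) >= 2]
    skipped = [t for t in term_images if t not in eligible_terms]
    for t in skipped:
        warnings.warn(f"term {t!r} has a single image; skipped", stacklevel=2)

    for t in sorted(eligible_terms):
        same_pool = term_images[t]
        if cfg.variant == "balanced":
            n_same, n_diff = cfg.n_same_pairs, cfg.n_diff_pairs_per_term
        else:
            n_same = n_diff = cfg.n_pairs_unbalanced
        same_pairs = _sample_pairs(same_pool, same_pool, n_same, distinct=True)
        if cfg.variant == "balanced":
            diff_pairs = []
            for u in sorted(term_images):
                if u == t or not term_images[u]:
                    continue
                diff_pairs.extend(_sample_pairs(same_pool, term_images[u], n_diff, False))
        else:
            other_pool = [g for g in images if term_of[g] != t]
            diff_pairs = _sample_pairs(same_pool, other_pool, n_diff, False)
        if not same_pairs or not diff_pairs:
            warnings.warn(f"term {t!r}: no valid pairs under constraints; skipped", stacklevel=2)
            continue
        d_same = np.array([_dist(a, b) for a, b in same_pairs])
        d_diff = np.array([_dist(a, b) for a, b in diff_pairs])
        n_sampled += len(same_pairs) + len(diff_pairs)
        if cfg.normalization == "ratio":
            denom = d_diff.mean()
            # degenerate geometry: equal means (incl. all-zero) score 0
            per_term[t] = float((d_same.mean() - denom) / denom) if denom > 0 else 0.0
        else:
            sd = d_diff.std()
            per_term[t] = float((d_same.mean() - d_diff.mean()) / (sd if sd > 0 else 1.0))

    overall = float(np.mean(list(per_term.values()))) if per_term else float("nan")
    return PairDistanceReport(per_term=per_term, overall=overall, seed=cfg.seed, n_pairs=n_sampled)


# ---------------------------------------------------------------------------
# Multi-localization score and variability
# ---------------------------------------------------------------------------

def multiloc_score(
    cell: np.ndarray, compartment_a: np.ndarray, compartment_b: np.ndarray
) -> float:
    """ln(d(cell, mean_A) / d(cell, mean_B)): negative means closer to A."""
    A = np.atleast_2d(np.asarray(compartment_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(compartment_b, dtype=np.float64))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ContractError("both compartment reference sets must be non-empty")
    cell = np.asarray(cell, dtype=np.float64)
    da = float(np.linalg.norm(cell - A.mean(axis=0)))
    db = float(np.linalg.norm(cell - B.mean(axis=0)))
    if da == 0.0 or db == 0.0:
        warnings.warn("cell lies exactly at a compartment centroid", stacklevel=2)
        return float("-inf") if da == 0.0 else float("inf")
    return float(np.log(da / db))


def multiloc_scores(
    cells: np.ndarray, compartment_a: np.ndarray, compartment_b: np.ndarray
) -> np.ndarray:
    return np.array([multiloc_score(c, compartment_a, compartment_b) for c in np.atleast_2d(cells)])


def variability_statistic(
    scores_by_image: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-image mean and population sd of per-cell scores, ranked by sd
    (descending).  Singleton images are excluded with a warning."""
    rows = []
    for gid, scores in scores_by_image.items():
        arr = np.asarray(list(scores), dtype=np.float64)
        if arr.size < 2:
            warnings.warn(f"image {gid!r} has <2 cells; sd undefined, excluded", stacklevel=2)
            continue
        rows.append({"image_id": gid, "mean": float(arr.mean()), "sd": float(arr.std())})
    df = pd.DataFrame(rows, columns=["image_id", "mean", "sd"])
    return df.sort_values("sd", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    ids: list[str]
    leaf_order: list[str]
    flat: dict[str, int] = field(default_factory=dict)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
            if node.is_leaf():
                length = parent_height
                return f"{self.ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

        body = rec(tree, tree.dist)
        return body.rsplit(":", 1)[0] + ";"


def hierarchical_cluster(
    features: FeatureTable | np.ndarray,
    ids: Sequence[str] | None = None,
    linkage: str = "ward",
    n_clusters: int | None = None,
    height: float | None = None,
) -> ClusterResult:
    """Deterministic agglomerative clustering on Euclidean distances.

    Linkage is configurable ({ward, average, complete}); Ward is the default.
    Flat clusters are cut either at ``n_clusters`` or at ``height``.
    """
    if isinstance(features, FeatureTable):
        X = features.matrix
        if ids is None:
            ids = [f"{g}/{c}" if g != c else g for g, c in features.keys()]
    else:
        X = np.asarray(features, dtype=np.float64)
        if ids is None:
            ids = [str(i) for i in range(X.shape[0])]
    ids = list(ids)
    if X.shape[0] < 2:
        raise ContractError("clustering needs at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ContractError("features contain non-finite values")
    if linkage not in ("ward", "average", "complete"):
        raise ContractError(f"unsupported linkage {linkage!r}")
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    order = hierarchy.leaves_list(Z)
    result = ClusterResult(Z, ids, [ids[i] for i in order])
    if n_clusters is not None:
        assign = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        result.flat = {ids[i]: int(assign[i]) for i in range(len(ids))}
    elif height is not None:
        assign = hierarchy.fcluster(Z, t=height, criterion="distance")
        result.flat = {ids[i]: int(assign[i]) for i in range(len(ids))}
    return result
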