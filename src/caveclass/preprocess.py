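"""From raw localizations to labeled, balanced blob sets.

Stages, in pipeline order:

1. :func:`iterative_merge` — multiple-blinking correction: localizations
   within 20 nm are merged (connected components -> centroid) until no pair
   is closer than the radius.
2. :func:`filter_noise` — removes unclustered background: a point survives
   only if its local neighbor count exceeds the expectation under complete
   spatial randomness (CSR) at the dataset's global density by more than
   ``k`` Poisson standard deviations.
3. :func:`segment_blobs` — connected components of the proximity graph at
   the segmentation radius; each component becomes one blob.
4. :func:`label_with_mask` — a blob is PTRF+ iff at least a configurable
   fraction of its points falls inside the positive area of the wide-field
   CAVIN1/PTRF mask.
5. :func:`stratify_classes` — a blob is a caveola iff it is PTRF+ with at
   least 60 molecules; everything else is non-caveolar.
6. :func:`balance_dataset` — downsample the majority class uniformly at
   random to the minority count.

Stages 1-3 are pure point-set geometry (arrays in, arrays out); stages 4-6
annotate :class:`~caveclass.blobs.Blob` objects and never touch geometry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .blobs import (
    CLASS_CAVEOLAE,
    CLASS_NON_CAVEOLAE,
    PTRF_NEGATIVE,
    PTRF_POSITIVE,
    Blob,
    MaskImage,
)

logger = logging.getLogger(__name__)


@dataclass
class NoiseFilterConfig:
    """CSR local-density test: keep a point iff its neighbor count within
    ``neighbor_radius_nm`` exceeds the CSR expectation by ``k`` Poisson SDs."""

    neighbor_radius_nm: float = 50.0
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.neighbor_radius_nm <= 0:
            raise ValueError("neighbor_radius_nm must be > 0")


@dataclass
class PreprocessConfig:
    merge_radius_nm: float = 20.0
    segmentation_radius_nm: float = 80.0
    noise_filter: NoiseFilterConfig = field(default_factory=NoiseFilterConfig)
    mask_overlap_threshold: float = 0.5
    caveolae_min_molecules: int = 60
    balance_seed: int = 0

    def __post_init__(self) -> None:
        if self.merge_radius_nm <= 0 or self.segmentation_radius_nm <= 0:
            raise ValueError("radii must be > 0")
        if not 0 < self.mask_overlap_threshold <= 1:
            raise ValueError("mask_overlap_threshold must be in (0, 1]")
        if self.caveolae_min_molecules < 1:
            raise ValueError("caveolae_min_molecules must be >= 1")


def _adjacency_components(points: np.ndarray, radius: float) -> np.ndarray:
    """Connected-component labels of the <=radius adjacency graph."""
    n = points.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def iterative_merge(points: np.ndarray, merge_radius_nm: float = 20.0) -> np.ndarray:
    """Merge localizations within the radius until convergence.

    Each iteration groups points into connected components of the <=radius
    adjacency relation and replaces every component by its centroid
    (component-wise grouping keeps the result independent of point order).
    On return every pairwise distance exceeds the radius.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    while pts.shape[0] > 1:
        labels = _adjacency_components(pts, merge_radius_nm)
        n_comp = labels.max() + 1
        if n_comp == pts.shape[0]:
            break
        merged = np.empty((n_comp, 3))
        for c in range(n_comp):
            merged[c] = pts[labels == c].mean(axis=0)
        pts = merged
    return pts


def merge_eventlist(locs: pd.DataFrame, merge_radius_nm: float = 20.0) -> pd.DataFrame:
    """Apply :func:`iterative_merge` per cell to a canonical eventlist.

    The merged localization inherits the smallest ``source_row`` of any
    localization that contributed to it (provenance of the merged molecule).
    """
    out = []
    for cell, grp in locs.groupby("cell_id", sort=False):
        pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy()
        rows = grp["source_row"].to_numpy()
        # track min source_row through the same component reduction
        while pts.shape[0] > 1:
            labels = _adjacency_components(pts, merge_radius_nm)
            n_comp = labels.max() + 1
            if n_comp == pts.shape[0]:
                break
            merged = np.empty((n_comp, 3))
            merged_rows = np.empty(n_comp, dtype=rows.dtype)
            for c in range(n_comp):
                sel = labels == c
                merged[c] = pts[sel].mean(axis=0)
                merged_rows[c] = rows[sel].min()
            pts, rows = merged, merged_rows
        out.append(
            pd.DataFrame(
                {"x_nm": pts[:, 0], "y_nm": pts[:, 1], "z_nm": pts[:, 2],
                 "cell_id": cell, "source_row": rows}
            )
        )
    merged = pd.concat(out, ignore_index=True) if out else locs.iloc[:0].copy()
    logger.info("iterative_merge: %d -> %d localizations", len(locs), len(merged))
    return merged


def csr_expected_neighbors(n: int, bbox_volume: float, radius: float) -> float:
    """Expected neighbor count within ``radius`` for a CSR process of global
    density n / bbox_volume (excluding the point itself)."""
    density = n / bbox_volume
    return density * (4.0 / 3.0) * np.pi * radius**3


def filter_noise(
    points: np.ndarray,
    config: Optional[NoiseFilterConfig] = None,
    bbox_volume: Optional[float] = None,
) -> np.ndarray:
    """Boolean retain-mask under the CSR local-density test.

    A point is retained iff its neighbor count within ``neighbor_radius_nm``
    exceeds ``lambda + k * sqrt(lambda)`` where ``lambda`` is the CSR
    expectation at the dataset's global density (points per axis-aligned
    bounding-box volume, or ``bbox_volume`` if given). Deterministic.
    """
    config = config or NoiseFilterConfig()
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if n < 2:
        warnings.warn("filter_noise: fewer than 2 points, returned unchanged", stacklevel=2)
        return np.ones(n, dtype=bool)
    if bbox_volume is None:
        extent = pts.max(axis=0) - pts.min(axis=0)
        bbox_volume = float(np.prod(np.maximum(extent, 1e-9)))
    lam = csr_expected_neighbors(n, bbox_volume, config.neighbor_radius_nm)
    tree = cKDTree(pts)
    counts = np.array(tree.query_ball_point(pts, config.neighbor_radius_nm, return_length=True))
    counts = counts - 1  # exclude the point itself
    keep = counts > lam + config.k * np.sqrt(lam)
    logger.info("filter_noise: retained %d / %d points", int(keep.sum()), n)
    return keep


def segment_blobs(
    locs: pd.DataFrame,
    segmentation_radius_nm: float = 80.0,
    blob_prefix: str = "blob",
) -> list[Blob]:
    """Segment an eventlist into blobs: connected components of the <=radius
    adjacency graph, per cell. Blob ids are ordered by the component's
    minimum ``source_row`` so segmentation is deterministic.
    """
    if segmentation_radius_nm <= 0:
        raise ValueError("segmentation_radius_nm must be > 0")
    blobs: list[Blob] = []
    for cell, grp in locs.groupby("cell_id", sort=False):
        pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy()
        rows = grp["source_row"].to_numpy()
        labels = _adjacency_components(pts, segmentation_radius_nm)
        if labels.size == 0:
            continue
        order = sorted(range(labels.max() + 1), key=lambda c: rows[labels == c].min())
        for rank, c in enumerate(order):
            blobs.append(
                Blob(
                    blob_id=f"{blob_prefix}_{cell}_{rank:05d}",
                    points=pts[labels == c],
                    cell_id=str(cell),
                )
            )
    logger.info("segment_blobs: %d localizations -> %d blobs", len(locs), len(blobs))
    return blobs


def label_with_mask(
    blobs: Sequence[Blob],
    mask: Optional[MaskImage],
    overlap_threshold: float = 0.5,
) -> list[Blob]:
    """Assign PTRF status from the wide-field mask (annotation only).

    A blob is PTRF+ iff the fraction of its points whose XY position falls in
    a positive mask pixel is >= ``overlap_threshold`` (inclusive boundary).
    ``mask=None`` declares the cell PTRF-free: every blob is labeled PTRF-
    directly (PC3 cells without CAVIN1/PTRF).
    """
    out = []
    for b in blobs:
        if mask is None:
            status = PTRF_NEGATIVE
        else:
            inside = mask.contains_xy(b.points[:, 0], b.points[:, 1])
            h, w = mask.pixels.shape
            col = np.floor((b.points[:, 0] - mask.origin_nm[0]) / mask.pixel_size_nm)
            row = np.floor((b.points[:, 1] - mask.origin_nm[1]) / mask.pixel_size_nm)
            on_raster = (row >= 0) & (row < h) & (col >= 0) & (col < w)
            if not on_raster.any():
                warnings.warn(
                    f"blob {b.blob_id!r} lies entirely outside the mask raster; labeled PTRF-",
                    stacklevel=2,
                )
            status = PTRF_POSITIVE if inside.mean() >= overlap_threshold else PTRF_NEGATIVE
        out.append(
            Blob(
                blob_id=b.blob_id, points=b.points, cell_id=b.cell_id,
                ptrf_status=status, class_label=b.class_label,
            )
        )
    n_pos = sum(b.ptrf_status == PTRF_POSITIVE for b in out)
    logger.info("label_with_mask: %d PTRF+ / %d blobs", n_pos, len(out))
    return out


def stratify_classes(blobs: Sequence[Blob], caveolae_min_molecules: int = 60) -> list[Blob]:
    """Binary class from PTRF status and molecule count.

    caveolae iff PTRF+ and molecule_count >= threshold (inclusive); PTRF-
    blobs and PTRF+ blobs below the threshold are non-caveolae.
    """
    out = []
    for b in blobs:
        if b.ptrf_status is None:
            raise ValueError(f"blob {b.blob_id!r} has no ptrf_status; run label_with_mask first")
        cls = (
            CLASS_CAVEOLAE
            if b.ptrf_status == PTRF_POSITIVE and b.molecule_count >= caveolae_min_molecules
            else CLASS_NON_CAVEOLAE
        )
        out.append(
            Blob(
                blob_id=b.blob_id, points=b.points, cell_id=b.cell_id,
                ptrf_status=b.ptrf_status, class_label=cls,
            )
        )
    n_cav = sum(b.class_label == CLASS_CAVEOLAE for b in out)
    logger.info("stratify_classes: %d caveolae / %d blobs", n_cav, len(out))
    return out


def balance_dataset(blobs: Sequence[Blob], seed: int = 0) -> list[Blob]:
    """Downsample the majority class uniformly at random (without replacement)
    to the minority count. Output order: input order restricted to kept blobs.
    """
    pos = [b for b in blobs if b.class_label == CLASS_CAVEOLAE]
    neg = [b for b in blobs if b.class_label == CLASS_NON_CAVEOLAE]
    if not pos or not neg:
        raise ValueError(
            f"both classes required to balance, got {len(pos)} caveolae / {len(neg)} non-caveolae"
        )
    rng = np.random.default_rng(seed)
    minority = min(len(pos), len(neg))
    keep_ids = set()
    for group in (pos, neg):
        if len(group) > minority:
            idx = rng.choice(len(group), size=minority, replace=False)
            keep_ids.update(group[i].blob_id for i in idx)
        else:
            keep_ids.update(b.blob_id for b in group)
    out = [b for b in blobs if b.blob_id in keep_ids]
    logger.info("balance_dataset: %d -> %d blobs (%d per class)", len(blobs), len(out), minority)
    return out
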