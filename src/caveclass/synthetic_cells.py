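"""Synthetic multi-cell eventlists plus painted CAVIN1/PTRF masks.

Emulates the inputs of the experimental workflow so the full
preprocess -> label -> stratify -> balance -> classify pipeline can run
without any acquired data: each cell is a field of Gaussian blob clusters
(caveola-like and scaffold-like) over a uniform background of spurious
localizations, and PTRF-transfected cells come with a binary wide-field
mask (20 nm pixels) painted as disks over the caveola-designated clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .blobs import MaskImage


@dataclass
class SyntheticCellParams:
    """One simulated cell's layout.

    Blob centers are scattered on a jittered grid so clusters stay well
    separated (minimum spacing far above the segmentation radius). Caveola-
    designated clusters get >= 60 molecules and a mask disk; scaffold-like
    clusters get fewer molecules and/or no mask coverage.
    """

    field_size_nm: float = 6000.0
    n_caveolae: int = 12
    n_scaffolds: int = 24
    caveola_sigma_nm: float = 55.0
    scaffold_sigma_nm: float = 50.0
    caveola_molecules: tuple[int, int] = (150, 250)
    scaffold_molecules: tuple[int, int] = (15, 55)
    background_points: int = 150
    mask_pixel_nm: float = 20.0
    mask_disk_radius_nm: float = 250.0
    z_spread_nm: float = 120.0


def _blob_centers(rng: np.random.Generator, n: int, field: float, spacing: float) -> np.ndarray:
    """Jittered-grid centers with guaranteed minimum spacing."""
    per_side = int(np.ceil(np.sqrt(n)))
    cell = field / per_side
    if cell < spacing:
        raise ValueError(f"field too small for {n} blobs at spacing {spacing}")
    jitter = (cell - spacing) / 2.0
    centers = []
    for i in range(per_side):
        for j in range(per_side):
            cx = (i + 0.5) * cell + rng.uniform(-jitter, jitter)
            cy = (j + 0.5) * cell + rng.uniform(-jitter, jitter)
            centers.append((cx, cy))
    centers = np.array(centers)
    rng.shuffle(centers)
    return centers[:n]


def generate_cell(
    params: SyntheticCellParams,
    rng: np.random.Generator,
    cell_id: str,
    with_mask: bool = True,
) -> tuple[pd.DataFrame, Optional[MaskImage]]:
    """One cell's eventlist (canonical nm columns) and, for PTRF-transfected
    cells, the painted mask. ``with_mask=False`` emulates a PTRF-absent cell
    (no caveolae, no mask)."""
    n_cav = params.n_caveolae if with_mask else 0
    n_total = n_cav + params.n_scaffolds
    centers = _blob_centers(rng, n_total, params.field_size_nm, spacing=900.0)
    xs, ys, zs = [], [], []
    mask = None
    if with_mask:
        side = int(np.ceil(params.field_size_nm / params.mask_pixel_nm))
        mask_px = np.zeros((side, side), dtype=np.uint8)
    for b in range(n_total):
        cx, cy = centers[b]
        caveola = b < n_cav
        lo, hi = params.caveola_molecules if caveola else params.scaffold_molecules
        n_mol = int(rng.integers(lo, hi + 1))
        sigma = params.caveola_sigma_nm if caveola else params.scaffold_sigma_nm
        pts_xy = rng.normal([cx, cy], sigma, size=(n_mol, 2))
        pts_z = rng.normal(0.0, params.z_spread_nm / 3.0, size=n_mol)
        xs.append(pts_xy[:, 0]); ys.append(pts_xy[:, 1]); zs.append(pts_z)
        if caveola and with_mask:
            rr = params.mask_disk_radius_nm / params.mask_pixel_nm
            ci, cj = cy / params.mask_pixel_nm, cx / params.mask_pixel_nm
            ii, jj = np.ogrid[:mask_px.shape[0], :mask_px.shape[1]]
            mask_px[(ii - ci) ** 2 + (jj - cj) ** 2 <= rr**2] = 1
    # uniform background of spurious localizations
    n_bg = params.background_points
    xs.append(rng.uniform(0, params.field_size_nm, n_bg))
    ys.append(rng.uniform(0, params.field_size_nm, n_bg))
    zs.append(rng.uniform(-params.z_spread_nm, params.z_spread_nm, n_bg))
    x = np.concatenate(xs); y = np.concatenate(ys); z = np.concatenate(zs)
    locs = pd.DataFrame(
        {"x_nm": x, "y_nm": y, "z_nm": z, "cell_id": cell_id,
         "source_row": np.arange(len(x))}
    )
    if with_mask:
        mask = MaskImage(pixels=mask_px, pixel_size_nm=params.mask_pixel_nm)
    return locs, mask


def generate_experiment(
    n_ptrf_cells: int = 3,
    n_plain_cells: int = 1,
    params: Optional[SyntheticCellParams] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Optional[MaskImage]]]:
    """A small multi-cell experiment: PTRF-transfected cells (with masks) and
    PTRF-absent cells (mask-free, all-negative). Returns the concatenated
    eventlist and a cell_id -> mask mapping (None marks mask-free cells)."""
    params = params or SyntheticCellParams()
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_ptrf_cells + n_plain_cells)
    frames, masks = [], {}
    for i in range(n_ptrf_cells):
        cid = f"ptrf_{i + 1}"
        locs, mask = generate_cell(params, np.random.default_rng(streams[i]), cid, with_mask=True)
        frames.append(locs); masks[cid] = mask
    for i in range(n_plain_cells):
        cid = f"pc3_{i + 1}"
        locs, _ = generate_cell(
            params, np.random.default_rng(streams[n_ptrf_cells + i]), cid, with_mask=False
        )
        frames.append(locs); masks[cid] = None
    return pd.concat(frames, ignore_index=True), masks
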