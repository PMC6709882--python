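"""Readers and writers for eventlists, blob sets and mask rasters.

The on-disk model is deliberately plain: delimited text (UTF-8, header row)
for localization tables and blob sets, TIFF/PNG rasters for masks, and a JSON
manifest next to every multi-file artifact recording units and row counts so
silently truncated files are rejected on read. All coordinates are converted
to nm at ingest; nothing downstream performs unit conversion.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.morphology import closing, disk

from .blobs import Blob, MaskImage

#: Acquisition calibration: XY pixel 20 nm, Z pixel 25 nm.
XY_PIXEL_NM = 20.0
Z_PIXEL_NM = 25.0

EVENTLIST_COLUMNS = ["x_nm", "y_nm", "z_nm", "cell_id", "source_row"]


def read_eventlist(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    units: str = "nm",
    xy_pixel_nm: float = XY_PIXEL_NM,
    z_pixel_nm: float = Z_PIXEL_NM,
    sep: str = ",",
    cell_id: Optional[str] = None,
) -> pd.DataFrame:
    """Read a localization table into the canonical nm frame.

    Parameters
    ----------
    path : path
        Delimited-text file with a header row.
    column_map : mapping, optional
        Maps canonical names ``{"x", "y", "z", "cell_id"}`` to the file's
        column names. Defaults to identity (``x``, ``y``, ``z``).
    units : {"nm", "pixels"}
        If ``"pixels"``, XY coordinates are multiplied by ``xy_pixel_nm`` and
        Z by ``z_pixel_nm``.
    cell_id : str, optional
        Cell identifier applied to every row when the file has no cell column.

    Returns
    -------
    DataFrame with columns ``x_nm, y_nm, z_nm, cell_id, source_row``; row
    order preserved, ``source_row`` is the 0-based input row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {"x": "x", "y": "y", "z": "z"}
    if column_map:
        cmap.update(column_map)
    table = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if table.shape[0] == 0:
        raise ValueError(f"empty eventlist: {path}")
    missing = [cmap[k] for k in ("x", "y", "z") if cmap[k] not in table.columns]
    if missing:
        raise ValueError(f"eventlist {path} is missing columns {missing}; has {list(table.columns)}")
    coords = table[[cmap["x"], cmap["y"], cmap["z"]]].apply(pd.to_numeric, errors="coerce")
    if coords.isna().any().any():
        bad = int(coords.isna().any(axis=1).sum())
        raise ValueError(f"eventlist {path}: {bad} rows with non-numeric coordinates")
    x, y, z = (coords.iloc[:, i].to_numpy(dtype=float) for i in range(3))
    if units == "pixels":
        x = x * xy_pixel_nm
        y = y * xy_pixel_nm
        z = z * z_pixel_nm
    elif units != "nm":
        raise ValueError(f"units must be 'nm' or 'pixels', got {units!r}")
    if "cell_id" in cmap and cmap["cell_id"] in table.columns:
        cells = table[cmap["cell_id"]].astype(str).to_numpy()
    else:
        cells = np.full(len(x), cell_id if cell_id is not None else "cell0", dtype=object)
    return pd.DataFrame(
        {"x_nm": x, "y_nm": y, "z_nm": z, "cell_id": cells, "source_row": np.arange(len(x))}
    )


def write_eventlist(locs: pd.DataFrame, path: str | Path) -> Path:
    """Write a canonical eventlist back to CSV (nm units, full precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    locs.to_csv(path, index=False, float_format="%.17g")
    return path


def read_mask(
    path: str | Path,
    pixel_size_nm: float,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> MaskImage:
    """Read a raster (TIFF/PNG), binarize it (nonzero -> 1), attach calibration."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse RGB(A) to a single channel
        arr = arr[..., :3].max(axis=-1)
    mask = MaskImage(pixels=arr, pixel_size_nm=pixel_size_nm, origin_nm=origin_nm)
    if mask.pixels.sum() == 0:
        warnings.warn(f"mask {path} has zero positive area", stacklevel=2)
    return mask


def write_mask(mask: MaskImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))
    return path


def morphological_close(mask: MaskImage, radius_px: int) -> MaskImage:
    """Binary closing (dilation then erosion) with a disk structuring element.

    Used to close small holes in the CAVIN1/PTRF mask before blob labeling.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    closed = closing(mask.pixels.astype(bool), footprint=disk(radius_px))
    return MaskImage(
        pixels=closed.astype(np.uint8), pixel_size_nm=mask.pixel_size_nm, origin_nm=mask.origin_nm
    )


# ---------------------------------------------------------------------------
# Blob set serialization: long-format points table + annotations table,
# keyed by blob_id (N varies per blob, so a wide layout does not fit).
# ---------------------------------------------------------------------------

def write_blobs(blobs: Sequence[Blob], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pts_frames = []
    ann_rows = []
    for b in blobs:
        pts_frames.append(
            pd.DataFrame(
                {
                    "blob_id": b.blob_id,
                    "x_nm": b.points[:, 0],
                    "y_nm": b.points[:, 1],
                    "z_nm": b.points[:, 2],
                }
            )
        )
        ann_rows.append(
            {
                "blob_id": b.blob_id,
                "cell_id": b.cell_id if b.cell_id is not None else "",
                "ptrf_status": b.ptrf_status if b.ptrf_status is not None else "",
                "molecule_count": b.molecule_count,
                "class": b.class_label if b.class_label is not None else "",
            }
        )
    points = (
        pd.concat(pts_frames, ignore_index=True)
        if pts_frames
        else pd.DataFrame(columns=["blob_id", "x_nm", "y_nm", "z_nm"])
    )
    annotations = pd.DataFrame(
        ann_rows, columns=["blob_id", "cell_id", "ptrf_status", "molecule_count", "class"]
    )
    points.to_csv(out / "points.csv", index=False, float_format="%.17g")
    annotations.to_csv(out / "annotations.csv", index=False)
    manifest = {
        "kind": "blob_set",
        "units": "nm",
        "n_blobs": len(blobs),
        "n_points_rows": int(points.shape[0]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_blobs(in_dir: str | Path) -> list[Blob]:
    """Read a blob set written by :func:`write_blobs` (manifest-checked)."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    points = pd.read_csv(in_dir / "points.csv", float_precision="round_trip")
    annotations = pd.read_csv(
        in_dir / "annotations.csv", dtype={"blob_id": str}, keep_default_na=False
    )
    if points.shape[0] != manifest["n_points_rows"]:
        raise ValueError(
            f"truncated points table: manifest declares {manifest['n_points_rows']} rows, "
            f"found {points.shape[0]}"
        )
    if annotations.shape[0] != manifest["n_blobs"]:
        raise ValueError(
            f"truncated annotations table: manifest declares {manifest['n_blobs']} blobs, "
            f"found {annotations.shape[0]}"
        )
    groups = {str(k): v for k, v in points.groupby("blob_id", sort=False)}
    blobs = []
    for row in annotations.to_dict("records"):
        bid = str(row["blob_id"])
        grp = groups.get(bid)
        if grp is None:
            raise ValueError(f"annotations reference blob {bid!r} absent from points table")
        b = Blob(
            blob_id=bid,
            points=grp[["x_nm", "y_nm", "z_nm"]].to_numpy(),
            cell_id=str(row["cell_id"]) or None,
            ptrf_status=str(row["ptrf_status"]) or None,
            class_label=str(row["class"]) or None,
        )
        if b.molecule_count != int(row["molecule_count"]):
            raise ValueError(
                f"blob {bid!r}: molecule_count {row['molecule_count']} does not match "
                f"{b.molecule_count} points"
            )
        blobs.append(b)
    return blobs
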