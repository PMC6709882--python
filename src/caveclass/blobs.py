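"""Core in-memory containers shared across the pipeline.

All coordinates are carried in nanometres. A *blob* is one segmented 3D
cluster of localizations (one candidate cellular structure); annotations
(PTRF status, class) are attached as the pipeline progresses and never
modify the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: PTRF status labels (wide-field CAVIN1/PTRF mask overlap).
PTRF_POSITIVE = "PTRF+"
PTRF_NEGATIVE = "PTRF-"

#: Binary class labels. Caveolae are the positive class.
CLASS_CAVEOLAE = "caveolae"
CLASS_NON_CAVEOLAE = "non-caveolae"

#: Integer encoding used by every classifier in the package.
LABEL_POSITIVE = 1
LABEL_NEGATIVE = 0


@dataclass
class Blob:
    """A segmented cluster of 3D localizations.

    Parameters
    ----------
    blob_id : str
        Unique identifier within a dataset.
    points : (N, 3) ndarray
        Localization coordinates in nm, one row per molecule.
    cell_id : str, optional
        Identifier of the source cell.
    ptrf_status : str, optional
        ``"PTRF+"`` or ``"PTRF-"`` once mask labeling has run.
    class_label : str, optional
        ``"caveolae"`` or ``"non-caveolae"`` once stratification has run.
    """

    blob_id: str
    points: np.ndarray
    cell_id: Optional[str] = None
    ptrf_status: Optional[str] = None
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"blob {self.blob_id!r}: points must be (N, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError(f"blob {self.blob_id!r}: at least one point required")
        self.points = pts

    @property
    def molecule_count(self) -> int:
        """Number of molecules (points) in the blob."""
        return int(self.points.shape[0])

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def label(self) -> Optional[int]:
        """Integer class label (1 = caveolae, 0 = non-caveolae), if assigned."""
        if self.class_label is None:
            return None
        return LABEL_POSITIVE if self.class_label == CLASS_CAVEOLAE else LABEL_NEGATIVE


@dataclass
class MaskImage:
    """Calibrated binary 2D raster (wide-field CAVIN1/PTRF mask).

    ``pixels[i, j]`` covers the nm rectangle
    ``origin + [j, j+1) * pixel_size`` in x and ``[i, i+1) * pixel_size`` in y.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {px.shape}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        self.pixels = (px != 0).astype(np.uint8)

    def contains_xy(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        """Vectorized membership test: is each (x, y) inside a positive pixel?

        Points outside the raster extent are reported as not contained.
        """
        col = np.floor((np.asarray(x_nm, float) - self.origin_nm[0]) / self.pixel_size_nm).astype(int)
        row = np.floor((np.asarray(y_nm, float) - self.origin_nm[1]) / self.pixel_size_nm).astype(int)
        h, w = self.pixels.shape
        inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
        out = np.zeros(col.shape, dtype=bool)
        if inside.any():
            out[inside] = self.pixels[row[inside], col[inside]] > 0
        return out


@dataclass
class SimulatedBlob:
    """A synthetic blob with its generating class recorded at draw time."""

    blob_id: str
    points: np.ndarray
    true_class: str  # "positive" (isotropic) or "negative" (anisotropic)
    seed_used: int = field(default=0)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        self.points = pts

    @property
    def label(self) -> int:
        return LABEL_POSITIVE if self.true_class == "positive" else LABEL_NEGATIVE
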