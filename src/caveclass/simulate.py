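"""Synthetic two-class blob generator.

Blobs are i.i.d. draws from a zero-mean 3D multivariate normal. The positive
(isotropic, caveola-like) class uses Sigma = diag(sigma^2, sigma^2, sigma^2);
the negative (anisotropic, scaffold-like) class uses
Sigma = diag(2*sigma^2, sigma^2, sigma^2), with sigma = 10 nm. Points per
blob are drawn uniformly from 60-210 (positive) and 10-160 (negative), so
the two classes overlap heavily in molecule count and differ only in shape.

A master seed spawns one independent substream per blob, so datasets are
bitwise reproducible regardless of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blobs import SimulatedBlob

CLASS_POSITIVE = "positive"
CLASS_NEGATIVE = "negative"


@dataclass
class SimulationParams:
    """Parameters of the two-class multivariate-normal blob model.

    Defaults are the study conditions: sigma = 10 nm, mu = 0, a balanced
    dataset of 1000 blobs per class, point counts uniform on the inclusive
    intervals 60-210 (positive) and 10-160 (negative).
    """

    sigma: float = 10.0
    mu: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_range_positive: tuple[int, int] = (60, 210)
    n_range_negative: tuple[int, int] = (10, 160)
    n_blobs_per_class: int = 1000
    seed: int = 0
    cov_positive: Optional[np.ndarray] = field(default=None)
    cov_negative: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        s2 = float(self.sigma) ** 2
        if self.cov_positive is None:
            self.cov_positive = np.diag([s2, s2, s2])
        if self.cov_negative is None:
            self.cov_negative = np.diag([2.0 * s2, s2, s2])
        self.cov_positive = np.asarray(self.cov_positive, dtype=float)
        self.cov_negative = np.asarray(self.cov_negative, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, cov in (("cov_positive", self.cov_positive), ("cov_negative", self.cov_negative)):
            if cov.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3")
            if not np.allclose(cov, cov.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError(f"{name} must be positive definite")
        for name, (lo, hi) in (
            ("n_range_positive", self.n_range_positive),
            ("n_range_negative", self.n_range_negative),
        ):
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi, got ({lo}, {hi})")
        if self.n_blobs_per_class < 0:
            raise ValueError("n_blobs_per_class must be >= 0")

    def cov_for(self, class_label: str) -> np.ndarray:
        if class_label == CLASS_POSITIVE:
            return self.cov_positive
        if class_label == CLASS_NEGATIVE:
            return self.cov_negative
        raise ValueError(f"unknown class label {class_label!r}")

    def n_range_for(self, class_label: str) -> tuple[int, int]:
        if class_label == CLASS_POSITIVE:
            return self.n_range_positive
        if class_label == CLASS_NEGATIVE:
            return self.n_range_negative
        raise ValueError(f"unknown class label {class_label!r}")

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "mu": list(self.mu),
            "cov_positive": self.cov_positive.tolist(),
            "cov_negative": self.cov_negative.tolist(),
            "n_range_positive": list(self.n_range_positive),
            "n_range_negative": list(self.n_range_negative),
            "n_blobs_per_class": self.n_blobs_per_class,
            "seed": self.seed,
        }


def generate_blob(
    params: SimulationParams,
    class_label: str,
    n_points: int,
    rng: np.random.Generator,
    blob_id: str = "blob",
    seed_used: int = 0,
) -> SimulatedBlob:
    """Draw one blob: ``n_points`` i.i.d. samples from N(mu, Sigma_class).

    Sampling goes through the Cholesky factor of the class covariance applied
    to standard-normal draws, so any diagonal or full SPD covariance works.
    """
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    cov = params.cov_for(class_label)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_points, 3))
    points = np.asarray(params.mu, dtype=float) + z @ chol.T
    return SimulatedBlob(blob_id=blob_id, points=points, true_class=class_label, seed_used=seed_used)


def generate_dataset(params: SimulationParams) -> list[SimulatedBlob]:
    """Generate the balanced labeled dataset (``n_blobs_per_class`` per class).

    Point counts per blob are discrete-uniform over the class interval
    (inclusive bounds). One :class:`numpy.random.SeedSequence` child per blob
    makes the output independent of generation order.
    """
    params.validate()
    n = params.n_blobs_per_class
    master = np.random.SeedSequence(params.seed)
    children = master.spawn(2 * n)
    blobs: list[SimulatedBlob] = []
    for i, class_label in enumerate((CLASS_POSITIVE, CLASS_NEGATIVE)):
        lo, hi = params.n_range_for(class_label)
        tag = "pos" if class_label == CLASS_POSITIVE else "neg"
        for j in range(n):
            child = children[i * n + j]
            rng = np.random.default_rng(child)
            n_points = int(rng.integers(lo, hi + 1))
            blob = generate_blob(
                params,
                class_label,
                n_points,
                rng,
                blob_id=f"{tag}_{j:04d}",
                seed_used=int(child.generate_state(1)[0]),
            )
            blobs.append(blob)
    return blobs


def dataset_to_frame(blobs: Sequence[SimulatedBlob]) -> pd.DataFrame:
    """Long-format table: one row per point, columns blob_id, class, x/y/z_nm."""
    frames = []
    for b in blobs:
        frames.append(
            pd.DataFrame(
                {
                    "blob_id": b.blob_id,
                    "class": b.true_class,
                    "x_nm": b.points[:, 0],
                    "y_nm": b.points[:, 1],
                    "z_nm": b.points[:, 2],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["blob_id", "class", "x_nm", "y_nm", "z_nm"])
    return pd.concat(frames, ignore_index=True)


def write_dataset(blobs: Sequence[SimulatedBlob], params: SimulationParams, out_dir: str | Path) -> Path:
    """Export the dataset as ``blobs.csv`` plus a run manifest. Returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = dataset_to_frame(blobs)
    table.to_csv(out / "blobs.csv", index=False, float_format="%.9g")
    manifest = {
        "kind": "simulated_blob_dataset",
        "params": params.to_dict(),
        "n_blobs": len(blobs),
        "n_rows": int(table.shape[0]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_dataset(in_dir: str | Path) -> list[SimulatedBlob]:
    """Read a dataset written by :func:`write_dataset`, checking the manifest row count."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    table = pd.read_csv(in_dir / "blobs.csv")
    if table.shape[0] != manifest["n_rows"]:
        raise ValueError(
            f"truncated dataset: manifest declares {manifest['n_rows']} rows, found {table.shape[0]}"
        )
    blobs = []
    for blob_id, grp in table.groupby("blob_id", sort=False):
        blobs.append(
            SimulatedBlob(
                blob_id=str(blob_id),
                points=grp[["x_nm", "y_nm", "z_nm"]].to_numpy(),
                true_class=str(grp["class"].iloc[0]),
            )
        )
    return blobs
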