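"""Phantom-based HU-to-density calibration.

A densitometric phantom (e.g. the European Spine Phantom) carries inserts of
known calcium-hydroxyapatite equivalent density. The mean HU inside each
insert ROI is regressed (ordinary least squares) against the nominal insert
densities to obtain the calibration line ``rho = intercept + slope * HU`` in
mg/cm^3. The same :class:`CalibrationLine` container also carries phantomless
fits, distinguished by the ``method`` tag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .core import CTVolume

__all__ = [
    "CalibrationLine",
    "CylinderROI",
    "PhantomSpec",
    "measure_insert_hu",
    "fit_calibration",
    "apply_calibration",
]

DEFAULT_INSERT_DENSITIES = (50.0, 100.0, 200.0, 400.0, 800.0)
"""Nominal HA-equivalent insert densities of an ESP-style phantom (mg/cm^3)."""


@dataclass
class CalibrationLine:
    """Linear HU -> HA-equivalent-density mapping with fit diagnostics.

    ``intercept`` is in mg/cm^3, ``slope`` in mg/cm^3 per HU. ``method`` tags
    the provenance of the fit (``"phantom"`` or ``"phantomless"``).
    """

    intercept: float
    slope: float
    r_squared: float = 1.0
    n_points: int = 0
    method: str = "phantom"

    def __post_init__(self) -> None:
        self.intercept = float(self.intercept)
        self.slope = float(self.slope)
        self.r_squared = float(self.r_squared)
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("calibration coefficients must be finite")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))
        if self.slope <= 0:
            warnings.warn(
                f"calibration slope {self.slope} is non-positive; a physically "
                "valid HU-to-density line has positive slope",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "r_squared": self.r_squared,
            "n_points": int(self.n_points),
            "method": self.method,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationLine":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class CylinderROI:
    """Cylindrical insert ROI defined in physical mm (LPS).

    Voxels whose centres fall inside the cylinder are included when
    rasterized onto a volume grid.
    """

    center: Sequence[float]
    axis: Sequence[float]
    radius: float
    height: float

    def rasterize(self, volume: CTVolume) -> np.ndarray:
        center = np.asarray(self.center, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("cylinder axis must be non-zero")
        axis = axis / norm
        shape = volume.shape
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1
        )
        pts = volume.index_to_physical(idx) - center
        along = pts @ axis
        radial2 = np.einsum("...i,...i->...", pts, pts) - along**2
        return (np.abs(along) <= self.height / 2.0) & (radial2 <= self.radius**2)


@dataclass
class PhantomSpec:
    """Inserts of a calibration phantom: densities plus one ROI per insert.

    ROIs are boolean voxel masks or :class:`CylinderROI` geometry; densities
    must be strictly increasing with at least two inserts.
    """

    insert_densities: Sequence[float]
    insert_rois: Sequence[np.ndarray | CylinderROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.insert_densities = tuple(float(d) for d in self.insert_densities)
        if len(self.insert_densities) < 2:
            raise ValueError("a phantom needs at least two inserts")
        if any(b <= a for a, b in zip(self.insert_densities, self.insert_densities[1:])):
            raise ValueError(
                f"insert densities must be strictly increasing, got {self.insert_densities}"
            )
        if self.insert_rois and len(self.insert_rois) != len(self.insert_densities):
            raise ValueError("need exactly one ROI per insert")

    def masks(self, volume: CTVolume) -> list[np.ndarray]:
        """Rasterize/validate the insert ROIs on a volume grid."""
        if not self.insert_rois:
            raise ValueError("phantom spec carries no insert ROIs")
        masks = []
        for i, roi in enumerate(self.insert_rois):
            if isinstance(roi, CylinderROI):
                mask = roi.rasterize(volume)
            else:
                mask = np.asarray(roi, dtype=bool)
                if mask.shape != volume.shape:
                    raise ValueError(
                        f"ROI {i} shape {mask.shape} does not match volume {volume.shape}"
                    )
            masks.append(mask)
        combined = np.zeros(volume.shape, dtype=np.int64)
        for mask in masks:
            combined += mask
        if np.any(combined > 1):
            raise ValueError("insert ROIs overlap")
        return masks


def measure_insert_hu(volume: CTVolume, spec: PhantomSpec) -> np.ndarray:
    """Arithmetic mean HU inside each insert ROI, in insert order."""
    means = []
    for i, mask in enumerate(spec.masks(volume)):
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"insert ROI {i} (density {spec.insert_densities[i]}) is empty")
        boundary = (
            mask[0].any() or mask[-1].any()
            or mask[:, 0].any() or mask[:, -1].any()
            or mask[..., 0].any() or mask[..., -1].any()
        )
        if boundary:
            warnings.warn(f"insert ROI {i} touches the volume boundary", stacklevel=2)
        means.append(float(volume.voxels[mask].mean()))
    return np.asarray(means)


def fit_calibration(
    mean_hu: Sequence[float],
    densities: Sequence[float],
    method: str = "phantom",
) -> CalibrationLine:
    """OLS fit of ``density = intercept + slope * HU``.

    Density is the response and HU the regressor, matching how the line is
    consumed downstream; the inverse regression is deliberately not offered.
    """
    hu = np.asarray(mean_hu, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if hu.shape != rho.shape or hu.ndim != 1:
        raise ValueError("mean_hu and densities must be 1-D of equal length")
    if hu.size < 2:
        raise ValueError(f"need at least 2 calibration points, got {hu.size}")
    if np.ptp(hu) == 0:
        raise ValueError("HU values are all identical; calibration line is undefined")
    res = stats.linregress(hu, rho)
    return CalibrationLine(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(hu.size),
        method=method,
    )


def apply_calibration(line: CalibrationLine, hu):
    """Element-wise ``intercept + slope * HU`` (mg/cm^3), shape preserved."""
    hu_arr = np.asarray(hu, dtype=float)
    out = line.intercept + line.slope * hu_arr
    if np.isscalar(hu) or hu_arr.ndim == 0:
        return float(out)
    return out
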