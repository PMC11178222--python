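"""Volume and landmark data model with DICOM/NIfTI readers and a NIfTI writer.

All physical coordinates inside the package are expressed in the patient-based
LPS convention (x toward Left, y toward Posterior, z toward Superior), the
native frame of DICOM. NIfTI affines (RAS) and landmark files declaring an
``RAS`` convention are converted on load. Voxel indexing is 0-based and a
voxel's physical coordinate refers to its centre.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CTVolume",
    "Landmarks",
    "read_volume",
    "read_landmarks",
    "write_nifti",
    "knee_center",
]

# voxel-axis orientation label -> (LPS axis index, sign of increasing index)
_LABEL_TO_LPS = {
    "L": (0, 1.0),
    "R": (0, -1.0),
    "P": (1, 1.0),
    "A": (1, -1.0),
    "S": (2, 1.0),
    "I": (2, -1.0),
}

# maximum angular deviation from an anatomical axis for axis-aligned loading
_MAX_OBLIQUITY_DEG = 5.0


class VolumeFormatError(ValueError):
    """Raised when an image on disk lacks required geometry/rescale metadata."""


@dataclass
class CTVolume:
    """A 3-D scalar field of Hounsfield Units on a regular axis-aligned grid.

    Parameters
    ----------
    voxels:
        3-D array of HU values, indexed ``[i, j, k]``.
    spacing:
        Physical size of a voxel along each voxel axis, in mm (all > 0).
    origin:
        LPS coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    orientation:
        One anatomical direction label per voxel axis (``L/R``, ``A/P``,
        ``S/I``), giving the patient direction along which the index grows.
        The three labels must cover three distinct anatomical axes.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    orientation: tuple[str, str, str] = ("L", "P", "S")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = tuple(str(o).upper() for o in self.orientation)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        for label in self.orientation:
            if label not in _LABEL_TO_LPS:
                raise ValueError(f"unknown orientation label {label!r}")
        axes = [_LABEL_TO_LPS[label][0] for label in self.orientation]
        if sorted(axes) != [0, 1, 2]:
            raise ValueError(
                f"orientation {self.orientation} does not span three distinct "
                "anatomical axes"
            )

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def _axis_for(self, lps_axis: int) -> tuple[int, float]:
        """Voxel axis index and sign realising the given LPS axis."""
        for vox_axis, label in enumerate(self.orientation):
            ax, sign = _LABEL_TO_LPS[label]
            if ax == lps_axis:
                return vox_axis, sign
        raise AssertionError("unreachable: orientation validated in __post_init__")

    @property
    def axial_axis(self) -> int:
        """The voxel axis running cranio-caudally (label S or I)."""
        return self._axis_for(2)[0]

    @property
    def caudal_step(self) -> int:
        """+1 if increasing axial index moves caudally (toward I), else -1."""
        return -1 if _LABEL_TO_LPS[self.orientation[self.axial_axis]][1] > 0 else 1

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices, shape (..., 3), to LPS mm."""
        idx = np.asarray(index, dtype=float)
        out = np.empty(idx.shape, dtype=float)
        for vox_axis, label in enumerate(self.orientation):
            lps_axis, sign = _LABEL_TO_LPS[label]
            out[..., lps_axis] = (
                self.origin[lps_axis] + sign * idx[..., vox_axis] * self.spacing[vox_axis]
            )
        return out

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map LPS mm points, shape (..., 3), to fractional voxel indices."""
        pts = np.asarray(point, dtype=float)
        out = np.empty(pts.shape, dtype=float)
        for vox_axis, label in enumerate(self.orientation):
            lps_axis, sign = _LABEL_TO_LPS[label]
            out[..., vox_axis] = (
                sign * (pts[..., lps_axis] - self.origin[lps_axis]) / self.spacing[vox_axis]
            )
        return out

    def axis_coordinates(self, lps_axis: int) -> np.ndarray:
        """Physical coordinate along one LPS axis for every index of the
        voxel axis that realises it (1-D array)."""
        vox_axis, sign = self._axis_for(lps_axis)
        n = self.shape[vox_axis]
        return self.origin[lps_axis] + sign * np.arange(n) * self.spacing[vox_axis]

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) LPS corner coordinates of the voxel-centre grid."""
        corners = self.index_to_physical(
            np.array([[0.0, 0.0, 0.0], [s - 1 for s in self.shape]])
        )
        return corners.min(axis=0), corners.max(axis=0)

    def contains_point(self, point: Sequence[float]) -> bool:
        lo, hi = self.physical_bounds()
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))


def knee_center(medial: Sequence[float], lateral: Sequence[float]) -> np.ndarray:
    """Knee rotation centre: component-wise midpoint of the epicondyles."""
    m = np.asarray(medial, dtype=float)
    l = np.asarray(lateral, dtype=float)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(l))):
        raise ValueError("epicondyle coordinates must be finite")
    return (m + l) / 2.0


@dataclass
class Landmarks:
    """Anatomical landmarks in LPS mm.

    ``knee_center`` is derived as the epicondyle midpoint when not given
    explicitly.
    """

    head_center: np.ndarray
    medial_epicondyle: np.ndarray | None = None
    lateral_epicondyle: np.ndarray | None = None
    knee_center: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.head_center = np.asarray(self.head_center, dtype=float)
        for name in ("medial_epicondyle", "lateral_epicondyle", "knee_center"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, np.asarray(value, dtype=float))
        if self.knee_center is None:
            if self.medial_epicondyle is None or self.lateral_epicondyle is None:
                raise ValueError(
                    "landmarks need either knee_center or both epicondyles; "
                    "missing: "
                    + ", ".join(
                        n
                        for n in ("medial_epicondyle", "lateral_epicondyle")
                        if getattr(self, n) is None
                    )
                )
            self.knee_center = knee_center(self.medial_epicondyle, self.lateral_epicondyle)

    def check_within(self, volume: CTVolume) -> None:
        """Warn for any landmark outside the volume's physical bounds."""
        for name in ("head_center", "medial_epicondyle", "lateral_epicondyle", "knee_center"):
            point = getattr(self, name)
            if point is not None and not volume.contains_point(point):
                warnings.warn(
                    f"landmark {name} at {tuple(point)} lies outside the volume bounds",
                    stacklevel=2,
                )


def read_landmarks(path: str | Path) -> Landmarks:
    """Load landmarks from a JSON file with mm coordinates.

    The file must declare its coordinate ``convention`` ("LPS" or "RAS");
    RAS points are converted to LPS. Required: ``head_center`` plus either
    ``knee_center`` or both epicondyles.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed landmark file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"landmark file {path} must contain a JSON object")
    convention = str(data.get("convention", "")).upper()
    if convention not in {"LPS", "RAS"}:
        raise ValueError(
            f"landmark file {path} must declare 'convention' as 'LPS' or 'RAS'"
        )

    def _point(key: str) -> np.ndarray | None:
        if key not in data:
            return None
        p = np.asarray(data[key], dtype=float)
        if p.shape != (3,):
            raise ValueError(f"landmark {key} must be a 3-vector, got {data[key]!r}")
        if convention == "RAS":
            p = p * np.array([-1.0, -1.0, 1.0])
        return p

    head = _point("head_center")
    if head is None:
        raise ValueError(f"landmark file {path} is missing required point: head_center")
    return Landmarks(
        head_center=head,
        medial_epicondyle=_point("medial_epicondyle"),
        lateral_epicondyle=_point("lateral_epicondyle"),
        knee_center=_point("knee_center"),
    )


# -- NIfTI ---------------------------------------------------------------


def _labels_from_ras_axes(ras_axis: np.ndarray, flips: np.ndarray) -> list[str]:
    # RAS axis/sign -> label of the direction of increasing voxel index
    table = {(0, 1): "R", (0, -1): "L", (1, 1): "A", (1, -1): "P", (2, 1): "S", (2, -1): "I"}
    return [table[(int(a), int(s))] for a, s in zip(ras_axis, flips)]


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D image, got ndim={img.ndim}")
    affine = np.asarray(img.affine, dtype=float)
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise VolumeFormatError(f"{path}: affine has degenerate voxel spacing {spacing}")
    cosines = rot / spacing
    ras_axis = np.argmax(np.abs(cosines), axis=0)
    if sorted(ras_axis.tolist()) != [0, 1, 2]:
        raise VolumeFormatError(f"{path}: affine axes are not separable into R/A/S")
    max_cos = np.abs(cosines[ras_axis, np.arange(3)])
    min_cos = math.cos(math.radians(_MAX_OBLIQUITY_DEG))
    if np.any(max_cos < min_cos):
        raise VolumeFormatError(
            f"{path}: acquisition is oblique by more than {_MAX_OBLIQUITY_DEG} degrees"
        )
    flips = np.sign(cosines[ras_axis, np.arange(3)]).astype(int)
    labels = _labels_from_ras_axes(ras_axis, flips)
    origin_ras = affine[:3, 3]
    origin_lps = origin_ras * np.array([-1.0, -1.0, 1.0])
    data = img.get_fdata()  # applies scl_slope / scl_inter -> HU
    return CTVolume(
        voxels=data,
        spacing=tuple(spacing),
        origin=tuple(origin_lps),
        orientation=tuple(labels),
    )


def write_nifti(volume: CTVolume, path: str | Path) -> None:
    """Write a volume (HU field or mask) as NIfTI, preserving dtype."""
    import nibabel as nib

    affine = np.eye(4)
    ras_sign = np.array([-1.0, -1.0, 1.0])
    for vox_axis, label in enumerate(volume.orientation):
        lps_axis, sign = _LABEL_TO_LPS[label]
        col = np.zeros(3)
        col[lps_axis] = sign * volume.spacing[vox_axis] * ras_sign[lps_axis]
        affine[:3, vox_axis] = col
    affine[:3, 3] = np.asarray(volume.origin) * ras_sign
    data = volume.voxels
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


# -- DICOM ---------------------------------------------------------------

_REQUIRED_DICOM_TAGS = (
    "PixelSpacing",
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "RescaleSlope",
    "RescaleIntercept",
)


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # non-DICOM files in the directory are ignored
        if not hasattr(ds, "PixelData"):
            continue
        slices.append((f, ds))
    if not slices:
        raise VolumeFormatError(f"{path}: no DICOM image slices found")
    for f, ds in slices:
        missing = [tag for tag in _REQUIRED_DICOM_TAGS if getattr(ds, tag, None) is None]
        if missing:
            raise VolumeFormatError(f"{f.name}: missing required tags {missing}")

    ref = slices[0][1]
    iop = np.asarray([float(v) for v in ref.ImageOrientationPatient], dtype=float)
    row_cos, col_cos = iop[:3], iop[3:]  # LPS direction cosines
    normal = np.cross(row_cos, col_cos)

    slices.sort(key=lambda item: float(np.dot(np.asarray(item[1].ImagePositionPatient, float), normal)))
    positions = np.array(
        [np.dot(np.asarray(ds.ImagePositionPatient, float), normal) for _, ds in slices]
    )
    if len(slices) > 1:
        steps = np.diff(positions)
        step = float(np.median(steps))
        if step <= 0:
            raise VolumeFormatError(f"{path}: duplicate or unordered slice positions")
        bad = np.flatnonzero(np.abs(steps - step) > max(1e-3, 0.01 * abs(step)))
        if bad.size:
            names = [slices[int(b) + 1][0].name for b in bad]
            raise VolumeFormatError(
                f"{path}: inconsistent inter-slice spacing at slices {names} "
                f"(expected {step:.4f} mm)"
            )
    else:
        step = float(getattr(ref, "SliceThickness", 1.0) or 1.0)

    min_cos = math.cos(math.radians(_MAX_OBLIQUITY_DEG))

    def _label(vec: np.ndarray) -> str:
        table = {(0, 1): "L", (0, -1): "R", (1, 1): "P", (1, -1): "A", (2, 1): "S", (2, -1): "I"}
        ax = int(np.argmax(np.abs(vec)))
        if abs(vec[ax]) < min_cos:
            raise VolumeFormatError(
                f"{path}: acquisition is oblique by more than {_MAX_OBLIQUITY_DEG} degrees"
            )
        return table[(ax, int(np.sign(vec[ax])))]

    labels = (_label(row_cos), _label(col_cos), _label(normal))

    row_spacing, col_spacing = (float(v) for v in ref.PixelSpacing)
    arrays = []
    for _, ds in slices:
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        arrays.append(hu.T)  # (rows, cols) -> (i along row direction, j along column direction)
    voxels = np.stack(arrays, axis=2)
    origin = np.asarray(slices[0][1].ImagePositionPatient, dtype=float)
    return CTVolume(
        voxels=voxels,
        spacing=(col_spacing, row_spacing, step),
        origin=tuple(origin),
        orientation=labels,
    )


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume in HU from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom-series"``; when omitted it is
    inferred (directory -> DICOM series, file -> NIfTI). DICOM stored values
    are converted to HU with the per-slice rescale slope/intercept; NIfTI
    scaling headers are applied by the reader.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")
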