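"""Synthetic CT fixtures with known ground-truth calibration.

Two generators cover the whole pipeline without any external data:

* :func:`generate_phantom_volume` — an ESP-style phantom: five cylindrical
  hydroxyapatite inserts (50–800 mg/cm^3) in a soft-tissue background, with
  voxel HU produced by inverting a known ground-truth calibration line.
* :func:`generate_thigh_volume` — a single-limb thigh: concentric air /
  adipose / muscle / bone compartments in axial section, long enough for the
  9-slice internal-calibration VOI, with landmarks placed so the reference
  point falls mid-shaft.

Anatomy is deliberately crude (circular annuli, i.i.d. Gaussian HU noise, no
beam hardening or partial volume): the phantomless method consumes an HU
distribution, not anatomy, and the compartment mixture reproduces the
air/adipose/muscle mode structure seen in real thigh sections. Inter-subject
variability enters through per-subject tissue-density draws whose default
standard deviations (2.6 / 2.3 / 3.1 mg/cm^3) match cohort-reported tissue
dispersion.

All randomness flows from one integer seed through counter-based substreams
(``(seed, subject_index, stream)`` entropy tuples), so cohorts are bitwise
reproducible and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import CTVolume, Landmarks
from .phantom import (
    DEFAULT_INSERT_DENSITIES,
    CalibrationLine,
    CylinderROI,
    PhantomSpec,
)
from .phantomless import DEFAULT_REFERENCE_DENSITIES, TISSUES

__all__ = [
    "ThighGeometry",
    "SyntheticSubject",
    "generate_phantom_volume",
    "generate_thigh_volume",
    "generate_cohort",
    "DEFAULT_TISSUE_DENSITY_SDS",
]

#: Per-tissue inter-subject density SDs (air, adipose, muscle), mg/cm^3.
DEFAULT_TISSUE_DENSITY_SDS = (2.6, 2.3, 3.1)

#: Slope/intercept ranges for ground-truth line draws (mg/cm^3 per HU, mg/cm^3).
DEFAULT_SLOPE_RANGE = (0.60, 0.80)
DEFAULT_INTERCEPT_RANGE = (-20.0, 0.0)


@dataclass(frozen=True)
class ThighGeometry:
    """Compartment radii (mm) and grid of the synthetic thigh.

    Concentric in axial section: bone core inside muscle inside an adipose
    ring, surrounded by air. Landmarks sit on the cylinder axis, one slice in
    from each end, so the head/knee midpoint lands mid-shaft.
    """

    shape: tuple[int, int, int] = (128, 128, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    bone_radius: float = 16.0
    muscle_radius: float = 62.0
    adipose_radius: float = 80.0
    epicondyle_halfwidth: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.bone_radius < self.muscle_radius < self.adipose_radius:
            raise ValueError("compartments must nest: bone < muscle < adipose")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))


@dataclass
class SyntheticSubject:
    """Ground truth for one synthetic subject.

    ``true_line`` is the HU-to-density line the scanner is assumed to
    realise; tissue HU values are obtained by inverting it. ``seed`` may be
    an int or a tuple of ints (counter-based substream key).
    """

    true_line: CalibrationLine
    tissue_densities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_DENSITIES)
    )
    bone_density: float = 800.0
    noise_sd: float = 0.0
    geometry: ThighGeometry = field(default_factory=ThighGeometry)
    seed: int | tuple[int, ...] = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = [t for t in TISSUES if t not in self.tissue_densities]
        if missing:
            raise ValueError(f"tissue_densities missing {missing}")

    def substream(self, *key: int) -> np.random.Generator:
        base = self.seed if isinstance(self.seed, tuple) else (self.seed,)
        return np.random.default_rng(tuple(base) + key)


def _hu_for_density(line: CalibrationLine, density: float) -> float:
    """Invert the calibration line: the HU realising a given density."""
    return (density - line.intercept) / line.slope


def _centered_volume(shape, spacing, fill: float) -> CTVolume:
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return CTVolume(
        voxels=np.full(shape, fill, dtype=float),
        spacing=tuple(spacing),
        origin=origin,
        orientation=("L", "P", "S"),
    )


def generate_phantom_volume(
    line: CalibrationLine,
    spec: PhantomSpec | None = None,
    noise_sd: float = 0.0,
    seed: int | tuple[int, ...] = 0,
    background_hu: float = 0.0,
    shape: tuple[int, int, int] = (96, 48, 16),
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0),
) -> tuple[CTVolume, PhantomSpec]:
    """Synthesize a phantom scan realising a known calibration line.

    Each insert's voxels are set to ``(rho - intercept) / slope`` plus
    i.i.d. Gaussian noise; the background is a uniform soft-tissue HU.
    Returns the volume and a spec whose ROIs are rasterized voxel masks.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if line.slope == 0:
        raise ValueError("ground-truth line must have non-zero slope")
    volume = _centered_volume(shape, spacing, background_hu)
    if spec is None:
        densities = DEFAULT_INSERT_DENSITIES
        n = len(densities)
        pitch = (shape[0] * spacing[0] - 40.0) / n
        centers = (np.arange(n) - (n - 1) / 2.0) * pitch
        rois = [
            CylinderROI(center=(c, 0.0, 0.0), axis=(0.0, 0.0, 1.0), radius=8.0, height=30.0)
            for c in centers
        ]
        spec = PhantomSpec(insert_densities=densities, insert_rois=rois)
    masks = spec.masks(volume)
    for density, mask in zip(spec.insert_densities, masks):
        volume.voxels[mask] = _hu_for_density(line, density)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        volume.voxels += rng.normal(0.0, noise_sd, size=volume.shape)
    return volume, PhantomSpec(insert_densities=spec.insert_densities, insert_rois=masks)


def generate_thigh_volume(
    subject: SyntheticSubject,
) -> tuple[CTVolume, Landmarks, np.ndarray]:
    """Synthesize a single-limb thigh CT, its landmarks and the femur mask.

    Compartment HU values are the subject's tissue densities pushed through
    the inverse of the ground-truth line, plus seeded Gaussian noise. The
    femur mask is the bone core, strictly inside the muscle compartment.
    """
    geo = subject.geometry
    line = subject.true_line
    nz = geo.shape[2]
    if (nz // 2) < 10:
        raise ValueError(
            f"geometry too short for the internal-calibration VOI: {nz} slices"
        )
    fov_half = min(geo.shape[0] * geo.spacing[0], geo.shape[1] * geo.spacing[1]) / 2.0
    if geo.adipose_radius >= fov_half:
        raise ValueError("adipose compartment does not fit in the field of view")

    volume = _centered_volume(geo.shape, geo.spacing, 0.0)
    x = volume.axis_coordinates(0)
    y = volume.axis_coordinates(1)
    r2 = (x[:, None] ** 2 + y[None, :] ** 2)[:, :, None]  # broadcast over slices

    hu = {t: _hu_for_density(line, subject.tissue_densities[t]) for t in TISSUES}
    hu_bone = _hu_for_density(line, subject.bone_density)
    section = np.select(
        [
            r2 <= geo.bone_radius**2,
            r2 <= geo.muscle_radius**2,
            r2 <= geo.adipose_radius**2,
        ],
        [hu_bone, hu["muscle"], hu["adipose"]],
        default=hu["air"],
    )
    volume.voxels[:] = np.broadcast_to(section, geo.shape)
    if subject.noise_sd > 0:
        rng = subject.substream(1)
        volume.voxels += rng.normal(0.0, subject.noise_sd, size=geo.shape)

    z = volume.axis_coordinates(2)
    z_head = z.max() - geo.spacing[2]
    z_knee = z.min() + geo.spacing[2]
    landmarks = Landmarks(
        head_center=np.array([0.0, 0.0, z_head]),
        medial_epicondyle=np.array([geo.epicondyle_halfwidth, 0.0, z_knee]),
        lateral_epicondyle=np.array([-geo.epicondyle_halfwidth, 0.0, z_knee]),
    )
    femur_mask = np.broadcast_to(r2 <= geo.bone_radius**2, geo.shape).copy()
    return volume, landmarks, femur_mask


def generate_cohort(
    n: int,
    seed: int = 0,
    tissue_density_sds: Sequence[float] = DEFAULT_TISSUE_DENSITY_SDS,
    reference_densities: Mapping[str, float] | None = None,
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
    intercept_range: tuple[float, float] = DEFAULT_INTERCEPT_RANGE,
    noise_sd: float = 15.0,
    bone_density_range: tuple[float, float] = (500.0, 1000.0),
    geometry: ThighGeometry | None = None,
) -> list[SyntheticSubject]:
    """Draw a reproducible cohort of synthetic subjects.

    Per subject: tissue densities ~ Normal(reference, sd) per tissue; a
    ground-truth line with slope/intercept uniform over the given ranges; a
    homogeneous bone density uniform over ``bone_density_range``. Subject
    ``i`` uses the substream keyed ``(seed, i, ...)`` regardless of ``n``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    sds = tuple(float(s) for s in tissue_density_sds)
    if len(sds) != 3 or any(s < 0 for s in sds):
        raise ValueError(f"tissue_density_sds must be three non-negative values, got {sds}")
    refs = dict(reference_densities or DEFAULT_REFERENCE_DENSITIES)
    geometry = geometry or ThighGeometry()

    cohort = []
    for i in range(n):
        rng = np.random.default_rng((seed, i, 0))
        densities = {
            t: float(rng.normal(refs[t], sd)) for t, sd in zip(TISSUES, sds)
        }
        slope = float(rng.uniform(*slope_range))
        intercept = float(rng.uniform(*intercept_range))
        bone = float(rng.uniform(*bone_density_range))
        cohort.append(
            SyntheticSubject(
                true_line=CalibrationLine(
                    intercept=intercept, slope=slope, r_squared=1.0, n_points=0,
                    method="phantom",
                ),
                tissue_densities=densities,
                bone_density=bone,
                noise_sd=noise_sd,
                geometry=geometry,
                seed=(seed, i),
            )
        )
    return cohort
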