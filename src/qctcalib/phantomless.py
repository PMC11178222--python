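"""Phantomless (internal-tissue) HU-to-density calibration.

The subject's own tissues stand in for a phantom: a volume of interest is
anchored at the reference point RP (midpoint of the femoral-head and knee
centres), spans a fixed number of axial slices caudally from the slice
nearest RP, and is trimmed of everything posterior of the coronal plane
through a point OP a fixed distance posterior to RP. The HU sample inside
this ``VOIcut`` is fitted with a Gaussian kernel density (5 HU bandwidth by
default); the air, adipose and muscle modes are located within configurable
HU search windows; and an OLS line through the three (peak HU, reference
density) pairs yields the patient-specific calibration.

Reference densities default to cohort-derived HA-equivalent values of
-797 / -95 / 38 mg/cm^3 for air / adipose / muscle; cohort-specific values
can be re-derived with :func:`derive_reference_densities`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .core import CTVolume, Landmarks
from .phantom import CalibrationLine, apply_calibration, fit_calibration

__all__ = [
    "TISSUES",
    "TissueReference",
    "VOISpec",
    "HUDistribution",
    "PeakNotFoundError",
    "default_references",
    "compute_rp",
    "build_voi_cut",
    "fit_kde",
    "detect_tissue_peaks",
    "fit_phantomless_calibration",
    "derive_reference_densities",
    "search_windows_for_lines",
    "calibrate_phantomless",
]

TISSUES = ("air", "adipose", "muscle")

#: Cohort-derived HA-equivalent reference densities, mg/cm^3.
DEFAULT_REFERENCE_DENSITIES = {"air": -797.0, "adipose": -95.0, "muscle": 38.0}

#: Default HU search windows bracketing the expected tissue modes on a
#: roughly identity-like HU scale. They must stay disjoint and ordered.
DEFAULT_HU_WINDOWS = {
    "air": (-1050.0, -850.0),
    "adipose": (-200.0, -30.0),
    "muscle": (10.0, 90.0),
}


class PeakNotFoundError(RuntimeError):
    """No strict local maximum of the kernel density inside a tissue window."""


@dataclass(frozen=True)
class TissueReference:
    """A reference tissue: name, HA-equivalent density and HU search window."""

    name: str
    density: float
    hu_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.name not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.name!r}")
        low, high = self.hu_window
        if not low < high:
            raise ValueError(f"hu_window must satisfy low < high, got {self.hu_window}")


def default_references() -> list[TissueReference]:
    return [
        TissueReference(name, DEFAULT_REFERENCE_DENSITIES[name], DEFAULT_HU_WINDOWS[name])
        for name in TISSUES
    ]


def _validate_references(refs: Sequence[TissueReference]) -> dict[str, TissueReference]:
    by_name = {r.name: r for r in refs}
    if sorted(by_name) != sorted(TISSUES) or len(refs) != 3:
        raise ValueError(f"need exactly one reference per tissue {TISSUES}")
    ordered = [by_name[t] for t in TISSUES]
    for a, b in zip(ordered, ordered[1:]):
        if a.hu_window[1] >= b.hu_window[0]:
            raise ValueError(
                f"HU windows must be disjoint and ordered air < adipose < muscle; "
                f"{a.name} {a.hu_window} overlaps {b.name} {b.hu_window}"
            )
    return by_name


@dataclass
class VOISpec:
    """Geometry of the internal-calibration VOI.

    ``rp`` anchors the VOI; ``n_slices`` axial slices are taken caudally from
    the slice nearest ``rp``; voxels more than ``posterior_offset`` mm
    posterior of ``rp`` are removed (the coronal half-space through OP).
    """

    rp: np.ndarray
    n_slices: int = 9
    posterior_offset: float = 50.0

    def __post_init__(self) -> None:
        self.rp = np.asarray(self.rp, dtype=float)
        if self.rp.shape != (3,) or not np.all(np.isfinite(self.rp)):
            raise ValueError("rp must be a finite 3-vector (LPS mm)")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.posterior_offset < 0:
            raise ValueError("posterior_offset must be >= 0")

    @property
    def op_point(self) -> np.ndarray:
        """OP: the posterior cut origin, ``posterior_offset`` mm posterior to RP."""
        op = self.rp.copy()
        op[1] += self.posterior_offset  # +y is posterior in LPS
        return op


def compute_rp(head_center: Sequence[float], knee_center: Sequence[float]) -> np.ndarray:
    """Reference point: midpoint of the femoral-head and knee centres."""
    h = np.asarray(head_center, dtype=float)
    k = np.asarray(knee_center, dtype=float)
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(k))):
        raise ValueError("landmark coordinates must be finite")
    return (h + k) / 2.0


def build_voi_cut(volume: CTVolume, spec: VOISpec) -> np.ndarray:
    """Boolean mask of the VOIcut on the volume grid.

    The mask covers exactly ``n_slices`` axial slices starting at the slice
    nearest RP (cranio-caudal distance, ties resolved caudally) and
    proceeding caudally, minus all voxels strictly posterior of the coronal
    plane through OP. No medial restriction is applied.
    """
    if not volume.contains_point(spec.rp):
        raise ValueError(f"RP {tuple(spec.rp)} lies outside the volume")

    ax = volume.axial_axis
    step = volume.caudal_step
    z_coords = volume.axis_coordinates(2)  # S coordinate per axial index
    dist = np.abs(z_coords - spec.rp[2])
    best = dist.min()
    candidates = np.flatnonzero(np.isclose(dist, best))
    # tie toward the caudal slice
    start = int(candidates[-1] if step > 0 else candidates[0])

    last = start + step * (spec.n_slices - 1)
    n_ax = volume.shape[ax]
    if last < 0 or last >= n_ax:
        available = (n_ax - start) if step > 0 else (start + 1)
        raise ValueError(
            f"only {available} caudal slice(s) available from the RP slice "
            f"(index {start}); {spec.n_slices} required"
        )
    lo, hi = sorted((start, last))

    mask = np.zeros(volume.shape, dtype=bool)
    slicer = [slice(None)] * 3
    slicer[ax] = slice(lo, hi + 1)
    mask[tuple(slicer)] = True

    # posterior (LPS +y) coordinate varies along exactly one voxel axis
    p_axis = volume._axis_for(1)[0]
    p_coords = volume.axis_coordinates(1)
    keep = p_coords <= spec.op_point[1]
    shape = [1, 1, 1]
    shape[p_axis] = keep.size
    mask &= keep.reshape(shape)
    return mask


@dataclass
class HUDistribution:
    """HU sample with a fitted Gaussian kernel density on a regular grid.

    ``density[i]`` is the exact mean over samples of the normal kernel with
    scale ``bandwidth`` evaluated at ``grid[i]``; detected tissue peaks are
    filled in by :func:`detect_tissue_peaks`.
    """

    samples: np.ndarray
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray
    peaks: dict[str, float] = field(default_factory=dict)

    def evaluate(self, x) -> np.ndarray | float:
        """Exact kernel density at arbitrary HU locations (direct summation)."""
        pts = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty(pts.size)
        s = self.samples
        inv = 1.0 / (2.0 * self.bandwidth**2)
        norm = 1.0 / (s.size * self.bandwidth * np.sqrt(2.0 * np.pi))
        for i, p in enumerate(pts):
            out[i] = norm * np.exp(-((s - p) ** 2) * inv).sum()
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out[0])
        return out


def fit_kde(
    samples: np.ndarray,
    bandwidth: float = 5.0,
    grid_step: float = 1.0,
    min_samples: int = 1000,
) -> HUDistribution:
    """Fit a Gaussian kernel density to an HU sample on a regular grid.

    The grid spans ``[min - 3*bandwidth, max + 3*bandwidth]`` at
    ``grid_step`` HU resolution. Kernel contributions are accumulated with a
    +-10-sigma cutoff, below double-precision resolution of the density.
    """
    s = np.asarray(samples, dtype=float).ravel()
    if s.size < min_samples:
        raise ValueError(
            f"HU sample too small for a stable kernel fit: {s.size} voxels "
            f"(minimum {min_samples})"
        )
    if bandwidth <= 0 or grid_step <= 0:
        raise ValueError("bandwidth and grid_step must be positive")

    g0 = s.min() - 3.0 * bandwidth
    g1 = s.max() + 3.0 * bandwidth
    m = int(np.ceil((g1 - g0) / grid_step)) + 1
    grid = g0 + grid_step * np.arange(m)

    idx_f = (s - g0) / grid_step
    center = np.rint(idx_f).astype(np.int64)
    frac = idx_f - center  # in grid-step units, in [-0.5, 0.5]
    w = int(np.ceil(10.0 * bandwidth / grid_step))
    inv = grid_step**2 / (2.0 * bandwidth**2)
    acc = np.zeros(m)
    for d in range(-w, w + 1):
        target = center + d
        valid = (target >= 0) & (target < m)
        x = d - frac[valid]
        acc += np.bincount(target[valid], weights=np.exp(-(x**2) * inv), minlength=m)
    density = acc / (s.size * bandwidth * np.sqrt(2.0 * np.pi))
    return HUDistribution(samples=s, bandwidth=float(bandwidth), grid=grid, density=density)


def _refine_peak(dist: HUDistribution, grid_idx: int) -> float:
    """Continuously refine a grid-level mode of the exact kernel density."""
    lo = dist.grid[max(grid_idx - 1, 0)]
    hi = dist.grid[min(grid_idx + 1, dist.grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: -dist.evaluate(x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def detect_tissue_peaks(
    dist: HUDistribution, refs: Sequence[TissueReference], refine: bool = True
) -> dict[str, float]:
    """Locate the air/adipose/muscle modes of the fitted kernel density.

    For each tissue the strict local maxima of the density inside the HU
    window are enumerated; the one with the greatest density wins and is
    refined by bounded continuous maximization of the exact kernel density
    within one grid step. Results are stored on ``dist.peaks`` and returned.
    """
    by_name = _validate_references(refs)
    d = dist.density
    interior = np.zeros(d.size, dtype=bool)
    # plateau-aware grid maxima: a mode landing halfway between grid points
    # produces two equal neighbouring values; either qualifies and the
    # continuous refinement recovers the strict mode between them
    interior[1:-1] = (
        (d[1:-1] >= d[:-2])
        & (d[1:-1] >= d[2:])
        & ((d[1:-1] > d[:-2]) | (d[1:-1] > d[2:]))
    )
    peaks: dict[str, float] = {}
    for name in TISSUES:
        low, high = by_name[name].hu_window
        in_window = interior & (dist.grid >= low) & (dist.grid <= high)
        idx = np.flatnonzero(in_window)
        if idx.size == 0:
            raise PeakNotFoundError(f"peak not found for tissue {name!r} in window [{low}, {high}] HU")
        best = int(idx[np.argmax(d[idx])])
        peaks[name] = _refine_peak(dist, best) if refine else float(dist.grid[best])
    dist.peaks = peaks
    return peaks


def fit_phantomless_calibration(
    peaks: Mapping[str, float], refs: Sequence[TissueReference]
) -> CalibrationLine:
    """OLS line through the three (tissue peak HU, reference density) pairs."""
    by_name = _validate_references(refs)
    missing = [t for t in TISSUES if t not in peaks]
    if missing:
        raise ValueError(f"missing tissue peaks: {missing}")
    hu = np.array([float(peaks[t]) for t in TISSUES])
    rho = np.array([by_name[t].density for t in TISSUES])
    if np.unique(hu).size != hu.size:
        raise ValueError(f"tissue peak HU values must be distinct, got {hu.tolist()}")
    return fit_calibration(hu, rho, method="phantomless")


@dataclass
class ReferenceDerivation:
    """Cohort-derived tissue references with per-tissue dispersion."""

    references: list[TissueReference]
    means: dict[str, float]
    sds: dict[str, float]
    n_subjects: int


def derive_reference_densities(
    subjects: Iterable[tuple[Mapping[str, float], CalibrationLine]],
    windows: Mapping[str, tuple[float, float]] | None = None,
) -> ReferenceDerivation:
    """Derive cohort reference densities from phantom-calibrated subjects.

    Each subject contributes its detected tissue peak HU values and its
    phantom-based calibration line; per tissue, the line maps the peak to an
    equivalent density and the cohort mean (with standard deviation) becomes
    the shipped reference.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("need at least one subject")
    per_tissue: dict[str, list[float]] = {t: [] for t in TISSUES}
    for i, (peaks, line) in enumerate(subjects):
        if line is None:
            raise ValueError(f"subject {i} has no phantom calibration line")
        for t in TISSUES:
            if t not in peaks:
                raise ValueError(f"subject {i} is missing the {t!r} peak")
            per_tissue[t].append(float(apply_calibration(line, float(peaks[t]))))
    windows = dict(windows) if windows is not None else dict(DEFAULT_HU_WINDOWS)
    means = {t: float(np.mean(per_tissue[t])) for t in TISSUES}
    sds = {
        t: float(np.std(per_tissue[t], ddof=1)) if len(subjects) > 1 else 0.0
        for t in TISSUES
    }
    refs = [TissueReference(t, means[t], tuple(windows[t])) for t in TISSUES]
    return ReferenceDerivation(
        references=refs, means=means, sds=sds, n_subjects=len(subjects)
    )


def search_windows_for_lines(
    reference_densities: Mapping[str, float],
    slope_range: tuple[float, float],
    intercept_range: tuple[float, float],
    margin: float = 30.0,
) -> dict[str, tuple[float, float]]:
    """HU search windows bracketing the tissue modes over a family of lines.

    For each tissue the window is the hull of ``(rho - b) / a`` over the
    corner combinations of the slope/intercept ranges, padded by ``margin``
    HU. Useful when calibrating cohorts whose HU scales vary more widely
    than the defaults assume; raises if the padded windows overlap.
    """
    windows = {}
    for t in TISSUES:
        rho = reference_densities[t]
        corners = [
            (rho - b) / a for a in slope_range for b in intercept_range
        ]
        windows[t] = (min(corners) - margin, max(corners) + margin)
    ordered = [windows[t] for t in TISSUES]
    for (a_lo, a_hi), (b_lo, b_hi) in zip(ordered, ordered[1:]):
        if a_hi >= b_lo:
            raise ValueError(f"derived HU windows overlap: {windows}")
    return windows


def calibrate_phantomless(
    volume: CTVolume,
    landmarks: Landmarks,
    refs: Sequence[TissueReference] | None = None,
    bandwidth: float = 5.0,
    grid_step: float = 1.0,
    n_slices: int = 9,
    posterior_offset: float = 50.0,
    min_samples: int = 1000,
) -> tuple[CalibrationLine, HUDistribution, np.ndarray]:
    """End-to-end phantomless calibration of one subject.

    Returns the fitted line, the HU distribution (with detected peaks) and
    the VOIcut mask.
    """
    if refs is None:
        refs = default_references()
    landmarks.check_within(volume)
    rp = compute_rp(landmarks.head_center, landmarks.knee_center)
    spec = VOISpec(rp=rp, n_slices=n_slices, posterior_offset=posterior_offset)
    mask = build_voi_cut(volume, spec)
    dist = fit_kde(
        volume.voxels[mask], bandwidth=bandwidth, grid_step=grid_step, min_samples=min_samples
    )
    peaks = detect_tissue_peaks(dist, refs)
    line = fit_phantomless_calibration(peaks, refs)
    return line, dist, mask
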