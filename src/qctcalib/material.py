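"""Density-to-elasticity material mapping.

Converts a calibrated HA-equivalent density field into a voxel-wise Young's
modulus field through a power law on apparent density,

    E [MPa] = coefficient * rho_app[g/cm^3] ** exponent,

with rho_ash = qct_to_ash * rho_qct and rho_app = rho_ash / ash_to_apparent.
The default is the widely used femoral law E = 6850 * rho_app^1.49 with
rho_ash = rho_qct and an ash fraction of 0.6. Densities below
``density_floor`` (default 0 mg/cm^3 — soft tissue can calibrate negative)
are clamped before exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CTVolume
from .phantom import CalibrationLine, apply_calibration

__all__ = ["DensityElasticityLaw", "density_to_modulus", "calibrated_modulus_field"]


@dataclass(frozen=True)
class DensityElasticityLaw:
    """Power-law density-elasticity relation with unit-conversion factors.

    ``coefficient`` in MPa, ``exponent`` dimensionless, ``qct_to_ash`` the
    QCT-to-ash density factor, ``ash_to_apparent`` the ash fraction divisor,
    ``density_floor`` the clamp level in mg/cm^3.
    """

    coefficient: float = 6850.0
    exponent: float = 1.49
    qct_to_ash: float = 1.0
    ash_to_apparent: float = 0.6
    density_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.coefficient <= 0 or self.exponent <= 0:
            raise ValueError("coefficient and exponent must be positive")
        if self.qct_to_ash <= 0 or self.ash_to_apparent <= 0:
            raise ValueError("density conversion factors must be positive")


def density_to_modulus(rho_qct, law: DensityElasticityLaw | None = None):
    """Map HA-equivalent density (mg/cm^3) to Young's modulus (MPa).

    Densities are clamped at ``law.density_floor``, converted to apparent
    density in g/cm^3, and passed through the power law. Shape is preserved;
    monotone non-decreasing in the input density.
    """
    if law is None:
        law = DensityElasticityLaw()
    rho = np.asarray(rho_qct, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("density field contains non-finite values")
    clamped = np.maximum(rho, law.density_floor)
    rho_app = (law.qct_to_ash * clamped) / law.ash_to_apparent / 1000.0  # g/cm^3
    e = law.coefficient * np.power(rho_app, law.exponent)
    if np.isscalar(rho_qct) or rho.ndim == 0:
        return float(e)
    return e


def calibrated_modulus_field(
    volume: CTVolume,
    line: CalibrationLine,
    mask: np.ndarray,
    law: DensityElasticityLaw | None = None,
) -> np.ndarray:
    """Young's modulus (MPa) for the masked voxels of a calibrated volume.

    Applies the calibration line to the HU values under ``mask`` and maps the
    densities through the power law. Returns a 1-D array in flat mask order;
    voxels outside the mask are absent.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume {volume.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    rho = apply_calibration(line, volume.voxels[mask])
    return density_to_modulus(rho, law)
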