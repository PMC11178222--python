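# qctcalib

Densitometric calibration of quantitative CT (QCT) for bone biomechanics:
phantom-based and **phantomless** (internal-tissue) calibration of Hounsfield
Units to calcium-hydroxyapatite-equivalent mineral density, density-to-elasticity
material mapping, and agreement metrics between the two calibration routes.

It is aimed at researchers building subject-specific femur models from clinical
CT who do not always have a calibration phantom in (or alongside) the scan.

## The method

CT voxel values (HU) are converted to HA-equivalent density ρ (mg/cm³) with a
linear calibration

```
ρ = a + b · HU
```

**Phantom-based route.** A density phantom with inserts of known ρ (here the
ESP-style set 50, 100, 200, 400, 800 mg/cm³) is scanned with matching
acquisition parameters; the mean HU of each insert ROI is regressed (OLS)
against the nominal densities.

**Phantomless route.** The subject's own tissues act as the phantom:

1. A reference point **RP** is taken as the midpoint of the femoral-head
   centre and the knee centre (itself the midpoint of the epicondyles).
2. A volume of interest spans **9 axial slices** caudally from the slice
   nearest RP; everything posterior of the coronal plane through **OP**
   (5 cm posterior to RP) is removed → *VOIcut*.
3. The HU sample inside VOIcut is fitted with a Gaussian **kernel density**
   (bandwidth 5 HU, 1 HU grid); the **air**, **adipose** and **muscle** modes
   are located within configurable HU windows.
4. An OLS line through the three (peak HU, reference density) pairs, with
   reference densities **−797 / −95 / 38 mg/cm³** (air/adipose/muscle,
   derivable for a new cohort with `derive_reference_densities`), gives the
   patient-specific calibration.

Calibrated density maps to Young's modulus through a power law on apparent
density, by default `E [MPa] = 6850 · ρ_app^1.49` with `ρ_app = ρ_QCT / 0.6`
(g/cm³). Agreement between two calibrated fields is summarised by the root
mean square relative error normalized by the pairwise mean,

```
RMSRE = sqrt( (1/n) Σ ((xᵢ − x̂ᵢ) / x̄ᵢ)² ),   x̄ᵢ = (xᵢ + x̂ᵢ)/2,
```

per-voxel relative differences (same normalizer, in %), 1.5·IQR outlier
screening for summary statistics, and cross-calibration regression R².

A synthetic-data module generates phantom scans and single-limb thigh volumes
(concentric air/adipose/muscle/bone compartments) with known ground-truth
calibration lines, so every stage — and the two-group cohort study design —
runs with no external data.

## Worked example

Calibrate one synthetic subject both ways and compare the femur modulus
fields:

```python
from qctcalib import (CalibrationLine, SyntheticSubject, generate_thigh_volume,
                      generate_phantom_volume, measure_insert_hu, fit_calibration,
                      calibrate_phantomless, default_references,
                      calibrated_modulus_field, compare_fields)

truth = CalibrationLine(intercept=-5.0, slope=0.78)       # unknown in practice
subject = SyntheticSubject(true_line=truth, noise_sd=15.0, seed=11)
volume, landmarks, femur = generate_thigh_volume(subject)

# route 1: phantom-based
pvol, pspec = generate_phantom_volume(line=truth, noise_sd=15.0, seed=99)
phantom_line = fit_calibration(measure_insert_hu(pvol, pspec), pspec.insert_densities)

# route 2: phantomless
phantomless_line, dist, voi = calibrate_phantomless(volume, landmarks,
                                                    refs=default_references())

e_phantom = calibrated_modulus_field(volume, phantom_line, femur)
e_phantomless = calibrated_modulus_field(volume, phantomless_line, femur)
report = compare_fields(e_phantom, e_phantomless)
```

Output:

```
true line:        rho = -5.000 + 0.7800 * HU
phantom line:     rho = -5.642 + 0.7817 * HU  (R^2 = 0.99999)
phantomless line: rho = -5.194 + 0.7800 * HU
tissue peaks: {'air': -1015.1, 'adipose': -115.5, 'muscle': 55.6}
RMSRE = 0.234 %  mean rel diff = 0.234 %  R^2 = 1.00000  (9984 voxels)
```

The detected internal-tissue peaks sit where the ground-truth line places
air/adipose/muscle (≈ −1015, −115, 55 HU for this scanner line); both fitted
lines track the truth, and the voxel-wise Young's modulus fields from the
two routes differ by a fraction of a percent.

The same steps are available from the shell via the `qctcalib` command
(`simulate`, `phantom`, `phantomless`, `derive-refs`, `map-modulus`,
`compare`); run `qctcalib --help`.

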