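# Methods

## Coordinate and slice conventions

All physical coordinates are patient-based LPS mm (x→left, y→posterior,
z→superior), DICOM's native frame; NIfTI affines (RAS) and landmark files
tagged `RAS` are converted on load. Voxel indexing is 0-based and refers to
voxel centres, so the index↔physical mapping is exactly invertible.
Acquisitions whose voxel axes deviate more than 5° from the anatomical axes
are rejected: the VOI is defined in axial slices, and "slice" is only
meaningful for near-axial stacks. The axial voxel axis is the one labelled
S or I; "caudal" is the direction of decreasing S.

## Phantom-based calibration

Insert ROIs are either voxel masks or cylinders (centre, axis, radius,
height in mm; rasterized by voxel-centre inclusion). The calibration is an
unweighted OLS of insert density on mean insert HU — density is the response
because the line is consumed as ρ = a + b·HU; the inverse regression is not
offered. R² is the ordinary coefficient of determination. No ROI erosion is
applied; partial-volume rims are the user's responsibility when segmenting
manually. Both OLS fits in the package (here and in the metrics module) are
computed with `scipy.stats.linregress`.

## Phantomless calibration

**VOI.** RP is the midpoint of the femoral-head and knee centres; the knee
centre is the epicondyle midpoint when not given. The VOI comprises
`n_slices` (default 9) axial slices starting at the slice nearest RP
(minimal |Δz| between slice-centre plane and RP; ties resolved toward the
caudal slice) and proceeding caudally — the RP slice is included. Voxels
strictly posterior of the coronal plane through OP (RP + 50 mm posterior by
default) are removed; no medial restriction is applied (single-limb field of
view). Slice count is kept fixed rather than a fixed physical height, and
the physical VOI height therefore scales with slice spacing; bone and other
high-HU voxels inside the VOI are left in the sample — they form no peaks
inside the tissue windows.

**Kernel density.** The VOIcut HU sample (floor 1000 voxels, configurable)
is fitted with a Gaussian kernel of fixed bandwidth 5 HU, evaluated on a
regular grid of 1 HU steps spanning [min − 3·bw, max + 3·bw]. The grid
density is the exact mean-of-kernels (not a binned approximation); kernel
contributions are truncated at ±10σ, which is below double-precision
resolution of the density, and accumulated per grid offset so the cost is
O((n + m)·w) rather than O(n·m). `HUDistribution.evaluate` exposes the
untruncated direct summation for arbitrary points.

**Peak detection.** Within each tissue's HU window the grid local maxima are
enumerated plateau-aware (a mode falling exactly halfway between grid points
— common in noiseless synthetic data — produces two equal neighbouring grid
values; either endpoint qualifies). The highest-density candidate wins and
is then refined by bounded continuous maximization of the exact kernel
density within one grid step (tolerance 1e-8 HU), removing grid
quantization from the downstream fit. A window with no local maximum raises
an error naming the tissue.

**Windows.** Default search windows are air [−1050, −850], adipose
[−200, −30], muscle [10, 90] HU — wide enough to bracket the expected modes
on a clinical CT while staying disjoint; they are a package choice, not a
measured quantity, and are fully configurable. For cohorts whose HU scales
vary widely (e.g. synthetic studies drawing calibration slopes well below
the physical ≈0.8 mg/cm³/HU), `search_windows_for_lines` derives windows as
the hull of (ρ − b)/a over the slope/intercept ranges plus a 30 HU margin,
and verifies disjointness.

**References.** Shipped reference densities are −797 / −95 / 38 mg/cm³
(air/adipose/muscle), cohort-derived values whose provenance is recorded in
the serialized line; populations scanned under different protocols should
re-derive them via `derive_reference_densities`, which maps each subject's
peaks through that subject's phantom-based line and averages per tissue
(reporting SDs). The phantomless fit itself is an OLS through three points;
its R² is reported but is close to 1 by construction.

## Material mapping

`E = coefficient · ρ_app^exponent` with `ρ_ash = qct_to_ash · ρ_QCT`,
`ρ_app = ρ_ash / ash_to_apparent`, input in mg/cm³ and ρ_app in g/cm³ (the
mg→g factor of 1000 is part of the unit chain, not of the configurable
factors). Defaults: coefficient 6850 MPa, exponent 1.49, qct_to_ash 1,
ash_to_apparent 0.6 — a standard femoral power law; comparisons between two
calibrations are insensitive to the particular monotone law, but a concrete
default is needed and all four constants are configurable via the law file.
Densities below `density_floor` (default 0 mg/cm³) are clamped before
exponentiation since soft tissue can calibrate negative. Mapping is
voxel-wise on the image grid; no element integration or mesh export is
attempted.

## Comparison metrics

The RMSRE normalizer is the pairwise mean x̄ᵢ = (xᵢ + x̂ᵢ)/2, making the
statistic symmetric; per-voxel relative differences use the same normalizer
(one normalizer throughout keeps RMSRE ≡ RMS(relative differences) exact).
Pairs with zero mean raise an error identifying the index. Quartiles for
the 1.5·IQR outlier fence use the linear-interpolation convention
(`numpy.percentile` default), fences are computed once on the full sample,
and outlier removal affects summary statistics only — never the RMSRE. When
the first field is constant no regression exists; R² is reported as 1 for
exactly identical fields and NaN otherwise.

## Synthetic data

The thigh generator is deliberately crude anatomy: concentric circular
compartments (bone core ⊂ muscle ⊂ adipose ring ⊂ surrounding air) on a
128×128×48 grid at (2, 2, 3) mm spacing, homogeneous per compartment with
i.i.d. Gaussian voxel noise. Tissue HU values are obtained by inverting a
known ground-truth line, so the full pipeline can be checked against truth.
Landmarks are placed one slice in from each end of the shaft so RP falls
mid-shaft with ample caudal slices. Inter-subject variability enters as
Normal draws of the tissue densities (SDs 2.6 / 2.3 / 3.1 mg/cm³ —
cohort-reported tissue dispersion), uniform ground-truth slopes/intercepts
([0.60, 0.80] mg/cm³/HU, [−20, 0] mg/cm³) and a uniform homogeneous bone
density ([500, 1000] mg/cm³). All randomness derives from one seed through
`(seed, subject_index, stream)` substreams, so cohorts are bitwise
reproducible and order-independent.

What the generator does **not** model: partial-volume mixing at compartment
boundaries, beam hardening, kVp/mA effects on the HU scale, metal artifacts,
anatomical asymmetry, or inhomogeneous trabecular/cortical bone. Passing
tests therefore demonstrate the correctness and internal consistency of the
calibration pipeline under the stated noise model — not clinical accuracy on
real scanners, where tube-voltage effects in particular dominate the error
budget of internal calibration.

## Study-scale choices

The cohort analogue study uses 17 subjects (comparison study) and 24
subjects (reference derivation) at the default grid, with 15 HU voxel
noise; peak-robustness properties use 100 single-subject repeats. These
sizes give each tissue ≥ several thousand VOI voxels and complete in
seconds on one CPU.

## Known limitations

- The VOI posterior cut assumes the subject is supine-ish in the gantry
  (posterior = +y LPS); unusual positioning would need a preliminary
  reorientation.
- Reference densities are protocol-specific; using the shipped defaults on
  a scanner with a different effective energy biases the calibration — the
  cohort-derivation workflow exists precisely for that case.
- DICOM support covers axis-aligned single-frame CT series with per-slice
  rescale tags; enhanced multi-frame DICOM is not parsed.
- Peaks are assumed unimodal per tissue window; severe beam-hardening can
  split the adipose mode in real data and would require window tuning.
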