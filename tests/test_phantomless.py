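import numpy as np
import pytest

from qctcalib import (
    CalibrationLine,
    PeakNotFoundError,
    SyntheticSubject,
    ThighGeometry,
    TissueReference,
    VOISpec,
    build_voi_cut,
    calibrate_phantomless,
    compute_rp,
    default_references,
    derive_reference_densities,
    detect_tissue_peaks,
    fit_kde,
    fit_phantomless_calibration,
    generate_thigh_volume,
    search_windows_for_lines,
)

from conftest import make_volume


def kde_oracle(samples, grid, bandwidth):
    """Direct summation of the normal kernel over all samples."""
    s = np.asarray(samples, dtype=float)
    out = np.empty(len(grid))
    for i, g in enumerate(grid):
        out[i] = np.mean(np.exp(-((g - s) ** 2) / (2 * bandwidth**2)))
    return out / (bandwidth * np.sqrt(2 * np.pi))


def refs_for(air=-797.0, adipose=-95.0, muscle=38.0,
             windows=((-1050, -850), (-200, -30), (10, 90))):
    names = ("air", "adipose", "muscle")
    return [TissueReference(n, d, tuple(w)) for n, d, w in zip(names, (air, adipose, muscle), windows)]


class TestComputeRP:
    @pytest.mark.parametrize(
        "head, knee, expected",
        [
            ((0, 0, 0), (0, 0, -400), (0, 0, -200)),
            ((3.5, -1, 9), (3.5, -1, 9), (3.5, -1, 9)),
            ((10, 20, 100), (30, -20, -300), (20, 0, -100)),
        ],
    )
    def test_midpoint(self, head, knee, expected):
        assert np.allclose(compute_rp(head, knee), expected)


class TestBuildVOICut:
    def test_nine_slices_caudally_from_rp_slice(self):
        # axial label I: caudal is increasing slice index
        vol = make_volume(shape=(8, 8, 32), orientation=("L", "P", "I"),
                          origin=(0, 0, 0), spacing=(1, 1, 1))
        mask = build_voi_cut(vol, VOISpec(rp=(3, 3, -20), posterior_offset=50))
        used = np.flatnonzero(mask.any(axis=(0, 1)))
        assert used.tolist() == list(range(20, 29))

    def test_posterior_voxels_beyond_op_excluded(self):
        vol = make_volume(shape=(8, 8, 32), orientation=("L", "P", "S"),
                          origin=(0, 0, 0), spacing=(1, 10, 1))
        rp = (3, 5, 20)  # OP at y = 55
        mask = build_voi_cut(vol, VOISpec(rp=rp, posterior_offset=50))
        y_used = np.flatnonzero(mask.any(axis=(0, 2)))
        # y coordinates 0,10,...,70: indices 0..5 (y <= 55) kept, 6..7 (60, 70) removed
        assert y_used.tolist() == [0, 1, 2, 3, 4, 5]

    def test_rp_in_last_caudal_slice_is_error(self):
        vol = make_volume(shape=(8, 8, 32), orientation=("L", "P", "I"),
                          origin=(0, 0, 0), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="caudal slice"):
            build_voi_cut(vol, VOISpec(rp=(3, 3, -31)))

    def test_rp_outside_volume_is_error(self):
        vol = make_volume(shape=(8, 8, 32))
        with pytest.raises(ValueError, match="outside"):
            build_voi_cut(vol, VOISpec(rp=(100, 0, 0)))

    def test_mask_proportional_to_slice_count(self):
        vol = make_volume(shape=(16, 16, 32), orientation=("L", "P", "I"),
                          origin=(0, 0, 0), spacing=(1, 1, 1))
        counts = [
            build_voi_cut(vol, VOISpec(rp=(8, 8, -10), n_slices=n, posterior_offset=1000)).sum()
            for n in (1, 3, 9)
        ]
        assert counts[1] == 3 * counts[0]
        assert counts[2] == 9 * counts[0]

    def test_mask_non_increasing_as_posterior_offset_shrinks(self):
        vol = make_volume(shape=(16, 16, 32), origin=(-8, -8, 0), spacing=(1, 1, 1),
                          orientation=("L", "P", "I"))
        sizes = [
            build_voi_cut(vol, VOISpec(rp=(0, 0, -10), posterior_offset=off)).sum()
            for off in (8.0, 4.0, 2.0, 0.0)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_tie_between_slices_resolves_caudally(self):
        vol = make_volume(shape=(4, 4, 10), orientation=("L", "P", "I"),
                          origin=(0, 0, 0), spacing=(1, 1, 2))
        # RP z = -5 is equidistant from slices z=-4 (idx 2) and z=-6 (idx 3)
        mask = build_voi_cut(vol, VOISpec(rp=(1, 1, -5), n_slices=2, posterior_offset=100))
        used = np.flatnonzero(mask.any(axis=(0, 1)))
        assert used.tolist() == [3, 4]


class TestFitKDE:
    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        samples = np.concatenate([
            rng.normal(-1000, 10, 400), rng.normal(-100, 12, 300), rng.normal(40, 8, 300),
        ])
        dist = fit_kde(samples, bandwidth=5.0, grid_step=1.0, min_samples=1)
        expected = kde_oracle(samples, dist.grid, 5.0)
        assert np.allclose(dist.density, expected, rtol=1e-9, atol=1e-15)
        assert np.all(dist.density >= 0)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(0, 30, 2000)
        dist = fit_kde(samples, bandwidth=5.0)
        assert np.trapezoid(dist.density, dist.grid) == pytest.approx(1.0, abs=0.01)

    def test_degenerate_sample_peaks_at_value(self):
        dist = fit_kde(np.full(50, 123.0), bandwidth=5.0, min_samples=1)
        assert dist.grid[np.argmax(dist.density)] == pytest.approx(123.0)

    def test_two_separated_clusters_give_two_modes(self):
        samples = np.concatenate([np.full(500, -1000.0), np.full(500, 40.0)])
        dist = fit_kde(samples, bandwidth=5.0, min_samples=1)
        expected = kde_oracle(samples, dist.grid, 5.0)
        assert np.allclose(dist.density, expected, rtol=1e-9, atol=1e-15)
        near_air = np.abs(dist.grid - (-1000)) <= 1
        near_muscle = np.abs(dist.grid - 40) <= 1
        assert dist.density[near_air].max() == dist.density.max()
        assert dist.density[near_muscle].max() > 0.9 * dist.density.max()

    def test_small_sample_error_reports_count(self):
        with pytest.raises(ValueError, match="3 voxels"):
            fit_kde(np.array([1.0, 2.0, 3.0]), min_samples=1000)

    def test_exact_evaluation_agrees_with_grid(self):
        rng = np.random.default_rng(5)
        samples = rng.normal(0, 20, 500)
        dist = fit_kde(samples, bandwidth=5.0, min_samples=1)
        probe = dist.grid[::50]
        assert np.allclose(dist.evaluate(probe), dist.density[::50], rtol=1e-9, atol=1e-15)


class TestDetectTissuePeaks:
    def _mixture(self, rng, centers=(-1000, -100, 40), sizes=(4000, 3000, 3000), sd=8.0):
        return np.concatenate([rng.normal(c, sd, n) for c, n in zip(centers, sizes)])

    def test_modes_match_brute_force_argmax_per_window(self):
        rng = np.random.default_rng(11)
        samples = self._mixture(rng)
        dist = fit_kde(samples, bandwidth=5.0)
        peaks = detect_tissue_peaks(dist, refs_for(), refine=False)
        oracle = kde_oracle(samples, dist.grid, 5.0)
        for name, window in zip(("air", "adipose", "muscle"),
                                ((-1050, -850), (-200, -30), (10, 90))):
            in_w = (dist.grid >= window[0]) & (dist.grid <= window[1])
            grid_mode = dist.grid[in_w][np.argmax(oracle[in_w])]
            assert abs(peaks[name] - grid_mode) <= 1.0

    def test_refined_peaks_stay_within_one_grid_step(self):
        rng = np.random.default_rng(13)
        samples = self._mixture(rng)
        dist = fit_kde(samples, bandwidth=5.0)
        coarse = detect_tissue_peaks(dist, refs_for(), refine=False)
        fine = detect_tissue_peaks(dist, refs_for(), refine=True)
        for name in coarse:
            assert abs(fine[name] - coarse[name]) <= 1.0
            # refinement never decreases the density at the peak
            assert dist.evaluate(fine[name]) >= dist.evaluate(coarse[name]) - 1e-15

    def test_missing_tissue_is_named_in_error(self):
        rng = np.random.default_rng(17)
        samples = np.concatenate([rng.normal(-1000, 8, 3000), rng.normal(40, 8, 3000)])
        dist = fit_kde(samples, bandwidth=5.0)
        with pytest.raises(PeakNotFoundError, match="adipose"):
            detect_tissue_peaks(dist, refs_for())

    def test_higher_of_two_local_maxima_wins(self):
        samples = np.concatenate([
            np.full(2000, -1000.0), np.full(2000, -100.0),
            np.full(1100, 30.0), np.full(1000, 70.0),  # two modes in the muscle window
        ])
        dist = fit_kde(samples, bandwidth=3.0)
        peaks = detect_tissue_peaks(dist, refs_for())
        d30, d70 = dist.evaluate(30.0), dist.evaluate(70.0)
        assert d30 > d70
        assert peaks["muscle"] == pytest.approx(30.0, abs=1.0)

    def test_overlapping_windows_rejected(self):
        rng = np.random.default_rng(19)
        dist = fit_kde(self._mixture(rng), bandwidth=5.0)
        bad = refs_for(windows=((-1050, -850), (-900, -30), (10, 90)))
        with pytest.raises(ValueError, match="disjoint"):
            detect_tissue_peaks(dist, bad)


class TestFitPhantomlessCalibration:
    def test_identity_when_peaks_equal_references(self):
        peaks = {"air": -797.0, "adipose": -95.0, "muscle": 38.0}
        line = fit_phantomless_calibration(peaks, refs_for(windows=((-850, -700), (-150, -50), (0, 90))))
        assert line.slope == pytest.approx(1.0, rel=1e-12)
        assert line.intercept == pytest.approx(0.0, abs=1e-9)
        assert line.method == "phantomless"

    def test_three_point_ols_closed_form(self):
        peaks = {"air": -1000.0, "adipose": -100.0, "muscle": 40.0}
        line = fit_phantomless_calibration(peaks, refs_for())
        x = np.array([-1000.0, -100.0, 40.0])
        y = np.array([-797.0, -95.0, 38.0])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        assert line.slope == pytest.approx(slope, rel=1e-12)
        assert line.intercept == pytest.approx(intercept, rel=1e-12)
        assert line.slope == pytest.approx(0.7947, abs=2e-4)
        assert line.intercept == pytest.approx(-3.88, abs=0.01)

    def test_duplicate_peak_hu_rejected(self):
        peaks = {"air": -1000.0, "adipose": -1000.0, "muscle": 40.0}
        with pytest.raises(ValueError, match="distinct"):
            fit_phantomless_calibration(peaks, refs_for())

    def test_missing_peak_rejected(self):
        with pytest.raises(ValueError, match="muscle"):
            fit_phantomless_calibration({"air": -1000.0, "adipose": -100.0}, refs_for())


class TestDeriveReferenceDensities:
    def test_identity_line_passes_peaks_through(self, identity_line):
        peaks = {"air": -797.0, "adipose": -95.0, "muscle": 38.0}
        derived = derive_reference_densities([(peaks, identity_line)])
        assert derived.means == pytest.approx({"air": -797.0, "adipose": -95.0, "muscle": 38.0})
        assert derived.n_subjects == 1

    def test_two_subject_mean(self, identity_line):
        subjects = [
            ({"air": -800.0, "adipose": -96.0, "muscle": 38.0}, identity_line),
            ({"air": -794.0, "adipose": -94.0, "muscle": 38.0}, identity_line),
        ]
        derived = derive_reference_densities(subjects)
        assert derived.means == pytest.approx({"air": -797.0, "adipose": -95.0, "muscle": 38.0})
        assert derived.sds["air"] == pytest.approx(np.std([-800, -794], ddof=1))

    def test_permutation_invariance(self, identity_line):
        rng = np.random.default_rng(23)
        subjects = [
            ({t: float(rng.normal(m, 3)) for t, m in
              (("air", -797), ("adipose", -95), ("muscle", 38))}, identity_line)
            for _ in range(6)
        ]
        a = derive_reference_densities(subjects)
        b = derive_reference_densities(subjects[::-1])
        assert a.means == pytest.approx(b.means)
        assert a.sds == pytest.approx(b.sds)

    def test_missing_peak_names_subject(self, identity_line):
        subjects = [
            ({"air": -797.0, "adipose": -95.0, "muscle": 38.0}, identity_line),
            ({"air": -797.0, "muscle": 38.0}, identity_line),
        ]
        with pytest.raises(ValueError, match="subject 1"):
            derive_reference_densities(subjects)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            derive_reference_densities([])


class TestSearchWindows:
    def test_windows_bracket_all_line_corners(self):
        refs = {"air": -797.0, "adipose": -95.0, "muscle": 38.0}
        windows = search_windows_for_lines(refs, (0.6, 0.8), (-20.0, 0.0), margin=30.0)
        for t, rho in refs.items():
            lo, hi = windows[t]
            for a in (0.6, 0.8):
                for b in (-20.0, 0.0):
                    assert lo < (rho - b) / a < hi

    def test_overlapping_windows_rejected(self):
        refs = {"air": -797.0, "adipose": -95.0, "muscle": 38.0}
        with pytest.raises(ValueError, match="overlap"):
            search_windows_for_lines(refs, (0.6, 0.8), (-20.0, 0.0), margin=200.0)


class TestEndToEnd:
    def test_noiseless_pipeline_recovers_true_line(self):
        line = CalibrationLine(intercept=-8.0, slope=0.72)
        geo = ThighGeometry(shape=(64, 64, 24), spacing=(2.0, 2.0, 3.0),
                            bone_radius=10.0, muscle_radius=32.0, adipose_radius=44.0)
        subject = SyntheticSubject(true_line=line, noise_sd=0.0, geometry=geo, seed=0)
        volume, landmarks, _ = generate_thigh_volume(subject)
        windows = search_windows_for_lines(
            {"air": -797.0, "adipose": -95.0, "muscle": 38.0}, (0.72, 0.72), (-8.0, -8.0)
        )
        refs = refs_for(windows=(windows["air"], windows["adipose"], windows["muscle"]))
        fitted, _, _ = calibrate_phantomless(volume, landmarks, refs=refs)
        assert fitted.slope == pytest.approx(line.slope, rel=1e-6)
        assert fitted.intercept == pytest.approx(line.intercept, rel=1e-6)

    def test_noisy_peaks_near_true_tissue_hu(self):
        line = CalibrationLine(intercept=-10.0, slope=0.78)
        hits = 0
        for seed in range(10):
            subject = SyntheticSubject(true_line=line, noise_sd=20.0, seed=seed)
            volume, landmarks, _ = generate_thigh_volume(subject)
            _, dist, _ = calibrate_phantomless(volume, landmarks, refs=default_references())
            ok = all(
                abs(dist.peaks[t] - (rho + 10.0) / 0.78) <= 6.0
                for t, rho in (("air", -797.0), ("adipose", -95.0), ("muscle", 38.0))
            )
            hits += ok
        assert hits >= 9
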