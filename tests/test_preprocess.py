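import numpy as np
import pytest

from ramantriage.preprocess import (
    BaselineConvergenceError,
    CalibrationError,
    PreprocessConfig,
    PreprocessError,
    bin_to_grid,
    calibrate_wavenumber,
    despike,
    normalise,
    preprocess_spectrum,
    run_preprocessing,
    smooth,
    subtract_background,
)
from ramantriage.spectra_io import CohortBundle, RawSpectrum
from ramantriage.synthetic_data import (
    PeakSpec,
    SimConfig,
    inject_artifacts,
    simulate_cohort,
    training_config,
)

REF_PEAKS = (852.0, 1004.0, 1157.0, 1518.0, 1655.0)


def clean_spectrum(seed=0, noise_sd=2.0):
    cfg = SimConfig(n_patients=1, replicates_per_patient=1, prevalence=0.5,
                    noise_sd=noise_sd, seed=seed)
    spectra, _, _ = simulate_cohort(cfg)
    return spectra[0], cfg


class TestCalibration:
    def test_recovers_injected_offset(self):
        s, cfg = clean_spectrum()
        cfg.miscalibration = (2.0, 1.0)
        shifted = inject_artifacts(s, cfg)
        _, rec = calibrate_wavenumber(shifted, REF_PEAKS)
        assert abs(rec["offset_cm1"] - (-2.0)) < 0.2
        assert abs(rec["gain"] - 1.0) < 0.002

    def test_unperturbed_is_near_identity(self):
        s, _ = clean_spectrum(seed=1)
        _, rec = calibrate_wavenumber(s, REF_PEAKS)
        assert abs(rec["offset_cm1"]) < 0.2 or abs(rec["offset_cm1"] + rec["gain"] * 1004 - 1004) < 0.2
        assert abs(rec["gain"] - 1.0) < 0.002

    def test_recovers_offset_and_gain(self):
        # low-noise spectrum: gain recovery is a precision calibration task
        s, cfg = clean_spectrum(seed=2, noise_sd=0.3)
        cfg.miscalibration = (-1.5, 1.01)
        pert = inject_artifacts(s, cfg)
        corrected, rec = calibrate_wavenumber(pert, REF_PEAKS)
        # corrected axis should undo the affine perturbation: compare to truth
        assert np.max(np.abs(corrected.axis - s.axis)) < 0.5
        # implied perturbation estimate within 10% of (−1.5 cm⁻¹, 1.01)
        implied_gain = 1.0 / rec["gain"]
        implied_offset = -rec["offset_cm1"] / rec["gain"]
        assert abs(implied_offset - (-1.5)) < 0.15
        assert abs(implied_gain - 1.01) < 0.001

    def test_mean_recovery_error_over_offset_grid(self):
        """Injected offsets across [−3, +3] cm⁻¹ are recovered to < 0.3 cm⁻¹ MAE."""
        errors = []
        for i, offset in enumerate(np.linspace(-3, 3, 13)):
            s, cfg = clean_spectrum(seed=i)
            cfg.miscalibration = (float(offset), 1.0)
            pert = inject_artifacts(s, cfg)
            _, rec = calibrate_wavenumber(pert, REF_PEAKS)
            errors.append(abs(rec["offset_cm1"] + offset))
        assert np.mean(errors) < 0.3

    def test_too_few_peaks_is_error(self):
        s, _ = clean_spectrum()
        flat = RawSpectrum(s.patient_id, s.replicate_id, s.axis, np.ones_like(s.axis))
        with pytest.raises(CalibrationError, match="underdetermined"):
            calibrate_wavenumber(flat, REF_PEAKS)


class TestBinning:
    def test_arithmetic_example(self):
        s = RawSpectrum("P", "r", np.array([100.0, 101, 102, 103]), np.array([1.0, 2, 3, 4]))
        out, rec = bin_to_grid(s, (100.0, 104.0, 2.0))
        assert np.allclose(out.intensities, [1.5, 3.5])
        assert rec["empty_bins"] == 0

    def test_constant_stays_constant(self):
        s = RawSpectrum("P", "r", np.linspace(0, 100, 201), np.full(201, 7.0))
        out, _ = bin_to_grid(s, (0.0, 100.0, 5.0))
        assert np.allclose(out.intensities, 7.0)

    def test_width_one_aligned_bins_are_identity(self, rng):
        axis = np.arange(50.0, 150.0)
        y = rng.uniform(0, 10, len(axis))
        s = RawSpectrum("P", "r", axis, y)
        out, _ = bin_to_grid(s, (49.5, 149.5, 1.0))
        assert np.allclose(out.intensities, y)

    def test_empty_bins_interpolated_and_flagged(self):
        s = RawSpectrum("P", "r", np.array([0.0, 1.0, 9.0, 10.0]), np.array([1.0, 1.0, 5.0, 5.0]))
        out, rec = bin_to_grid(s, (0.0, 10.0, 2.0))
        assert rec["empty_bins"] > 0
        assert np.all(np.isfinite(out.intensities))

    def test_disjoint_grid_is_error(self):
        s = RawSpectrum("P", "r", np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(PreprocessError, match="outside"):
            bin_to_grid(s, (100.0, 200.0, 10.0))


class TestSmoothing:
    @pytest.mark.parametrize("degree", [0, 1, 2, 3])
    def test_polynomial_reproduced_exactly(self, degree):
        x = np.linspace(0, 1, 101)
        y = np.polyval(np.arange(degree + 1) + 1.0, x)
        s = RawSpectrum("P", "r", x, y)
        out, _ = smooth(s, window=11, polyorder=3)
        assert np.allclose(out.intensities, y, rtol=1e-9, atol=1e-9 * np.abs(y).max())

    def test_noise_variance_reduced(self, rng):
        reduced = 0
        for _ in range(100):
            y = rng.normal(size=200)
            s = RawSpectrum("P", "r", np.arange(200.0), y)
            out, _ = smooth(s, window=11, polyorder=3)
            reduced += out.intensities.var() < y.var()
        assert reduced == 100

    def test_window_too_large_is_error(self):
        s = RawSpectrum("P", "r", np.arange(9.0), np.ones(9))
        with pytest.raises(PreprocessError, match="window"):
            smooth(s, window=11, polyorder=3)


class TestBackground:
    def test_pure_polynomial_fully_removed(self):
        x = np.linspace(600, 1800, 400)
        t = (x - 600) / 1200
        y = 500 * (0.2 + t - 0.5 * t**2 + 0.3 * t**3 - 0.1 * t**4 + 0.05 * t**5)
        s = RawSpectrum("P", "r", x, y)
        out, _ = subtract_background(s, "polynomial", {"order": 5})
        assert np.max(np.abs(out.intensities)) < 1e-6 * np.abs(y).max()

    def test_peak_heights_recovered_over_polynomial_baseline(self):
        x = np.linspace(600, 1800, 600)
        t = (x - 600) / 1200
        baseline = 400 * (1 - 0.8 * t + 0.3 * t**2)
        peaks = [PeakSpec(1004.0, 12.0, 120.0), PeakSpec(1450.0, 25.0, 90.0),
                 PeakSpec(1655.0, 35.0, 100.0)]
        signal = sum(p.profile(x) for p in peaks)
        s = RawSpectrum("P", "r", x, signal + baseline)
        out, _ = subtract_background(s, "asymmetric_least_squares", {"lam": 1e5, "p": 0.01})
        for p in peaks:
            recovered = out.intensities[np.argmin(np.abs(x - p.center))]
            assert abs(recovered - p.amplitude) / p.amplitude < 0.05, p.center

    def test_zero_spectrum_stays_zero(self):
        x = np.linspace(0, 100, 200)
        s = RawSpectrum("P", "r", x, np.zeros(200))
        out, _ = subtract_background(s, "asymmetric_least_squares")
        assert np.max(np.abs(out.intensities)) < 1e-9

    def test_nonconvergence_carries_iteration_count(self):
        x = np.linspace(0, 100, 300)
        rng = np.random.default_rng(0)
        s = RawSpectrum("P", "r", x, rng.normal(size=300))
        with pytest.raises(BaselineConvergenceError) as exc:
            subtract_background(s, "asymmetric_least_squares", {"max_iter": 1})
        assert exc.value.iterations == 1


class TestNormalise:
    def test_three_four_five(self):
        s = RawSpectrum("P", "r", np.array([0.0, 1.0]), np.array([3.0, 4.0]))
        out, _ = normalise(s, "vector_l2")
        assert np.allclose(out.intensities, [0.6, 0.8])

    def test_scale_invariance(self, rng):
        y = rng.uniform(1, 10, 50)
        s1 = RawSpectrum("P", "r", np.arange(50.0), y)
        s2 = RawSpectrum("P", "r", np.arange(50.0), 7.3 * y)
        assert np.allclose(normalise(s1)[0].intensities, normalise(s2)[0].intensities)

    def test_total_area_integrates_to_one(self, rng):
        y = rng.uniform(1, 10, 80)
        s = RawSpectrum("P", "r", np.linspace(600, 1800, 80), y)
        out, _ = normalise(s, "total_area")
        assert abs(np.trapezoid(out.intensities, out.axis) - 1.0) < 1e-12

    def test_all_zero_is_error(self):
        s = RawSpectrum("P", "r", np.arange(5.0), np.zeros(5))
        with pytest.raises(PreprocessError, match="normalise"):
            normalise(s)


class TestFullChain:
    def test_pipeline_equals_manual_composition(self, small_bundle):
        cfg = PreprocessConfig()
        processed = run_preprocessing(small_bundle, cfg)
        s = small_bundle.spectra[0]
        m, _ = calibrate_wavenumber(s, cfg.reference_peaks,
                                    search_window=cfg.calibration_search_window,
                                    residual_threshold=cfg.calibration_residual_threshold)
        m, _ = bin_to_grid(m, cfg.grid)
        m, _ = smooth(m, cfg.smooth_window, cfg.smooth_polyorder)
        m, _ = subtract_background(m, cfg.baseline_method, cfg.baseline_params)
        m, _ = normalise(m, cfg.normalisation)
        match = [p for p in processed
                 if (p.patient_id, p.replicate_id) == (s.patient_id, s.replicate_id)]
        assert np.array_equal(match[0].values, m.intensities)

    def test_provenance_lists_steps_in_order(self, processed_small):
        steps = [rec["step"] for rec in processed_small[0].provenance]
        assert steps == ["wavenumber_calibration", "binning", "smoothing",
                         "background_subtraction", "normalisation"]

    def test_artifact_cohort_passes_invariants(self):
        cfg = training_config(n_patients=6, replicates_per_patient=2, seed=9,
                              spike_rate=2.0, miscalibration=(1.5, 1.001))
        spectra, patients, _ = simulate_cohort(cfg)
        pp = PreprocessConfig(despike=True)
        processed = run_preprocessing(CohortBundle(patients=patients, spectra=spectra), pp)
        grids = {p.grid_fingerprint() for p in processed}
        assert len(grids) == 1
        for p in processed:
            assert abs(np.linalg.norm(p.values) - 1.0) < 1e-9

    def test_deterministic_rerun(self, small_bundle):
        cfg = PreprocessConfig()
        a = run_preprocessing(small_bundle, cfg)
        b = run_preprocessing(small_bundle, cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_despike_removes_single_point_spike(self):
        s, cfg = clean_spectrum(seed=3)
        cfg.spike_rate = 4.0
        spiked = inject_artifacts(s, cfg, rng=np.random.default_rng(1))
        cleaned = despike(spiked)
        resid = np.abs(cleaned.intensities - s.intensities)
        spiked_resid = np.abs(spiked.intensities - s.intensities)
        assert resid.max() < spiked_resid.max() / 5

    def test_invalid_config_rejected(self):
        with pytest.raises(PreprocessError):
            PreprocessConfig(smooth_window=4).validate()
        with pytest.raises(PreprocessError):
            PreprocessConfig(grid=(1800.0, 600.0, 4.0)).validate()
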