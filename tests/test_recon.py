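import numpy as np
import pytest

from fpmkit import (
    ComplexField,
    GSConfig,
    LEDGrid,
    LowResStack,
    OpticalConfig,
    compute_wave_vectors,
    forward_lowres_estimate,
    initialize_spectrum,
    make_ctf,
    replace_amplitude,
    run_gs,
    simulate_capture,
    update_subspectrum,
)
from fpmkit.errors import InputError
from fpmkit.metrics import psnr
from fpmkit.optics import PupilCTF
from fpmkit.recon import SpectrumEstimate

from .oracles import lowres_field_oracle


def bandlimited_sample(optics: OpticalConfig, side: int, seed: int = 0) -> ComplexField:
    """A random complex field whose spectrum lies entirely inside the
    central (unshifted) pupil of the sensor grid."""
    rng = np.random.default_rng(seed)
    n = side // optics.upsample_factor
    ctf = make_ctf(optics, n)
    spec = np.zeros((side, side), dtype=complex)
    c, half = side // 2, n // 2
    sub = (rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))) * ctf.mask
    spec[c - half : c - half + n, c - half : c - half + n] = sub
    values = np.fft.ifft2(np.fft.ifftshift(spec))
    # positive-mean field keeps the phase channel well-defined
    values = values + 2.0 * np.max(np.abs(values))
    return ComplexField(values, pixel_um=optics.object_pixel_um)


class TestInitialization:
    def test_constant_central_image_gives_dc_delta(self, paper_optics, paper_grid):
        kvecs = compute_wave_vectors(paper_grid, paper_optics.wavelength)
        images = np.ones((paper_grid.n_led, 48, 48))
        stack = LowResStack(images=images, wave_vectors=kvecs, meta={"optics": paper_optics})
        ctf = make_ctf(paper_optics, 48)
        est = initialize_spectrum(stack, ctf, GSConfig())
        power = np.abs(est.spectrum) ** 2
        dc = power[96, 96]
        assert dc == pytest.approx(power.sum(), rel=1e-10)

    def test_factor_one_initialization_reproduces_sqrt_intensity(self):
        rng = np.random.default_rng(0)
        optics = OpticalConfig(na=0.3, wavelength=0.505, upsample_factor=1, object_pixel_um=0.4)
        grid = LEDGrid(rows=1, cols=1)
        images = rng.uniform(0.1, 1.0, size=(1, 16, 16))
        stack = LowResStack(
            images=images,
            wave_vectors=compute_wave_vectors(grid, optics.wavelength),
            meta={"optics": optics},
        )
        ctf = make_ctf(optics, 16)
        est = initialize_spectrum(stack, ctf, GSConfig())
        recovered = np.fft.ifft2(np.fft.ifftshift(est.spectrum))
        assert np.max(np.abs(recovered - np.sqrt(images[0]))) < 1e-10

    def test_48_to_192_initialization_shape(self, paper_optics, paper_grid, closed_loop):
        est = initialize_spectrum(closed_loop["stack"], closed_loop["ctf"], GSConfig())
        assert est.spectrum.shape == (192, 192)

    def test_stack_without_central_led_rejected(self, paper_optics):
        images = np.ones((1, 8, 8))
        stack = LowResStack(images=images, wave_vectors=np.array([[1.0, 0.0]]))
        with pytest.raises(InputError):
            initialize_spectrum(stack, make_ctf(paper_optics, 8), GSConfig())


class TestForwardLowresEstimate:
    def test_inband_signal_at_normal_incidence_is_identity(self, paper_optics):
        """A field band-limited inside the pupil passes the normal-incidence
        low-pass unchanged: g is exactly the field decimated to the sensor
        grid (amplitude-preserving convention)."""
        sample = bandlimited_sample(paper_optics, 64, seed=1)
        est = SpectrumEstimate(spectrum=np.fft.fftshift(np.fft.fft2(sample.values)))
        ctf = make_ctf(paper_optics, 16)
        g = forward_lowres_estimate(est, ctf, np.zeros(2))
        f = paper_optics.upsample_factor
        expected = sample.values[::f, ::f]
        scale = np.max(np.abs(expected))
        assert np.max(np.abs(g - expected)) < 1e-10 * scale

    def test_matches_naive_dft_oracle(self, small_optics, small_grid, small_sample):
        est = SpectrumEstimate(spectrum=np.fft.fftshift(np.fft.fft2(small_sample.values)))
        ctf = make_ctf(small_optics, 8)
        for k_n in compute_wave_vectors(small_grid, small_optics.wavelength):
            g = forward_lowres_estimate(est, ctf, k_n)
            oracle = lowres_field_oracle(small_sample.values, small_optics, k_n)
            assert np.max(np.abs(g - oracle)) <= 1e-8 * np.max(np.abs(oracle))

    def test_energy_never_exceeds_windowed_spectrum(self, small_optics, small_sample):
        est = SpectrumEstimate(spectrum=np.fft.fftshift(np.fft.fft2(small_sample.values)))
        ctf = make_ctf(small_optics, 8)
        g = forward_lowres_estimate(est, ctf, np.zeros(2))
        full = np.sum(np.abs(est.spectrum) ** 2) / 8**2 * (8 / 16) ** 4
        assert np.sum(np.abs(g) ** 2) <= full * (1 + 1e-12)


class TestReplaceAmplitude:
    def test_idempotent_on_consistent_data(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        out = replace_amplitude(g, np.abs(g) ** 2)
        assert np.max(np.abs(out - g)) < 1e-12

    def test_zero_measurement_gives_zero_field(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        assert np.all(replace_amplitude(g, np.zeros((8, 8))) == 0)

    def test_phase_kept_and_amplitude_imposed_elementwise(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        measured = rng.uniform(0.1, 2.0, size=(8, 8))
        out = replace_amplitude(g, measured)
        assert np.allclose(np.angle(out), np.angle(g))
        assert np.allclose(np.abs(out) ** 2, measured)

    def test_zero_amplitude_pixels_get_unit_phasor(self):
        g = np.zeros((4, 4), dtype=complex)
        measured = np.full((4, 4), 2.0)
        out = replace_amplitude(g, measured)
        assert np.allclose(out, np.sqrt(2.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            replace_amplitude(np.zeros((4, 4), complex), np.zeros((5, 5)))


class TestUpdateSubspectrum:
    def test_projector_idempotence(self, small_optics, small_grid, small_sample):
        stack = simulate_capture(small_sample, small_optics, small_grid)
        ctf = make_ctf(small_optics, 8)
        est = SpectrumEstimate(spectrum=np.fft.fftshift(np.fft.fft2(small_sample.values)))
        for n in range(stack.n_led):
            before = est.spectrum.copy()
            g = forward_lowres_estimate(est, ctf, stack.wave_vectors[n])
            update_subspectrum(est, g, ctf, stack.wave_vectors[n])
            assert np.max(np.abs(est.spectrum - before)) < 1e-10 * np.max(np.abs(before))

    def test_empty_pupil_leaves_spectrum_exactly_unchanged(self, small_optics):
        rng = np.random.default_rng(5)
        spec = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        est = SpectrumEstimate(spectrum=spec.copy())
        empty = PupilCTF(mask=np.zeros((8, 8)), cutoff=0.0, dk=make_ctf(small_optics, 8).dk)
        update_subspectrum(est, np.ones((8, 8), complex), empty, np.zeros(2))
        assert np.array_equal(est.spectrum, spec)

    def test_single_pixel_pupil_changes_exactly_one_pixel(self, small_optics):
        rng = np.random.default_rng(6)
        spec = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        est = SpectrumEstimate(spectrum=spec.copy())
        mask = np.zeros((8, 8))
        mask[4, 4] = 1.0  # DC bin only
        ctf = PupilCTF(mask=mask, cutoff=1e-6, dk=make_ctf(small_optics, 8).dk)
        update_subspectrum(est, rng.normal(size=(8, 8)) + 0j, ctf, np.zeros(2))
        changed = np.argwhere(est.spectrum != spec)
        assert changed.shape == (1, 2)
        assert tuple(changed[0]) == (8, 8)

    def test_pixels_outside_shifted_pupil_bit_identical(self, small_optics, small_grid, small_sample):
        from fpmkit.fourier import integer_shift, window_slices

        stack = simulate_capture(small_sample, small_optics, small_grid)
        ctf = make_ctf(small_optics, 8)
        rng = np.random.default_rng(7)
        spec = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        est = SpectrumEstimate(spectrum=spec.copy())
        k_n = stack.wave_vectors[0]
        update_subspectrum(est, np.sqrt(stack.images[0]).astype(complex), ctf, k_n)
        outside = np.ones((16, 16), dtype=bool)
        rs, cs = window_slices(16, 8, integer_shift(k_n, ctf.dk))
        region = np.zeros((16, 16), dtype=bool)
        region[rs, cs] = ctf.mask > 0
        outside &= ~region
        assert np.array_equal(est.spectrum[outside], spec[outside])


class TestRunGS:
    def test_closed_loop_gains_at_least_5db_over_bilinear_baseline(self, closed_loop):
        truth = closed_loop["sample"].intensity
        p_base = psnr(closed_loop["baseline_intensity"], truth, 1.0)
        p_rec = psnr(closed_loop["recon"].intensity, truth, 1.0)
        assert p_rec - p_base >= 5.0

    def test_residual_history_non_increasing_on_noise_free_data(self, closed_loop):
        hist = np.asarray(closed_loop["residuals"])
        assert len(hist) == 50
        assert np.all(np.diff(hist) <= 1e-12 + 1e-9 * hist[0])

    def test_single_central_led_recovers_lowpassed_sample_in_one_round(self):
        """A real nonnegative band-limited sample under a single on-axis
        acquisition is one consistent constraint set: after one sweep the
        reconstruction's pupil-supported spectrum equals the truth's."""
        from fpmkit.fourier import spectrum, window_slices

        optics = OpticalConfig(na=0.3, wavelength=0.505, upsample_factor=2, object_pixel_um=0.4)
        grid = LEDGrid(rows=1, cols=1)
        base = bandlimited_sample(optics, 32, seed=8)
        values = np.real(base.values) + 2.0 * np.max(np.abs(base.values))
        sample = ComplexField(values.astype(complex), pixel_um=0.4)
        stack = simulate_capture(sample, optics, grid)
        ctf = make_ctf(optics, 16)
        recon, hist = run_gs(stack, ctf, GSConfig(max_rounds=2))
        rs, cs = window_slices(32, 16, (0, 0))
        support = ctf.mask > 0
        truth_sub = spectrum(sample.values)[rs, cs][support]
        recon_sub = spectrum(recon.values)[rs, cs][support]
        assert np.max(np.abs(recon_sub - truth_sub)) < 1e-8 * np.max(np.abs(truth_sub))
        # the constraint set is already satisfied in the second sweep
        assert hist[1] < 1e-16

    def test_deterministic_bit_identical_outputs(self, small_optics, small_grid):
        grid = LEDGrid(rows=3, cols=3, pitch_mm=30.0, height_mm=90.0)
        sample = bandlimited_sample(small_optics, 16, seed=9)
        stack = simulate_capture(sample, small_optics, grid)
        ctf = make_ctf(small_optics, 8)
        r1, h1 = run_gs(stack, ctf, GSConfig(max_rounds=5))
        r2, h2 = run_gs(stack, ctf, GSConfig(max_rounds=5))
        assert np.array_equal(r1.values, r2.values)
        assert h1 == h2

    def test_empty_stack_rejected(self, paper_optics):
        stack = LowResStack(images=np.empty((0, 8, 8)), wave_vectors=np.empty((0, 2)))
        with pytest.raises(InputError):
            run_gs(stack, make_ctf(paper_optics, 8), GSConfig())

    def test_convergence_tolerance_stops_early(self, small_optics):
        grid = LEDGrid(rows=3, cols=3, pitch_mm=30.0, height_mm=90.0)
        sample = bandlimited_sample(small_optics, 16, seed=10)
        stack = simulate_capture(sample, small_optics, grid)
        ctf = make_ctf(small_optics, 8)
        _, hist = run_gs(stack, ctf, GSConfig(max_rounds=50, convergence_tol=1e-3))
        assert len(hist) < 50

    def test_covered_support_error_falls_below_1e3_within_50_rounds(self, closed_loop):
        """Relative spectrum error on the union of shifted pupils after the
        full reconstruction, noise-free reference scene."""
        from fpmkit.fourier import integer_shift, spectrum, window_slices

        sample = closed_loop["sample"]
        ctf = closed_loop["ctf"]
        stack = closed_loop["stack"]
        truth_spec = spectrum(sample.values)
        recon_spec = spectrum(closed_loop["recon"].values)
        covered = np.zeros(truth_spec.shape, dtype=bool)
        for k_n in stack.wave_vectors:
            rs, cs = window_slices(truth_spec.shape[0], ctf.side, integer_shift(k_n, ctf.dk))
            block = np.zeros(truth_spec.shape, dtype=bool)
            block[rs, cs] = ctf.mask > 0
            covered |= block
        # phase retrieval recovers the field up to a global phase factor
        theta = np.angle(np.sum(recon_spec * np.conj(truth_spec)))
        aligned = recon_spec * np.exp(-1j * theta)
        err = np.linalg.norm((aligned - truth_spec)[covered]) / np.linalg.norm(
            truth_spec[covered]
        )
        assert err < 1e-3
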