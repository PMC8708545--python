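"""PSF/OTF/Strehl computation, phase-plate correction, retinal imaging."""

import numpy as np
import pytest

from keratoptics.diffraction_imaging import (NEAR_FOCUS_D, capture_baseline,
                                             compute_otf, compute_psf,
                                             imaging_result,
                                             phase_plate_correction,
                                             psf_pixel_pitch_mm,
                                             retinal_scale_mm_per_rad,
                                             simulate_retinal_image,
                                             strehl_from_coeffs,
                                             strehl_ratio)
from keratoptics.synthetic_data import (generate_letter_scene,
                                        generate_synthetic_opd)
from keratoptics.wavefront_zernike import fit_zernike, osa_index, sample_opd


def disk_mask(n):
    u = np.linspace(-1, 1, n)
    px, py = np.meshgrid(u, u)
    return np.hypot(px, py) <= 1.0


class TestPSF:
    def test_airy_first_zero(self):
        """Unaberrated circular pupil gives the Airy pattern: first zero at
        1.22 lambda/D, i.e. 1.22 * padding * n/(n-1) PSF pixels."""
        n, pad = 64, 16
        mask = disk_mask(n)
        psf = compute_psf(np.zeros((n, n)), mask, 589.0, pad)
        c = n * pad // 2
        prof = psf[c, c:]
        j = next(i for i in range(1, 60)
                 if prof[i] < prof[i - 1] and prof[i] < prof[i + 1])
        a, b, cc = prof[j - 1], prof[j], prof[j + 1]
        r0 = j + 0.5 * (a - cc) / (a - 2 * b + cc)
        expect = 1.22 * pad * n / (n - 1)  # disk diameter is n-1 spacings
        assert r0 == pytest.approx(expect, rel=0.01)

    def test_sum_normalized_and_parseval(self):
        n = 64
        mask = disk_mask(n)
        opd = generate_synthetic_opd(np.r_[np.zeros(4), 0.2, np.zeros(10)],
                                     grid_n=n)
        psf = compute_psf(opd)
        assert psf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(psf >= 0.0)

    def test_tilt_shifts_without_reshaping(self):
        """Fourier shift theorem: pure tilt translates the PSF; with a
        tilt chosen to shift by a whole number of pixels the sampled peak
        is unchanged."""
        n, pad = 64, 4
        N = n * pad
        mask = disk_mask(n)
        flat = compute_psf(np.zeros((n, n)), mask, 589.0, pad)
        lam_um = 0.589
        vec = np.zeros(15)
        vec[osa_index(1, 1)] = 8 * (n - 1) * lam_um / (4 * N)  # 8-px shift
        tilted = compute_psf(generate_synthetic_opd(vec, n), padding=pad)
        assert tilted.max() == pytest.approx(flat.max(), rel=1e-6)
        c = N // 2
        assert np.unravel_index(tilted.argmax(), tilted.shape) != (c, c)

    def test_padding_convergence(self):
        vec = np.zeros(15)
        vec[4] = 0.05
        opd = generate_synthetic_opd(vec, 64)
        flat = np.zeros((64, 64))
        s4 = (compute_psf(opd, padding=4).max()
              / compute_psf(flat, opd.mask, 589.0, 4).max())
        s8 = (compute_psf(opd, padding=8).max()
              / compute_psf(flat, opd.mask, 589.0, 8).max())
        assert abs(s4 - s8) < 1e-4

    def test_insufficient_padding_rejected(self):
        with pytest.raises(ValueError):
            compute_psf(np.zeros((32, 32)), disk_mask(32), 589.0, 1)


class TestStrehl:
    def test_identical_inputs_unity(self):
        psf = compute_psf(np.zeros((64, 64)), disk_mask(64), 589.0, 4)
        assert strehl_ratio(psf, psf) == 1.0

    def test_marechal_approximation(self):
        """sigma = 0.02 lambda RMS -> S ~ exp(-(2 pi sigma/lambda)^2)."""
        lam_um = 0.589
        vec = np.zeros(15)
        vec[4] = 0.02 * lam_um  # unit-RMS normalized mode
        s = strehl_from_coeffs(vec, mask_grid_n=128)
        assert s == pytest.approx(np.exp(-(2 * np.pi * 0.02) ** 2),
                                  abs=0.005)

    def test_monotone_in_defocus(self):
        lam_um = 0.589
        vals = []
        for frac in np.linspace(0.0, 0.1, 6):
            vec = np.zeros(15)
            vec[4] = frac * lam_um
            vals.append(strehl_from_coeffs(vec, mask_grid_n=96))
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 + 1e-9 for v in vals)

    def test_mismatched_grids_rejected(self):
        a = compute_psf(np.zeros((32, 32)), disk_mask(32), 589.0, 4)
        b = compute_psf(np.zeros((64, 64)), disk_mask(64), 589.0, 4)
        with pytest.raises(ValueError):
            strehl_ratio(a, b)


class TestOTF:
    def test_dc_unity_and_mtf_bounded(self):
        vec = np.zeros(15)
        vec[4] = 0.1
        psf = compute_psf(generate_synthetic_opd(vec, 64))
        otf = compute_otf(psf)
        assert otf[0, 0] == pytest.approx(1.0)
        assert np.max(np.abs(otf)) <= 1.0 + 1e-9

    def test_identity_otf_preserves_scene(self):
        scene = generate_letter_scene("F", 0.025, 128)
        out = simulate_retinal_image(scene, np.ones((128, 128), complex))
        assert np.allclose(out, scene, atol=1e-12)

    def test_delta_scene_reproduces_psf(self):
        n = 32
        psf = compute_psf(np.zeros((n, n)), disk_mask(n), 589.0, 4)
        N = psf.shape[0]
        delta = np.zeros((N, N))
        delta[N // 2, N // 2] = 1.0
        img = simulate_retinal_image(delta, compute_otf(psf))
        assert np.allclose(img, psf, atol=1e-12)

    def test_energy_conserved(self):
        scene = generate_letter_scene("F", 0.025, 256)
        psf = compute_psf(np.zeros((64, 64)), disk_mask(64), 589.0, 4)
        img = simulate_retinal_image(scene, compute_otf(psf))
        assert img.sum() == pytest.approx(scene.sum(), rel=1e-6)

    def test_blur_reduces_contrast(self):
        """RMS contrast through an aberrated OTF never exceeds the
        diffraction-limited one (MTF <= 1 everywhere)."""
        scene = generate_letter_scene("F", 0.025, 256)
        sharp = compute_psf(np.zeros((64, 64)), disk_mask(64), 589.0, 4)
        vec = np.zeros(15)
        vec[4] = 0.3
        blur = compute_psf(generate_synthetic_opd(vec, 64))
        img_s = simulate_retinal_image(scene, compute_otf(sharp))
        img_b = simulate_retinal_image(scene, compute_otf(blur))
        assert img_b.std() < img_s.std()


class TestPhasePlate:
    def test_self_correction_gives_unit_strehl(self, baseline_eye):
        base = capture_baseline(baseline_eye, fields=(0.0,), grid_n=64,
                                object_vergence_D=NEAR_FOCUS_D)
        corrected = phase_plate_correction(baseline_eye, base)
        z = fit_zernike(sample_opd(corrected, 0.0, 64,
                                   object_vergence_D=NEAR_FOCUS_D))
        # every mode the plate carries is cancelled to < lambda/1000
        assert np.max(np.abs(z.vector)) < 0.589 / 1000.0
        assert strehl_from_coeffs(z) == pytest.approx(1.0, abs=1e-3)

    def test_zero_plate_is_identity(self, baseline_eye):
        plated = phase_plate_correction(baseline_eye,
                                        {0.0: np.zeros(15)})
        z0 = fit_zernike(sample_opd(baseline_eye, 0.0, 64))
        z1 = fit_zernike(sample_opd(plated, 0.0, 64))
        assert np.allclose(z0.vector, z1.vector, atol=1e-12)

    def test_linearity_of_subtraction(self, baseline_eye):
        """Modified system + reference plate shows exactly the aberration
        difference (within fit tolerance)."""
        from keratoptics.design_optimizer import reference_design
        from keratoptics.eye_model import replace_cornea
        mod = replace_cornea(
            baseline_eye,
            reference_design("without_glasses", "P407DA_PHEMA", "biconic"),
            validate=False)
        base = capture_baseline(baseline_eye, fields=(0.0,), grid_n=64,
                                object_vergence_D=0.0)
        z_mod = fit_zernike(sample_opd(mod, 0.0, 64))
        z_base = fit_zernike(sample_opd(baseline_eye, 0.0, 64))
        plated = phase_plate_correction(mod, base)
        z_resid = fit_zernike(sample_opd(plated, 0.0, 64))
        assert np.allclose(z_resid.vector, z_mod.vector - z_base.vector,
                           atol=1e-6)

    def test_missing_field_rejected(self, baseline_eye):
        plated = phase_plate_correction(baseline_eye, {0.0: np.zeros(15)})
        with pytest.raises(KeyError):
            sample_opd(plated, 5.0, 64)


class TestRetinalImaging:
    def test_retinal_scale_plausible(self, baseline_eye):
        # human eyes map ~0.28-0.30 mm per degree on the retina
        mmrad = retinal_scale_mm_per_rad(baseline_eye)
        assert 0.25 < mmrad * np.pi / 180.0 < 0.32

    def test_imaging_result_bundle(self, baseline_eye):
        pitch = psf_pixel_pitch_mm(baseline_eye, 64, padding=4)
        scene = generate_letter_scene("F", 0.025, 256, pitch_mm=pitch)
        res = imaging_result(baseline_eye, 0.0, 64, scene=scene)
        assert res.psf.shape == (256, 256)
        assert 0.0 <= res.strehl <= 1.0 + 1e-9
        assert res.retinal_image.shape == scene.shape
        assert res.psf.sum() == pytest.approx(1.0, abs=1e-9)
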