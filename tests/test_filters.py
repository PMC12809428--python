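"""CTF, whitening and Fourier-slice projection."""

import numpy as np
import pytest

from tm2d import (
    CTFParams,
    FourierSliceProjector,
    ctf_2d,
    electron_wavelength,
    euler_to_matrix,
    fourier_slice_project,
    whitening_filter,
)
from tm2d._exceptions import ParameterError
from tm2d.containers import VolumeGrid
from tm2d.filters import apply_radial_profile, bandpass_filter


def simple_ctf(**kw):
    base = dict(voltage=300.0, cs=0.0, amplitude_contrast=0.0,
                defocus_u=5000.0, defocus_v=5000.0, pixel_size=1.0)
    base.update(kw)
    return CTFParams(**base)


def gaussian_ball(n=48, sigma=5.0, px=1.0):
    """Smooth positive blob; its projections have analytic structure."""
    idx = np.indices((n, n, n), dtype=float) - n // 2
    r2 = (idx**2).sum(0)
    return VolumeGrid(data=np.exp(-r2 / (2 * sigma**2)).astype(np.float32), pixel_size=px)


class TestCTF:
    def test_wavelength_300kv(self):
        assert electron_wavelength(300.0) == pytest.approx(0.0197, abs=2e-4)

    def test_dc_value_is_minus_amplitude_contrast(self):
        f = ctf_2d(simple_ctf(amplitude_contrast=0.07, cs=2.7), (16, 16))
        assert f[0, 0] == pytest.approx(-0.07, abs=1e-12)

    def test_first_zero_closed_form_without_cs(self):
        p = simple_ctf()
        f = ctf_2d(p, (512, 512))
        row = f[0]  # ky = 0 line; skip the exact zero at DC
        k = np.fft.fftfreq(512, 1.0)
        crossings = 1 + np.nonzero(np.diff(np.sign(row[1:256])))[0]
        k_zero = k[crossings[0] + 1]
        expected = 1.0 / np.sqrt(p.wavelength * 5000.0)
        assert abs(k_zero - expected) <= 1.0 / 512  # within one Fourier pixel

    def test_zero_crossings_increase_with_defocus(self):
        counts = []
        for df in (3000.0, 6000.0, 12000.0):
            row = ctf_2d(simple_ctf(defocus_u=df, defocus_v=df), (256, 256))[0, :128]
            counts.append(int((np.diff(np.sign(row)) != 0).sum()))
        assert counts[0] < counts[1] < counts[2]

    def test_b_factor_envelope_attenuates_monotonically(self):
        f0 = np.abs(ctf_2d(simple_ctf(), (128, 128)))
        fb = np.abs(ctf_2d(simple_ctf(b_factor=150.0), (128, 128)))
        ratio = fb[0, 1:64] / np.maximum(f0[0, 1:64], 1e-12)
        assert np.all(ratio <= 1.0 + 1e-12)
        assert np.all(np.diff(ratio) < 1e-12)

    def test_astigmatism_orients_defocus(self):
        f = ctf_2d(simple_ctf(defocus_u=8000.0, defocus_v=4000.0, astig_angle=0.0),
                   (256, 256))
        # along kx (astig angle 0) the defocus is defocus_u: earlier first zero
        kx_zero = np.nonzero(np.diff(np.sign(f[0, 1:128])))[0][0]
        ky_zero = np.nonzero(np.diff(np.sign(f[1:128, 0])))[0][0]
        assert kx_zero < ky_zero

    def test_defocus_offset_shifts_both_axes(self):
        a = ctf_2d(simple_ctf(), (64, 64), defocus_offset=200.0)
        b = ctf_2d(simple_ctf(defocus_u=5200.0, defocus_v=5200.0), (64, 64))
        assert np.allclose(a, b, atol=1e-12)


class TestWhitening:
    def test_white_noise_gives_flat_filter(self):
        img = np.random.default_rng(0).standard_normal((256, 256))
        prof = whitening_filter(img, 1.0)
        mid = prof.values[20:110]
        # per-ring estimates fluctuate as 1/sqrt(ring size); flat to ~10%
        assert np.sqrt(np.mean((mid - 1.0) ** 2)) < 0.05
        assert np.all(np.abs(mid - 1.0) < 0.15)

    def test_inverts_a_known_lowpass(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((256, 256))
        amp = np.exp(-np.hypot(np.fft.fftfreq(256)[:, None] * 256,
                               np.fft.rfftfreq(256)[None, :] * 256) / 40.0)
        colored = np.fft.irfft2(np.fft.rfft2(img) * amp, s=img.shape)
        prof = whitening_filter(colored, 1.0)
        # whitening filter should be proportional to 1/amp along the radius
        r = np.arange(20, 90)
        expected = np.exp(r / 40.0)
        ratio = prof.values[r] / expected
        ratio /= ratio.mean()
        assert np.all(np.abs(ratio - 1) < 0.25)

    def test_idempotence_whitened_image_has_flat_psd(self):
        rng = np.random.default_rng(2)
        amp = np.exp(-np.hypot(np.fft.fftfreq(256)[:, None] * 256,
                               np.fft.rfftfreq(256)[None, :] * 256) / 60.0)
        colored = np.fft.irfft2(np.fft.rfft2(rng.standard_normal((256, 256))) * amp,
                                s=(256, 256))
        prof = whitening_filter(colored, 1.0)
        white = apply_radial_profile(colored, prof, 1.0)
        prof2 = whitening_filter(white, 1.0)
        assert np.all(np.abs(prof2.values[10:110] - 1.0) < 0.05)

    def test_dc_bin_zero_and_normalization(self):
        prof = whitening_filter(np.random.default_rng(3).standard_normal((128, 128)))
        assert prof.values[0] == 0.0
        assert np.mean(prof.values[1:] ** 2) == pytest.approx(1.0, rel=1e-9)

    def test_all_zero_image_raises(self):
        with pytest.raises(ParameterError):
            whitening_filter(np.zeros((32, 32)))

    def test_parseval_consistency(self):
        img = np.random.default_rng(4).standard_normal((128, 128))
        prof = whitening_filter(img, 1.0)
        white = apply_radial_profile(img, prof, 1.0)
        filt = prof.sample(img.shape, 1.0, rfft=True)
        fhat = np.fft.rfft2(img) * filt
        # account for the folded columns of the real FFT
        w = np.full(fhat.shape, 2.0)
        w[:, 0] = 1.0
        w[:, -1] = 1.0
        fourier_energy = (w * np.abs(fhat) ** 2).sum() / img.size
        assert fourier_energy == pytest.approx(float((white**2).sum()), rel=1e-6)


class TestBandpass:
    def test_masks_outside_band(self):
        m = bandpass_filter((64, 64), 1.0, low_cutoff=0.05, high_cutoff=0.25)
        k = np.hypot(np.fft.fftfreq(64)[:, None], np.fft.fftfreq(64)[None, :])
        assert np.all(m[k < 0.05] == 0) and np.all(m[k > 0.25] == 0)
        assert np.all(m[(k >= 0.05) & (k <= 0.25)] == 1)


class TestFourierSliceProjection:
    def test_identity_equals_axis_sum(self):
        v = gaussian_ball()
        p = fourier_slice_project(v, np.eye(3))
        oracle = v.data.sum(axis=0)
        assert np.linalg.norm(p - oracle) / np.linalg.norm(oracle) < 1e-3

    def test_ry90_equals_x_axis_sum(self):
        # use an asymmetric volume so the orientation actually matters
        rng = np.random.default_rng(5)
        from tm2d import make_blob_atoms, simulate_volume
        from tm2d.scattering import SimulationParams
        atoms = make_blob_atoms(100, 10.0, seed=6, b_range=(60.0, 120.0))
        v = simulate_volume(atoms, SimulationParams(box_size=48, pixel_size=1.0))
        p = fourier_slice_project(v, euler_to_matrix((0, 90, 0)))
        oracle = v.data.sum(axis=2).T  # beam along rotated z = original x
        assert np.linalg.norm(p - oracle) / np.linalg.norm(oracle) < 1e-3

    def test_mass_conservation_any_rotation(self):
        v = gaussian_ball()
        total = float(v.data.sum())
        for e in [(10, 20, 30), (100, 75, 200), (0, 135, 45)]:
            p = fourier_slice_project(v, euler_to_matrix(e))
            assert p.sum() == pytest.approx(total, rel=1e-3)

    def test_linearity_in_volume(self):
        v1 = gaussian_ball(sigma=4.0)
        v2 = gaussian_ball(sigma=7.0)
        both = VolumeGrid(data=v1.data + v2.data, pixel_size=1.0)
        R = euler_to_matrix((15, 60, 120))
        p = fourier_slice_project(both, R)
        p12 = fourier_slice_project(v1, R) + fourier_slice_project(v2, R)
        assert np.allclose(p, p12, atol=1e-4 * np.abs(p).max())

    def test_projector_batch_matches_single(self):
        v = gaussian_ball(sigma=6.0)
        proj = FourierSliceProjector(v)
        Rs = np.stack([euler_to_matrix((10, 20, 30)), euler_to_matrix((40, 50, 60))])
        batch = proj.project_many(Rs)
        assert np.allclose(batch[0], proj.project(Rs[0]), atol=1e-6)
        assert np.allclose(batch[1], proj.project(Rs[1]), atol=1e-6)
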