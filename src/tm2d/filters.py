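"""CTF generation, spectral whitening and Fourier-slice projection.

Sign and unit conventions:

* Spatial frequency ``k`` is in 1/A (cycles per angstrom).
* Positive defocus means underfocus.
* ``CTF(k) = -[sqrt(1 - w^2) sin(gamma) + w cos(gamma)] * exp(-B k^2 / 4)``
  with ``gamma = pi lambda df(alpha) k^2 - (pi/2) Cs lambda^3 k^4 + phase``,
  the usual weak-phase-object form; ``w`` is the amplitude contrast fraction.
* The electron wavelength comes from the relativistic formula
  ``lambda = 12.2639 / sqrt(V + 0.97845e-6 V^2)`` A (V in volts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from ._exceptions import ParameterError
from .containers import VolumeGrid

__all__ = [
    "CTFParams",
    "RadialProfile",
    "electron_wavelength",
    "ctf_2d",
    "whitening_filter",
    "apply_radial_profile",
    "bandpass_filter",
    "FourierSliceProjector",
    "fourier_slice_project",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in angstroms."""
    v = voltage_kv * 1e3
    return 12.2639 / math.sqrt(v + 0.97845e-6 * v * v)


@dataclass(frozen=True)
class CTFParams:
    """Per-micrograph contrast transfer function parameters.

    voltage: kV; cs: mm; amplitude_contrast: fraction; defocus_u/v: A
    (positive = underfocus); astig_angle: degrees; phase_shift: degrees;
    b_factor: A^2 envelope; pixel_size: A.
    """

    voltage: float
    cs: float
    amplitude_contrast: float
    defocus_u: float
    defocus_v: float
    astig_angle: float = 0.0
    phase_shift: float = 0.0
    b_factor: float = 0.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ParameterError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ParameterError("amplitude_contrast must be in [0, 1]")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage)


def _freq_grids(shape: tuple[int, int], pixel_size: float, rfft: bool = False):
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_size)
    fx = np.fft.rfftfreq(nx, d=pixel_size) if rfft else np.fft.fftfreq(nx, d=pixel_size)
    return fy[:, None], fx[None, :]


def ctf_2d(
    params: CTFParams,
    shape: tuple[int, int],
    defocus_offset: float = 0.0,
    rfft: bool = False,
) -> np.ndarray:
    """Sample the CTF on an FFT-layout frequency grid of the given shape.

    ``defocus_offset`` (A) is added to both defocus axes; used to step
    through defocus planes without rebuilding parameter objects.
    """
    fy, fx = _freq_grids(shape, params.pixel_size, rfft=rfft)
    k2 = fy * fy + fx * fx
    alpha = np.arctan2(fy, fx)
    lam = params.wavelength
    df_u = params.defocus_u + defocus_offset
    df_v = params.defocus_v + defocus_offset
    df = 0.5 * (df_u + df_v
                + (df_u - df_v) * np.cos(2.0 * (alpha - math.radians(params.astig_angle))))
    gamma = (math.pi * lam * df * k2
             - 0.5 * math.pi * params.cs * 1e7 * lam**3 * k2 * k2
             + math.radians(params.phase_shift))
    w = params.amplitude_contrast
    ctf = -(math.sqrt(1.0 - w * w) * np.sin(gamma) + w * np.cos(gamma))
    if params.b_factor != 0.0:
        ctf = ctf * np.exp(-params.b_factor * k2 / 4.0)
    return ctf


# ---------------------------------------------------------------------------
# Spectral whitening
# ---------------------------------------------------------------------------


@dataclass
class RadialProfile:
    """Radially binned filter: ``freq`` (1/A, ascending from 0) -> ``values``."""

    freq: np.ndarray
    values: np.ndarray

    def sample(self, shape: tuple[int, int], pixel_size: float, rfft: bool = False) -> np.ndarray:
        """Interpolate the profile onto a 2D FFT-layout grid (linear in |k|,
        clamped to the outermost bin beyond Nyquist corners)."""
        fy, fx = _freq_grids(shape, pixel_size, rfft=rfft)
        k = np.sqrt(fy * fy + fx * fx)
        return np.interp(k, self.freq, self.values).astype(np.float64)


def whitening_filter(image: np.ndarray, pixel_size: float = 1.0) -> RadialProfile:
    """Whitening filter from an image's radially averaged power spectrum.

    ``filter(k) = 1 / sqrt(radially averaged PSD)``, DC set to 0, normalized
    so the mean square over non-DC bins is 1. Radial bins are one Fourier
    pixel wide (indexed by the rounded Fourier-pixel radius).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ParameterError("image must be 2D")
    if not np.all(np.isfinite(image)):
        raise ParameterError("image contains non-finite values")
    if np.all(image == 0):
        raise ParameterError("cannot whiten an all-zero image")
    ny, nx = image.shape
    power = np.abs(np.fft.rfft2(image)) ** 2
    # Fourier-pixel radius on the rfft grid (normalized per-axis so that
    # rectangular images bin on ellipses of constant physical frequency)
    uy = np.fft.fftfreq(ny)[:, None] * max(ny, nx)
    ux = np.fft.rfftfreq(nx)[None, :] * max(ny, nx)
    r = np.rint(np.hypot(uy, ux)).astype(np.intp)
    # weight doubles the interior columns that rfft folds away
    wts = np.full((ny, nx // 2 + 1), 2.0)
    wts[:, 0] = 1.0
    if nx % 2 == 0:
        wts[:, -1] = 1.0
    n_bins = int(r.max()) + 1
    psum = np.bincount(r.ravel(), weights=(power * wts).ravel(), minlength=n_bins)
    cnt = np.bincount(r.ravel(), weights=wts.ravel(), minlength=n_bins)
    mean_power = psum / np.maximum(cnt, 1e-30)
    values = np.zeros(n_bins)
    nonzero = mean_power > 0
    nonzero[0] = False
    values[nonzero] = 1.0 / np.sqrt(mean_power[nonzero])
    ms = np.mean(values[1:] ** 2)
    if ms > 0:
        values[1:] /= math.sqrt(ms)
    freq = np.arange(n_bins) / (max(ny, nx) * pixel_size)
    return RadialProfile(freq=freq, values=values)


def apply_radial_profile(image: np.ndarray, profile: RadialProfile,
                         pixel_size: float = 1.0) -> np.ndarray:
    """Multiply an image by a radial filter in Fourier space."""
    image = np.asarray(image, dtype=np.float64)
    filt = profile.sample(image.shape, pixel_size, rfft=True)
    return np.fft.irfft2(np.fft.rfft2(image) * filt, s=image.shape)


def bandpass_filter(shape: tuple[int, int], pixel_size: float,
                    low_cutoff: float | None = None,
                    high_cutoff: float | None = None,
                    rfft: bool = False) -> np.ndarray:
    """Hard radial bandpass mask; cutoffs in 1/A (None = open end)."""
    fy, fx = _freq_grids(shape, pixel_size, rfft=rfft)
    k = np.sqrt(fy * fy + fx * fx)
    mask = np.ones_like(k)
    if low_cutoff is not None:
        mask[k < low_cutoff] = 0.0
    if high_cutoff is not None:
        mask[k > high_cutoff] = 0.0
    return mask


# ---------------------------------------------------------------------------
# Fourier-slice projection
# ---------------------------------------------------------------------------


class FourierSliceProjector:
    """Projects a cubic volume along the beam (+z) axis for arbitrary
    rotations by central-slice extraction with trilinear interpolation.

    The volume's 3D FFT (centered layout) is computed once at construction;
    `project` then samples the central plane ``R^T (kx, ky, 0)`` and inverse
    transforms, which by the Fourier slice theorem equals the real-space
    projection of the rotated volume.
    """

    def __init__(self, volume: VolumeGrid):
        data = np.asarray(volume.data, dtype=np.float64)
        n = data.shape[0]
        f3 = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(data)))
        # float32 sampling: interpolation error ~1e-7 relative, far below the
        # trilinear interpolation error itself
        self._re = np.ascontiguousarray(f3.real, dtype=np.float32)
        self._im = np.ascontiguousarray(f3.imag, dtype=np.float32)
        self.box_size = n
        self.pixel_size = volume.pixel_size
        c = n // 2
        u = np.arange(n, dtype=np.float64) - c
        uu, vv = np.meshgrid(u, u, indexing="xy")  # [v(y), u(x)] layout
        # base central-plane coordinates (kx, ky, kz=0), one column per pixel
        self._plane = np.stack([uu.ravel(), vv.ravel(), np.zeros(n * n)])
        self._center = c

    def project_many(self, rotations: np.ndarray) -> np.ndarray:
        """(M, 3, 3) rotation matrices -> (M, N, N) real projections."""
        rotations = np.asarray(rotations, dtype=np.float64).reshape(-1, 3, 3)
        m = rotations.shape[0]
        n = self.box_size
        # sample F(R^T k): coordinates in (x, y, z), then to array order (z, y, x)
        q = np.einsum("mji,jp->mip", rotations, self._plane)  # R^T @ plane
        coords = np.empty((3, m * n * n))
        coords[0] = q[:, 2].ravel() + self._center  # z index
        coords[1] = q[:, 1].ravel() + self._center  # y index
        coords[2] = q[:, 0].ravel() + self._center  # x index
        from scipy import fft as sfft

        re = map_coordinates(self._re, coords, order=1, mode="constant", cval=0.0)
        im = map_coordinates(self._im, coords, order=1, mode="constant", cval=0.0)
        slices = np.empty((m, n, n), dtype=np.complex64)
        slices.real = re.reshape(m, n, n)
        slices.imag = im.reshape(m, n, n)
        proj = np.fft.fftshift(
            sfft.ifft2(np.fft.ifftshift(slices, axes=(-2, -1)), axes=(-2, -1)),
            axes=(-2, -1),
        )
        return np.ascontiguousarray(proj.real)

    def project(self, rotation: np.ndarray) -> np.ndarray:
        return self.project_many(rotation[None])[0]


def fourier_slice_project(volume: VolumeGrid, rotation: np.ndarray) -> np.ndarray:
    """One-shot central-slice projection of ``volume`` rotated by ``rotation``."""
    return FourierSliceProjector(volume).project(rotation)
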