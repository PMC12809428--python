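"""Exhaustive whitened matched-filter search over orientations and defocus.

For every (orientation, defocus) pair the engine Fourier-slice-projects the
template, applies CTF x whitening, normalizes the projection to zero mean and
unit L2 over the full padded frame, and cross-correlates it with the whitened,
unit-variance micrograph by FFT. Per pixel it keeps the running maximum (MIP)
with its argmax pose, and the running mean and variance of *all* correlation
values; the detection statistic is the scaled MIP

    z(x) = (MIP(x) - mean(x)) / sqrt(variance(x)).

Under the Gaussian background model each correlation value is standard
normal, so a detection threshold for an expected number of false positives
follows from the survival function and the total number of comparisons
(pixels x orientations x defocus planes).

Correlation maps are indexed by particle *center* position. Peaks within half
a template box of the image edge are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy.stats import norm

from ._exceptions import ParameterError, PixelSizeMismatchError
from .containers import Micrograph, VolumeGrid
from .filters import CTFParams, FourierSliceProjector, RadialProfile, ctf_2d, whitening_filter
from .geometry import OrientationGrid

__all__ = [
    "SearchSpace",
    "MatchResultMaps",
    "ParticleRecord",
    "defocus_planes",
    "prepare_whitened_image",
    "run_match",
    "detection_threshold",
    "fp_probability",
    "extract_peaks",
]

logger = logging.getLogger(__name__)


def defocus_planes(minimum: float, maximum: float, step: float) -> np.ndarray:
    """Inclusive defocus-offset schedule in angstroms (e.g. -1200..1200 by
    200 gives 13 planes)."""
    if step <= 0:
        raise ParameterError("defocus step must be positive")
    return np.arange(minimum, maximum + 1e-9, step)


@dataclass
class SearchSpace:
    """Orientation grid x defocus offsets; knows its own cardinality."""

    grid: OrientationGrid
    defocus_offsets: np.ndarray = field(default_factory=lambda: np.array([0.0]))

    def __post_init__(self) -> None:
        self.defocus_offsets = np.atleast_1d(np.asarray(self.defocus_offsets, dtype=float))
        if len(self.grid) == 0 or self.defocus_offsets.size == 0:
            raise ParameterError("search space must be non-empty")
        if not np.all(np.diff(self.defocus_offsets) >= 0):
            raise ParameterError("defocus offsets must be sorted ascending")

    @property
    def n_per_pixel(self) -> int:
        """Number of cross-correlations per pixel."""
        return len(self.grid) * self.defocus_offsets.size


@dataclass
class ParticleRecord:
    """One detection: center position (0-based pixels), pose, defocus offset
    relative to the nominal CTF, z-score and false-positive probability."""

    micrograph_id: str
    x: int
    y: int
    phi: float
    theta: float
    psi: float
    defocus: float
    z_score: float
    fp_probability: float
    flag: str = ""


@dataclass
class MatchResultMaps:
    """Per-pixel outputs of a full search, all maps image-shaped."""

    mip: np.ndarray
    scaled_mip: np.ndarray
    best_phi: np.ndarray
    best_theta: np.ndarray
    best_psi: np.ndarray
    best_defocus: np.ndarray
    corr_mean: np.ndarray
    corr_variance: np.ndarray
    n_total: int               # pixels x orientations x defocus planes
    n_per_pixel: int           # orientations x defocus planes
    template_box: int
    pixel_size: float
    tail_counts: dict[float, int] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mip.shape

    @property
    def value_mean(self) -> float:
        """Global mean of all correlation values of the search."""
        return float(self.corr_mean.mean())

    @property
    def value_variance(self) -> float:
        """Global variance of all correlation values of the search (law of
        total variance over pixels); approximately 1 under the Gaussian
        background model."""
        mu = self.corr_mean.mean()
        return float((self.corr_variance + self.corr_mean**2).mean() - mu * mu)

    def named_maps(self) -> dict[str, np.ndarray]:
        return {
            "mip": self.mip, "scaled_mip": self.scaled_mip,
            "best_phi": self.best_phi, "best_theta": self.best_theta,
            "best_psi": self.best_psi, "best_defocus": self.best_defocus,
            "corr_mean": self.corr_mean, "corr_variance": self.corr_variance,
        }


def prepare_whitened_image(
    micrograph: Micrograph, profile: RadialProfile | None = None
) -> tuple[np.ndarray, RadialProfile]:
    """Whiten a micrograph with its own radial power spectrum and standardize
    it to zero mean / unit variance. All scoring paths (search, refinement,
    pixel-size optimization, constrained search) share this preparation so
    their z values are directly comparable."""
    data = np.asarray(micrograph.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ParameterError("micrograph contains non-finite values")
    if profile is None:
        profile = whitening_filter(data, micrograph.pixel_size)
    filt = profile.sample(data.shape, micrograph.pixel_size, rfft=True)
    white = np.fft.irfft2(np.fft.rfft2(data) * filt, s=data.shape)
    white -= white.mean()
    sd = white.std()
    if sd == 0:
        raise ParameterError("whitened image has zero variance")
    return white / sd, profile


def _filtered_templates(
    projections: np.ndarray, filters: np.ndarray
) -> np.ndarray:
    """Apply per-defocus (CTF x whitening) filters to a batch of projections
    and normalize each result to zero mean, unit L2.

    projections: (M, b, b) real; filters: (D, b, b) real ->
    (M, D, b, b) float32, plane order (orientation-major, then defocus).
    """
    phat = sfft.fft2(projections)
    stack = sfft.ifft2(phat[:, None, :, :] * filters[None, :, :, :]).real
    stack -= stack.mean(axis=(-2, -1), keepdims=True)
    nrm = np.sqrt(np.sum(stack * stack, axis=(-2, -1), keepdims=True))
    nrm[nrm == 0] = 1.0
    return (stack / nrm).astype(np.float32)


def run_match(
    micrograph: Micrograph,
    template: VolumeGrid,
    ctf: CTFParams,
    space: SearchSpace,
    tail_thresholds: tuple[float, ...] = (3.0, 3.5, 4.0),
    pixel_size_tolerance: float = 1e-3,
    plane_budget_elements: int = 25_000_000,
) -> MatchResultMaps:
    """Run the exhaustive search of ``space`` on one micrograph.

    The template pixel size must equal the micrograph pixel size within
    ``pixel_size_tolerance``; when it does not, resimulate the template at
    the micrograph pixel size (see `tm2d.refine.optimize_pixel_size`).
    """
    h, w = micrograph.shape
    box = template.box_size
    if box > min(h, w):
        raise ParameterError(f"template box {box} exceeds image size {micrograph.shape}")
    if abs(template.pixel_size - micrograph.pixel_size) > pixel_size_tolerance:
        raise PixelSizeMismatchError(
            f"template pixel size {template.pixel_size} differs from micrograph pixel "
            f"size {micrograph.pixel_size}; resimulate the template at the micrograph "
            "pixel size or run the optimize-template program to calibrate it"
        )
    if not np.all(np.isfinite(template.data)):
        raise ParameterError("template contains non-finite values")

    image_w, profile = prepare_whitened_image(micrograph)
    half = box // 2
    # phase ramp re-centers correlation maps on particle centers
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    ihat = sfft.rfft2(image_w) * np.exp(-2j * np.pi * (fy * half + fx * half))

    px = micrograph.pixel_size
    whit_box = profile.sample((box, box), px, rfft=False)
    offsets = space.defocus_offsets
    d_count = offsets.size
    filters = (np.stack([ctf_2d(ctf, (box, box), d) for d in offsets])
               * whit_box[None]).astype(np.float32)

    projector = FourierSliceProjector(template)
    rmats = space.grid.matrices()
    n_orient = len(space.grid)

    sum_ = np.zeros((h, w))
    sumsq = np.zeros((h, w))
    mip = np.full((h, w), -np.inf, dtype=np.float32)
    argplane = np.zeros((h, w), dtype=np.int64)
    tails = {float(t): 0 for t in tail_thresholds}

    chunk = max(1, plane_budget_elements // (h * w * max(d_count, 1)))
    logger.info("search: %d orientations x %d defocus planes on %dx%d image",
                n_orient, d_count, h, w)
    for o0 in range(0, n_orient, chunk):
        rots = rmats[o0:o0 + chunk]
        m = rots.shape[0]
        projs = projector.project_many(rots)
        tmpl = _filtered_templates(projs, filters).reshape(m * d_count, box, box)
        padded = np.zeros((m * d_count, h, w), dtype=np.float32)
        padded[:, :box, :box] = tmpl
        that = sfft.rfft2(padded)
        np.conjugate(that, out=that)
        that *= ihat[None]
        corr = sfft.irfft2(that, s=(h, w))
        del that, padded

        sum_ += corr.sum(axis=0, dtype=np.float64)
        sumsq += np.einsum("pij,pij->ij", corr, corr, dtype=np.float64)
        cmax = corr.max(axis=0)
        carg = corr.argmax(axis=0)
        upd = cmax > mip
        mip[upd] = cmax[upd]
        argplane[upd] = carg[upd] + o0 * d_count
        for t in tails:
            tails[t] += int(np.count_nonzero(corr > t))
        del corr

    n_planes = n_orient * d_count
    corr_mean = sum_ / n_planes
    corr_var = np.maximum(sumsq / n_planes - corr_mean**2, 0.0)
    sd = np.sqrt(np.maximum(corr_var, 1e-12))
    scaled = (mip.astype(np.float64) - corr_mean) / sd

    o_idx, d_idx = np.divmod(argplane, d_count)
    eulers = space.grid.orientations
    return MatchResultMaps(
        mip=mip.astype(np.float64),
        scaled_mip=scaled,
        best_phi=eulers[o_idx, 0],
        best_theta=eulers[o_idx, 1],
        best_psi=eulers[o_idx, 2],
        best_defocus=offsets[d_idx],
        corr_mean=corr_mean,
        corr_variance=corr_var,
        n_total=h * w * n_planes,
        n_per_pixel=n_planes,
        template_box=box,
        pixel_size=px,
        tail_counts=tails,
    )


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------


def detection_threshold(n_correlations_total: float, expected_false_positives: float = 1.0) -> float:
    """z* such that ``n_total * SF(z*) = expected_false_positives`` under the
    standard-normal background model."""
    if n_correlations_total <= 0 or expected_false_positives <= 0:
        raise ParameterError("both arguments must be positive")
    return float(norm.isf(expected_false_positives / n_correlations_total))


def fp_probability(z, n_correlations_total: float):
    """Probability that at least one of ``n`` standard-normal comparisons
    exceeds ``z``: ``1 - (1 - SF(z))^n``, evaluated in log space."""
    if n_correlations_total <= 0:
        raise ParameterError("n_correlations_total must be positive")
    sf = norm.sf(np.asarray(z, dtype=float))
    with np.errstate(divide="ignore"):
        out = -np.expm1(n_correlations_total * np.log1p(-np.minimum(sf, 1.0 - 1e-300)))
    return np.clip(out, 0.0, 1.0) if np.ndim(z) else float(np.clip(out, 0.0, 1.0))


def extract_peaks(
    maps: MatchResultMaps,
    z_threshold: float,
    exclusion_radius: int | None = None,
    micrograph_id: str = "",
) -> list[ParticleRecord]:
    """Greedy descending-z peak extraction from the scaled MIP.

    Local maxima at or above ``z_threshold`` are accepted in decreasing-z
    order; each accepted peak suppresses later candidates within
    ``exclusion_radius`` pixels (default: template box / 4). An edge band of
    half a template box is excluded.
    """
    if exclusion_radius is None:
        exclusion_radius = max(1, maps.template_box // 4)
    if exclusion_radius < 1:
        raise ParameterError("exclusion_radius must be >= 1")
    h, w = maps.shape
    half = maps.template_box // 2
    scaled = maps.scaled_mip.copy()
    scaled[:half, :] = -np.inf
    scaled[h - half:, :] = -np.inf
    scaled[:, :half] = -np.inf
    scaled[:, w - half:] = -np.inf

    ys, xs = np.nonzero(scaled >= z_threshold)
    if ys.size == 0:
        return []
    order = np.argsort(scaled[ys, xs])[::-1]
    ys, xs = ys[order], xs[order]
    suppressed = np.zeros((h, w), dtype=bool)
    r2 = exclusion_radius**2
    dy, dx = np.mgrid[-exclusion_radius:exclusion_radius + 1,
                      -exclusion_radius:exclusion_radius + 1]
    disk = np.stack([dy[dy**2 + dx**2 <= r2], dx[dy**2 + dx**2 <= r2]], axis=1)
    records = []
    for y, x in zip(ys, xs):
        if suppressed[y, x]:
            continue
        z = float(scaled[y, x])
        records.append(ParticleRecord(
            micrograph_id=micrograph_id, x=int(x), y=int(y),
            phi=float(maps.best_phi[y, x]), theta=float(maps.best_theta[y, x]),
            psi=float(maps.best_psi[y, x]), defocus=float(maps.best_defocus[y, x]),
            z_score=z, fp_probability=fp_probability(z, maps.n_total),
        ))
        pts = disk + np.array([y, x])
        ok = ((pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w))
        suppressed[pts[ok, 0], pts[ok, 1]] = True
    return records
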