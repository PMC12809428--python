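"""Synthetic fixture generation: blob atom lists, planted-particle
micrographs, pure-noise micrographs and two-body particle fields.

Every generator is a pure function of its arguments including the seed.

Signal scaling
--------------
Planted particles are CTF-filtered Fourier-slice projections of the
template, added in real space at integer pixel positions, exactly mirroring
the filtering applied by the search path (whitening is an analysis-side
filter and is not applied to the signal). The amplitude of each particle is
chosen so its nominal matched-filter z-score is ``snr``:

    amplitude = snr * noise_sigma / ||filtered projection||_2,

which for white noise makes the expected peak z of the search approximately
``snr``. The default ``snr`` of 15 emulates a large, well-ordered complex
(reported in-cell z-scores for ribosome-sized particles span roughly 8-30);
two-body fields default to a weaker second body (``snr2 = 8``), emulating a
subunit of roughly a quarter the mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sfft

from ._exceptions import ParameterError
from .constrained import ConstraintGeometry, pose_from_reference
from .containers import Micrograph, VolumeGrid
from .filters import CTFParams, FourierSliceProjector, ctf_2d
from .geometry import euler_to_matrix, matrix_to_euler
from .match import ParticleRecord
from .scattering import AtomRecord

__all__ = [
    "PlantedField",
    "make_blob_atoms",
    "sample_positions",
    "make_micrograph",
    "make_two_body_field",
    "default_offset_sampler",
]

TRUTH_COLUMNS = ["micrograph_id", "x", "y", "phi", "theta", "psi", "defocus",
                 "z_score", "fp_probability"]


@dataclass
class PlantedField:
    """A micrograph together with its planted ground truth."""

    micrograph: Micrograph
    truth: pd.DataFrame
    noise_sigma: float
    seed: int


def make_blob_atoms(
    n_atoms: int,
    radius: float,
    seed: int,
    element: str = "C",
    b_range: tuple[float, float] = (20.0, 60.0),
) -> list[AtomRecord]:
    """Reproducible globular cluster: atoms uniform in a sphere of the given
    radius (A), with B factors drawn uniformly from ``b_range``."""
    if n_atoms < 1:
        raise ParameterError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    direc = rng.standard_normal((n_atoms, 3))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, n_atoms) ** (1.0 / 3.0)
    pos = direc * r[:, None]
    b = rng.uniform(*b_range, n_atoms)
    return [AtomRecord(element, tuple(p), float(bi)) for p, bi in zip(pos, b)]


def sample_positions(
    shape: tuple[int, int],
    box: int,
    n: int,
    min_dist: float,
    rng: np.random.Generator,
    max_tries: int = 50_000,
    margin: int | None = None,
) -> np.ndarray:
    """n integer (x, y) positions at least ``min_dist`` apart and at least
    half a box (plus margin) from every edge, by rejection sampling."""
    h, w = shape
    if margin is None:
        margin = box // 2 + 4
    pts: list[tuple[int, int]] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        x = int(rng.integers(margin, w - margin))
        y = int(rng.integers(margin, h - margin))
        if all((x - px) ** 2 + (y - py) ** 2 >= min_dist**2 for px, py in pts):
            pts.append((x, y))
    if len(pts) < n:
        raise ParameterError(
            f"could not place {n} positions with min_dist {min_dist} in {shape}")
    return np.array(pts)


def _plant(
    canvas: np.ndarray,
    projector: FourierSliceProjector,
    ctf: CTFParams,
    x: int,
    y: int,
    eulers: tuple[float, float, float],
    defocus: float,
    amplitude_over_norm: float,
) -> float:
    """Add one CTF-filtered projection; returns the amplitude used."""
    box = projector.box_size
    half = box // 2
    h, w = canvas.shape
    if not (half <= x < w - (box - half) and half <= y < h - (box - half)):
        raise ParameterError(f"position ({x}, {y}) too close to the edge")
    proj = projector.project(euler_to_matrix(eulers))
    filt = ctf_2d(ctf, (box, box), defocus)
    t = sfft.ifft2(sfft.fft2(proj) * filt).real
    nrm = np.sqrt((t * t).sum())
    amp = amplitude_over_norm / nrm if nrm > 0 else 0.0
    canvas[y - half:y - half + box, x - half:x - half + box] += amp * t
    return amp


def make_micrograph(
    template: VolumeGrid,
    poses: pd.DataFrame | list[dict],
    ctf: CTFParams,
    noise_sigma: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    snr: float = 15.0,
) -> PlantedField:
    """Micrograph with CTF-filtered projections planted at known poses plus
    white Gaussian noise. ``poses`` rows need columns x, y, phi, theta, psi
    and optionally defocus (A, default 0) and snr (default the global one);
    an empty table gives a pure-noise micrograph."""
    poses = pd.DataFrame(poses, columns=None if len(poses) else
                         ["x", "y", "phi", "theta", "psi"])
    rng = np.random.default_rng(seed)
    canvas = np.zeros(shape)
    projector = FourierSliceProjector(template) if len(poses) else None
    if len(poses):
        xy = poses[["x", "y"]].to_numpy(dtype=float)
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < template.box_size**2:
            warnings.warn("planted particles closer than one template box overlap")
    rows = []
    for _, p in poses.iterrows():
        dfoc = float(p.get("defocus", 0.0))
        s = float(p.get("snr", snr))
        _plant(canvas, projector, ctf, int(p["x"]), int(p["y"]),
               (p["phi"], p["theta"], p["psi"]), dfoc,
               amplitude_over_norm=s * noise_sigma if noise_sigma > 0 else s)
        rows.append({"micrograph_id": f"synthetic_{seed}", "x": int(p["x"]),
                     "y": int(p["y"]), "phi": float(p["phi"]),
                     "theta": float(p["theta"]), "psi": float(p["psi"]),
                     "defocus": dfoc, "snr": s})
    canvas += noise_sigma * rng.standard_normal(shape)
    truth = pd.DataFrame(rows, columns=["micrograph_id", "x", "y", "phi", "theta",
                                        "psi", "defocus", "snr"])
    return PlantedField(
        micrograph=Micrograph(data=canvas.astype(np.float32),
                              pixel_size=template.pixel_size),
        truth=truth, noise_sigma=noise_sigma, seed=seed,
    )


def default_offset_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Default intersubunit offset mixture: 75% nonrotated
    (psi_off ~ N(0, 0.5)), 25% rotated (psi_off ~ N(-8, 1)); roll couples
    weakly to rotation (theta_off = 0.15 psi_off + N(0, 0.3)). Returns an
    (n, 2) array of (psi_off, theta_off) in degrees."""
    rotated = rng.uniform(size=n) < 0.25
    psi = np.where(rotated, rng.normal(-8.0, 1.0, n), rng.normal(0.0, 0.5, n))
    theta = 0.15 * psi + rng.normal(0.0, 0.3, n)
    return np.column_stack([psi, theta])


def make_two_body_field(
    template1: VolumeGrid,
    template2: VolumeGrid,
    geom: ConstraintGeometry,
    ctf: CTFParams,
    n_pairs: int,
    shape: tuple[int, int] = (512, 512),
    noise_sigma: float = 1.0,
    seed: int = 0,
    snr1: float = 15.0,
    snr2: float = 8.0,
    offset_sampler=default_offset_sampler,
    min_dist: float | None = None,
    reference_eulers: np.ndarray | None = None,
) -> PlantedField:
    """Two-body particle field: body-1 particles at random poses, each with a
    body-2 partner at the pose predicted by the constraint geometry plus a
    sampled (psi_off, theta_off) intersubunit offset.

    The truth table holds one row per pair with the body-1 pose/position and
    the planted offsets, plus the realized body-2 position/pose.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    box1 = template1.box_size
    px = template1.pixel_size
    if min_dist is None:
        min_dist = box1 * 0.9
    # keep room for the displaced body-2 box at any reference orientation
    margin = box1 // 2 + 4 + template2.box_size // 2 + int(
        np.ceil(np.linalg.norm(geom.center_offset) / px))
    positions = sample_positions(shape, box1, n_pairs, min_dist, rng, margin=margin)
    if reference_eulers is None:
        eulers1 = np.column_stack([
            rng.uniform(0, 360, n_pairs),
            np.degrees(np.arccos(rng.uniform(-1, 1, n_pairs))),
            rng.uniform(0, 360, n_pairs),
        ])
    else:
        eulers1 = np.broadcast_to(np.asarray(reference_eulers, dtype=float),
                                  (n_pairs, 3)).copy()
    offsets = np.asarray(offset_sampler(rng, n_pairs), dtype=float)

    canvas = np.zeros(shape)
    proj1 = FourierSliceProjector(template1)
    proj2 = FourierSliceProjector(template2)
    rows = []
    for i in range(n_pairs):
        x1, y1 = map(int, positions[i])
        e1 = tuple(eulers1[i])
        _plant(canvas, proj1, ctf, x1, y1, e1, 0.0,
               snr1 * noise_sigma if noise_sigma > 0 else snr1)
        ref = ParticleRecord(micrograph_id=f"twobody_{seed}", x=x1, y=y1,
                             phi=e1[0], theta=e1[1], psi=e1[2], defocus=0.0,
                             z_score=np.nan, fp_probability=np.nan)
        psi_off, theta_off = offsets[i]
        r2, x2f, y2f, dfoc2 = pose_from_reference(ref, geom, psi_off, theta_off, px)
        e2 = matrix_to_euler(r2)
        x2, y2 = int(round(x2f)), int(round(y2f))
        _plant(canvas, proj2, ctf, x2, y2, (e2.phi, e2.theta, e2.psi), dfoc2,
               snr2 * noise_sigma if noise_sigma > 0 else snr2)
        rows.append({
            "micrograph_id": f"twobody_{seed}", "x": x1, "y": y1,
            "phi": e1[0], "theta": e1[1], "psi": e1[2], "defocus": 0.0,
            "psi_off": psi_off, "theta_off": theta_off,
            "x2": x2, "y2": y2, "phi2": e2.phi, "theta2": e2.theta,
            "psi2": e2.psi, "defocus2": dfoc2,
        })
    canvas += noise_sigma * rng.standard_normal(shape)
    return PlantedField(
        micrograph=Micrograph(data=canvas.astype(np.float32), pixel_size=px),
        truth=pd.DataFrame(rows), noise_sigma=noise_sigma, seed=seed,
    )
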