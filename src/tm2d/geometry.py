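"""Rotation algebra and uniform orientation grids.

Euler convention
----------------
All Euler triplets ``(phi, theta, psi)`` are **intrinsic ZYZ** angles in
degrees: ``R = Rz(phi) @ Ry(theta) @ Rz(psi)``, applied to column vectors of
template coordinates. This is the common cryo-EM convention; exported pose
tables depend on it, so it is fixed here once and used everywhere else.

``theta`` lies in [0, 180]; ``phi`` and ``psi`` are reduced to [0, 360).

Orientation grids
-----------------
`uniform_grid` samples SO(3) on latitude rings: theta rings at multiples of
the theta step, per-ring azimuth (phi) counts proportional to ``sin(theta)``,
and in-plane (psi) angles on a regular grid whose range is reduced by Cn
symmetry. The azimuth count per ring is::

    n_phi(theta) = max(2, round(360 * sin(theta) / theta_step))

i.e. even the polar rings carry two azimuth samples. With a psi step of 1.5
degrees and a theta step of 2.5 degrees under C1 this yields 6602 directions
x 240 in-plane angles = 1 584 480 orientations, matching the search-space
cardinality used for full-micrograph searches with 13 defocus planes
(20 598 240 cross-correlations).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ._exceptions import GeometryError, ParameterError

__all__ = [
    "EulerTriplet",
    "AxisAngle",
    "SymmetryGroup",
    "OrientationGrid",
    "euler_to_matrix",
    "matrix_to_euler",
    "matrix_to_axis_angle",
    "axis_angle_to_matrix",
    "rotation_angle_between",
    "uniform_grid",
    "grid_count",
    "kabsch",
    "center_vector",
]


@dataclass(frozen=True)
class EulerTriplet:
    """Intrinsic ZYZ Euler angles in degrees."""

    phi: float
    theta: float
    psi: float

    def canonical(self) -> "EulerTriplet":
        """Reduce phi/psi to [0, 360); theta must already be in [0, 180]."""
        if not 0.0 <= self.theta <= 180.0:
            raise ParameterError(f"theta must be in [0, 180], got {self.theta}")
        return EulerTriplet(self.phi % 360.0, self.theta, self.psi % 360.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.phi, self.theta, self.psi], dtype=float)


@dataclass(frozen=True)
class AxisAngle:
    """Rotation axis (unit vector) and angle in degrees, angle in [0, 180]."""

    axis: tuple[float, float, float]
    angle: float


@dataclass(frozen=True)
class SymmetryGroup:
    """Cyclic point group Cn with the symmetry axis along template z."""

    schoenflies: str
    order: int

    @classmethod
    def from_string(cls, text: str) -> "SymmetryGroup":
        m = re.fullmatch(r"[Cc](\d+)", text.strip())
        if not m or int(m.group(1)) < 1:
            raise ParameterError(
                f"unsupported symmetry {text!r}; only cyclic groups C1, C2, ... are supported"
            )
        n = int(m.group(1))
        return cls(schoenflies=f"C{n}", order=n)


C1 = SymmetryGroup("C1", 1)


def euler_to_matrix(e: EulerTriplet | tuple[float, float, float] | np.ndarray) -> np.ndarray:
    """Rotation matrix for intrinsic ZYZ Euler angles in degrees."""
    if isinstance(e, EulerTriplet):
        ang = [e.phi, e.theta, e.psi]
    else:
        ang = list(np.asarray(e, dtype=float))
    return Rotation.from_euler("ZYZ", ang, degrees=True).as_matrix()


def eulers_to_matrices(eulers: np.ndarray) -> np.ndarray:
    """Vectorized `euler_to_matrix` for an (N, 3) array of degree triplets."""
    return Rotation.from_euler("ZYZ", np.asarray(eulers, dtype=float), degrees=True).as_matrix()


def matrix_to_euler(R: np.ndarray) -> EulerTriplet:
    """Inverse of `euler_to_matrix`; at gimbal lock (theta in {0, 180}) the
    returned phi is 0 by convention (phi and psi are degenerate there)."""
    phi, theta, psi = Rotation.from_matrix(np.asarray(R, dtype=float)).as_euler(
        "ZYZ", degrees=True
    )
    return EulerTriplet(phi % 360.0, float(theta), psi % 360.0).canonical()


def matrix_to_axis_angle(R: np.ndarray) -> AxisAngle:
    """Axis-angle decomposition; identity maps to axis (0, 0, 1), angle 0."""
    rotvec = Rotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec(degrees=True)
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-12:
        return AxisAngle(axis=(0.0, 0.0, 1.0), angle=0.0)
    ax = rotvec / angle
    return AxisAngle(axis=(float(ax[0]), float(ax[1]), float(ax[2])), angle=angle)


def axis_angle_to_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-12:
        raise ParameterError("rotation axis must be a non-zero vector")
    return Rotation.from_rotvec(axis / nrm * np.radians(angle_deg)).as_matrix()


def rotation_angle_between(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic distance on SO(3) in degrees between two rotation matrices."""
    return matrix_to_axis_angle(np.asarray(Ra) @ np.asarray(Rb).T).angle


# ---------------------------------------------------------------------------
# Orientation grids
# ---------------------------------------------------------------------------


def _ring_thetas(theta_step: float) -> np.ndarray:
    return np.arange(0.0, 180.0 + 1e-9, theta_step)


def _ring_phi_count(theta_deg: float, theta_step: float) -> int:
    # round-half-away-from-zero; every ring keeps at least two azimuth samples
    x = 360.0 * np.sin(np.radians(theta_deg)) / theta_step
    return max(2, int(np.floor(x + 0.5)))


def _psi_values(psi_step: float, symmetry: SymmetryGroup) -> np.ndarray:
    return np.arange(0.0, 360.0 / symmetry.order - 1e-9, psi_step)


@dataclass
class OrientationGrid:
    """Explicit list of Euler triplets sampled uniformly over SO(3)/Cn.

    ``orientations`` is an (N, 3) float array of (phi, theta, psi) in degrees,
    ordered theta-major, then phi, then psi, so that argmax tie-breaking in
    the search engine is deterministic.
    """

    psi_step: float
    theta_step: float
    symmetry: SymmetryGroup
    orientations: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.orientations)

    def matrices(self) -> np.ndarray:
        """(N, 3, 3) rotation matrices for all grid members."""
        return eulers_to_matrices(self.orientations)

    def to_text(self, path) -> None:
        """Write the grid as a plain-text table (phi theta psi, degrees)."""
        header = (
            "phi theta psi  (degrees, intrinsic ZYZ: R = Rz(phi) Ry(theta) Rz(psi))\n"
            f"psi_step={self.psi_step} theta_step={self.theta_step} "
            f"symmetry={self.symmetry.schoenflies}"
        )
        np.savetxt(path, self.orientations, fmt="%.6f", header=header)

    @classmethod
    def from_text(cls, path, psi_step=np.nan, theta_step=np.nan, symmetry=C1):
        arr = np.atleast_2d(np.loadtxt(path))
        return cls(psi_step=psi_step, theta_step=theta_step, symmetry=symmetry, orientations=arr)


def uniform_grid(
    psi_step: float,
    theta_step: float,
    symmetry: SymmetryGroup | str = C1,
) -> OrientationGrid:
    """Uniform SO(3) grid at the given in-plane (psi) and out-of-plane
    (theta) steps in degrees, with the psi range reduced to [0, 360/n) for Cn.
    """
    if isinstance(symmetry, str):
        symmetry = SymmetryGroup.from_string(symmetry)
    for name, step in (("psi_step", psi_step), ("theta_step", theta_step)):
        if not 0.0 < step <= 180.0:
            raise ParameterError(f"{name} must be in (0, 180], got {step}")

    psis = _psi_values(psi_step, symmetry)
    blocks = []
    for theta in _ring_thetas(theta_step):
        n_phi = _ring_phi_count(theta, theta_step)
        phis = np.arange(n_phi) * (360.0 / n_phi)
        block = np.empty((n_phi * len(psis), 3))
        block[:, 0] = np.repeat(phis, len(psis))
        block[:, 1] = theta
        block[:, 2] = np.tile(psis, n_phi)
        blocks.append(block)
    orientations = np.concatenate(blocks, axis=0)
    return OrientationGrid(
        psi_step=psi_step, theta_step=theta_step, symmetry=symmetry, orientations=orientations
    )


def grid_count(
    psi_step: float, theta_step: float, symmetry: SymmetryGroup | str = C1
) -> int:
    """Closed-form cardinality of `uniform_grid` without materializing it."""
    if isinstance(symmetry, str):
        symmetry = SymmetryGroup.from_string(symmetry)
    for name, step in (("psi_step", psi_step), ("theta_step", theta_step)):
        if not 0.0 < step <= 180.0:
            raise ParameterError(f"{name} must be in (0, 180], got {step}")
    n_dirs = sum(_ring_phi_count(t, theta_step) for t in _ring_thetas(theta_step))
    return n_dirs * len(_psi_values(psi_step, symmetry))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares proper rotation superposing ``moving`` onto ``fixed``
    after centroid removal.

    Returns ``(R, rmsd)`` with ``R @ (moving - centroid)`` closest to
    ``fixed - centroid`` in the least-squares sense.

    Raises
    ------
    GeometryError
        If the point sets are degenerate (fewer than 3 points, collinear or
        coincident), leaving the rotation underdetermined.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ParameterError("point sets must be (N, 3) arrays of equal shape")
    n = moving.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points for superposition")
    mc = moving - moving.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)
    for pts in (mc, fc):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(1.0, s[0]):
            raise GeometryError("degenerate (collinear or coincident) point set")
    rot, rssd = Rotation.align_vectors(fc, mc)
    return rot.as_matrix(), float(rssd / np.sqrt(n))


def center_vector(body_a: np.ndarray, body_b: np.ndarray) -> np.ndarray:
    """``centroid(body_b) - centroid(body_a)`` in template coordinates (A)."""
    body_a = np.asarray(body_a, dtype=float)
    body_b = np.asarray(body_b, dtype=float)
    if body_a.size == 0 or body_b.size == 0:
        raise ParameterError("point sets must be non-empty")
    return body_b.reshape(-1, 3).mean(axis=0) - body_a.reshape(-1, 3).mean(axis=0)
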