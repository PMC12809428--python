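"""Pose-constrained search for a second body using reference detections.

Given reference detections of body 1 (e.g. the large ribosomal subunit), the
orientation and position of an attached body 2 (e.g. the small-subunit body)
are predicted from a constraint geometry derived from two model states:

* the **rotation axis** (frame z) is the axis of the rotation superposing
  the rotated-state model onto the nonrotated-state model;
* the **roll axis** (frame y) is a second, orthogonal axis;
* the **center offset** ``c`` is the vector from the body-1 center to the
  body-2 center in template coordinates (A).

A candidate with intersubunit rotation ``psi_off`` and roll ``theta_off``
(degrees) has orientation

    R = R_ref . F . Rz(psi_off) . Ry(theta_off) . F^-1

with F the constraint frame; its center is displaced by ``R_ref . c``, whose
in-plane components shift the predicted position and whose beam-axis (+z)
component adds to the particle defocus (positive = more underfocus).

The search proceeds in stages of decreasing angular step (rotation sweep,
roll sweep, joint coarse, joint fine + defocus), carrying the single best
candidate forward; because far fewer comparisons are made than in a full
search, the per-particle detection threshold is much lower at a matched
false-positive budget (default: 1 false positive per 200 particles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ParameterError
from .containers import Micrograph, VolumeGrid
from .filters import CTFParams
from .geometry import (
    axis_angle_to_matrix,
    center_vector,
    euler_to_matrix,
    kabsch,
    matrix_to_axis_angle,
    matrix_to_euler,
)
from .match import MatchResultMaps, ParticleRecord, detection_threshold
from .refine import PatchScorer

__all__ = [
    "ConstraintGeometry",
    "SearchStage",
    "StageSchedule",
    "ConstrainedResult",
    "constraint_from_models",
    "pose_from_reference",
    "run_constrained",
    "classify_rotation",
    "detectable_mass_ratio",
]


@dataclass
class ConstraintGeometry:
    """Constraint frame (columns x, y=roll axis, z=rotation axis) and
    body-1 -> body-2 center offset in template coordinates (A)."""

    frame: np.ndarray
    center_offset: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=float)
        self.center_offset = np.asarray(self.center_offset, dtype=float).reshape(3)
        if self.frame.shape != (3, 3) or abs(np.linalg.det(self.frame) - 1.0) > 1e-8 \
                or np.abs(self.frame @ self.frame.T - np.eye(3)).max() > 1e-8:
            raise ParameterError("frame must be a proper rotation matrix")


def _frame_from_axis(axis: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame with z along ``axis``; y is the
    projection of the global y axis (fallback: x axis) onto the plane."""
    z = np.asarray(axis, dtype=float)
    z = z / np.linalg.norm(z)
    ref = np.array([0.0, 1.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    y = ref - (ref @ z) * z
    y /= np.linalg.norm(y)
    x = np.cross(y, z)
    return np.column_stack([x, y, z])


def constraint_from_models(
    state_a: np.ndarray,
    state_b: np.ndarray,
    body2: np.ndarray,
    body1: np.ndarray,
) -> ConstraintGeometry:
    """Constraint geometry from two conformational states and the two bodies.

    ``state_a``/``state_b`` are matched coordinate sets of the mobile body in
    the two states (e.g. rotated and nonrotated); their superposition
    rotation defines the rotation axis. ``body1``/``body2`` give the center
    offset. Identical states fall back to the z axis.
    """
    rot, _ = kabsch(state_a, state_b)
    aa = matrix_to_axis_angle(rot)
    axis = np.array([0.0, 0.0, 1.0]) if aa.angle < 1e-9 else np.asarray(aa.axis)
    return ConstraintGeometry(
        frame=_frame_from_axis(axis),
        center_offset=center_vector(body1, body2),
    )


def pose_from_reference(
    ref: ParticleRecord,
    geom: ConstraintGeometry,
    psi_off: float,
    theta_off: float,
    pixel_size: float,
) -> tuple[np.ndarray, float, float, float]:
    """Predicted body-2 pose from a body-1 detection.

    Returns ``(R, x, y, defocus)`` with the position in (float) pixels and
    the defocus offset in A (reference defocus plus the beam-axis component
    of the rotated center offset).
    """
    r_ref = euler_to_matrix((ref.phi, ref.theta, ref.psi))
    f = geom.frame
    r_off = axis_angle_to_matrix([0, 0, 1], psi_off) @ axis_angle_to_matrix([0, 1, 0], theta_off)
    r_new = r_ref @ f @ r_off @ f.T
    disp = r_ref @ geom.center_offset
    x = ref.x + disp[0] / pixel_size
    y = ref.y + disp[1] / pixel_size
    defocus = ref.defocus + disp[2]
    return r_new, float(x), float(y), float(defocus)


@dataclass(frozen=True)
class SearchStage:
    """One stage: offset ranges (degrees / A) relative to the current best
    estimate; ``None`` leaves that coordinate fixed."""

    psi: tuple[float, float, float] | None = None       # (lo, hi, step)
    theta: tuple[float, float, float] | None = None
    defocus: tuple[float, float, float] | None = None

    @staticmethod
    def _values(spec: tuple[float, float, float] | None) -> np.ndarray:
        if spec is None:
            return np.array([0.0])
        lo, hi, step = spec
        if step <= 0 or hi < lo:
            raise ParameterError(f"bad stage range {spec}")
        return np.arange(lo, hi + 1e-9, step)

    def psi_values(self) -> np.ndarray:
        return self._values(self.psi)

    def theta_values(self) -> np.ndarray:
        return self._values(self.theta)

    def defocus_values(self) -> np.ndarray:
        return self._values(self.defocus)

    @property
    def cardinality(self) -> int:
        return len(self.psi_values()) * len(self.theta_values()) * len(self.defocus_values())


@dataclass
class StageSchedule:
    """Ordered stages, finest last."""

    stages: list[SearchStage]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ParameterError("schedule must contain at least one stage")

    @property
    def cardinality(self) -> int:
        return sum(s.cardinality for s in self.stages)


def default_schedule() -> StageSchedule:
    """Four-stage schedule: rotation sweep -13..2.5 deg by 1; roll sweep
    -6..4 deg by 1; joint +-5 deg by 0.5; joint +-0.5 deg by 0.1 with a
    defocus search of +-100 A by 20 A."""
    return StageSchedule(stages=[
        SearchStage(psi=(-13.0, 2.5, 1.0)),
        SearchStage(theta=(-6.0, 4.0, 1.0)),
        SearchStage(psi=(-5.0, 5.0, 0.5), theta=(-5.0, 5.0, 0.5)),
        SearchStage(psi=(-0.5, 0.5, 0.1), theta=(-0.5, 0.5, 0.1),
                    defocus=(-100.0, 100.0, 20.0)),
    ])


@dataclass
class ConstrainedResult:
    """Best body-2 candidate for one reference particle."""

    reference_index: int
    micrograph_id: str
    psi_off: float
    theta_off: float
    x: int
    y: int
    defocus: float
    z_score: float
    n_comparisons: int
    threshold: float
    significant: bool
    flag: str = ""


def run_constrained(
    refs: list[ParticleRecord],
    micrograph: Micrograph,
    template2: VolumeGrid,
    ctf: CTFParams,
    geom: ConstraintGeometry,
    schedule: StageSchedule | None = None,
    window: int = 2,
    noise_maps: MatchResultMaps | None = None,
    expected_fp: float = 1.0 / 200.0,
) -> list[ConstrainedResult]:
    """Staged constrained search for body 2 around each reference particle.

    ``noise_maps`` must come from a prior full search of ``template2`` on
    this micrograph: its per-pixel correlation mean/variance standardize the
    constrained scores onto the full-search z scale. Each stage searches the
    scheduled offsets around the current best estimate over a
    ``(2 window + 1)^2`` pixel neighborhood of the predicted position;
    significance uses the particle's own comparison count at the
    ``expected_fp`` per-particle false-positive budget.
    """
    if noise_maps is None:
        raise ParameterError(
            "noise_maps from a prior full search of the body-2 template on this "
            "micrograph are required for the z-score calculation")
    if schedule is None:
        schedule = default_schedule()
    scorer = PatchScorer(micrograph, template2, ctf, noise_maps,
                         position_window=window)
    f = geom.frame
    results: list[ConstrainedResult] = []
    n_window = (2 * window + 1) ** 2
    for i, ref in enumerate(refs):
        r_ref = euler_to_matrix((ref.phi, ref.theta, ref.psi))
        disp = r_ref @ geom.center_offset
        x0 = int(round(ref.x + disp[0] / scorer.px))
        y0 = int(round(ref.y + disp[1] / scorer.px))
        base_def = ref.defocus + disp[2]
        if not scorer.in_bounds(x0, y0):
            results.append(ConstrainedResult(
                reference_index=i, micrograph_id=ref.micrograph_id,
                psi_off=np.nan, theta_off=np.nan, x=x0, y=y0,
                defocus=np.nan, z_score=np.nan, n_comparisons=0,
                threshold=np.nan, significant=False, flag="out_of_bounds"))
            continue
        cur_psi = cur_theta = cur_dfoc = 0.0
        best_z = -np.inf
        best_xy = (x0, y0)
        n_comp = 0
        for stage in schedule.stages:
            psis = cur_psi + stage.psi_values()
            thetas = cur_theta + stage.theta_values()
            dfocs = cur_dfoc + stage.defocus_values()
            pp, tt = np.meshgrid(psis, thetas, indexing="ij")
            pairs = np.column_stack([pp.ravel(), tt.ravel()])
            rots = np.stack([
                r_ref @ f @ axis_angle_to_matrix([0, 0, 1], p)
                @ axis_angle_to_matrix([0, 1, 0], t) @ f.T
                for p, t in pairs
            ])
            z = scorer.score(rots, dfocs + base_def, x0, y0)
            n_comp += len(pairs) * len(dfocs) * n_window
            m, d_idx, dyi, dxi = np.unravel_index(int(np.argmax(z)), z.shape)
            val = float(z[m, d_idx, dyi, dxi])
            if val > best_z:
                best_z = val
                cur_psi, cur_theta = pairs[int(m)]
                cur_dfoc = float(dfocs[int(d_idx)])
                best_xy = (x0 + int(dxi) - window, y0 + int(dyi) - window)
        thr = detection_threshold(n_comp, expected_fp)
        results.append(ConstrainedResult(
            reference_index=i, micrograph_id=ref.micrograph_id,
            psi_off=float(cur_psi), theta_off=float(cur_theta),
            x=best_xy[0], y=best_xy[1], defocus=float(base_def + cur_dfoc),
            z_score=best_z, n_comparisons=n_comp, threshold=thr,
            significant=bool(best_z >= thr)))
    return results


def classify_rotation(
    results: list[ConstrainedResult],
    threshold: float = 4.0,
    bin_width: float = 0.1,
) -> tuple[list[ConstrainedResult], list[ConstrainedResult], pd.DataFrame]:
    """Partition results into nonrotated (|rotation offset| < threshold) and
    rotated (>= threshold) subsets, with a 2D (psi_off, theta_off) histogram
    binned at the final-stage resolution."""
    valid = [r for r in results if not r.flag and np.isfinite(r.psi_off)]
    nonrot = [r for r in valid if abs(r.psi_off) < threshold]
    rot = [r for r in valid if abs(r.psi_off) >= threshold]
    if valid:
        p = np.array([r.psi_off for r in valid])
        t = np.array([r.theta_off for r in valid])
        pb = np.round(p / bin_width) * bin_width
        tb = np.round(t / bin_width) * bin_width
        hist = (pd.DataFrame({"psi_off": pb, "theta_off": tb})
                .value_counts().rename("count").reset_index()
                .sort_values(["psi_off", "theta_off"]).reset_index(drop=True))
    else:
        hist = pd.DataFrame(columns=["psi_off", "theta_off", "count"])
    return nonrot, rot, hist


def detectable_mass_ratio(z_threshold_full: float, z_threshold_constrained: float) -> float:
    """Factor by which the minimum detectable molecular mass shrinks when
    the threshold drops from the full-search to the constrained value; the
    matched-filter SNR scales with the square root of mass, so the ratio is
    the squared threshold ratio."""
    if z_threshold_full <= 0 or z_threshold_constrained <= 0:
        raise ParameterError("thresholds must be positive")
    return (z_threshold_full / z_threshold_constrained) ** 2
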