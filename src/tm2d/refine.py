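"""Local pose/defocus refinement and template pixel-size optimization.

Refinement re-scores candidate poses on the same whitened image and with the
same per-pixel correlation mean/variance normalization as the original
search, so refined z-scores are directly comparable to (and never below)
the input z-scores: the input pose is always in the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import fft as sfft

from ._exceptions import ParameterError
from .containers import Micrograph, VolumeGrid
from .filters import CTFParams, FourierSliceProjector, RadialProfile, ctf_2d
from .geometry import eulers_to_matrices
from .match import MatchResultMaps, ParticleRecord, fp_probability, prepare_whitened_image
from .scattering import SimulationParams, resimulate_at_offset

__all__ = [
    "RefinementConfig",
    "PixelSizeSearch",
    "PatchScorer",
    "refine_particles",
    "optimize_pixel_size",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Coarse-to-fine local search parameters.

    The angular schedule halves the step from ``angular_step_initial`` down
    to ``angular_step_final`` (degrees); at each stage the three Euler angles
    are perturbed on a 5-point grid (+-2 steps) around the current estimate,
    followed by a defocus line search of ``+-defocus_range`` in
    ``defocus_step`` (A). ``position_window`` is the +- pixel range over
    which the peak is re-localized.
    """

    angular_step_initial: float = 0.5
    angular_step_final: float = 0.05
    defocus_range: float = 100.0
    defocus_step: float = 20.0
    position_window: int = 2

    def __post_init__(self) -> None:
        if self.angular_step_final <= 0 or self.angular_step_initial < self.angular_step_final:
            raise ParameterError("need angular_step_initial >= angular_step_final > 0")
        if self.defocus_step <= 0:
            raise ParameterError("defocus_step must be positive")

    def angular_steps(self) -> list[float]:
        steps, s = [], self.angular_step_initial
        while s > self.angular_step_final * (1 + 1e-9):
            steps.append(s)
            s /= 2.0
        steps.append(self.angular_step_final)
        return steps


class PatchScorer:
    """Scores candidate (rotation, defocus) pairs at a fixed image location.

    Templates are filtered (CTF x whitening), zero-meaned and L2-normalized
    exactly as in the full search; correlation values against the whitened
    image are standardized with the per-pixel mean/variance maps of a prior
    full search, so scores are z-values on the same scale.
    """

    def __init__(
        self,
        micrograph: Micrograph,
        template: VolumeGrid,
        ctf: CTFParams,
        noise_maps: MatchResultMaps | None = None,
        whitening: RadialProfile | None = None,
        position_window: int = 2,
    ):
        self.image_w, self.profile = prepare_whitened_image(micrograph, whitening)
        self.projector = FourierSliceProjector(template)
        self.box = template.box_size
        self.ctf = ctf
        self.px = micrograph.pixel_size
        self.window = int(position_window)
        self.whit_box = self.profile.sample((self.box, self.box), self.px, rfft=False)
        self._filter_cache: dict[float, np.ndarray] = {}
        if noise_maps is not None:
            self._mean, self._sd = noise_maps.corr_mean, np.sqrt(
                np.maximum(noise_maps.corr_variance, 1e-12))
        else:
            self._mean = np.zeros(micrograph.shape)
            self._sd = np.ones(micrograph.shape)

    def _filter(self, defocus_offset: float) -> np.ndarray:
        key = round(float(defocus_offset), 6)
        if key not in self._filter_cache:
            self._filter_cache[key] = (
                ctf_2d(self.ctf, (self.box, self.box), key) * self.whit_box
            ).astype(np.float32)
        return self._filter_cache[key]

    def in_bounds(self, x: int, y: int) -> bool:
        """Whether the scoring window around (x, y) fits inside the image."""
        h, w = self.image_w.shape
        half = self.box // 2
        return (
            y - half - self.window >= 0
            and x - half - self.window >= 0
            and y - half + self.box + self.window <= h
            and x - half + self.box + self.window <= w
        )

    def score(
        self,
        rotations: np.ndarray,
        defocus_offsets,
        x: int,
        y: int,
    ) -> np.ndarray:
        """z-scores of the outer product rotations x defocus offsets,
        shape (n_rot, n_defocus, 2w+1, 2w+1); each rotation is projected
        once and every position in the window around (x, y) is evaluated."""
        rotations = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
        defocus_offsets = np.atleast_1d(np.asarray(defocus_offsets, dtype=float))
        box, wdw = self.box, self.window
        half = box // 2
        y0, x0 = y - half - wdw, x - half - wdw
        side = box + 2 * wdw
        patch = self.image_w[y0:y0 + side, x0:x0 + side]
        if patch.shape != (side, side):
            raise ParameterError("candidate window extends beyond the image")

        projs = self.projector.project_many(rotations)          # (R, b, b)
        phat = sfft.fft2(projs.astype(np.float32))
        filters = np.stack([self._filter(d) for d in defocus_offsets])
        tmpl = sfft.ifft2(phat[:, None] * filters[None]).real   # (R, D, b, b)
        tmpl -= tmpl.mean(axis=(-2, -1), keepdims=True)
        nrm = np.sqrt(np.sum(tmpl * tmpl, axis=(-2, -1), keepdims=True))
        nrm[nrm == 0] = 1.0
        tmpl /= nrm

        wins = np.lib.stride_tricks.sliding_window_view(patch, (box, box))
        wmat = wins.reshape(-1, box * box).astype(np.float32)   # (P, box^2)
        n_cand = rotations.shape[0] * defocus_offsets.size
        corr = tmpl.reshape(n_cand, -1) @ wmat.T                # (R*D, P)
        sub_mean = self._mean[y - wdw:y + wdw + 1, x - wdw:x + wdw + 1].ravel()
        sub_sd = self._sd[y - wdw:y + wdw + 1, x - wdw:x + wdw + 1].ravel()
        z = (corr - sub_mean[None, :]) / sub_sd[None, :]
        return z.reshape(rotations.shape[0], defocus_offsets.size,
                         2 * wdw + 1, 2 * wdw + 1)


def _best_candidate(z: np.ndarray) -> tuple[int, int, int, int, float]:
    """(rotation index, defocus index, dy, dx, value) of the maximum of a
    (R, D, P, P) score block; ties resolve to the earliest search index."""
    flat = np.argmax(z)
    m, d, dy, dx = np.unravel_index(flat, z.shape)
    return (int(m), int(d), int(dy) - z.shape[2] // 2, int(dx) - z.shape[3] // 2,
            float(z[m, d, dy, dx]))


def refine_particles(
    records: list[ParticleRecord],
    micrograph: Micrograph,
    template: VolumeGrid,
    ctf: CTFParams,
    config: RefinementConfig = RefinementConfig(),
    noise_maps: MatchResultMaps | None = None,
) -> list[ParticleRecord]:
    """Coarse-to-fine local refinement of pose, defocus and position.

    Each particle's Euler angles are perturbed on successively halved grids
    down to ``angular_step_final``; defocus is line-searched after each
    angular stage; the position is re-localized within ``position_window``
    pixels. Particles whose window leaves the image are returned unchanged
    (flag ``"edge"``).
    """
    scorer = PatchScorer(micrograph, template, ctf, noise_maps,
                         position_window=config.position_window)
    d_offsets = np.arange(-config.defocus_range, config.defocus_range + 1e-9,
                          config.defocus_step)
    out = []
    offsets5 = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    for rec in records:
        if not scorer.in_bounds(rec.x, rec.y):
            out.append(dc_replace(rec, flag="edge"))
            continue
        cur = np.array([rec.phi, rec.theta, rec.psi])
        cur_def = rec.defocus
        x, y = rec.x, rec.y
        # baseline: score of the input pose itself
        z0 = scorer.score(eulers_to_matrices(cur[None]), [cur_def], x, y)
        best_z = float(z0[0, 0, config.position_window, config.position_window])
        for step in config.angular_steps():
            trips = np.array([cur + np.array(d) * step
                              for d in product(offsets5, repeat=3)])
            trips[:, 1] = np.clip(trips[:, 1], 0.0, 180.0)
            z = scorer.score(eulers_to_matrices(trips), [cur_def], x, y)
            m, _, dy, dx, val = _best_candidate(z)
            if val > best_z:
                best_z, cur = val, trips[m]
                x, y = x + dx, y + dy
            # defocus line search at the current angles
            zd = scorer.score(eulers_to_matrices(cur[None]),
                              cur_def + d_offsets, x, y)
            _, d, dy, dx, val = _best_candidate(zd)
            if val > best_z:
                best_z, cur_def = val, cur_def + d_offsets[d]
                x, y = x + dx, y + dy
        out.append(dc_replace(
            rec, x=x, y=y, phi=cur[0] % 360.0, theta=float(cur[1]), psi=cur[2] % 360.0,
            defocus=float(cur_def), z_score=best_z,
            fp_probability=fp_probability(best_z, noise_maps.n_total)
            if noise_maps is not None else rec.fp_probability,
        ))
    return out


# ---------------------------------------------------------------------------
# Pixel-size optimization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PixelSizeSearch:
    """Two-stage pixel-size scan. Ranges/steps in A; the fine scan is
    centered on the coarse optimum. The objective is the mean re-scored z of
    the top N particles (``objective="top_n"``) or of all particles above
    ``z_min`` (``objective="z_above"``); in both cases particles whose input
    z-score is below ``z_min`` are dropped first."""

    coarse_range: float = 0.05
    coarse_step: float = 0.01
    fine_range: float = 0.008
    fine_step: float = 0.001
    objective: str = "top_n"
    top_n: int = 50
    z_min: float = 8.0

    def __post_init__(self) -> None:
        if min(self.coarse_step, self.fine_step) <= 0:
            raise ParameterError("steps must be positive")
        if self.fine_range > self.coarse_step + 1e-12:
            raise ParameterError("fine_range must not exceed coarse_step")
        if self.objective not in ("top_n", "z_above"):
            raise ParameterError("objective must be 'top_n' or 'z_above'")


def _rescore_at_delta(
    delta: float,
    atoms,
    params: SimulationParams,
    records: list[ParticleRecord],
    micrograph: Micrograph,
    ctf: CTFParams,
    noise_maps: MatchResultMaps | None,
    whitening: RadialProfile | None,
) -> np.ndarray:
    """Re-simulate the template at ``pixel_size + delta`` and re-score every
    particle at its fixed position and pose. Positions are held fixed."""
    vol = resimulate_at_offset(atoms, params, delta)
    scorer = PatchScorer(micrograph, vol, ctf, noise_maps, whitening,
                         position_window=0)
    zs = np.empty(len(records))
    for i, rec in enumerate(records):
        rot = eulers_to_matrices(np.array([[rec.phi, rec.theta, rec.psi]]))
        zs[i] = scorer.score(rot, [rec.defocus], rec.x, rec.y)[0, 0, 0, 0]
    return zs


def optimize_pixel_size(
    records: list[ParticleRecord],
    micrograph: Micrograph,
    atoms,
    params: SimulationParams,
    ctf: CTFParams,
    search: PixelSizeSearch = PixelSizeSearch(),
    noise_maps: MatchResultMaps | None = None,
) -> tuple[float, pd.DataFrame, dict[float, np.ndarray]]:
    """Find the template pixel-size offset maximizing the z-score objective.

    Returns ``(best_delta, table, per_delta_scores)`` where ``table`` has one
    row per evaluated delta (delta, objective, n_peaks, stage) and
    ``per_delta_scores`` maps each delta to the per-particle re-scored z
    values (for export as individual CSV files).
    """
    if len(records) == 0:
        raise ParameterError("need at least one particle record")
    kept = [r for r in records if r.z_score >= search.z_min] or None
    if kept is None:
        raise ParameterError(
            f"no particles with z >= {search.z_min}; objective undefined")

    def objective(zs: np.ndarray) -> tuple[float, int]:
        if search.objective == "top_n":
            top = np.sort(zs)[::-1][: search.top_n]
            return float(top.mean()), len(top)
        above = zs[zs >= search.z_min]
        if len(above) == 0:
            return float("-inf"), 0
        return float(above.mean()), len(above)

    rows, scores = [], {}

    def scan(deltas, stage):
        for d in deltas:
            d = round(float(d), 9)
            if d in scores or params.pixel_size + d <= 0:
                continue
            zs = _rescore_at_delta(d, atoms, params, kept, micrograph, ctf,
                                   noise_maps, None)
            scores[d] = zs
            obj, npk = objective(zs)
            rows.append({"delta": d, "objective": obj, "n_peaks": npk, "stage": stage})

    scan(np.arange(-search.coarse_range, search.coarse_range + 1e-9,
                   search.coarse_step), "coarse")
    coarse_best = max((r for r in rows if r["stage"] == "coarse"),
                      key=lambda r: r["objective"])["delta"]
    scan(coarse_best + np.arange(-search.fine_range, search.fine_range + 1e-9,
                                 search.fine_step), "fine")
    table = pd.DataFrame(rows).sort_values("delta").reset_index(drop=True)
    best = float(table.loc[table["objective"].idxmax(), "delta"])
    return best, table, scores
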