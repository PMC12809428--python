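"""Shared fixtures: templates, CTF, constraint geometry and planted fields.

Two template regimes are used throughout the suite:

* the *default* blob (B factors 20-60 A^2, radius 20 A) emulates a generic
  globular particle and is used for detection and null-calibration tests;
* the *sharp* blobs (B factors 5-20 A^2, larger radius) emulate the
  high-resolution template regime in which fine angular sampling pays off,
  and are used for refinement, pixel-size and constrained-search tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tm2d import (
    CTFParams,
    ConstraintGeometry,
    SearchSpace,
    defocus_planes,
    make_blob_atoms,
    make_micrograph,
    run_match,
    sample_positions,
    simulate_volume,
    uniform_grid,
)
from tm2d.constrained import _frame_from_axis
from tm2d.scattering import SimulationParams


@pytest.fixture(scope="session")
def ctf():
    return CTFParams(voltage=300.0, cs=2.7, amplitude_contrast=0.07,
                     defocus_u=5000.0, defocus_v=5000.0, pixel_size=1.0)


@pytest.fixture(scope="session")
def default_atoms():
    return make_blob_atoms(800, 20.0, seed=11)


@pytest.fixture(scope="session")
def default_template(default_atoms):
    return simulate_volume(default_atoms, SimulationParams(box_size=64, pixel_size=1.0))


@pytest.fixture(scope="session")
def sharp_atoms():
    return make_blob_atoms(2000, 26.0, seed=21, b_range=(5.0, 20.0))


@pytest.fixture(scope="session")
def sharp_template(sharp_atoms):
    return simulate_volume(sharp_atoms, SimulationParams(box_size=64, pixel_size=1.0))


@pytest.fixture(scope="session")
def sharp_template2():
    atoms = make_blob_atoms(900, 18.0, seed=22, b_range=(5.0, 20.0))
    return simulate_volume(atoms, SimulationParams(box_size=48, pixel_size=1.0))


@pytest.fixture(scope="session")
def constraint_geom():
    axis = np.array([0.3, 0.5, 0.81])
    return ConstraintGeometry(frame=_frame_from_axis(axis / np.linalg.norm(axis)),
                              center_offset=np.array([30.0, 10.0, 50.0]))


@pytest.fixture(scope="session")
def coarse_space():
    return SearchSpace(grid=uniform_grid(15.0, 15.0),
                       defocus_offsets=defocus_planes(-200.0, 200.0, 200.0))


@pytest.fixture(scope="session")
def sharp_planted(sharp_template, ctf):
    """High-signal sparse field in the sharp-template regime used for
    convergence experiments: angular precision scales as the template's
    orientation-decorrelation angle divided by z, so sub-0.1-degree recovery
    requires strong detections (z ~ 100, as for large well-ordered
    complexes)."""
    rng = np.random.default_rng(3)
    pos = sample_positions((448, 448), 64, 4, 120.0, rng)
    truths = [(int(x), int(y), rng.uniform(0, 360), rng.uniform(60, 120),
               rng.uniform(0, 360), float(rng.choice([-60.0, 0.0, 60.0])))
              for x, y in pos]
    poses = [{"x": t[0], "y": t[1], "phi": t[2], "theta": t[3], "psi": t[4],
              "defocus": t[5]} for t in truths]
    field = make_micrograph(sharp_template, poses, ctf, noise_sigma=1.0,
                            seed=4, shape=(448, 448), snr=150.0)
    return field, truths


@pytest.fixture(scope="session")
def mismatched_field(sharp_template, ctf):
    """Micrograph generated from the template at 1.00 A/px; analyses that
    nominally believe a 1.02 A model pixel size should recover -0.02 A."""
    rng = np.random.default_rng(9)
    pos = sample_positions((448, 448), 64, 12, 80.0, rng)
    truths = [(int(x), int(y), rng.uniform(0, 360), rng.uniform(30, 150),
               rng.uniform(0, 360)) for x, y in pos]
    poses = [{"x": t[0], "y": t[1], "phi": t[2], "theta": t[3], "psi": t[4],
              "defocus": 0.0} for t in truths]
    field = make_micrograph(sharp_template, poses, ctf, noise_sigma=1.0,
                            seed=10, shape=(448, 448), snr=15.0)
    return field, truths


@pytest.fixture(scope="session")
def planted_field(default_template, ctf, coarse_space):
    """320x320 micrograph with 20 particles at generator-default SNR, planted
    at orientation-grid poses, plus its full coarse search."""
    grid = coarse_space.grid
    rng = np.random.default_rng(7)
    pos = sample_positions((320, 320), 64, 20, 52.0, rng)
    gi = rng.choice(len(grid), 20, replace=False)
    poses = [
        {"x": int(x), "y": int(y),
         "phi": grid.orientations[g, 0], "theta": grid.orientations[g, 1],
         "psi": grid.orientations[g, 2], "defocus": 0.0}
        for (x, y), g in zip(pos, gi)
    ]
    field = make_micrograph(default_template, poses, ctf, noise_sigma=1.0,
                            seed=8, shape=(320, 320), snr=15.0)
    maps = run_match(field.micrograph, default_template, ctf, coarse_space)
    return field, maps
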