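"""In-memory containers for volumes and micrographs.

Axis conventions used throughout the package:

* 3D volumes are indexed ``[z, y, x]`` with the beam along +z.
* 2D images are indexed ``[y, x]``; particle positions are reported as
  0-based ``(x, y)`` with x the fast axis.
* Pixel sizes are in angstroms per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ParameterError


@dataclass
class VolumeGrid:
    """Cubic 3D real-valued scattering volume.

    Parameters
    ----------
    data : ndarray, shape (N, N, N)
        Real-valued scattering potential, indexed ``[z, y, x]``.
    pixel_size : float
        Voxel edge length in angstroms.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ParameterError(f"volume must be cubic, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("volume contains non-finite values")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def box_size(self) -> int:
        return self.data.shape[0]


@dataclass
class Micrograph:
    """2D real-valued image with its pixel size.

    ``data`` is indexed ``[y, x]``.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ParameterError(f"micrograph must be 2D, got shape {self.data.shape}")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape
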