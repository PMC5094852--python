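"""Physical voxel geometry for anisotropic EM volumes.

FIB/SEM stacks have finer lateral than axial sampling (the milling step sets
the z pitch).  All physical lengths in this package are nanometres; arrays are
indexed ``(z, y, x)`` and a voxel at index ``(k, j, i)`` has its centre at
``(k*dz, j*dy, i*dx)`` nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import require


@dataclass(frozen=True)
class VoxelGeometry:
    """Edge lengths of one voxel in nanometres.

    Anisotropy is permitted and expected: the reference FIB/SEM geometry is
    6.7 x 6.7 nm laterally with a 20 nm milling pitch.
    """

    dx_nm: float
    dy_nm: float
    dz_nm: float

    def __post_init__(self) -> None:
        require(
            self.dx_nm > 0 and self.dy_nm > 0 and self.dz_nm > 0,
            "voxel edge lengths must be strictly positive",
        )

    @property
    def spacing_zyx(self) -> np.ndarray:
        """Per-axis pitch in array order ``(z, y, x)``."""
        return np.array([self.dz_nm, self.dy_nm, self.dx_nm], dtype=float)

    @property
    def voxel_volume_nm3(self) -> float:
        return self.dx_nm * self.dy_nm * self.dz_nm

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_volume_nm3 * 1e-9

    def radius_voxels(self, radius_nm: float) -> tuple[int, int, int]:
        """Physical radius converted to whole-voxel radii per (z, y, x) axis."""
        return tuple(int(round(radius_nm / p)) for p in self.spacing_zyx)


#: The FIB/SEM acquisition geometry the analysis defaults assume.
REFERENCE_GEOMETRY = VoxelGeometry(dx_nm=6.7, dy_nm=6.7, dz_nm=20.0)
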