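"""Voxel grid geometry shared by all modules.

Array axis convention throughout the package: volumes are indexed
``[x, z, y]`` where x is the lateral axis of the imaging plane, z is depth
(illumination travels toward increasing z) and y is the scan direction.
A single imaging-plane slice is the 2-D array ``vol[:, :, iy]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default grid: 64 lateral x 47 depth x 62 scan voxels at 0.6 mm spacing
DEFAULT_DIMS = (64, 47, 62)
DEFAULT_SPACING_MM = 0.6


@dataclass(frozen=True)
class GridSpec:
    """Regular isotropic voxel grid.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along (x = lateral, z = depth, y = scan).
    spacing_mm : float
        Isotropic voxel edge length in millimetres.
    """

    dims: tuple[int, int, int] = DEFAULT_DIMS
    spacing_mm: float = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all grid dims must be >= 1, got {self.dims}")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def nx(self) -> int:
        return self.dims[0]

    @property
    def nz(self) -> int:
        return self.dims[1]

    @property
    def ny(self) -> int:
        return self.dims[2]

    @property
    def n_plane(self) -> int:
        """Number of voxels in one imaging-plane slice (x * z)."""
        return self.nx * self.nz

    @property
    def spacing_cm(self) -> float:
        return self.spacing_mm / 10.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def plane_shape(self) -> tuple[int, int]:
        return (self.nx, self.nz)

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coordinate arrays (1-D, mm) of voxel centers along x, z, y."""
        return tuple(
            (np.arange(n) + 0.5) * self.spacing_mm for n in self.dims
        )

    def plane_flat_index(self, ix, iz):
        """Flatten (ix, iz) plane coordinates row-major (x-major)."""
        return np.asarray(ix) * self.nz + np.asarray(iz)

    def plane_unflat_index(self, flat):
        flat = np.asarray(flat)
        return flat // self.nz, flat % self.nz

    def equidistant_slices(self, n: int = 5) -> np.ndarray:
        """Scan-axis indices of ``n`` equidistant slices, ends included."""
        return np.round(np.linspace(0, self.ny - 1, n)).astype(int)
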