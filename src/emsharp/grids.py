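"""Real-space voxel grids, Fourier volumes and MRC/CCP4 map I/O.

Conventions
-----------
* ``VoxelGrid.values[ix, iy, iz]`` is the potential at Cartesian position
  ``origin + (ix, iy, iz) * voxel_size`` (voxel centres; x is numpy axis 0).
* Spatial frequency is ``s = 1/d`` in 1/Å (the modulus of the frequency
  vector), so a B-factor envelope reads ``exp(-B * s**2 / 4)``.
* Forward transforms use numpy's sign convention, i.e. a point scatterer at
  ``r`` contributes ``exp(-2*pi*1j * s_vec @ r)`` to ``F(s_vec)``.

Only isotropic (cubic) voxels are supported; maps are written as MRC2014
mode-2 (float32) with the origin stored in header words 50-52.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "VoxelGrid",
    "FourierVolume",
    "read_map",
    "write_map",
    "fourier_transform",
    "inverse_fourier_transform",
    "frequency_grid",
]


@dataclass
class VoxelGrid:
    """A real-valued density/potential on a regular cubic-voxel grid."""

    values: np.ndarray          # 3-D float array, indexed [ix, iy, iz]
    voxel_size: float           # Å, isotropic
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # Å

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid.values must be a 3-D array")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if min(self.values.shape) < 8:
            raise ValueError("grids must have at least 8 voxels per axis")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def box_edges(self) -> np.ndarray:
        """Physical edge lengths (Å) of the grid box."""
        return np.array(self.values.shape) * self.voxel_size

    def voxel_volume(self) -> float:
        return float(self.voxel_size**3)

    def copy(self, values: np.ndarray | None = None) -> "VoxelGrid":
        v = self.values.copy() if values is None else values
        return VoxelGrid(v, self.voxel_size, self.origin.copy())

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cartesian coordinates (Å) of voxel centres along each axis."""
        return tuple(
            self.origin[k] + np.arange(self.values.shape[k]) * self.voxel_size
            for k in range(3)
        )


@dataclass
class FourierVolume:
    """Complex Fourier coefficients of a :class:`VoxelGrid`.

    Stored in half-spectrum (rfft) layout: the last axis holds only
    non-negative frequencies; Hermitian symmetry of real maps is implicit.
    """

    coefficients: np.ndarray    # complex, shape (nx, ny, nz//2 + 1)
    shape: tuple[int, int, int]  # real-space dims
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def frequency_grid(self) -> np.ndarray:
        """Modulus ``s = |s_vec|`` in 1/Å at every stored coefficient."""
        return frequency_grid(self.shape, self.voxel_size)

    def frequency_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        d = self.voxel_size
        return (
            np.fft.fftfreq(nx, d=d),
            np.fft.fftfreq(ny, d=d),
            np.fft.rfftfreq(nz, d=d),
        )

    def copy(self, coefficients: np.ndarray | None = None) -> "FourierVolume":
        c = self.coefficients.copy() if coefficients is None else coefficients
        return FourierVolume(c, self.shape, self.voxel_size, self.origin.copy())


def frequency_grid(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """|s| in 1/Å on the rfft layout for a real grid of ``shape``."""
    sx = np.fft.fftfreq(shape[0], d=voxel_size)
    sy = np.fft.fftfreq(shape[1], d=voxel_size)
    sz = np.fft.rfftfreq(shape[2], d=voxel_size)
    return np.sqrt(
        sx[:, None, None] ** 2 + sy[None, :, None] ** 2 + sz[None, None, :] ** 2
    )


def fourier_transform(grid: VoxelGrid) -> FourierVolume:
    """Forward FFT scaled so coefficients are structure-factor-like.

    The DC term equals ``sum(values) * voxel_volume``, i.e. the total
    scattering mass, matching the continuous transform of the density.
    """
    coeff = np.fft.rfftn(grid.values) * grid.voxel_volume()
    return FourierVolume(coeff, grid.values.shape, grid.voxel_size, grid.origin.copy())


def inverse_fourier_transform(fv: FourierVolume) -> VoxelGrid:
    values = np.fft.irfftn(fv.coefficients, s=fv.shape,
                           axes=(0, 1, 2)) / (fv.voxel_size**3)
    return VoxelGrid(values, fv.voxel_size, fv.origin.copy())


def read_map(path: str | os.PathLike) -> VoxelGrid:
    """Read an MRC/CCP4 map (mode 2) into a :class:`VoxelGrid`.

    Axes are normalised to the canonical X, Y, Z order regardless of the
    file's MAPC/MAPR/MAPS permutation. Anisotropic voxels are rejected.
    """
    m = gemmi.read_ccp4_map(str(path), setup=True)
    if m.header_i32(4) != 2:
        raise ValueError(
            f"unsupported MRC mode {m.header_i32(4)} in {path}; only mode 2 "
            "(float32) maps are supported"
        )
    spacing = np.array(m.grid.spacing)
    if not np.allclose(spacing, spacing[0], rtol=1e-4):
        raise ValueError(
            f"anisotropic voxels {tuple(spacing)} in {path} are unsupported"
        )
    values = np.array(m.grid, copy=True)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    # honour NCSTART/NRSTART/NSSTART when ORIGIN words are zero (CCP4 style)
    if np.all(origin == 0.0):
        start = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = start * spacing[0]
    return VoxelGrid(values, float(spacing[0]), origin)


def write_map(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a :class:`VoxelGrid` as a standard MRC2014 mode-2 map."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    edges = grid.box_edges
    m.grid.unit_cell = gemmi.UnitCell(edges[0], edges[1], edges[2], 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))
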