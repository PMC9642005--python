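"""Simulation of electrostatic potential maps from atomic models.

Structure factors are evaluated as the exact B-weighted sum

    F(s_vec) = sum_j occ_j * f_j(s) * exp(-B_j s^2 / 4) * exp(-2 pi i s_vec . r_j)

with f_j the element's electron scattering factor and s = |s_vec| = 1/d.
Because each atom is an analytic sum of Gaussians, evaluating the sum
directly in Fourier space is alias-free; the optional ``b_add`` blur /
``exp(+B_add s^2/4)`` unblur round-trip mirrors the conventional real-space
rasterisation workflow and is retained for compatibility (it is an exact
no-op in this evaluator up to floating-point error, by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formfactors import FormFactorTable, default_table
from .grids import FourierVolume, VoxelGrid, inverse_fourier_transform
from .models import AtomicModel

__all__ = ["SimulationConfig", "structure_factors", "model_to_map",
           "apply_b_factor"]


@dataclass
class SimulationConfig:
    """Grid and blur settings for map simulation.

    Parameters
    ----------
    box_edge : float
        Cubic box edge in Å.
    voxel_size : float
        Isotropic voxel size in Å.
    b_add : float
        Extra isotropic displacement (Å²) added to every atom during
        structure-factor evaluation and removed again by multiplying each
        coefficient with ``exp(+B_add s^2/4)``. Guards against sampling
        error when rasterising sharp (zero-B) atoms.
    resolution_limit : float or None
        Optional band limit d_min in Å: coefficients with 1/s < d_min are
        zeroed.
    """

    box_edge: float = 64.0
    voxel_size: float = 1.0
    b_add: float = 0.0
    resolution_limit: float | None = None

    def __post_init__(self) -> None:
        if self.b_add < 0:
            raise ValueError("b_add must be >= 0")
        if self.resolution_limit is not None and \
                self.voxel_size > self.resolution_limit / 2:
            raise ValueError(
                "voxel_size must be <= resolution_limit/2 (Nyquist)")

    @property
    def n_voxels(self) -> int:
        n = int(round(self.box_edge / self.voxel_size))
        return n + (n % 2)  # even grids keep the Nyquist plane unambiguous


def _grid_shape(config: SimulationConfig) -> tuple[int, int, int]:
    n = config.n_voxels
    return (n, n, n)


def structure_factors(model: AtomicModel, config: SimulationConfig,
                      table: FormFactorTable | None = None,
                      origin: np.ndarray | None = None) -> FourierVolume:
    """Exact B-weighted structure-factor sum on the config's Fourier grid.

    Atom positions are taken relative to ``origin`` (defaults to a corner
    such that the model centroid sits at the box centre). Atoms falling
    outside the box raise, since the FFT grid would wrap them around.
    """
    if table is None:
        table = default_table()
    missing = sorted({e for e in model.elements if e not in table})
    if missing:
        raise KeyError(f"untabulated element(s): {', '.join(missing)}")

    shape = _grid_shape(config)
    vox = config.voxel_size
    if origin is None:
        origin = model.centroid() - 0.5 * np.array(shape) * vox
    origin = np.asarray(origin, dtype=float)

    rel = model.positions - origin
    if np.any(rel < 0) or np.any(rel >= np.array(shape) * vox):
        raise ValueError(
            "model extends outside the simulation box (no periodic wrap); "
            "increase box_edge or supply an origin")

    sx = np.fft.fftfreq(shape[0], d=vox)
    sy = np.fft.fftfreq(shape[1], d=vox)
    sz = np.fft.rfftfreq(shape[2], d=vox)
    s2 = (sx[:, None, None] ** 2 + sy[None, :, None] ** 2
          + sz[None, None, :] ** 2)

    coeff = np.zeros(s2.shape, dtype=complex)
    b = model.b_factors + config.b_add
    occ = model.occupancies
    elements = np.array(model.elements)

    # group atoms by (element, B) so the radial envelope is computed once
    for el in np.unique(elements):
        a_coef, b_coef = table.coefficients(el)
        sel_el = elements == el
        for bj in np.unique(b[sel_el]):
            sel = sel_el & (b == bj)
            # f(s) * exp(-B s^2/4) as a single Gaussian sum
            envelope = np.sum(
                a_coef * np.exp(-(b_coef + bj) * s2[..., None] / 4.0), axis=-1)
            phase_sum = np.zeros(s2.shape, dtype=complex)
            for r, o in zip(rel[sel], occ[sel]):
                ex = np.exp(-2j * np.pi * sx * r[0])
                ey = np.exp(-2j * np.pi * sy * r[1])
                ez = np.exp(-2j * np.pi * sz * r[2])
                phase_sum += o * np.einsum("i,j,k->ijk", ex, ey, ez)
            coeff += envelope * phase_sum

    if config.resolution_limit is not None:
        coeff[s2 > (1.0 / config.resolution_limit) ** 2] = 0.0
    return FourierVolume(coeff, shape, vox, origin)


def model_to_map(model: AtomicModel, config: SimulationConfig,
                 table: FormFactorTable | None = None,
                 origin: np.ndarray | None = None) -> VoxelGrid:
    """Simulate the electrostatic potential map of a model.

    When ``config.b_add > 0`` the atoms are blurred by B_add during
    evaluation and the resulting coefficients are multiplied by
    ``exp(+B_add s^2/4)``, so the returned map carries no net extra blur.
    """
    fv = structure_factors(model, config, table=table, origin=origin)
    if config.b_add > 0:
        fv = apply_b_factor(fv, -config.b_add)
    return inverse_fourier_transform(fv)


def apply_b_factor(obj: VoxelGrid | FourierVolume, b: float):
    """Multiply every Fourier coefficient by ``exp(-b s^2/4)``.

    ``b > 0`` blurs, ``b < 0`` sharpens; the operation composes additively.
    Accepts and returns either a real map or a Fourier volume.
    """
    if isinstance(obj, VoxelGrid):
        from .grids import fourier_transform
        fv = fourier_transform(obj)
        return inverse_fourier_transform(apply_b_factor(fv, b))
    s2 = obj.frequency_grid**2
    return obj.copy(obj.coefficients * np.exp(-b * s2 / 4.0))
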