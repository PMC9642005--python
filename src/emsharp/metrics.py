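"""Map-comparison metrics: Fourier shell correlation and real-space
correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import VoxelGrid, fourier_transform
from .profiles import shell_bins

__all__ = ["FSCCurve", "fsc", "rscc"]


@dataclass
class FSCCurve:
    frequencies: np.ndarray   # shell centres, 1/Å
    correlation: np.ndarray   # per-shell normalized correlation; NaN if the
                              # shell has zero power in either map
    counts: np.ndarray        # Fourier voxels per shell


def fsc(map_a: VoxelGrid, map_b: VoxelGrid, n_shells: int | None = None,
        mask: VoxelGrid | None = None) -> FSCCurve:
    """Fourier shell correlation between two maps on identical grids.

    Per shell: Re<F_a conj(F_b)> / sqrt(<|F_a|^2><|F_b|^2>). An optional
    mask is applied multiplicatively to both maps (note: no correction for
    masking-induced correlation is attempted).
    """
    if map_a.values.shape != map_b.values.shape or \
            not np.isclose(map_a.voxel_size, map_b.voxel_size):
        raise ValueError("fsc requires maps on identical grids")
    va, vb = map_a.values, map_b.values
    if mask is not None:
        if mask.values.shape != va.shape:
            raise ValueError("mask grid does not match the maps")
        va = va * mask.values
        vb = vb * mask.values
    fa = fourier_transform(map_a.copy(values=va)).coefficients
    fb = fourier_transform(map_b.copy(values=vb)).coefficients
    index, weights, centres = shell_bins(map_a.values.shape,
                                         map_a.voxel_size, n_shells)
    idx = index.ravel()
    w = weights.ravel()
    n = len(centres)
    cross = np.bincount(idx, weights=w * (fa * np.conj(fb)).real.ravel(),
                        minlength=n)
    pa = np.bincount(idx, weights=w * (np.abs(fa) ** 2).ravel(), minlength=n)
    pb = np.bincount(idx, weights=w * (np.abs(fb) ** 2).ravel(), minlength=n)
    wsum = np.bincount(idx, weights=w, minlength=n)
    s_nyq = 1.0 / (2.0 * map_a.voxel_size)
    keep = (wsum > 0) & (centres <= s_nyq * (1 + 1e-9))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cross / np.sqrt(pa * pb)
    corr[(pa == 0) | (pb == 0)] = np.nan
    return FSCCurve(centres[keep], corr[keep], wsum[keep])


def rscc(map_a: VoxelGrid, map_b: VoxelGrid,
         mask: VoxelGrid | None = None) -> float:
    """Pearson correlation of voxel values, optionally over mask > 0.5."""
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("rscc requires maps on identical grids")
    a = map_a.values.ravel()
    b = map_b.values.ravel()
    if mask is not None:
        sel = mask.values.ravel() > 0.5
        if not np.any(sel):
            raise ValueError("mask has no voxels above 0.5")
        a, b = a[sel], b[sel]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant map")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))
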