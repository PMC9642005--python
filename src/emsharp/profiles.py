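"""Radial amplitude spectra, Wilson/Guinier B-factor fits, profile ensembles
and B-factor matching of profiles.

The radial profile of a map is the spherically averaged Fourier amplitude
|F(s)| per frequency shell, the one-dimensional "texture spectrum" of a
macromolecule. Beyond ~10 Å the spectrum of a protein behaves like that of
uniformly random independent atoms (the Wilson range) and ln|F| is close to
linear in s^2 with slope -B/4 — the basis of all B estimation here.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import FourierVolume, VoxelGrid, fourier_transform

__all__ = [
    "RadialProfile", "WilsonFit", "ProfileEnsemble",
    "radial_profile", "profile_from_fourier", "wilson_fit",
    "average_profiles", "match_profile_b",
    "write_profile", "read_profile",
    "DEFAULT_WILSON_RANGE", "DEFAULT_DEBYE_BAND",
]

#: default Wilson fit window in d-spacing (Å): 10 Å out to Nyquist
DEFAULT_WILSON_RANGE = (10.0, None)
#: secondary-structure (Debye) modulation band excluded from Wilson fits, Å
DEFAULT_DEBYE_BAND = (6.5, 3.5)


@dataclass
class RadialProfile:
    """Spherically averaged Fourier amplitudes on shells of width 1/box."""

    frequencies: np.ndarray    # shell centres, s in 1/Å, increasing
    amplitudes: np.ndarray     # mean |F| per shell, >= 0
    counts: np.ndarray = None  # Fourier voxels per shell

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.counts is None:
            self.counts = np.ones_like(self.frequencies)
        self.counts = np.asarray(self.counts)
        if len(self.frequencies) != len(self.amplitudes):
            raise ValueError("frequencies and amplitudes must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def d_spacings(self) -> np.ndarray:
        """Resolution d = 1/s in Å (inf at the origin shell)."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.frequencies

    def resample(self, frequencies: np.ndarray) -> "RadialProfile":
        """Linear interpolation onto a new frequency axis (no extrapolation)."""
        frequencies = np.asarray(frequencies, dtype=float)
        if frequencies.min() < self.frequencies.min() - 1e-12 or \
                frequencies.max() > self.frequencies.max() + 1e-12:
            raise ValueError("resampling axis extends beyond the profile range")
        amp = np.interp(frequencies, self.frequencies, self.amplitudes)
        return RadialProfile(frequencies, amp)

    def scaled(self, factor) -> "RadialProfile":
        return RadialProfile(self.frequencies.copy(),
                             self.amplitudes * factor, self.counts.copy())


@dataclass
class WilsonFit:
    """Least-squares line on (s^2, ln|F|) over the Wilson range."""

    slope: float          # d ln|F| / d s^2
    intercept: float
    b_wilson: float       # = -4 * slope, Å²
    r_squared: float
    fit_range: tuple      # (s_min, s_max) actually used, 1/Å
    n_points: int = 0


@dataclass
class ProfileEnsemble:
    """Mean ± sigma amplitude profile over a set of structures."""

    frequencies: np.ndarray
    mean: np.ndarray
    sigma: np.ndarray
    n_members: int
    label: str = "mixed"   # alpha | beta | dna | rna | mixed

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("sigma must be >= 0")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")

    def mean_profile(self) -> RadialProfile:
        return RadialProfile(np.asarray(self.frequencies, float).copy(),
                             np.asarray(self.mean, float).copy())


# ---------------------------------------------------------------------------
# shell binning

def shell_bins(shape, voxel_size: float, n_shells: int | None = None):
    """Shell index per rfft-layout voxel plus Hermitian weights.

    Returns (index, weights, centres): shells are centred at k*ds with
    ds = s_nyquist / (n_shells - 1); weights count the full-FFT multiplicity
    of each stored coefficient so shell statistics match a full transform.
    ``centres`` extends beyond Nyquist to cover the corner voxels of the
    Fourier cube, which live at s up to sqrt(3) * s_nyquist; callers that
    want a spherical profile truncate at Nyquist.
    """
    box = min(shape) * voxel_size
    s_nyq = 1.0 / (2.0 * voxel_size)
    ds_native = 1.0 / box
    max_shells = int(np.floor(s_nyq / ds_native)) + 1
    if n_shells is None:
        n_shells = max_shells
    elif n_shells > max_shells:
        raise ValueError(
            f"n_shells={n_shells} finer than the Fourier sampling "
            f"(max {max_shells} for this grid)")
    ds = s_nyq / (n_shells - 1)
    sx = np.fft.fftfreq(shape[0], d=voxel_size)
    sy = np.fft.fftfreq(shape[1], d=voxel_size)
    sz = np.fft.rfftfreq(shape[2], d=voxel_size)
    s = np.sqrt(sx[:, None, None] ** 2 + sy[None, :, None] ** 2
                + sz[None, None, :] ** 2)
    index = np.rint(s / ds).astype(np.intp)
    w = np.full(len(sz), 2.0)
    w[0] = 1.0
    if shape[2] % 2 == 0:
        w[-1] = 1.0
    weights = np.broadcast_to(w, index.shape)
    centres = np.arange(index.max() + 1) * ds
    return index, weights, centres


def profile_from_fourier(fv: FourierVolume, n_shells: int | None = None,
                         keep_beyond_nyquist: bool = False) -> RadialProfile:
    index, weights, centres = shell_bins(fv.shape, fv.voxel_size, n_shells)
    amp = np.abs(fv.coefficients)
    wsum = np.bincount(index.ravel(), weights=weights.ravel(),
                       minlength=len(centres))
    asum = np.bincount(index.ravel(), weights=(weights * amp).ravel(),
                       minlength=len(centres))
    keep = wsum > 0
    if not keep_beyond_nyquist:
        # corner shells of the Fourier cube have poor angular coverage
        s_nyq = 1.0 / (2.0 * fv.voxel_size)
        keep &= centres <= s_nyq * (1.0 + 1e-9)
    return RadialProfile(centres[keep], asum[keep] / wsum[keep], wsum[keep])


def radial_profile(grid: VoxelGrid, n_shells: int | None = None) -> RadialProfile:
    """Spherically averaged amplitude spectrum of a map.

    Shell width defaults to one Fourier voxel (1/box edge); empty shells
    are dropped.
    """
    if not np.any(grid.values):
        raise ValueError("cannot compute a radial profile of an empty map")
    return profile_from_fourier(fourier_transform(grid), n_shells)


# ---------------------------------------------------------------------------
# Wilson / Guinier fitting

def _wilson_mask(freqs: np.ndarray, fit_range, exclude_band) -> np.ndarray:
    d_min_fit, d_max_s = fit_range
    s_lo = 0.0 if d_min_fit is None else 1.0 / d_min_fit
    s_hi = np.inf if d_max_s is None else d_max_s
    mask = (freqs >= s_lo) & (freqs <= s_hi) & (freqs > 0)
    if exclude_band is not None:
        d_hi, d_lo = exclude_band
        mask &= ~((freqs > 1.0 / d_hi) & (freqs < 1.0 / d_lo))
    return mask


def wilson_fit(profile: RadialProfile,
               fit_range: tuple = DEFAULT_WILSON_RANGE,
               exclude_band: tuple | None = DEFAULT_DEBYE_BAND) -> WilsonFit:
    """Fit ln|F| vs s^2 over the Wilson range; B = -4 * slope.

    ``fit_range`` is (d_start, s_max): the fit spans frequencies from
    1/d_start (default 10 Å) up to s_max (default: all available shells).
    ``exclude_band`` removes the secondary-structure modulation band,
    given as (d_high, d_low) in Å, from the fit.
    """
    mask = _wilson_mask(profile.frequencies, fit_range, exclude_band)
    if mask.sum() < 5:
        raise ValueError(
            f"only {int(mask.sum())} shells inside the fit range; >= 5 required")
    amp = profile.amplitudes[mask]
    if np.any(amp <= 0):
        raise ValueError("nonpositive amplitudes inside the Wilson fit range")
    s2 = profile.frequencies[mask] ** 2
    y = np.log(amp)
    res = stats.linregress(s2, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0   # constant data, perfectly fit by a flat line
    else:
        resid = y - (res.intercept + res.slope * s2)
        r2 = 1.0 - float(resid @ resid) / ss_tot
    return WilsonFit(
        slope=float(res.slope), intercept=float(res.intercept),
        b_wilson=float(-4.0 * res.slope),
        r_squared=r2,
        fit_range=(float(np.sqrt(s2.min())), float(np.sqrt(s2.max()))),
        n_points=int(mask.sum()),
    )


def match_profile_b(profile: RadialProfile, b_target: float,
                    fit_range: tuple = DEFAULT_WILSON_RANGE,
                    exclude_band: tuple | None = DEFAULT_DEBYE_BAND
                    ) -> RadialProfile:
    """Rescale a profile's Wilson fall-off to a target B factor.

    Amplitudes are multiplied by ``exp(-(b_target - b_current) s^2/4)``
    where b_current is the profile's own fitted Wilson B.
    """
    fit = wilson_fit(profile, fit_range, exclude_band)
    db = b_target - fit.b_wilson
    factor = np.exp(-db * profile.frequencies**2 / 4.0)
    return RadialProfile(profile.frequencies.copy(),
                         profile.amplitudes * factor, profile.counts.copy())


def debye_peak(profile: RadialProfile, band: tuple = (6.0, 3.0),
               detrend: bool = True,
               fit_range: tuple = DEFAULT_WILSON_RANGE,
               exclude_band: tuple | None = DEFAULT_DEBYE_BAND):
    """Locate the secondary-structure peak in the Wilson range.

    Returns ``(d_peak, prominence)``: the resolution (Å) of the local
    maximum of the (optionally Wilson-detrended, i.e. normalised) log
    amplitude within ``band = (d_high, d_low)``, and its prominence —
    the log-amplitude contrast between the peak and the dip that precedes
    it on the low-frequency side. Detrending removes the B-factor/form-
    factor fall-off so the peak position is not dragged towards low
    frequency by the envelope.
    """
    ln = np.log(np.maximum(profile.amplitudes, 1e-300))
    if detrend:
        fit = wilson_fit(profile, fit_range, exclude_band)
        ln = ln - (fit.intercept + fit.slope * profile.frequencies**2)
    d = profile.d_spacings
    d_hi, d_lo = band
    in_band = np.where((d <= d_hi) & (d >= d_lo))[0]
    if len(in_band) < 3:
        raise ValueError("band contains fewer than 3 shells")
    i_peak = in_band[np.argmax(ln[in_band])]
    # dip between the start of the Wilson range and the peak
    d_start = fit_range[0] if fit_range[0] else 10.0
    pre = np.where((d <= d_start) & (np.arange(len(d)) < i_peak)
                   & (profile.frequencies > 0))[0]
    dip = ln[pre].min() if len(pre) else ln[i_peak]
    return float(d[i_peak]), float(ln[i_peak] - dip)


def debye_dip(profile: RadialProfile, band: tuple = (9.0, 4.8),
              fit_range: tuple = DEFAULT_WILSON_RANGE,
              exclude_band: tuple | None = DEFAULT_DEBYE_BAND) -> float:
    """Resolution (Å) of the local minimum of the Wilson-detrended log
    amplitude within ``band = (d_high, d_low)`` — the dip preceding the
    secondary-structure peak."""
    fit = wilson_fit(profile, fit_range, exclude_band)
    ln = np.log(np.maximum(profile.amplitudes, 1e-300)) \
        - (fit.intercept + fit.slope * profile.frequencies**2)
    d = profile.d_spacings
    d_hi, d_lo = band
    in_band = np.where((d <= d_hi) & (d >= d_lo))[0]
    if len(in_band) < 3:
        raise ValueError("band contains fewer than 3 shells")
    return float(d[in_band[np.argmin(ln[in_band])]])


# ---------------------------------------------------------------------------
# ensembles

def average_profiles(profiles: list[RadialProfile],
                     label: str = "mixed") -> ProfileEnsemble:
    """Per-frequency mean and standard deviation over profiles.

    Members are linearly resampled onto the coarsest common axis restricted
    to the frequency range covered by every member (truncation, never
    extrapolation).
    """
    if not profiles:
        raise ValueError("average_profiles requires at least one profile")
    lo = max(p.frequencies.min() for p in profiles)
    hi = min(p.frequencies.max() for p in profiles)
    if hi <= lo:
        raise ValueError("profiles share no common frequency range")
    coarsest = max(profiles, key=lambda p: np.median(np.diff(p.frequencies)))
    axis = coarsest.frequencies
    axis = axis[(axis >= lo - 1e-12) & (axis <= hi + 1e-12)]
    stack = np.stack([p.resample(axis).amplitudes for p in profiles])
    return ProfileEnsemble(axis.copy(), stack.mean(axis=0),
                           stack.std(axis=0), len(profiles), label)


# ---------------------------------------------------------------------------
# serialization: two-column text + JSON sidecar

def write_profile(profile: RadialProfile, path: str | os.PathLike,
                  metadata: dict | None = None) -> None:
    path = str(path)
    np.savetxt(path, np.column_stack([profile.frequencies, profile.amplitudes]),
               header="s_invA\tamplitude", delimiter="\t")
    side = {"counts": profile.counts.tolist()}
    if metadata:
        side.update(metadata)
    with open(path + ".json", "w") as fh:
        json.dump(side, fh, indent=1)


def read_profile(path: str | os.PathLike) -> RadialProfile:
    path = str(path)
    data = np.loadtxt(path)
    counts = None
    if os.path.exists(path + ".json"):
        with open(path + ".json") as fh:
            side = json.load(fh)
        counts = np.asarray(side.get("counts")) if "counts" in side else None
    return RadialProfile(data[:, 0], data[:, 1], counts)
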