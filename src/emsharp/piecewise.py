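"""Continuous piecewise-linear fitting of log-amplitude spectra.

Used to extract characteristic Debye-modulation frequencies (the ~6.2 Å
dip and the ~4.2 / ~4.6 Å secondary-structure peaks) from radial profiles:
a continuous n-segment line is fitted to ln|F| vs s and the interior
breakpoints mark where the local slope changes, i.e. the extrema of the
modulation riding on the Wilson fall-off.

For fixed breakpoints the model is linear in its parameters (a hinge
basis), so the search is a low-dimensional optimisation over breakpoint
positions: a coarse combinatorial scan over data-quantile candidates
followed by a Nelder-Mead polish. Deterministic throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

from .profiles import RadialProfile

__all__ = ["PiecewiseFit", "piecewise_fit", "fit_fixed_breakpoints",
           "classify_breakpoints"]


@dataclass
class PiecewiseFit:
    n_segments: int
    breakpoints: np.ndarray     # interior breakpoints in the fit variable
    slopes: np.ndarray          # per-segment slope, length n_segments
    intercept: float            # value of the fit at x = x_min
    r_squared: float
    x: np.ndarray               # fit variable (s, or s^2)
    y: np.ndarray               # ln amplitude
    x_axis: str = "s"

    @property
    def breakpoints_d(self) -> np.ndarray:
        """Breakpoints as resolution d = 1/s in Å (only for x_axis='s')."""
        if self.x_axis == "s":
            return 1.0 / self.breakpoints
        return 1.0 / np.sqrt(self.breakpoints)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        x0 = self.x.min()
        out = self.intercept + self.slopes[0] * (x - x0)
        prev = self.slopes[0]
        for bp, sl in zip(self.breakpoints, self.slopes[1:]):
            out += (sl - prev) * np.clip(x - bp, 0.0, None)
            prev = sl
        return out

    def characteristic_frequencies(self, window=(6.0, 3.0)) -> np.ndarray:
        """Breakpoints with d = 1/s inside the (d_high, d_low) window, in Å."""
        d = self.breakpoints_d
        d_hi, d_lo = window
        return d[(d <= d_hi) & (d >= d_lo)]


def _hinge_design(x: np.ndarray, bp: np.ndarray) -> np.ndarray:
    x0 = x.min()
    cols = [np.ones_like(x), x - x0]
    for b in bp:
        cols.append(np.clip(x - b, 0.0, None))
    return np.column_stack(cols)


def fit_fixed_breakpoints(x: np.ndarray, y: np.ndarray, bp: np.ndarray):
    """Least-squares continuous PWL fit for given interior breakpoints.

    Returns (sse, coefficients); coefficients are [c0, m0, dm1, dm2, ...]
    in the hinge basis.
    """
    design = _hinge_design(x, np.asarray(bp, float))
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def piecewise_fit(profile: RadialProfile, n_segments: int = 4,
                  fit_range: tuple = (10.0, None),
                  x_axis: str = "s",
                  n_candidates: int = 18) -> PiecewiseFit:
    """Fit a continuous n-segment line to ln amplitude over the Wilson range.

    Parameters
    ----------
    profile : RadialProfile
    n_segments : int
        Number of linear segments (n_segments - 1 interior breakpoints).
    fit_range : (d_start, s_max)
        Fit from 1/d_start (Å) up to s_max (1/Å; None = all shells).
    x_axis : "s" or "s2"
        Fit against frequency s (default; breakpoints report naturally as
        d = 1/s) or against s^2 (pure Wilson coordinates).
    n_candidates : int
        Size of the coarse breakpoint-candidate grid per dimension.
    """
    d_start, s_max = fit_range
    freqs = profile.frequencies
    mask = freqs > (0.0 if d_start is None else 1.0 / d_start)
    if s_max is not None:
        mask &= freqs <= s_max
    x = freqs[mask]
    amp = profile.amplitudes[mask]
    if np.any(amp <= 0):
        raise ValueError("nonpositive amplitudes inside the fit range")
    if len(x) < 2 * n_segments:
        raise ValueError(
            f"{len(x)} points cannot constrain {n_segments} segments")
    y = np.log(amp)
    if x_axis == "s2":
        x = x**2
    elif x_axis != "s":
        raise ValueError("x_axis must be 's' or 's2'")

    n_bp = n_segments - 1
    lo, hi = x.min(), x.max()
    if n_bp == 0:
        sse, coef = fit_fixed_breakpoints(x, y, np.empty(0))
        sst = float(np.sum((y - y.mean()) ** 2))
        return PiecewiseFit(n_segments=1, breakpoints=np.empty(0),
                            slopes=np.array([coef[1]]),
                            intercept=float(coef[0]),
                            r_squared=1.0 if sst == 0 else 1.0 - sse / sst,
                            x=x, y=y, x_axis=x_axis)
    cand = np.linspace(lo + (hi - lo) * 0.03, hi - (hi - lo) * 0.03,
                       n_candidates)
    best_sse, best_bp = np.inf, None
    for combo in combinations(range(n_candidates), n_bp):
        bp = cand[list(combo)]
        sse, _ = fit_fixed_breakpoints(x, y, bp)
        if sse < best_sse:
            best_sse, best_bp = sse, bp

    # polish with Nelder-Mead; clamp to the interior and keep ordering
    span = hi - lo

    def objective(bp):
        bp = np.sort(bp)
        if bp[0] <= lo + 1e-9 * span or bp[-1] >= hi - 1e-9 * span:
            return best_sse * 10 + 1.0
        return fit_fixed_breakpoints(x, y, bp)[0]

    res = minimize(objective, best_bp, method="Nelder-Mead",
                   options={"xatol": span * 1e-4, "fatol": 1e-12,
                            "maxiter": 2000})
    bp = np.sort(res.x) if res.fun <= best_sse else np.asarray(best_bp)
    sse, coef = fit_fixed_breakpoints(x, y, bp)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    slopes = np.cumsum(np.concatenate([[coef[1]], coef[2:]]))
    return PiecewiseFit(n_segments=n_segments, breakpoints=bp, slopes=slopes,
                        intercept=float(coef[0]), r_squared=float(r2),
                        x=x, y=y, x_axis=x_axis)


def classify_breakpoints(fit: PiecewiseFit) -> list[tuple[float, str]]:
    """Label each interior breakpoint as a local 'min', 'max' or 'bend'.

    In ln|F| vs s, a dip in the spectrum appears where the segment slope
    turns from negative to positive, a peak where it turns from positive
    to negative; monotone slope changes are plain bends.
    """
    out = []
    for i, bp in enumerate(fit.breakpoints):
        left, right = fit.slopes[i], fit.slopes[i + 1]
        if left < 0 < right:
            kind = "min"
        elif left > 0 > right:
            kind = "max"
        else:
            kind = "bend"
        out.append((float(bp), kind))
    return out
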