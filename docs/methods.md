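# Methods

## Model

A cryo-EM map is treated as an electrostatic potential sampled on a cubic
grid of isotropic voxels. Its Fourier coefficients `F(s⃗)` carry a
resolution-dependent dampening described by the Debye–Waller factor: a
per-atom envelope `exp(-Bⱼ·s²/4)` with `s = 1/d` in Å⁻¹ and `Bⱼ = 8π²⟨uⱼ²⟩`
the isotropic atomic displacement in Å². Maps are simulated from atomic
models by the exact Fourier-space sum

    F(s⃗) = Σⱼ occⱼ · fⱼ(s) · exp(-Bⱼ s²/4) · exp(-2πi s⃗·r⃗ⱼ)

with `fⱼ` the 5-Gaussian electron scattering factor of the element
(Peng et al. 1996, shipped as a versioned TSV for H, C, N, O, S, P;
hydrogens are excluded by default). The tabulated widths are in the
`sin θ/λ` convention and converted once at load, so all user-facing code
uses `s = 1/d` and the dampening exponent is always `B·s²/4` — the one
place a factor-of-two bug could otherwise enter. Because each atom is an
analytic Gaussian sum, evaluating directly in Fourier space is alias-free;
the conventional `B_add` blur / `exp(+B_add·s²/4)` correction workflow is
implemented for compatibility and is a numerical no-op in this evaluator.
The phase sign (`-2πi`) is chosen so numpy's inverse FFT places atoms at
their coordinates; amplitudes, which carry all quantities of interest
here, are independent of this choice.

Beyond ~10 Å resolution a protein's spherically averaged amplitude
spectrum behaves like that of uniformly random independent atoms (the
Wilson range): `ln|F|` is close to linear in `s²` with slope `-B/4`.
Riding on that fall-off are reproducible secondary-structure ("Debye")
modulations — a dip near 6.2 Å and peaks near 4.2–4.5 Å (α) and 4.6 Å
(β) — which both perturb Wilson fits and, conversely, provide a
molecule-independent reference texture for model-free sharpening.

## Radial profiles and B estimation

Profiles are shell means of `|F|` with shell width one Fourier voxel
(`Δs = 1/box edge`). Shells are binned on the half-spectrum with
Hermitian multiplicity weights so statistics equal those of a full
transform; bins extend internally beyond Nyquist to keep the corner
voxels of the Fourier cube out of the interpretable shells, and public
profiles truncate at Nyquist (their shell counts therefore sum to the
voxels inside the Nyquist sphere). This matters: assigning corner voxels
to the last shell biases Wilson fits by several Å² per hundred.

`wilson_fit` is an unweighted least-squares line on `(s², ln|F|)` with
`B = -4·slope`, by default over d = 10 Å → Nyquist excluding the
6.5–3.5 Å modulation band; both limits are configurable.
`match_profile_b` rescales a profile's fall-off to a target B by
multiplying with `exp(-(B_target - B_fit)·s²/4)`.

Local B maps come from the same fit applied per rolling window. Two
practical caveats, both demonstrated in the tests: hard-edged windows
leak low-frequency power into high shells, flooring the apparent fall-off
(a B = 300 Å² domain reads as ~70 Å² through a hard 25 Å window), so
strongly blurred regions need the cosine-tapered window and a fit capped
where signal still exceeds the leakage floor (d ≥ ~3.3 Å at these sizes);
and small windows quantize the fit to few shells, so window sizes below
~20 voxels leave too few shells once the modulation band is excluded.

## Feature extraction

Characteristic Debye frequencies are read from a continuous 4-segment
piecewise-linear fit to `ln|F|` vs `s` over the Wilson range. For fixed
interior breakpoints the model is linear (hinge basis, solved by least
squares); breakpoints are found by a coarse combinatorial scan over an
18-point grid followed by a Nelder–Mead polish, which the tests verify
against exhaustive grid search. Fitting against `s` (not `s²`) makes
breakpoints report naturally as d = 1/s; the `s²` axis is available. A
breakpoint where the segment slope turns negative→positive marks a dip,
positive→negative a peak. A complementary detrended-extremum locator
(`debye_peak`, `debye_dip`) removes the fitted Wilson line and takes the
extremum of the residual — this matches how features are read off a
normalised spectrum plot and is insensitive to the envelope tilt that
drags raw-amplitude maxima toward low frequency.

## Local amplitude scaling

`locscale` rolls a cubic window (default 25 Å, hard-edged, stride 1) over
every voxel with mask > 0.5, scales the window's amplitudes shell-by-shell
onto the reference window's profile with `k(s) = ref/max(obs, ε)`,
`ε = 10⁻⁶ ×` the window's largest shell amplitude, and keeps the central
voxel (evaluated directly from the scaled coefficients, saving the
inverse transform). Voxels outside the mask are zeroed (passthrough
optional); boundaries are zero-padded (reflection optional). The default
mask is the model envelope: 1 within 3 Å of any atom, cosine ramp to 0
over 5 voxels.

The model-free variant replaces the reference window by the generalized
ensemble profile, matched via `match_profile_b` to a per-voxel target B
supplied by the caller — a `LocalBMap` from windowed estimation, or a
constant (as in the restoration experiment below). The matching target is
deliberately *not* the window's own fitted B of the map being scaled:
that would reproduce the input. Below the Wilson range the window keeps
its own amplitudes, because the low-frequency fall-off is shaped by the
molecular envelope rather than by texture and generalized profiles
diverge there; the ensemble profile is stitched on continuously at the
junction shell, which anchors it to the window's own scattering mass.
For deliberate deblurring experiments the junction can be moved to the
first non-DC shell (`anchor_d`), since there the "shape" region is itself
known to be dampened.

Restoration fidelity is bounded by two mechanisms the tests quantify: the
per-shell scalar `k` cannot follow the `exp(+ΔB·s²/4)` correction *within*
a shell (at ΔB = 250 Å² the factor varies ~4× across one 1/25 Å⁻¹ shell),
and window-edge leakage mixes shells. With a 25 Å window the blurred-helix
experiment recovers RSCC ≈ 0.90–0.97 against the sharp ground truth
(0.84 blurred; tapered windows at the upper end), while the *mutual*
agreement of maps scaled with different generalized profiles is ≥ 0.995 —
the result of interest. Sharpening inverted globally (`sharpen_global`
with `-B`) is exact for moderate B but amplifies the floating-point noise
floor at the Fourier-cube corners beyond Nyquist once
`exp(B·s²/4)` exceeds ~10¹⁵ there; the rolling-window path is protected
by its ε floor.

## Synthetic fixtures

Fragments are built from canonical backbone internal coordinates by
natural-extension placement: α-helix φ/ψ = (-57°, -47°) (rise 1.50 Å per
residue, 3.6 residues/turn), β-strand (-139°, +135°), ω = 180°, standard
bond lengths/angles, CB placed tetrahedrally with L-chirality (validated
against the CCD alanine geometry). Sheets are flat and antiparallel by
default: strands are rolled so carbonyls lie in the sheet plane (the
hydrogen-bond direction) with the CA pleat perpendicular, stacked on a
4.7 Å lattice, with the axial registry chosen so the nearest interstrand
CA–CA contact equals 4.7 Å. B-DNA duplexes use fibre-model pseudo-atoms
(rise 3.4 Å, twist 36°). Side chains beyond CB are omitted deliberately —
the Debye features arise from backbone periodicity — which is why feature
positions in tests carry ±0.3–0.4 Å tolerances relative to all-atom
surveys.

Ensembles draw fragment length uniformly from 8–30 residues (sheets: 2–4
strands of 5–12 residues), orientation uniformly from SO(3), sequence
uniformly from the 20 amino-acid codes, with B = 0, mimicking a structure
survey whose atomic B factors were reset before simulation. Maps for
ensemble work use a 96 Å box at 1.0 Å voxels: the resulting 1/96 Å⁻¹
shell spacing is the coarsest that resolves the 6–3 Å band well enough
for breakpoint placement (a 64 Å box quantizes feature positions to
±0.2 Å); the restoration experiment uses the 64 Å / 0.75 Å grid of its
37-residue helix. These desk-scale sizes (20–30 ensemble members) stand
in for a survey of hundreds of deposited structures.

What the surrogate does and does not reproduce: the α-class dip (6.2 Å),
α peak (4.4–4.7 Å), β peak (4.66–4.87 Å) and the combined α+β dip
(6.4 Å) all appear at positions consistent with all-atom surveys; but the
flat CB-only sheets place the *β-class* dip higher (~6.9–7.3 Å) than the
6.2 Å seen for real, twisted, fully side-chained sheets, so the "shared
minimum" reported from per-class breakpoints averages to ~6.7 Å. Twisted
variants were evaluated and made the β peak worse, so the flat canonical
construction is kept and the discrepancy documented rather than tuned
away. Passing tests on these fixtures demonstrate the machinery and the
qualitative spectrum anatomy, not quantitative agreement with any
particular deposited structure.

## Perturbation

Model kicks displace every atom along a uniform random direction by a
magnitude ~ Uniform(0, 2·r_kick); proposals outside the soft molecular
mask (> 0.5) are redrawn up to `max_retries`, after which the atom stays
put (logged). The literal recipe gives an unclipped RMS displacement of
`2·r_kick/√3 ≈ 1.155·r_kick`, not r_kick; `rmsd()` reports the realized
value and nothing is silently rescaled. Rejection near the mask boundary
distorts the magnitude distribution there; this is accepted and noted.
The helix-pitch modulation's prominence decays with kick size and reaches
the noise floor by ~2 Å RMS error, after which it fluctuates — tests
assert strict decay to 2 Å and floor-level values beyond, averaged over
three perturbation draws.

## Numerical choices and limitations

* Deterministic throughout given seeds (`numpy.random.default_rng`);
  breakpoint search and registry scans are grid-based, not stochastic.
* Shell statistics, FSC and scaling use identical binning, so profiles
  and FSC curves are comparable shell-for-shell.
* ε floor, stride, taper, boundary policy, Wilson range and the
  modulation band are all exposed on `ScalingConfig`.
* Only cubic grids with isotropic voxels are supported; no half-map
  noise weighting, no FDR confidence maps, no anisotropic ADPs.
* Masked FSC applies the mask multiplicatively without phase-random
  correction; treat masked FSC values as optimistic.
* `local_b_map` on hard windows underestimates large local B (leakage);
  use `taper=True` and a capped fit range, as in the two-domain phantom
  test, when domains differ by ≳100 Å².
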