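# emsharp

Reference-based sharpening of cryo-EM electrostatic potential maps.

The signal in a cryo-EM reconstruction fades with spatial frequency. The
loss is well described by a Debye–Waller envelope `exp(-B·s²/4)` on the
Fourier amplitudes (`s = 1/d` in Å⁻¹), and the classical remedy is
*sharpening*: multiplying each coefficient by `exp(-B_sharpen·s²/4)` with
`B_sharpen = -B_overall`. Because real reconstructions have spatially
varying resolution, a single global B is often not enough. `emsharp`
implements the rolling-window alternative (the LocScale scheme): a cubic
window (default 25 Å) visits every masked voxel, the window's radially
averaged Fourier amplitudes `|F_obs(s)|` are scaled onto a reference
profile with `k(s) = F_ref(s) / max(F_obs(s), ε)`, and the scaled window's
central voxel is written to the output map.

The reference can be

* **model-based** — the matching window of a map simulated from an atomic
  model via the B-weighted structure-factor sum
  `F(s⃗) = Σⱼ occⱼ·fⱼ(s)·exp(-Bⱼs²/4)·exp(-2πi s⃗·r⃗ⱼ)` with published
  electron scattering factors, or
* **model-free** — a generalized radial profile averaged over many
  secondary-structure fragments, matched to a target Wilson B factor per
  window. This works because protein amplitude spectra beyond ~10 Å are
  dominated by universal secondary-structure "Debye" modulations (a dip
  near 6.2 Å, an α peak near 4.2–4.5 Å, a β peak near 4.6 Å) rather than
  by the particular molecule.

Supporting machinery: MRC/CCP4 and PDB/mmCIF I/O (via gemmi), radial
amplitude profiles, Wilson/Guinier B estimation (`ln|F|` vs `s²`,
`B = -4·slope`) with windowed local-B maps, continuous 4-segment
piecewise-linear feature extraction, controlled model perturbation
(random kicks of magnitude ~ Uniform(0, 2·r_kick) inside a soft molecular
mask), B-factor randomization, FSC and RSCC map comparison, and
deterministic builders for ideal α-helices, β-sheets, B-DNA duplexes and
multi-domain phantoms so everything is testable without downloads.

## Worked example

Build the 37-residue transmembrane helix used throughout the package's
experiments, simulate its map at B = 50 Å², blur it by +250 Å², and
sharpen it back with a generalized α-helical profile:

```python
import emsharp as es

helix = es.build_helix(es.FragmentSpec("alpha", es.HELIX_SEQUENCE_5HT3A,
                                       b_iso=50.0))
cfg = es.SimulationConfig(box_edge=64.0, voxel_size=1.0)
ground = es.model_to_map(helix, cfg)
blurred = es.apply_b_factor(ground, 250.0)

profile = es.radial_profile(ground)
print(es.wilson_fit(profile).b_wilson)     # 61.0 (50 + form-factor fall-off)
print(es.debye_peak(profile)[0])           # 4.57 — the helix-pitch maximum

members = es.fragment_ensemble("alpha", 24, seed=2)
profiles = [es.radial_profile(es.model_to_map(m, cfg)) for m in members]
ensemble = es.average_profiles(profiles, label="alpha")

mask = es.build_model_mask(helix, ground)
config = es.ScalingConfig(window_size=25.0, mask=mask)
sharpened = es.locscale_model_free(blurred, ensemble, 50.0, config)
print(es.rscc(sharpened, ground, mask))    # 0.901, up from 0.842 blurred
```

Swapping the α ensemble for a β or mixed one changes the output by less
than half a percent in real-space correlation (pairwise RSCC ≥ 0.995) —
the core model-free result: explicit atomic models are not required for
reference-based local sharpening.

The same operations are available from the shell:

```sh
emsharp fixtures helix helix.pdb
emsharp simulate helix.pdb helix.mrc --box 64
emsharp sharpen global helix.mrc sharp.mrc --b -107
emsharp profile helix.mrc profile.tsv && emsharp fit profile.tsv --piecewise
```

Every command writes a JSON manifest alongside its output recording the
exact parameters and seeds used.

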