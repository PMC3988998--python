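# cryokit

Desk-scale tools for the movie-processing and map-analysis arithmetic of
single-particle cryo-EM: per-particle beam-induced motion tracking,
per-frame dose weighting, FSC resolution estimation, solvent-corrected
starting references, difference-map ligand occupancy, antibody epitope
contact mapping, and the binding-equilibrium arithmetic that predicts what a
reconstruction of a sub-stoichiometric antibody–enzyme complex should show.
A seeded synthetic-data simulator makes every stage verifiable on a laptop,
without real micrographs.

The package is aimed at people studying or reimplementing movie-era cryo-EM
processing: each algorithm is small, explicit, and tested against ground
truth from its own simulator.

## The methods

**Motion tracking.** During an exposure, particles move; summing frames
blurs them. Each particle is tracked against the self-consistent average of
its own aligned frames with a band-limited, noise-weighted cross-correlation:
only Fourier components with 1/200 ≤ |s| ≤ 1/25 Å⁻¹ contribute, and each
Fourier shell is whitened to unit mean power. Because a single frame of a
small particle is too noisy for a reliable peak, frames are replaced by
running averages over an odd window (11 frames alone; 5 when pooling), and
because neighboring particles move together, the per-frame correlation
surfaces of all particles within 1,000 Å can be summed before peak finding.
Shifts are located to sub-pixel precision by a 3×3 quadratic fit, applied as
Fourier phase ramps, and the frames summed.

**Frame weighting.** Radiation damage destroys high-resolution signal as
dose accumulates, and the first frames carry extra motion. The information
content of frame *f* is measured as the FSC between a 3D map reconstructed
from frame *f* alone and a reference map; the curves become a frame ×
frequency weight matrix w[f](s) (either the clamped FSC itself or the
implied shell SNR, FSC/(1−FSC)), applied as Fourier multipliers before
summation so late frames contribute only at the low resolutions they still
support.

**Map analysis.** FSC(s) = Re Σ F_A F_B* / √(Σ|F_A|² Σ|F_B|²) per shell,
with resolution read at a threshold (0.143 for half maps, 0.5 map-vs-model)
by linear interpolation. Model maps are sums of per-atom Gaussians
(amplitude ∝ electron count, width from a B-factor via σ² = B/8π²); a rough
solvent correction subtracts a scale·exp(−B·s²/4) blurred copy (defaults
scale 0.8, B = 2000 Å²), i.e. transfer 1 − 0.8·exp(−B·s²/4), which scales
zero-frequency amplitude by 0.2, falls to ~1/3 effect at 20 Å and is
negligible by 10 Å. Phase randomization beyond a cutoff, with amplitudes
preserved, validates that FSC beyond the cutoff is not mask-inflated.

**Occupancy.** A ligand bound in a fraction θ of particles appears at θ of
full density in the reconstruction. After least-squares scale matching,
difference = holo − k·apo isolates it; occupancy is estimated (a) as the
ratio of the difference peak to the protein-region peak of the complex map
and (b) as the argmax over θ of the FSC between the experimental map and
composite models apo + θ·ligand.

**Binding arithmetic.** Site concentration n·c/M, equilibrium occupancy
θ = L/(L+Kd) (or the depletion-corrected root of the mass balance), and
binomial stoichiometry P(k bound) across the four sites of a tetramer.

## Worked example

```bash
python examples/difference_occupancy.py
```

```
true occupancy: 0.9
maps scale-matched with k = 0.996 over the protein region
difference peak = 23.4 × map RMS (a confident detection: solvent fluctuations are far smaller)
peak-ratio estimate:  0.90 (difference peak / protein peak — valid for a well-ordered ligand)
model-FSC estimate:   0.90 (argmax of map-vs-model FSC over a 0.05-spaced occupancy grid)
the two estimators are independent; their agreement near 0.9 is the cross-check
```

A 90%-occupied antibody-sized blob added to a synthetic protein map is
recovered at 0.90 by both estimators: the peak ratio reads the density
height directly, the FSC scan asks which composite model best explains the
map. The other scripts in `examples/` cover movie alignment
(`movie_alignment.py`), per-frame dose weighting (`frame_weighting.py`),
FSC/resolution/reference-map tools (`resolution_and_reference.py`), epitope
contact tables (`epitope_contacts.py`), and the binding equilibrium
(`binding_equilibrium.py`). A thin CLI (`cryokit simulate|track|fsc|makeref|
phaserand|diffmap|contacts|equilibrium`) wraps the same functions for shell
use.

Note on the equilibrium numbers: at Kd 2 µM, ligand 20 µM, the free-ligand
approximation gives θ = 20/22 ≈ 90.9%; accounting for ~9 µM of sites
depleting the ligand gives ≈ 86%. Both are reported; the approximation is
the usual back-of-envelope value.

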