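# Methods

This note records the models behind cryokit, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical choices that affect results.

## Conventions

Physical lengths are in Å, spatial frequency s in Å⁻¹, shifts in pixels.
Maps are `(x, y, z)` grids with isotropic voxels; the header origin gives
the physical coordinate of voxel (0,0,0). A B-factor acts on Fourier
amplitudes as exp(−B·s²/4). Fourier shells partition the grid up to Nyquist
= 1/(2·voxel); shell k is centered at k·Nyquist/n_shells, voxels assigned to
the nearest center (half-way ties round up, DC in shell 0). Grids are kept
cubic/square with even dimensions to avoid FFT-center ambiguity.

## Synthetic data generator

The simulator produces the conditions the processing algorithms are designed
for, with known ground truth:

- **Phantom**: a sum of positive Gaussian blobs, widths 0.8–2.4 voxels so
  the power spectrum extends toward Nyquist (a tracking or weighting test at
  a shell with no signal would be vacuous). Deterministic per seed.
- **Movies**: each frame is the sum of projected, damage-filtered, shifted
  particle images plus white Gaussian noise. Projections are central slices
  of a 2× zero-padded Fourier volume, interpolated trilinearly — padding
  keeps the interpolation error small enough that noiseless
  project→reconstruct round trips hold FSC > 0.98 to half Nyquist.
- **Drift**: a shared cumulative path (default studies use 0.25–0.3 px per
  frame), modulated linearly with position (per 1,000 Å) so nearby particles
  move together, plus an extra constant displacement on the first 3 frames.
  The early-frame effect is modeled as extra *motion*, not extra blur; that
  is the accepted physical reading of why early frames carry less
  information, and it is what per-frame map FSC actually responds to.
- **Damage**: amplitude attenuation exp(−B_f·s²/4) with B_f = rate ×
  accumulated dose; frame 0 is undamaged. The default study rate, 30 Å² per
  el/Å² at 1 el/Å²/frame, makes the 7 Å shell decay visibly within a
  16-frame exposure without erasing it.
- **Noise**: white Gaussian, amplitude in the same arbitrary units as the
  projections (no absolute el/Å²→counts scale is modeled). No CTF, no ice
  background, no detector fixed pattern.
- **Ligand pairs**: holo = apo + occupancy·(Gaussian blob); optional
  independent noise per map. Occupancy acts linearly, as it does in a
  reconstruction averaged over many particles.

What passing tests therefore show: the algorithms recover known shifts,
weights and occupancies under realistic noise, drift coherence and dose
decay. What they do not show: behavior under CTF modulation, structured ice
or detector artifacts, orientation errors, or magnification anisotropy —
real-data effects outside this package's scope.

## Motion tracking

"Noise-weighted" correlation is implemented as per-shell amplitude
whitening of both inputs inside the 1/200–1/25 Å⁻¹ band (each shell scaled
to unit mean power) before the conjugate product; with whitening off it is a
plain band-passed correlation. Whitening is the standard reading of
noise-weighting and is configurable because the original weighting scheme is
not published in detail.

The detector fixed-pattern guard zeroes the zero-shift correlation value and
its 4-neighborhood before peak search and can exclude the kx=0/ky=0 Fourier
lines. Both are off by default: simulated data has no fixed pattern, and the
guard would (by design) suppress the legitimate zero-shift peak of an
already-aligned pair.

Tracking iterates: build the average of currently aligned frames, correlate
each running-averaged frame against it, re-center the shifts to zero mean,
repeat until the largest update is below 0.05 px (tests use 0.02) or 10
iterations. The unaligned sum initializes the reference. A shift measured
from a clipped end-window belongs to that window's centroid, not its frame
index; estimates are therefore interpolated from window centroids onto frame
indices (linear, extrapolated at the ends) — without this the first and last
half-window of a drifting movie carry a systematic bias. Correlation
surfaces of window-averaged frames are correlated (rather than summing
single-frame surfaces over the window); the alternative would weight frame
noise differently but was not pursued. No temporal smoothing is applied to
the recovered paths.

Neighbor pooling sums the per-frame correlation surfaces of all particles
within the pooling radius (including self) before peak finding; radius 0
reduces exactly to unpooled tracking. Pooling assumes the pooled particles
share their drift — the simulator's coherence model — and the desk-scale
studies (4 particles, one box apart, noise σ about 1.7× the frame signal
RMS) roughly halve the tracking error when pooling.

## Frame weighting

Per-frame quality is the FSC between the map reconstructed from one frame
(all particles) and a reference. Two references are supported: the
summed-frame map (the conventional choice, default) and a
leave-one-frame-out mean of the other frames' maps. The summed-frame
reference shares each frame's noise and inflates the correlation by roughly
1/√n_frames — at desk scale (tens of particles rather than tens of
thousands) that floor can swamp the damage signal, so the desk-scale studies
and the acceptance script use the leave-one-out reference. The scalar
quality averages the FSC over shells within ±10% of 1/7 Å⁻¹ (configurable).

Weights: mode `fsc` uses max(FSC, 0); mode `snr` uses FSC/(1−FSC), the shell
SNR a correlation implies, which is the matched-filter weight when the
damage follows the assumed model. Negative FSC is clamped to zero — negative
multipliers would invert contrast. Curves are smoothed with a 3-shell moving
mean to damp shell noise (toggleable), and per-shell normalization rescales
each shell's weights to sum to n_frames, so identical frames give the same
sum under any mode. Whether to normalize is a free choice; normalization is
on by default because it preserves the power scale of the plain sum.

## FSC, references, validation

FSC uses unmasked full boxes by default; a soft spherical mask is available.
Resolution is the first downward threshold crossing, linearly interpolated
in s (curves that never cross are flagged and return the last shell; curves
starting below threshold are flagged and return the first). Model maps use a
single Gaussian per atom (amplitude ∝ atomic number, default per-atom
B = 100 Å²) rather than tabulated scattering factors — the reference map's
role is low/mid resolution, where the single-Gaussian error is far below the
~20% uncertainty already accepted in the solvent scale factor. The solvent
correction's scale defaults to 0.8 (an earlier estimate of 0.72 is available
by parameter). Phase randomization replaces phases beyond the cutoff with
those of a random real map, which preserves conjugate symmetry exactly; the
mask-corrected FSC is (FSC_raw − FSC_rand)/(1 − FSC_rand) beyond the cutoff.

## Difference maps and occupancy

Scale matching minimizes ‖A − k·B‖² over a protein-only mask that excludes
the expected ligand region — including the ligand region would bias k
upward and partially subtract the ligand. The "RMS density" in the
peak-to-RMS statistic is taken over the whole difference map, solvent
included. The protein reference peak for the peak-ratio estimator is read
from the complex map (in the difference map the protein cancels); the global
protein-region maximum is used rather than a matched feature, which is one
of two defensible readings. The peak-ratio estimator assumes the ligand's
intrinsic peak density matches the protein's; ratios above 1 are clamped at
1.2 and flagged. The FSC-scan estimator scores composites over shells
between 1/30 and 1/15 Å⁻¹ by default (the resolution regime of a ~13 Å
complex map); both the band and the occupancy grid are parameters. No
B-factor sharpening is applied anywhere in this module.

## Contacts

Contact tables list residue pairs with minimum heavy-atom distance below a
cutoff (default 4.5 Å — "possible contacts" conventions range over
3.5–4.5 Å, and the cutoff is exposed). The search uses a k-d tree and is
verified against a brute-force all-pairs scan. Antigen domain boundaries are
configuration data (a label/start/end table), not derivable from
coordinates. Altloc policy: highest occupancy wins; hydrogens are included
if present.

## Binding equilibrium

θ = L/(L+Kd) ignores ligand depletion; the exact mode solves the quadratic
mass balance for free ligand. At the default study point (Kd 2 µM, L 20 µM,
S 9 µM) the two give 90.9% and 86.1% — the package reports both rather than
silently choosing. Stoichiometry is binomial across the n sites (no
cooperativity): at θ = 0.909, 68% of tetramers carry 4 copies and 27% carry
3 — "about two thirds and most of the rest," not an exact half/half split.

## Problem sizes and numerical notes

Desk-scale studies use 32³–48³ voxel grids at 2.5–3.5 Å/voxel, 12–16 frame
movies, 4–48 particles, and 60–120 projection orientations; these sizes keep
every experiment seconds-long while leaving enough Fourier shells (16–24)
for shell statistics. Reconstruction divides accumulated slice values by
accumulated trilinear weights (voxels with weight < 1e-8 are zeroed);
all-coplanar view axes trigger a missing-cone warning. Sub-pixel peaks use a
per-axis quadratic fit clipped to ±0.5 px with a concavity check. Fractional
Fourier shifts of real images lose the Nyquist bin (the real-part
projection), so a shift-then-unshift round trip is exact only for integer
shifts — visible as a tiny alternating residual, about 1% of peak density in
the aligned-sum tests.

## Known limitations

No CTF estimation or correction, no orientation refinement, no particle
picking, no gold-standard half-set bookkeeping, no GPU path, no
super-resolution or compressed detector formats. The tracker assumes
translation-only motion within the correlation box; rotation during exposure
and anisotropic magnification are not modeled. Real-data behavior of the
weighting scheme depends on particle count; the leave-one-out reference
matters most when particles are few.
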