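"""FSC resolution estimation, solvent-corrected reference maps, and
phase-randomization validation.

Builds half-maps with controlled noise, reads resolution at the 0.143
threshold, renders a tiny atomic model into a solvent-corrected starting
reference, and shows that phase randomization kills FSC beyond the cutoff
while preserving the power spectrum.
"""

import numpy as np
import pandas as pd

import cryokit as ck
from cryokit.fscres import (fsc, model_to_map, phase_randomize_beyond,
                            resolution_at, solvent_correct_reference,
                            solvent_transfer)
from cryokit.volmap import make_shells

phantom = ck.make_phantom(seed=9, box=32, voxel_size=2.5)
shells = make_shells(phantom.shape, phantom.voxel_size, 16)
rng = np.random.default_rng(1)
half_a = phantom.copy(data=phantom.data + rng.normal(0, 0.25, phantom.shape))
half_b = phantom.copy(data=phantom.data + rng.normal(0, 0.25, phantom.shape))
est = resolution_at(fsc(half_a, half_b, shells), 0.143)
print(f"half-map resolution at FSC 0.143: {est.resolution:.1f} Å "
      f"(crossed={est.crossed}; noisier halves would push this coarser)")

atoms = pd.DataFrame({"element": ["C", "N", "O", "C"],
                      "x": [30.0, 36.0, 42.0, 36.0],
                      "y": [40.0, 40.0, 40.0, 46.0],
                      "z": [40.0, 40.0, 40.0, 40.0]})
vac = model_to_map(atoms, voxel_size=2.5, box=32, per_atom_B=100.0)
ref = solvent_correct_reference(vac, scale=0.8, B=2000.0)
print(f"\nsolvent-corrected reference: DC amplitude scaled to "
      f"{ref.data.sum() / vac.data.sum():.2f} of in-vacuo value "
      f"(transfer at 20 Å: {solvent_transfer(1 / 20):.3f}, "
      f"at 10 Å: {solvent_transfer(1 / 10):.4f} — correction only touches "
      "low resolution)")

randomized = phase_randomize_beyond(phantom, resolution_cutoff=12.0, seed=5)
curve = fsc(phantom, randomized, shells)
below = (curve.s > 0) & (curve.s < 1 / 12 * 0.9)
beyond = curve.s > 1 / 12 * 1.1
print(f"\nphase randomization beyond 12 Å: FSC below cutoff "
      f"{curve.fsc[below].min():.3f} (intact), beyond cutoff "
      f"|FSC| max {np.abs(curve.fsc[beyond]).max():.3f} (noise level) — "
      "amplitudes untouched, so any surviving correlation would expose "
      "processing artifacts")
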