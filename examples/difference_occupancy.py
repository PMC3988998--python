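"""Locate sub-stoichiometric ligand density by map subtraction and estimate
its occupancy two independent ways.

Builds an apo/holo map pair with a 90%-occupied antibody-sized blob, scale-
matches and subtracts the maps, and estimates occupancy from (a) the
difference-peak / protein-peak ratio and (b) a map-vs-model FSC scan over
composite models with variable ligand occupancy.
"""

import numpy as np

import cryokit as ck
from cryokit import diffmap, synth

box, voxel = 48, 3.5
phantom = ck.make_phantom(seed=13, box=box, voxel_size=voxel)
extent = box * voxel
ligand_center = np.array([extent * 0.85, extent * 0.5, extent * 0.5])
ligand_region = diffmap.sphere_region(phantom.shape, voxel, ligand_center, 25.0)
protein_region = diffmap.sphere_region(phantom.shape, voxel, [extent / 2] * 3,
                                       45.0) & ~ligand_region

true_occupancy = 0.9
amplitude = phantom.data[protein_region].max()  # ligand as dense as protein
apo, holo = synth.make_ligand_pair(phantom, ligand_center, amplitude,
                                   true_occupancy, seed=17, noise_sigma=0.03)

scale = diffmap.match_scale(holo, apo, protein_region)
diff = diffmap.difference_map(holo, apo, scale)
stats = diffmap.diff_stats(diff, ligand_region, protein_region,
                           reference_map=holo)
est_peak = diffmap.occupancy_from_peaks(stats)

ligand_model = phantom.copy(data=synth.gaussian_blob(
    phantom.shape, voxel, ligand_center, amplitude, 3 * voxel))
scan = diffmap.occupancy_from_model_fsc(holo, phantom, ligand_model,
                                        occupancy_grid=np.arange(0, 1.01, 0.05))

print(f"true occupancy: {true_occupancy}")
print(f"maps scale-matched with k = {scale:.3f} over the protein region")
print(f"difference peak = {stats.peak_to_rms:.1f} × map RMS "
      "(a confident detection: solvent fluctuations are far smaller)")
print(f"peak-ratio estimate:  {est_peak.value:.2f} "
      "(difference peak / protein peak — valid for a well-ordered ligand)")
print(f"model-FSC estimate:   {scan.best_occupancy:.2f} "
      "(argmax of map-vs-model FSC over a 0.05-spaced occupancy grid)")
print("the two estimators are independent; their agreement near 0.9 is the "
      "cross-check")
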