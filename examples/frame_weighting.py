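"""Measure per-frame information content and build dose-weighted sums.

Simulates 48 particle movies with extra motion in frames 1-3 and radiation
damage growing with accumulated dose (B_f = 30·f Å²), reconstructs a 3D map
from each frame, scores each frame by its FSC near 7 Å against a
leave-one-frame-out reference, and compares frame-weighted against plain
frame sums.
"""

import numpy as np

import cryokit as ck
from cryokit import frameweight, synth
from cryokit.fscres import fsc
from cryokit.volmap import make_shells

box, voxel = 32, 2.5
phantom = ck.make_phantom(seed=9, box=box, voxel_size=voxel)
n_frames, n_particles = 16, 48
rotations = ck.random_rotations(n_particles, 21)
drift = synth.DriftModel(global_path=np.zeros((n_frames, 2)),
                         early_frame_boost=(6.0, -5.0), n_early=3)
damage = synth.DamageModel(rate=30.0)

frames = np.array([
    synth.simulate_movie(phantom, [[0.0, 0.0]], [rot], drift, damage,
                         dose_per_frame=1.0, noise_sigma=0.3,
                         seed=100 + i)[0].frames
    for i, rot in enumerate(rotations)])

shells = make_shells((box,) * 3, voxel, box // 2)
frame_maps = [ck.reconstruct_known_angles(list(frames[:, f]), rotations, voxel)
              for f in range(n_frames)]
qualities = frameweight.per_frame_quality(frame_maps, shells=shells,
                                          reference_s=1.0 / 7.0,
                                          leave_one_out=True)
w = np.array([q.weight for q in qualities])
print("per-frame FSC weight near 7 Å (early frames low, peak at 4-9, then decay):")
print("  " + " ".join(f"{x:.2f}" for x in w))

W = frameweight.make_resol_weights([q.fsc_curve for q in qualities], mode="snr")
weighted = [frameweight.weight_and_sum(frames[p], W, voxel)
            for p in range(n_particles)]
rec_weighted = ck.reconstruct_known_angles(weighted, rotations, voxel)
rec_plain = ck.reconstruct_known_angles(list(frames.sum(axis=1)), rotations, voxel)

cw = fsc(rec_weighted, phantom, shells)
cu = fsc(rec_plain, phantom, shells)
band = (cw.s >= 0.05) & (cw.s <= 0.15)
print("\nFSC vs phantom over the damage-affected band (s = 0.05-0.15 Å⁻¹):")
print("  plain sum:    " + " ".join(f"{x:+.3f}" for x in cu.fsc[band]))
print("  weighted sum: " + " ".join(f"{x:+.3f}" for x in cw.fsc[band]))
print(f"  max per-shell gain: {np.max(cw.fsc[band] - cu.fsc[band]):.3f} "
      "(weighting recovers high-resolution signal late frames destroyed)")
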