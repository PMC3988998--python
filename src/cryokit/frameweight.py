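"""Per-frame information-content weighting of movie frames.

The information content of each movie frame is measured by the FSC between a
3D map reconstructed from that frame alone and a reference map reconstructed
from the summed frames.  The FSC curves are converted to a frame × frequency
weight matrix (down-weighting frequencies a frame no longer carries, e.g.
after radiation damage), and the weights are applied as Fourier multipliers
to the aligned frames before summation, so late frames contribute only at
the lower resolutions they still support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fscres import fsc as _fsc
from .volmap import DensityMap, FrequencyShells, FscCurve

__all__ = [
    "FrameQuality",
    "WeightMatrix",
    "per_frame_quality",
    "make_resol_weights",
    "weight_and_sum",
]


@dataclass
class FrameQuality:
    frame_index: int
    fsc_curve: FscCurve
    weight: float  # FSC near the reference shell, clamped to >= 0


@dataclass
class WeightMatrix:
    """Non-negative Fourier multipliers w[frame][shell]."""

    w: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if not np.all(np.isfinite(self.w)) or np.any(self.w < 0):
            raise ValueError("weights must be finite and >= 0")


def per_frame_quality(frame_maps, reference_map: DensityMap | None = None,
                      shells: FrequencyShells | None = None,
                      reference_s: float = 1.0 / 7.0,
                      window_frac: float = 0.10,
                      leave_one_out: bool = False) -> list[FrameQuality]:
    """FSC of each per-frame map against the reference, with a scalar quality.

    The scalar weight is the FSC averaged over shells within ±``window_frac``
    of ``reference_s`` (default the shells near 7 Å), clamped to zero from
    below.

    A reference built from all frames shares each frame's noise, which
    inflates the correlation by roughly 1/√n_frames; ``leave_one_out``
    instead compares frame f against the mean of the other frames' maps
    (reconstruction is linear in its input images, so this is the map from
    the remaining frames), removing the shared-noise term.  The default
    compares against the summed-frame reference.
    """
    frame_maps = list(frame_maps)
    if leave_one_out and len(frame_maps) < 2:
        raise ValueError("leave-one-out needs >= 2 frame maps")
    if not leave_one_out and reference_map is None:
        raise ValueError("reference_map required unless leave_one_out")
    stack = np.stack([m.data for m in frame_maps]) if leave_one_out else None
    qualities = []
    for f, frame_map in enumerate(frame_maps):
        if leave_one_out:
            others = (stack.sum(axis=0) - stack[f]) / (len(frame_maps) - 1)
            ref = frame_map.copy(data=others)
        else:
            ref = reference_map
        curve = _fsc(frame_map, ref, shells)
        sel = np.abs(curve.s - reference_s) <= window_frac * reference_s
        if not np.any(sel):
            sel = np.argmin(np.abs(curve.s - reference_s))  # nearest shell
        weight = max(float(np.mean(curve.fsc[sel])), 0.0)
        qualities.append(FrameQuality(frame_index=f, fsc_curve=curve,
                                      weight=weight))
    return qualities


def make_resol_weights(per_frame_fsc_curves, mode: str = "fsc",
                       normalize: bool = True, smooth: bool = True,
                       eps: float = 1e-3) -> WeightMatrix:
    """Convert per-frame FSC curves into frame × shell Fourier multipliers.

    mode "fsc": w = max(FSC, 0).  mode "snr": w = max(FSC,0)/(1 − min(FSC,
    1−eps)), the shell SNR implied by the correlation (the matched-filter
    weight).  Either way frequencies where a frame's FSC ≤ 0 get weight 0.
    With ``smooth`` the curves are first averaged over 3 adjacent shells to
    damp shell noise; with ``normalize`` each shell's weights are rescaled so
    they sum to n_frames (leaving the per-shell power scale of a sum of
    identical frames unchanged).
    """
    curves = list(per_frame_fsc_curves)
    if mode not in ("fsc", "snr"):
        raise ValueError(f"unknown mode {mode!r}")
    s = curves[0].s
    for c in curves[1:]:
        if len(c.s) != len(s) or not np.allclose(c.s, s):
            raise ValueError("all FSC curves must share one shell grid")
    F = np.stack([np.asarray(c.fsc, dtype=float) for c in curves])
    if smooth and F.shape[1] >= 3:
        kernel = np.ones(3) / 3.0
        F = np.apply_along_axis(
            lambda row: np.convolve(np.pad(row, 1, mode="edge"), kernel,
                                    mode="valid"), 1, F)
    pos = np.maximum(F, 0.0)
    if mode == "fsc":
        w = pos
    else:
        w = pos / (1.0 - np.minimum(F, 1.0 - eps))
    if normalize:
        col = w.sum(axis=0)
        scale = np.where(col > 0, len(curves) / np.where(col > 0, col, 1.0), 0.0)
        w = w * scale
    return WeightMatrix(w=w, s=s)


def weight_and_sum(aligned_frames: np.ndarray, weights: WeightMatrix,
                   pixel_size: float) -> np.ndarray:
    """Fourier-weighted sum of aligned 2D frames.

    FT(out)(s) = Σ_f w[f][shell(s)]·FT(frame_f)(s); each image frequency is
    assigned the nearest weight shell.  The multipliers are real and radially
    symmetric, so conjugate symmetry — and hence a real output — is
    preserved.
    """
    frames = np.asarray(aligned_frames, dtype=float)
    if frames.shape[0] != weights.w.shape[0]:
        raise ValueError(f"{frames.shape[0]} frames but "
                         f"{weights.w.shape[0]} weight rows")
    fy = np.fft.fftfreq(frames.shape[1], d=pixel_size)
    fx = np.fft.fftfreq(frames.shape[2], d=pixel_size)
    smag = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    shell_of = np.argmin(np.abs(smag[..., None] - weights.s), axis=-1)
    out_ft = np.zeros(frames.shape[1:], dtype=complex)
    for f in range(frames.shape[0]):
        out_ft += weights.w[f][shell_of] * np.fft.fft2(frames[f])
    return np.fft.ifft2(out_ft).real
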