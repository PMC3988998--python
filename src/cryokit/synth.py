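"""Seeded synthetic-data generators: phantoms, drifting dose-damaged movies,
apo/holo map pairs, and a known-orientation reconstructor.

The simulator emulates the recording conditions of direct-detector movie
exposures: multi-frame stacks at ~1 el/Å²/frame, spatially coherent drift
(neighboring particles within ~1000 Å move together, with an optional linear
spatial gradient), extra displacement in the first few frames, and
resolution-dependent radiation-damage decay exp(−B_f·s²/4) with B_f growing
with accumulated dose.  Image amplitudes are in arbitrary units — no absolute
scale linking el/Å² to detector counts is modeled — and noise is additive
white Gaussian.  No CTF is applied.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volmap import DensityMap, MicrographMovie

__all__ = [
    "DriftModel",
    "DamageModel",
    "GroundTruth",
    "make_phantom",
    "gaussian_blob",
    "project_map",
    "random_rotations",
    "simulate_movie",
    "extract_particle_movie",
    "make_ligand_pair",
    "reconstruct_known_angles",
]


@dataclass
class DriftModel:
    """Beam-induced drift shared by neighboring particles.

    ``global_path``: per-frame cumulative 2D shift (px), shape (n_frames, 2).
    ``local_gradient``: per-1000-Å linear modulation of the global path — a
    particle at displacement Δ (Å) from the field center follows
    path·(1 + g·Δ/1000), so particles within ~1000 Å share their drift to
    within this term.
    ``early_frame_boost``: extra shift (px) added to each of the first
    ``n_early`` frames, modeling the larger, less-trackable motion at the
    start of the exposure.
    """

    global_path: np.ndarray
    local_gradient: np.ndarray = field(default_factory=lambda: np.zeros(2))
    early_frame_boost: np.ndarray = field(default_factory=lambda: np.zeros(2))
    n_early: int = 3

    def __post_init__(self) -> None:
        self.global_path = np.atleast_2d(np.asarray(self.global_path, dtype=float))
        self.local_gradient = np.asarray(self.local_gradient, dtype=float)
        self.early_frame_boost = np.asarray(self.early_frame_boost, dtype=float)
        if not np.all(np.isfinite(self.global_path)):
            raise ValueError("drift path must be finite")

    @classmethod
    def linear(cls, n_frames: int, per_frame: tuple[float, float],
               **kwargs) -> "DriftModel":
        """Constant-velocity drift: cumulative path k·(dx, dy) at frame k."""
        path = np.outer(np.arange(n_frames), np.asarray(per_frame, dtype=float))
        return cls(global_path=path, **kwargs)

    @classmethod
    def none(cls, n_frames: int) -> "DriftModel":
        return cls(global_path=np.zeros((n_frames, 2)))

    def particle_path(self, position_offset_A: np.ndarray) -> np.ndarray:
        """Per-frame shift (px) for a particle displaced ``position_offset_A``
        (Å, 2-vector) from the field center."""
        mod = 1.0 + float(np.dot(self.local_gradient,
                                 np.asarray(position_offset_A) / 1000.0))
        path = self.global_path * mod
        path = path.copy()
        k = min(self.n_early, len(path))
        path[:k] += self.early_frame_boost
        return path


@dataclass
class DamageModel:
    """Radiation-damage amplitude decay exp(−B_f·s²/4), B_f = rate·dose(f).

    ``rate`` has units Å² per (el/Å²); the dose accumulated before frame f
    (f frames of ``dose_per_frame`` each) sets B_f, so frame 0 is undamaged
    and B_f is non-decreasing in f.
    """

    rate: float = 0.0

    def b_factor(self, frame_index: int, dose_per_frame: float) -> float:
        return self.rate * dose_per_frame * frame_index

    def attenuation(self, s: np.ndarray, frame_index: int,
                    dose_per_frame: float) -> np.ndarray:
        b = self.b_factor(frame_index, dose_per_frame)
        return np.exp(-b * np.asarray(s, dtype=float) ** 2 / 4.0)


@dataclass
class GroundTruth:
    """Exact generator state recorded alongside a simulation."""

    trajectories: np.ndarray        # (n_particles, n_frames, 2) px
    frame_attenuation: np.ndarray   # amplitude attenuation at the reference shell
    reference_s: float = 1.0 / 7.0  # Å⁻¹
    ligand_occupancy: float | None = None


# ---------------------------------------------------------------------------
# Phantoms

def gaussian_blob(shape: tuple[int, ...], voxel_size: float, center_A: np.ndarray,
                  amplitude: float, sigma_A: float) -> np.ndarray:
    """A 3D (or 2D) Gaussian of peak ``amplitude`` sampled on the grid."""
    center = np.asarray(center_A, dtype=float)
    axes = [(np.arange(n) * voxel_size - c) ** 2 for n, c in zip(shape, center)]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    r2 = sum(grids)
    return amplitude * np.exp(-r2 / (2.0 * sigma_A ** 2))


def make_phantom(seed: int, box: int = 48, voxel_size: float = 3.5,
                 n_blobs: int = 12, return_params: bool = False):
    """Random positive-density blob phantom standing in for a protein map.

    Blob widths are mixed (σ from ~1.2 to ~3 voxels) so the phantom has
    power out toward the Nyquist band; all blobs lie in the central half of
    the box.  A single blob (``n_blobs=1``) is placed exactly at the box
    center.  Deterministic for a fixed seed.
    """
    if box < 32:
        raise ValueError("box must be >= 32")
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    extent = box * voxel_size
    sigmas = rng.uniform(0.8, 2.4, size=n_blobs) * voxel_size
    if np.max(sigmas) * 8 > extent:
        raise ValueError(f"box {box} too small for blob width {np.max(sigmas):.1f} Å")
    amps = rng.uniform(0.5, 2.0, size=n_blobs)
    if n_blobs == 1:
        centers = np.array([[extent / 2.0] * 3])
    else:
        centers = rng.uniform(extent * 0.25, extent * 0.75, size=(n_blobs, 3))
        # snap centers to the voxel grid so projections/peaks are crisp
        centers = np.round(centers / voxel_size) * voxel_size
    data = np.zeros((box, box, box))
    for c, a, sig in zip(centers, amps, sigmas):
        data += gaussian_blob((box,) * 3, voxel_size, c, a, sig)
    phantom = DensityMap(data=data, voxel_size=voxel_size)
    if return_params:
        params = [{"center": c, "amplitude": a, "sigma": s}
                  for c, a, s in zip(centers, amps, sigmas)]
        return phantom, params
    return phantom


# ---------------------------------------------------------------------------
# Projection (central-slice, trilinear interpolation in Fourier space)

def random_rotations(n: int, seed: int) -> list[np.ndarray]:
    """Quasi-uniform random orientations as 3×3 rotation matrices."""
    rng = np.random.default_rng(seed)
    return list(Rotation.random(n, random_state=rng).as_matrix())


def _slice_coords(n: int, rot: np.ndarray) -> np.ndarray:
    """Centered Fourier coordinates of the central slice for rotation ``rot``.

    The projection is along the rotated z-axis; the slice plane is spanned by
    the rotated x- and y-axes (rows 0 and 1 of ``rot``).  ``n`` is the side
    of the (possibly oversampled) Fourier grid the slice lives on.
    """
    u = np.fft.fftshift(np.fft.fftfreq(n)) * n  # integer grid, centered
    uu, vv = np.meshgrid(u, u, indexing="ij")
    coords = (uu[..., None] * rot[0] + vv[..., None] * rot[1])  # (n, n, 3)
    return coords + n / 2.0


def _pad_centered(data: np.ndarray, factor: int) -> np.ndarray:
    """Zero-pad an array symmetrically to ``factor`` times its size."""
    n = data.shape[0]
    big = np.zeros(tuple(factor * s for s in data.shape), dtype=data.dtype)
    sl = tuple(slice((factor - 1) * s // 2, (factor - 1) * s // 2 + s)
               for s in data.shape)
    big[sl] = data
    return big


class Projector:
    """Central-slice projector with a cached, oversampled Fourier volume.

    The map is zero-padded ``oversample``× before transforming so that the
    trilinear slice interpolation samples a finer Fourier grid; this is what
    keeps noiseless project→reconstruct round trips faithful well past half
    Nyquist.
    """

    def __init__(self, density_map: DensityMap, oversample: int = 2):
        n = density_map.shape[0]
        if density_map.shape != (n, n, n):
            raise ValueError("projection requires a cubic map")
        self.n = n
        self.oversample = oversample
        self.voxel_size = density_map.voxel_size
        padded = _pad_centered(density_map.data, oversample)
        # move the box center to the DFT origin before transforming, so the
        # Fourier volume is smooth (no per-sample phase alternation) and
        # trilinear interpolation of the slice is accurate
        ft = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))
        self._re, self._im = np.ascontiguousarray(ft.real), np.ascontiguousarray(ft.imag)

    def project(self, rotation: np.ndarray) -> np.ndarray:
        """Real (y, x) projection image of shape (n, n) along the rotated z-axis."""
        m = self.n * self.oversample
        coords = _slice_coords(m, np.asarray(rotation)).reshape(-1, 3).T
        re = ndimage.map_coordinates(self._re, coords, order=1, mode="constant")
        im = ndimage.map_coordinates(self._im, coords, order=1, mode="constant")
        slc = (re + 1j * im).reshape(m, m)
        big = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(slc))).real
        k = (self.oversample - 1) * self.n // 2
        img = big[k:k + self.n, k:k + self.n]
        return img.T  # (y, x) axis order, amplitudes in arbitrary units


def project_map(density_map: DensityMap, rotation: np.ndarray,
                oversample: int = 2) -> np.ndarray:
    """Project the map along the rotated z-axis via central-slice extraction.

    For repeated projections of one map use :class:`Projector`, which caches
    the oversampled Fourier volume.
    """
    return Projector(density_map, oversample).project(rotation)


def fourier_shift_image(image: np.ndarray, shift_xy: tuple[float, float]) -> np.ndarray:
    """Shift a (y, x) image by (dx, dy) px with a Fourier phase ramp.

    Circular (wrap-around) shift, exact for integer shifts."""
    dx, dy = shift_xy
    return np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(image), (dy, dx))).real


# ---------------------------------------------------------------------------
# Movie simulation

def simulate_movie(phantom: DensityMap, particle_positions: np.ndarray,
                   orientations, drift: DriftModel, damage: DamageModel,
                   dose_per_frame: float = 1.0, noise_sigma: float = 0.0,
                   seed: int = 0, field_shape: tuple[int, int] | None = None,
                   reference_s: float = 1.0 / 7.0,
                   ) -> tuple[MicrographMovie, GroundTruth]:
    """Render a drifting, dose-damaged multi-frame exposure of projected particles.

    ``particle_positions`` are (n_p, 2) box-corner coordinates in Å on the
    micrograph (x = fast axis); each particle's projection (phantom box size)
    is damage-filtered per frame, shifted along its drift path, pasted into
    the field, and white Gaussian noise of ``noise_sigma`` is added per frame.

    Returns the movie and a :class:`GroundTruth` with the exact applied
    shifts per particle per frame.
    """
    positions = np.atleast_2d(np.asarray(particle_positions, dtype=float))
    n_p = len(positions)
    orientations = list(orientations)
    if len(orientations) != n_p:
        raise ValueError("need one orientation per particle")
    n_frames = len(drift.global_path)
    px = phantom.voxel_size
    box = phantom.shape[0]
    if field_shape is None:
        hi = positions.max(axis=0) / px + box
        field_shape = (int(np.ceil(hi[1])), int(np.ceil(hi[0])))
    ny, nx = field_shape

    corners = np.round(positions / px).astype(int)  # (x, y) px
    for (cx, cy) in corners:
        if cx < 0 or cy < 0 or cx + box > nx or cy + box > ny:
            raise ValueError(f"particle box at ({cx},{cy}) px falls outside the "
                             f"{ny}x{nx} field")
    if n_p > 1:
        d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < box * px:
            warnings.warn("particle boxes overlap", stacklevel=2)

    # base images and their FFTs
    projector = Projector(phantom)
    base_fts = [np.fft.fft2(projector.project(rot)) for rot in orientations]
    fy = np.fft.fftfreq(box, d=px)
    fx = np.fft.fftfreq(box, d=px)
    smag = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)

    center = positions.mean(axis=0)
    trajs = np.stack([drift.particle_path(p - center) for p in positions])

    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, ny, nx))
    atten_ref = np.empty(n_frames)
    for f in range(n_frames):
        att = damage.attenuation(smag, f, dose_per_frame)
        atten_ref[f] = damage.attenuation(np.array([reference_s]), f,
                                          dose_per_frame)[0]
        for p in range(n_p):
            dx, dy = trajs[p, f]
            # image axes are (y, x); shift rows by dy, cols by dx
            ft = ndimage.fourier_shift(base_fts[p] * att, (dy, dx))
            img = np.fft.ifft2(ft).real
            cx, cy = corners[p]
            frames[f, cy:cy + box, cx:cx + box] += img
        if noise_sigma > 0:
            frames[f] += rng.normal(0.0, noise_sigma, size=(ny, nx))

    movie = MicrographMovie(frames=frames, pixel_size=px,
                            dose_per_frame=dose_per_frame)
    truth = GroundTruth(trajectories=trajs, frame_attenuation=atten_ref,
                        reference_s=reference_s)
    return movie, truth


def extract_particle_movie(movie: MicrographMovie, position_A: np.ndarray,
                           box: int) -> MicrographMovie:
    """Crop the fixed ``box``-pixel window whose corner is at ``position_A``."""
    cx, cy = np.round(np.asarray(position_A, dtype=float)
                      / movie.pixel_size).astype(int)
    sub = movie.frames[:, cy:cy + box, cx:cx + box]
    if sub.shape[1:] != (box, box):
        raise ValueError("particle window extends beyond the micrograph")
    return MicrographMovie(frames=sub.copy(), pixel_size=movie.pixel_size,
                           dose_per_frame=movie.dose_per_frame,
                           frame_rate=movie.frame_rate)


# ---------------------------------------------------------------------------
# Apo/holo pairs with a sub-stoichiometric ligand

def make_ligand_pair(phantom: DensityMap, ligand_center_A: np.ndarray,
                     ligand_amplitude: float, occupancy: float, seed: int = 0,
                     ligand_sigma_A: float | None = None,
                     noise_sigma: float = 0.0,
                     ) -> tuple[DensityMap, DensityMap]:
    """Apo/holo map pair: holo = apo + occupancy·ligand (+ independent noise).

    The ligand is a Gaussian blob of peak ``ligand_amplitude`` at
    ``ligand_center_A``; ``occupancy`` scales its density linearly, the way a
    fractionally occupied binding site scales the ligand's contribution to a
    reconstruction averaged over many particles.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    center = np.asarray(ligand_center_A, dtype=float)
    extent = np.array(phantom.shape) * phantom.voxel_size
    if np.any(center < 0) or np.any(center >= extent):
        raise ValueError(f"ligand center {center} outside the map box {extent}")
    if ligand_sigma_A is None:
        ligand_sigma_A = 3.0 * phantom.voxel_size
    ligand = gaussian_blob(phantom.shape, phantom.voxel_size, center,
                           ligand_amplitude, ligand_sigma_A)
    rng = np.random.default_rng(seed)
    apo_data = phantom.data.copy()
    holo_data = phantom.data + occupancy * ligand
    if noise_sigma > 0:
        apo_data = apo_data + rng.normal(0, noise_sigma, phantom.shape)
        holo_data = holo_data + rng.normal(0, noise_sigma, phantom.shape)
    return phantom.copy(data=apo_data), phantom.copy(data=holo_data)


# ---------------------------------------------------------------------------
# Known-orientation reconstruction (direct Fourier-slice insertion)

def reconstruct_known_angles(particle_images, orientations,
                             voxel_size: float) -> DensityMap:
    """Reconstruct a 3D map from 2D projections with known orientations.

    Each image's 2D FFT is inserted as a central slice into the 3D Fourier
    volume with trilinear spreading; accumulated values are divided by the
    accumulated interpolation weights.  Orientation refinement is out of
    scope: angles are taken as given.
    """
    images = [np.asarray(im, dtype=float) for im in particle_images]
    rots = [np.asarray(r, dtype=float) for r in orientations]
    if len({im.shape for im in images}) != 1:
        raise ValueError("all particle images must share one shape")
    if len(images) != len(rots):
        raise ValueError("need one orientation per image")
    uniq = {np.round(r, 6).tobytes() for r in rots}
    if len(uniq) < 3:
        raise ValueError("need >= 3 distinct orientations")
    view_axes = np.stack([r[2] for r in rots])
    if np.linalg.matrix_rank(np.round(view_axes, 9)) < 3:
        warnings.warn("all projection axes are coplanar: expect missing-cone "
                      "artifacts", stacklevel=2)

    n = images[0].shape[0]
    accum = np.zeros((n, n, n), dtype=complex)
    weights = np.zeros((n, n, n))
    for img, rot in zip(images, rots):
        # images are (y, x); the slice grid is indexed (x, y); the image
        # center goes to the DFT origin so slice values vary smoothly
        slc = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img.T)))
        coords = _slice_coords(n, rot).reshape(-1, 3)
        vals = slc.reshape(-1)
        base = np.floor(coords).astype(int)
        frac = coords - base
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = base + off
            w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
            ok = np.all((idx >= 0) & (idx < n), axis=1)
            flat = np.ravel_multi_index(idx[ok].T, (n, n, n))
            np.add.at(accum.reshape(-1), flat, vals[ok] * w[ok])
            np.add.at(weights.reshape(-1), flat, w[ok])
    filled = weights > 1e-8
    f3 = np.zeros_like(accum)
    f3[filled] = accum[filled] / weights[filled]
    data = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(f3))).real
    return DensityMap(data=data, voxel_size=voxel_size)
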