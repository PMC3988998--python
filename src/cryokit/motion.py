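"""Per-particle motion tracking across movie frames.

The tracker measures each particle's drift relative to a self-consistent
average of its own frames, using band-limited, noise-weighted (per-shell
whitened) cross-correlation.  Because single frames of small particles are
too noisy for a reliable correlation peak, frames are replaced by running
averages over an odd window (11 by default, 5 when neighbor pooling supplies
extra signal), and the per-frame correlation surfaces of all particles
within a pooling radius (1000 Å by default) can be summed before peak
finding, exploiting the spatial coherence of beam-induced motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volmap import MicrographMovie

__all__ = [
    "CorrelationSettings",
    "CorrelationPeak",
    "Trajectory",
    "running_average",
    "noise_weighted_xcorr",
    "find_peak",
    "track_particle",
    "track_micrograph",
    "pool_neighbors",
    "apply_shifts_sum",
]


@dataclass
class CorrelationSettings:
    """Parameters of the band-limited noise-weighted cross-correlation.

    ``band_low``/``band_high`` are resolution limits in Å (default 200→25 Å,
    i.e. Fourier components with 1/200 ≤ |s| ≤ 1/25 Å⁻¹); ``window`` is the
    running-average length in frames (odd); ``neighbor_radius`` the pooling
    radius in Å.  ``whiten`` toggles per-shell amplitude whitening (off =
    plain band-passed correlation).  ``fixed_pattern_guard`` zeroes the
    zero-shift correlation value and its 4-neighborhood before peak search to
    suppress residual detector fixed-pattern signal; ``exclude_axial_lines``
    removes the kx=0 / ky=0 Fourier lines for the same reason.  Both are off
    by default (synthetic data carries no fixed pattern).
    """

    box: int = 256
    band_low: float = 200.0
    band_high: float = 25.0
    window: int = 11
    neighbor_radius: float = 1000.0
    max_iterations: int = 10
    tol: float = 0.05
    whiten: bool = True
    fixed_pattern_guard: bool = False
    exclude_axial_lines: bool = False

    def __post_init__(self) -> None:
        if self.band_low <= self.band_high:
            raise ValueError("band_low (Å) must exceed band_high (Å)")
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be odd and >= 1")
        if self.neighbor_radius < 0:
            raise ValueError("neighbor_radius must be >= 0")


@dataclass
class CorrelationPeak:
    dx: float
    dy: float
    height: float
    confidence: float  # peak height / surface RMS


@dataclass
class Trajectory:
    """Per-frame 2D shifts (px) of one particle, relative to its average."""

    particle_id: int
    shifts: np.ndarray                 # (n_frames, 2) as (dx, dy)
    peak_confidence: np.ndarray = field(default=None)
    window: int = 1
    converged: bool = True

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.peak_confidence is None:
            self.peak_confidence = np.zeros(len(self.shifts))
        if np.any(np.asarray(self.peak_confidence) < 0):
            raise ValueError("confidence must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.shifts)


# ---------------------------------------------------------------------------

def running_average(frames: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window mean over frames, window clipped at the stack ends.

    Frame f is replaced by the mean of frames [f−w//2, f+w//2] intersected
    with the stack, so the output has the input's length and the effective
    window shrinks near the ends.
    """
    frames = np.asarray(frames)
    n = frames.shape[0]
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not 1 <= window <= n:
        raise ValueError(f"window must lie in [1, {n}]")
    if window == 1:
        return frames.copy()
    half = window // 2
    csum = np.cumsum(frames, axis=0, dtype=float)
    csum = np.concatenate([np.zeros((1,) + frames.shape[1:]), csum], axis=0)
    out = np.empty_like(frames, dtype=float)
    for f in range(n):
        lo, hi = max(0, f - half), min(n, f + half + 1)
        out[f] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _window_centers(n: int, window: int) -> np.ndarray:
    """Effective center frame of each clipped running-average window.

    Interior windows are centered on their frame; at the stack ends the
    clipped window's centroid moves inward, so a shift measured from it
    belongs to that centroid, not the frame index.
    """
    half = window // 2
    centers = np.empty(n)
    for f in range(n):
        lo, hi = max(0, f - half), min(n, f + half + 1)
        centers[f] = (lo + hi - 1) / 2.0
    return centers


def _centers_to_frames(estimates: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Linearly interpolate window-center shift estimates onto frame indices,
    extrapolating at the stack ends."""
    n = len(estimates)
    frames = np.arange(n, dtype=float)
    out = np.empty_like(estimates)
    for axis in range(estimates.shape[1]):
        slope_lo = ((estimates[1, axis] - estimates[0, axis])
                    / max(centers[1] - centers[0], 1e-9))
        slope_hi = ((estimates[-1, axis] - estimates[-2, axis])
                    / max(centers[-1] - centers[-2], 1e-9))
        out[:, axis] = np.interp(frames, centers, estimates[:, axis])
        below = frames < centers[0]
        above = frames > centers[-1]
        out[below, axis] = estimates[0, axis] + slope_lo * (frames[below] - centers[0])
        out[above, axis] = estimates[-1, axis] + slope_hi * (frames[above] - centers[-1])
    return out


_shell_cache: dict = {}


def _shells_2d(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    key = (shape, round(pixel_size, 9))
    if key not in _shell_cache:
        fy = np.fft.fftfreq(shape[0], d=pixel_size)
        fx = np.fft.fftfreq(shape[1], d=pixel_size)
        smag = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
        nyq = 1.0 / (2.0 * pixel_size)
        n_shells = max(shape) // 2
        idx = np.minimum(np.rint(smag / nyq * n_shells).astype(np.int32),
                         n_shells - 1)
        _shell_cache[key] = (smag, idx, n_shells)
    return _shell_cache[key]


def _whiten(ft: np.ndarray, shell_idx: np.ndarray, n_shells: int,
            band: np.ndarray) -> np.ndarray:
    """Scale each Fourier shell (within the band) to unit mean power."""
    sel = band
    power = np.bincount(shell_idx[sel], weights=np.abs(ft[sel]) ** 2,
                        minlength=n_shells)
    counts = np.bincount(shell_idx[sel], minlength=n_shells)
    mean_power = np.where(counts > 0, power / np.maximum(counts, 1), 1.0)
    scale = np.zeros(n_shells)
    nz = mean_power > 0
    scale[nz] = 1.0 / np.sqrt(mean_power[nz])
    return ft * scale[shell_idx]


def noise_weighted_xcorr(image: np.ndarray, reference: np.ndarray,
                         settings: CorrelationSettings, pixel_size: float,
                         ) -> tuple[np.ndarray, CorrelationPeak]:
    """Band-limited, whitened cross-correlation of an image with a reference.

    Only Fourier components with 1/band_low ≤ |s| ≤ 1/band_high contribute.
    Returns the (unshifted, circular) correlation surface and the sub-pixel
    peak; a positive (dx, dy) means the image content sits at +(dx, dy) px
    relative to the reference.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != np.asarray(reference).shape:
        raise ValueError("image and reference must share a shape")
    smag, shell_idx, n_shells = _shells_2d(image.shape, pixel_size)
    nyq = 1.0 / (2.0 * pixel_size)
    s_lo, s_hi = 1.0 / settings.band_low, min(1.0 / settings.band_high, nyq)
    band = (smag >= s_lo) & (smag <= s_hi)
    if settings.exclude_axial_lines:
        fy = np.fft.fftfreq(image.shape[0], d=pixel_size)
        fx = np.fft.fftfreq(image.shape[1], d=pixel_size)
        band &= (fy[:, None] != 0) & (fx[None, :] != 0)
    if not np.any(band):
        raise ValueError(f"empty frequency band [{s_lo:.4g}, {s_hi:.4g}] Å⁻¹ "
                         f"for this box/pixel size")
    fa = np.fft.fft2(image)
    fb = np.fft.fft2(np.asarray(reference, dtype=float))
    if settings.whiten:
        fa = _whiten(fa, shell_idx, n_shells, band)
        fb = _whiten(fb, shell_idx, n_shells, band)
    prod = np.where(band, fa * np.conj(fb), 0.0)
    cc = np.fft.ifft2(prod).real / band.sum()
    peak = find_peak(cc, guard=settings.fixed_pattern_guard)
    return cc, peak


def find_peak(cc: np.ndarray, guard: bool = False) -> CorrelationPeak:
    """Locate the correlation peak to sub-pixel precision (3×3 quadratic fit).

    With ``guard`` the zero-shift value and its 4-neighborhood are zeroed
    first (fixed-pattern suppression).  Shifts are reported in the circular
    convention, wrapped to (−n/2, n/2].
    """
    work = cc.copy() if guard else cc
    if guard:
        for (i, j) in [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]:
            work[i % cc.shape[0], j % cc.shape[1]] = 0.0
    iy, ix = np.unravel_index(np.argmax(work), work.shape)
    h = work[iy, ix]

    def _subpix(axis: int, idx: int) -> float:
        minus = work[(iy - 1) % work.shape[0], ix] if axis == 0 else \
            work[iy, (ix - 1) % work.shape[1]]
        plus = work[(iy + 1) % work.shape[0], ix] if axis == 0 else \
            work[iy, (ix + 1) % work.shape[1]]
        denom = minus - 2.0 * h + plus
        if denom >= 0 or abs(denom) < 1e-30:
            return 0.0
        return float(np.clip(0.5 * (minus - plus) / denom, -0.5, 0.5))

    dy = iy + _subpix(0, iy)
    dx = ix + _subpix(1, ix)
    ny, nx = work.shape
    if dy > ny / 2:
        dy -= ny
    if dx > nx / 2:
        dx -= nx
    rms = float(np.sqrt(np.mean(work ** 2)))
    conf = float(h / rms) if rms > 0 else 0.0
    return CorrelationPeak(dx=float(dx), dy=float(dy), height=float(h),
                           confidence=max(conf, 0.0))


# ---------------------------------------------------------------------------

def _aligned_average(frames: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    out = np.zeros(frames.shape[1:])
    for frame, (dx, dy) in zip(frames, shifts):
        ft = ndimage.fourier_shift(np.fft.fft2(frame), (-dy, -dx))
        out += np.fft.ifft2(ft).real
    return out / len(frames)


def track_particle(particle_movie: MicrographMovie,
                   settings: CorrelationSettings | None = None,
                   particle_id: int = 0) -> Trajectory:
    """Track one particle against its self-consistent average.

    Iteratively: build the average of the currently aligned frames, correlate
    each running-averaged frame against it, update the per-frame shifts
    (re-centered to zero mean), and repeat until the largest shift update
    falls below ``settings.tol`` px or ``max_iterations`` is reached.  The
    returned shifts are relative to the average particle position.
    """
    settings = settings or CorrelationSettings()
    frames = particle_movie.frames
    n = frames.shape[0]
    if n < settings.window:
        raise ValueError(f"need at least window={settings.window} frames, got {n}")
    px = particle_movie.pixel_size
    shifts = np.zeros((n, 2))
    conf = np.zeros(n)
    converged = False
    ra = running_average(frames, settings.window)
    centers = _window_centers(n, settings.window)
    for _ in range(settings.max_iterations):
        ref = _aligned_average(frames, shifts)
        est = np.empty_like(shifts)
        for f in range(n):
            _, peak = noise_weighted_xcorr(ra[f], ref, settings, px)
            est[f] = (peak.dx, peak.dy)
            conf[f] = peak.confidence
        new = _centers_to_frames(est, centers) if settings.window > 1 else est
        new -= new.mean(axis=0)
        delta = np.max(np.abs(new - shifts))
        shifts = new
        if delta < settings.tol:
            converged = True
            break
    return Trajectory(particle_id=particle_id, shifts=shifts,
                      peak_confidence=conf, window=settings.window,
                      converged=converged)


def pool_neighbors(cc_surfaces: np.ndarray, particle_positions: np.ndarray,
                   radius: float, guard: bool = False) -> list[Trajectory]:
    """Sum per-frame correlation surfaces over neighbors before peak finding.

    ``cc_surfaces`` has shape (n_particles, n_frames, ny, nx); positions are
    particle centers in Å on the micrograph.  For each particle the surfaces
    of all particles within ``radius`` Å (always including itself) are summed
    per frame and the peak of the pooled surface gives the shift.  Radius 0
    degrades gracefully to unpooled peak finding.
    """
    cc_surfaces = np.asarray(cc_surfaces)
    positions = np.atleast_2d(np.asarray(particle_positions, dtype=float))
    n_p, n_f = cc_surfaces.shape[:2]
    dist = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    trajectories = []
    for p in range(n_p):
        members = np.where(dist[p] <= radius)[0]
        pooled = cc_surfaces[members].sum(axis=0)
        shifts = np.empty((n_f, 2))
        conf = np.empty(n_f)
        for f in range(n_f):
            pk = find_peak(pooled[f], guard=guard)
            shifts[f] = (pk.dx, pk.dy)
            conf[f] = pk.confidence
        shifts -= shifts.mean(axis=0)
        trajectories.append(Trajectory(particle_id=p, shifts=shifts,
                                       peak_confidence=conf))
    return trajectories


def track_micrograph(movie: MicrographMovie, particle_positions: np.ndarray,
                     settings: CorrelationSettings | None = None,
                     box: int | None = None) -> list[Trajectory]:
    """Track all particles on a micrograph with neighbor pooling.

    ``particle_positions`` are box-corner coordinates in Å (as used by the
    simulator); pooling distances are measured between box centers.  Each
    iteration recomputes every particle's correlation surfaces against its
    own aligned average, pools them within ``settings.neighbor_radius``, and
    updates all trajectories jointly.
    """
    from .synth import extract_particle_movie

    settings = settings or CorrelationSettings()
    positions = np.atleast_2d(np.asarray(particle_positions, dtype=float))
    box = box or settings.box
    px = movie.pixel_size
    movies = [extract_particle_movie(movie, pos, box) for pos in positions]
    centers = positions + box * px / 2.0
    n_p, n_f = len(movies), movie.n_frames
    shifts = np.zeros((n_p, n_f, 2))
    ras = [running_average(m.frames, settings.window) for m in movies]
    trajectories = None
    converged = False
    for _ in range(settings.max_iterations):
        surfaces = np.empty((n_p, n_f) + movies[0].frames.shape[1:])
        for p in range(n_p):
            ref = _aligned_average(movies[p].frames, shifts[p])
            for f in range(n_f):
                cc, _ = noise_weighted_xcorr(ras[p][f], ref, settings, px)
                surfaces[p, f] = cc
        trajectories = pool_neighbors(surfaces, centers,
                                      settings.neighbor_radius,
                                      guard=settings.fixed_pattern_guard)
        wcenters = _window_centers(n_f, settings.window)
        updated = []
        for t in trajectories:
            s = _centers_to_frames(t.shifts, wcenters) \
                if settings.window > 1 else t.shifts
            t.shifts = s - s.mean(axis=0)
            updated.append(t.shifts)
        new = np.stack(updated)
        delta = np.max(np.abs(new - shifts))
        shifts = new
        if delta < settings.tol:
            converged = True
            break
    for t in trajectories:
        t.window = settings.window
        t.converged = converged
    return trajectories


def apply_shifts_sum(movie: MicrographMovie, trajectory: Trajectory,
                     frame_subset: np.ndarray | None = None) -> np.ndarray:
    """Undo the tracked shifts and sum the selected frames.

    Each frame is shifted by −shift with a Fourier phase ramp (circular;
    exact roll for integer shifts) and the shifted frames are summed.
    """
    frames = movie.frames
    subset = np.arange(frames.shape[0]) if frame_subset is None \
        else np.asarray(frame_subset)
    if subset.max() >= trajectory.n_frames:
        raise ValueError("trajectory does not cover the requested frames")
    if np.max(np.abs(trajectory.shifts[subset])) > frames.shape[-1] / 4:
        warnings.warn("shifts exceed box/4: wrap-around may corrupt the sum",
                      stacklevel=2)
    out = np.zeros(frames.shape[1:])
    for f in subset:
        dx, dy = trajectory.shifts[f]
        ft = ndimage.fourier_shift(np.fft.fft2(frames[f]), (-dy, -dx))
        out += np.fft.ifft2(ft).real
    return out
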