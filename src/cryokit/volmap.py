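"""Core data containers and MRC volume/stack I/O.

All physical coordinates and lengths are in ångström (Å); spatial
frequencies are in Å⁻¹.  Map voxel grids are stored as numpy arrays whose
axis 0 corresponds to the MRC X (fast) axis, matching how gemmi exposes
CCP4/MRC grids.  Movie frame stacks are stored as ``(n_frames, ny, nx)``
arrays and written as MRC image stacks with one section per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "DensityMap",
    "MicrographMovie",
    "FrequencyShells",
    "FscCurve",
    "MapFormatError",
    "read_map",
    "write_map",
    "read_movie",
    "write_movie",
    "make_shells",
    "shell_average",
    "detector_sampling",
    "nyquist_resolution",
    "write_curve_tsv",
    "read_curve_tsv",
]


class MapFormatError(ValueError):
    """Raised when an MRC file cannot be interpreted."""


@dataclass
class DensityMap:
    """A 3D scalar density grid.

    Parameters
    ----------
    data:
        3D array of density values; axis 0 is the MRC X (fast) axis.
    voxel_size:
        Isotropic voxel edge length in Å.
    origin:
        Physical coordinate of voxel (0, 0, 0) in Å.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"map data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 2:
            raise ValueError(f"grid dimensions must be >= 2, got {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def nyquist(self) -> float:
        """Nyquist spatial frequency 1/(2·voxel_size) in Å⁻¹."""
        return 1.0 / (2.0 * self.voxel_size)

    def copy(self, data: np.ndarray | None = None) -> "DensityMap":
        return DensityMap(
            data=self.data.copy() if data is None else data,
            voxel_size=self.voxel_size,
            origin=self.origin.copy(),
        )


@dataclass
class MicrographMovie:
    """A stack of exposure frames from one micrograph.

    ``frames`` has shape ``(n_frames, ny, nx)``; ``pixel_size`` is Å/px;
    ``dose_per_frame`` is the electron exposure per frame in el/Å².
    """

    frames: np.ndarray
    pixel_size: float
    dose_per_frame: float = 1.0
    frame_rate: float = 18.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, ny, nx) stack with >= 1 frame")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.dose_per_frame < 0:
            raise ValueError("dose_per_frame must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def accumulated_dose(self) -> np.ndarray:
        """Dose accumulated *before the end of* each frame, in el/Å²."""
        return self.dose_per_frame * np.arange(1, self.n_frames + 1)


@dataclass
class FrequencyShells:
    """Assignment of every Fourier voxel to a spherical frequency shell.

    ``shell_index`` has the shape of the (full) FFT grid; voxels beyond
    Nyquist carry index −1 and are excluded from all shell sums.
    """

    shell_index: np.ndarray
    shell_centers: np.ndarray
    n_shells: int
    voxel_size: float

    @property
    def counts(self) -> np.ndarray:
        """Number of Fourier voxels in each shell."""
        idx = self.shell_index[self.shell_index >= 0]
        return np.bincount(idx, minlength=self.n_shells)


@dataclass
class FscCurve:
    """Fourier shell correlation per frequency shell."""

    s: np.ndarray
    fsc: np.ndarray
    n_voxels: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels)
        if len(self.s) != len(self.fsc):
            raise ValueError("s and fsc must have equal length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")


# ---------------------------------------------------------------------------
# MRC I/O (via gemmi)

def _gemmi_map_from_array(xyz_data: np.ndarray, voxel_size: float,
                          origin: np.ndarray) -> gemmi.Ccp4Map:
    grid = gemmi.FloatGrid(np.ascontiguousarray(xyz_data, dtype=np.float32))
    nx, ny, nz = xyz_data.shape
    grid.set_unit_cell(gemmi.UnitCell(nx * voxel_size, ny * voxel_size,
                                      nz * voxel_size, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), origin):
        m.set_header_float(word, float(value))
    return m


def write_map(density_map: DensityMap, path) -> None:
    """Write a :class:`DensityMap` as an MRC2014 file (mode 2, float32)."""
    m = _gemmi_map_from_array(density_map.data, density_map.voxel_size,
                              density_map.origin)
    m.write_ccp4_map(str(path))


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 map file into a :class:`DensityMap`."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC map {path!s}: {exc}") from exc
    data = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    sizes = np.array([cell.a, cell.b, cell.c]) / np.array(data.shape)
    if not np.allclose(sizes, sizes[0], rtol=1e-4):
        raise MapFormatError(
            f"anisotropic voxel size {sizes} unsupported (header CELLA/M fields)")
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    return DensityMap(data=data, voxel_size=float(sizes[0]), origin=origin)


def write_movie(movie: MicrographMovie, path) -> None:
    """Write a movie as an MRC image stack (NX, NY fast axes; NZ = frames)."""
    xyz = np.ascontiguousarray(np.transpose(movie.frames, (2, 1, 0)))
    grid = gemmi.FloatGrid(xyz.astype(np.float32))
    nx, ny, nz = xyz.shape
    # unit cell Z length carries no physical meaning for a stack
    grid.set_unit_cell(gemmi.UnitCell(nx * movie.pixel_size, ny * movie.pixel_size,
                                      nz * movie.pixel_size, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_movie(path, dose_per_frame: float = 1.0,
               frame_rate: float = 18.0) -> MicrographMovie:
    """Read an MRC image stack written by :func:`write_movie`."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC stack {path!s}: {exc}") from exc
    xyz = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    px = np.array([cell.a, cell.b]) / np.array(xyz.shape[:2])
    if not np.allclose(px, px[0], rtol=1e-4):
        raise MapFormatError(f"anisotropic pixel size {px} unsupported")
    frames = np.transpose(xyz, (2, 1, 0))
    return MicrographMovie(frames=frames, pixel_size=float(px[0]),
                           dose_per_frame=dose_per_frame, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# Fourier-shell bookkeeping

def frequency_grid(shape: tuple[int, ...], voxel_size: float) -> np.ndarray:
    """|s| in Å⁻¹ for every voxel of the full FFT grid of ``shape``."""
    axes = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(sum(g ** 2 for g in grids))


def make_shells(grid_shape: tuple[int, ...], voxel_size, n_shells: int) -> FrequencyShells:
    """Partition the Fourier grid into ``n_shells`` radial shells up to Nyquist.

    Shell k is centered at s_k = k · Nyquist / n_shells; each in-band Fourier
    voxel is assigned to the nearest shell center (DC term in shell 0; exact
    half-way ties round to the higher shell).  Voxels with |s| > Nyquist get
    index −1.
    """
    voxel_size = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if voxel_size.size > 1 and not np.allclose(voxel_size, voxel_size[0]):
        raise ValueError(f"anisotropic voxel size {voxel_size} unsupported")
    v = float(voxel_size.flat[0])
    if n_shells < 2:
        raise ValueError("n_shells must be >= 2")
    nyq = 1.0 / (2.0 * v)
    smag = frequency_grid(tuple(grid_shape), v)
    r = smag * 2.0 * v * n_shells  # |s| / (Nyquist/n_shells)
    idx = np.floor(r + 0.5).astype(np.int32)  # round half up
    idx[smag > nyq * (1 + 1e-9)] = -1
    np.clip(idx, -1, n_shells - 1, out=idx)
    centers = np.arange(n_shells) * nyq / n_shells
    return FrequencyShells(shell_index=idx, shell_centers=centers,
                           n_shells=n_shells, voxel_size=v)


def shell_average(values: np.ndarray, shells: FrequencyShells) -> np.ndarray:
    """Mean of ``values`` (same shape as the FFT grid) per shell."""
    mask = shells.shell_index >= 0
    idx = shells.shell_index[mask]
    sums = np.bincount(idx, weights=values[mask].real, minlength=shells.n_shells)
    counts = np.bincount(idx, minlength=shells.n_shells)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


# ---------------------------------------------------------------------------
# Small physical helpers

def detector_sampling(detector_pixel_um: float, magnification: float) -> float:
    """Specimen-level sampling in Å/px from detector pixel (µm) and magnification.

    A 14 µm physical detector pixel at 80,240× magnification samples the
    specimen at 14e4 Å / 80,240 ≈ 1.75 Å/px.
    """
    if magnification <= 0:
        raise ValueError("magnification must be > 0")
    return detector_pixel_um * 1.0e4 / magnification


def nyquist_resolution(pixel_size: float) -> float:
    """Finest resolvable spacing (Å) at sampling ``pixel_size`` Å/px: 2·pixel."""
    return 2.0 * pixel_size


# ---------------------------------------------------------------------------
# Curve TSV I/O (columns: shell, s_invA, value)

def write_curve_tsv(curve: FscCurve, path) -> None:
    df = pd.DataFrame({"shell": np.arange(len(curve.s)), "s_invA": curve.s,
                       "value": curve.fsc})
    df.to_csv(path, sep="\t", index=False)


def read_curve_tsv(path) -> FscCurve:
    df = pd.read_csv(path, sep="\t")
    return FscCurve(s=df["s_invA"].to_numpy(), fsc=df["value"].to_numpy(),
                    n_voxels=np.zeros(len(df), dtype=int))
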