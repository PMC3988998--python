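"""Difference-map computation and ligand-occupancy estimation.

Subtracting a scale-matched apo (unliganded) map from a holo (complex) map
isolates the ligand density; because a reconstruction averages over
particles, a site occupied in a fraction θ of particles shows ligand density
at a fraction θ of full height.  Two independent estimators are provided:
the ratio of the difference-map peak to a reference peak in the protein
region, and a scan of map-vs-model FSC over composite models with variable
ligand occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fscres import fsc as _fsc
from .volmap import DensityMap, FrequencyShells

__all__ = [
    "DiffStats",
    "OccupancyEstimate",
    "OccupancyScan",
    "sphere_region",
    "match_scale",
    "difference_map",
    "diff_stats",
    "occupancy_from_peaks",
    "occupancy_from_model_fsc",
]


@dataclass
class DiffStats:
    peak_value: float          # maximum in the ligand/difference region
    peak_location: tuple       # voxel index of that maximum
    rms: float                 # RMS density of the whole difference map
    peak_to_rms: float
    protein_peak: float        # maximum in the protein reference region
    peak_ratio: float          # difference peak / protein peak


@dataclass
class OccupancyEstimate:
    value: float
    flagged: bool = False      # True if the raw ratio exceeded 1


@dataclass
class OccupancyScan:
    best_occupancy: float
    table: pd.DataFrame        # columns: occupancy, score
    indeterminate: bool = False


def sphere_region(shape: tuple[int, ...], voxel_size: float,
                  center_A: np.ndarray, radius_A: float) -> np.ndarray:
    """Boolean spherical mask: voxels within ``radius_A`` of ``center_A``."""
    center = np.asarray(center_A, dtype=float)
    axes = [(np.arange(n) * voxel_size - c) ** 2 for n, c in zip(shape, center)]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return sum(grids) <= radius_A ** 2


def _check_grids(a: DensityMap, b: DensityMap) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")


def match_scale(map_a: DensityMap, map_b: DensityMap,
                region_mask: np.ndarray) -> float:
    """Least-squares scale k minimizing ‖A − k·B‖² over the mask.

    The mask should cover protein-only density (excluding the expected
    ligand region), otherwise the unmatched ligand signal biases k.
    """
    _check_grids(map_a, map_b)
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("region mask is empty")
    a, b = map_a.data[mask], map_b.data[mask]
    if np.ptp(b) == 0:
        raise ValueError("subtrahend map has zero variance in the mask")
    return float(np.dot(a, b) / np.dot(b, b))


def difference_map(holo: DensityMap, apo: DensityMap,
                   scale: float = 1.0) -> DensityMap:
    """holo − scale·apo, on identical grids, with no B-factor sharpening."""
    _check_grids(holo, apo)
    return holo.copy(data=holo.data - scale * apo.data)


def diff_stats(diff: DensityMap, ligand_region: np.ndarray,
               protein_region: np.ndarray,
               reference_map: DensityMap | None = None) -> DiffStats:
    """Peak and RMS statistics of a difference map.

    The RMS is taken over the whole difference map (solvent included).  The
    reference peak is the global maximum within the protein region of
    ``reference_map`` (normally the complex map the subtraction started
    from — in the difference map itself the protein density cancels); if no
    reference map is given the difference map is used.
    """
    lig = np.asarray(ligand_region, dtype=bool)
    prot = np.asarray(protein_region, dtype=bool)
    if not lig.any() or not prot.any():
        raise ValueError("ligand and protein regions must be non-empty")
    if np.any(lig & prot):
        raise ValueError("ligand and protein regions must be disjoint")
    data = diff.data
    masked = np.where(lig, data, -np.inf)
    peak_idx = np.unravel_index(np.argmax(masked), data.shape)
    peak = float(data[peak_idx])
    rms = float(np.sqrt(np.mean(data ** 2)))
    ref_data = diff.data if reference_map is None else reference_map.data
    if reference_map is not None:
        _check_grids(diff, reference_map)
    protein_peak = float(ref_data[prot].max())
    return DiffStats(
        peak_value=peak,
        peak_location=tuple(int(i) for i in peak_idx),
        rms=rms,
        peak_to_rms=peak / rms if rms > 0 else 0.0,
        protein_peak=protein_peak,
        peak_ratio=peak / protein_peak if protein_peak > 0 else 0.0,
    )


def occupancy_from_peaks(stats: DiffStats) -> OccupancyEstimate:
    """Occupancy as the difference-peak / protein-peak ratio.

    Valid when the ligand's intrinsic peak density matches the protein's
    (compact, well-ordered ligand); values above 1 are clamped to 1.2 and
    flagged.
    """
    ratio = stats.peak_ratio
    if stats.protein_peak <= 0:
        raise ValueError("protein reference peak must be positive")
    flagged = ratio > 1.0
    return OccupancyEstimate(value=float(np.clip(ratio, 0.0, 1.2)),
                             flagged=flagged)


def occupancy_from_model_fsc(experimental_map: DensityMap,
                             apo_model_map: DensityMap,
                             ligand_model_map: DensityMap,
                             occupancy_grid=np.arange(0.0, 1.0001, 0.05),
                             band: tuple[float, float] = (1.0 / 30.0, 1.0 / 15.0),
                             shells: FrequencyShells | None = None,
                             flat_tol: float = 1e-4) -> OccupancyScan:
    """Scan composite models apo + o·ligand for the best map-vs-model FSC.

    The score for each occupancy o is the mean FSC between the experimental
    map and the composite over the shell band ``band`` (Å⁻¹); the argmax over
    the grid is returned with the full table.  A score profile whose range is
    below ``flat_tol`` is flagged indeterminate.
    """
    grid = np.asarray(list(occupancy_grid), dtype=float)
    if len(grid) < 3 or grid.min() < 0 or grid.max() > 1:
        raise ValueError("occupancy_grid must have >= 3 points within [0, 1]")
    _check_grids(experimental_map, apo_model_map)
    _check_grids(experimental_map, ligand_model_map)
    scores = np.empty(len(grid))
    for i, o in enumerate(grid):
        composite = apo_model_map.copy(
            data=apo_model_map.data + o * ligand_model_map.data)
        curve = _fsc(experimental_map, composite, shells)
        sel = (curve.s >= band[0]) & (curve.s <= band[1])
        if not np.any(sel):
            raise ValueError(f"no FSC shells inside band {band} Å⁻¹")
        scores[i] = float(np.mean(curve.fsc[sel]))
    table = pd.DataFrame({"occupancy": grid, "score": scores})
    indeterminate = bool(np.ptp(scores) < flat_tol)
    best = float(grid[int(np.argmax(scores))])
    return OccupancyScan(best_occupancy=best, table=table,
                         indeterminate=indeterminate)
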