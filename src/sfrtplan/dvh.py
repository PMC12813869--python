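"""Cumulative dose-volume histograms and the DVH gamma comparison.

DVH curves use the at-or-above convention with exact voxel counting (no
smoothing); dose-at-volume queries interpolate linearly on the cumulative
curve, volume-at-dose queries count voxels exactly. The gamma comparison
operates on the absolute-volume (cc) axis with the 1%/1% convention: dose
criterion = 1% of the SFRT sum plan's maximum dose, volume criterion = 1%
of the structure volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseGrid
from .volumes import StructureMask


@dataclass
class DVHCurve:
    edges: np.ndarray = field(repr=False)       # Gy, uniform bin edges, ascending
    volume_cc: np.ndarray = field(repr=False)   # cc at-or-above each edge
    volume_pct: np.ndarray = field(repr=False)  # % of structure at-or-above
    label: str = ""
    total_cc: float = 0.0
    doses_sorted: np.ndarray = field(repr=False, default=None)  # Gy, ascending
    voxel_cc: float = 0.0

    @property
    def max_dose(self) -> float:
        return float(self.doses_sorted[-1])

    @property
    def min_dose(self) -> float:
        return float(self.doses_sorted[0])


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.01) -> DVHCurve:
    """Cumulative DVH of one structure by exact voxel counting."""
    if dose.grid != mask.grid:
        raise ValueError("dose and structure must share one grid")
    if mask.is_empty:
        raise ValueError(f"structure {mask.name!r} is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    doses = np.sort(dose.data[mask.data].astype(float))
    voxel_cc = mask.grid.voxel_volume_mm3 / 1000.0
    total_cc = doses.size * voxel_cc
    n_bins = int(np.floor(doses[-1] / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    counts = doses.size - np.searchsorted(doses, edges, side="left")
    volume_cc = counts * voxel_cc
    return DVHCurve(edges=edges, volume_cc=volume_cc,
                    volume_pct=volume_cc / total_cc * 100.0, label=mask.name,
                    total_cc=total_cc, doses_sorted=doses, voxel_cc=voxel_cc)


def volume_at_dose(dvh: DVHCurve, dose_gy: float) -> tuple[float, float]:
    """(percent, cc) of the structure receiving at least ``dose_gy``,
    exact from voxel counts."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    n_at_or_above = dvh.doses_sorted.size - np.searchsorted(dvh.doses_sorted, dose_gy, side="left")
    cc = float(n_at_or_above * dvh.voxel_cc)
    return cc / dvh.total_cc * 100.0, cc


def dose_at_volume(dvh: DVHCurve, pct: float | None = None, cc: float | None = None) -> float:
    """Dx% / Dx_cc: minimum dose to the hottest x% (or x cc) of the
    structure, linearly interpolated on the cumulative curve."""
    if (pct is None) == (cc is None):
        raise ValueError("give exactly one of pct or cc")
    if pct is not None:
        if not 0 < pct <= 100:
            raise ValueError(f"pct must be in (0, 100], got {pct}")
        target_cc = pct / 100.0 * dvh.total_cc
    else:
        if not 0 < cc <= dvh.total_cc:
            raise ValueError(f"cc must be in (0, {dvh.total_cc:.3f}], got {cc}")
        target_cc = cc
    # cumulative volume is non-increasing in dose; interpolate on reversed axes
    return float(np.interp(target_cc, dvh.volume_cc[::-1], dvh.edges[::-1]))


def _min_distance_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each point (m,2) to a polyline (k,2)."""
    a = poly[:-1]
    ab = poly[1:] - a
    denom = (ab * ab).sum(axis=1)
    denom[denom == 0] = 1.0
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def dvh_gamma(reference: DVHCurve, evaluated: DVHCurve, dose_criterion: float,
              volume_criterion: float) -> float:
    """DVH gamma pass rate (%) between two cumulative DVH curves.

    The evaluated curve is sampled at dose intervals of ``dose_criterion``
    (plus its terminal point); each sample's gamma is the minimum distance
    to the reference curve in criterion-normalized (dose, absolute-volume)
    space, and a sample passes when gamma <= 1.
    """
    if dose_criterion <= 0 or volume_criterion <= 0:
        raise ValueError("gamma criteria must be positive")
    if reference.total_cc <= 0 or evaluated.total_cc <= 0:
        raise ValueError("degenerate (zero-volume) structure")
    d_max = evaluated.max_dose
    sample_d = np.arange(int(np.floor(d_max / dose_criterion + 1e-12)) + 1,
                         dtype=float) * dose_criterion
    sample_v = np.array([volume_at_dose(evaluated, d)[1] for d in sample_d])
    sample_d = np.append(sample_d, d_max)
    sample_v = np.append(sample_v, 0.0)

    samples = np.column_stack([sample_d / dose_criterion, sample_v / volume_criterion])
    poly = np.column_stack([reference.edges / dose_criterion,
                            reference.volume_cc / volume_criterion])
    gamma = _min_distance_to_polyline(samples, poly)
    return float((gamma <= 1.0 + 1e-9).mean() * 100.0)
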