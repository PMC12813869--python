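"""Synthetic dose engine.

Stands in for a treatment planning system: an analytic lattice/SCART dose
field (uniform low-dose bath plus Gaussian-in-distance peaks over the vertex
target volume) and a conformal conventional-course field with a Gaussian
penumbra. The kernel scale sigma = 2.5 mm is chosen so the 15 Gy peak falls
below 1 Gy within ~5 mm of a vertex surface, which makes the valley goal
(< 5 Gy outside the peaks, on top of a <= 4 Gy/fraction bath) hold by
construction at >= 20 mm vertex spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import StructureMask, VoxelGrid


@dataclass(frozen=True)
class SfrtKernelParams:
    """Parameters of the analytic SFRT dose kernel (all Gy / mm)."""

    peak_dose: float = 15.0
    falloff_sigma: float = 2.5
    bath_dose: float = 4.0

    def __post_init__(self):
        if not self.peak_dose > self.bath_dose >= 0:
            raise ValueError("need peak_dose > bath_dose >= 0")
        if self.falloff_sigma <= 0:
            raise ValueError("falloff_sigma must be positive")


@dataclass
class DoseGrid:
    """Scalar dose per voxel (Gy) for one fraction or one course."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)
    label: str = "dose"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"dose array shape {self.data.shape} != grid {self.grid.shape}")

    def scaled(self, factor: float, label: str | None = None) -> "DoseGrid":
        return DoseGrid(self.grid, self.data * factor, label or self.label)


def sfrt_dose(grid: VoxelGrid, vertices=None, vtv: StructureMask | None = None,
              kernel: SfrtKernelParams = SfrtKernelParams()) -> DoseGrid:
    """Single-fraction SFRT dose field.

    dose(v) = bath + sum_i peak * exp(-(s_i/sigma)^2) with
    s_i = max(0, ||v - c_i|| - r_i), so the full peak dose covers each
    vertex sphere. With ``vertices`` (list of objects with ``center`` mm and
    ``diameter`` mm, or ``(center, diameter)`` tuples) each sphere is a
    kernel source; alternatively an arbitrary ``vtv`` mask (SCART core) is
    used with s = distance to the mask.
    """
    dose = np.full(grid.shape, kernel.bath_dose, dtype=float)
    inv_s2 = 1.0 / (kernel.falloff_sigma ** 2)
    if vertices:
        for v in vertices:
            center, diameter = (v.center, v.diameter) if hasattr(v, "center") else v
            s = np.sqrt(grid.distance_sq_to(center)) - diameter / 2.0
            np.maximum(s, 0.0, out=s)
            dose += kernel.peak_dose * np.exp(-(s * s) * inv_s2)
    elif vtv is not None and not vtv.is_empty:
        s = ndimage.distance_transform_edt(~vtv.data, sampling=grid.spacing)
        dose += kernel.peak_dose * np.exp(-(s * s) * inv_s2)
    else:
        raise ValueError("sfrt_dose needs a non-empty vertex list or VTV mask")
    return DoseGrid(grid, dose, "sfrt_fraction")


def conventional_dose(target: StructureMask, rx_per_fraction: float,
                      penumbra_sigma: float = 5.0) -> DoseGrid:
    """One conformal fraction: the prescription inside the target, Gaussian
    lateral fall-off with scale ``penumbra_sigma`` (mm) outside."""
    if rx_per_fraction <= 0:
        raise ValueError("rx_per_fraction must be positive")
    if penumbra_sigma <= 0:
        raise ValueError("penumbra_sigma must be positive")
    if target.is_empty:
        raise ValueError("conventional_dose needs a non-empty target")
    s = ndimage.distance_transform_edt(~target.data, sampling=target.grid.spacing)
    dose = rx_per_fraction * np.exp(-((s / penumbra_sigma) ** 2))
    return DoseGrid(target.grid, dose, f"conventional_{rx_per_fraction:g}Gy")


def cap_prescription(rx_per_fraction: float, cap: float = 4.0) -> float:
    """Cap the per-fraction PTV prescription used in the SFRT course at
    4 Gy/fraction; prescriptions at or under the cap are unchanged."""
    if rx_per_fraction <= 0:
        raise ValueError("rx_per_fraction must be positive")
    return min(rx_per_fraction, cap)
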