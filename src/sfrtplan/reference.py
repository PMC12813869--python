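"""The fully specified reference synthetic lattice plan.

One deterministic desk-scale plan used for end-to-end checks: a 67 cc
ellipsoidal GTV (semi-axes 40/20/20 mm) on a 1 mm isotropic grid, a 3 mm
PTV margin, three 14 mm vertices on the long axis spaced 25 mm apart, the
default analytic dose kernel (4 Gy bath + 15 Gy peaks, sigma 2.5 mm), and
the 5-10 mm shell ring for valley scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dose import DoseGrid, SfrtKernelParams, sfrt_dose
from .lattice import LatticeVTV, Vertex, rasterize_vtv
from .volumes import StructureMask, VoxelGrid, build_ring, ellipsoid_mask, expand


@dataclass
class ReferencePlan:
    grid: VoxelGrid
    gtv: StructureMask
    ptv: StructureMask
    vtv: StructureMask
    ring: StructureMask
    vertices: list[Vertex]
    dose: DoseGrid
    kernel: SfrtKernelParams


def reference_lattice_plan(spacing_mm: float = 1.0) -> ReferencePlan:
    """Build the reference plan (about 0.6 M voxels at 1 mm)."""
    semi = (40.0, 20.0, 20.0)
    pad = 16.0
    grid = VoxelGrid.centered((semi[0] + pad, semi[1] + pad, semi[2] + pad),
                              spacing=(spacing_mm,) * 3)
    gtv = ellipsoid_mask(grid, (0, 0, 0), semi, "GTV")
    ptv = expand(gtv, 3.0).with_name("PTV")
    vertices = [Vertex(center=(x, 0.0, 0.0), diameter=14.0) for x in (-25.0, 0.0, 25.0)]
    vtv = rasterize_vtv(grid, vertices, "VTV")
    ring = build_ring(vtv, outer_mm=10.0, inner_mm=-5.0, mode="shell")
    kernel = SfrtKernelParams()  # 15 Gy peak, sigma 2.5 mm, 4 Gy bath
    dose = sfrt_dose(grid, vertices=vertices, kernel=kernel)
    return ReferencePlan(grid=grid, gtv=gtv, ptv=ptv, vtv=vtv, ring=ring,
                         vertices=vertices, dose=dose, kernel=kernel)


def reference_lattice_vtv(plan: ReferencePlan) -> LatticeVTV:
    return LatticeVTV(vertices=plan.vertices, vtv_mask=plan.vtv, containment="GTV")
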