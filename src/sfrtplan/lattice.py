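"""LATTICE vertex placement for large targets (GTV > 15 cc).

Deterministic greedy sphere packing inside the tumor volume: candidate
voxel centers are ranked by interior (distance-to-surface) depth, visited
deepest-first with index order as the tie-break, and accepted when they
keep the required center-to-center spacing from every previously accepted
vertex. Vertices start at 8 mm diameter and grow (whole-mm steps) up to
15 mm as the local tumor thickness allows, capped so the vertex target
volume (VTV) never exceeds 10% of the GTV and every sphere keeps at least
1 cm surface clearance from critical organs at risk.

A spacing sweep (``tune_lattice``) replaces the manual resize/reposition
iterations of clinical planning: spacing is increased in 2.5 mm steps until
the valley-dose goal (ring V5Gy at or below 12%) is met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .volumes import (
    StructureMask,
    VoxelGrid,
    boolean,
    distance_to_mask,
    expand,
    interior_distance,
    sphere_mask,
)

LATTICE_THRESHOLD_CC = 15.0
EXCLUSION_FLOOR_CC = 3.0


class TargetTooSmallError(ValueError):
    """GTV below the 3 cc planning floor: SFRT offers no advantage."""


@dataclass(frozen=True)
class LatticePlacementConfig:
    initial_radius: float = 4.0      # mm
    diameter_min: float = 8.0        # mm
    diameter_max: float = 15.0       # mm
    spacing_initial: float = 25.0    # mm, center-to-center
    spacing_min: float = 20.0        # mm
    spacing_max: float = 40.0        # mm (sweep range, not a pairwise cap)
    oar_clearance: float = 10.0      # mm, vertex surface to OAR surface
    vgr_cap: float = 0.10            # VTV volume / GTV volume
    ring_v5_goal: float = 0.12       # tune_lattice valley goal (fraction)

    def __post_init__(self):
        if not self.diameter_min <= 2 * self.initial_radius <= self.diameter_max:
            raise ValueError("need diameter_min <= 2*initial_radius <= diameter_max")
        if not self.spacing_min <= self.spacing_initial <= self.spacing_max:
            raise ValueError("need spacing_min <= spacing_initial <= spacing_max")
        if self.spacing_min < self.diameter_max:
            raise ValueError("spacing_min must be >= diameter_max (non-overlap guarantee)")
        if not 0 < self.vgr_cap <= 1:
            raise ValueError("vgr_cap must be in (0, 1]")


@dataclass
class Vertex:
    center: tuple[float, float, float]  # mm, world coordinates
    diameter: float                     # mm
    clipped: bool = False


@dataclass
class LatticeVTV:
    vertices: list[Vertex]
    vtv_mask: StructureMask
    containment: str = "GTV"
    warnings: list[str] = field(default_factory=list)
    tuning_trace: list[dict] = field(default_factory=list)
    goal_met: bool | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class LatticeMetrics:
    n_vertices: int
    mvd: float                       # mean vertex diameter, mm
    mean_spacing: float | None       # mean nearest-neighbor center distance, mm
    vdsr: float | None               # mean_spacing / mvd
    vgr: float                       # VTV volume / GTV volume


def select_technique(gtv: StructureMask) -> str:
    """LATTICE for GTV > 15 cc, SCART for 3-15 cc; smaller targets are
    excluded from SFRT planning."""
    vol = gtv.volume_cc
    if vol < EXCLUSION_FLOOR_CC:
        raise TargetTooSmallError(
            f"GTV volume {vol:.2f} cc is below the {EXCLUSION_FLOOR_CC} cc floor"
        )
    return "LATTICE" if vol > LATTICE_THRESHOLD_CC else "SCART"


def _vertex_sphere(grid: VoxelGrid, vertex: Vertex) -> StructureMask:
    # open ball: keeps the sphere strictly inside the tumor when the
    # diameter saturates the local interior distance
    return sphere_mask(grid, vertex.center, vertex.diameter / 2.0, "vertex", closed=False)


def rasterize_vtv(grid: VoxelGrid, vertices: list[Vertex], name: str = "VTV") -> StructureMask:
    data = np.zeros(grid.shape, bool)
    for v in vertices:
        data |= _vertex_sphere(grid, v).data
    return StructureMask(grid, name, data)


def _oar_distance(grid: VoxelGrid, oars) -> np.ndarray:
    """Distance from each voxel center to the nearest OAR voxel (inf if none)."""
    if not oars:
        return np.full(grid.shape, np.inf)
    combined = np.zeros(grid.shape, bool)
    for oar in oars:
        if oar.grid != grid:
            raise ValueError("OAR masks must share the GTV grid")
        combined |= oar.data
    mask = StructureMask(grid, "oars", combined)
    return distance_to_mask(mask)


def place_vertices(gtv: StructureMask, config: LatticePlacementConfig = LatticePlacementConfig(),
                   oars=(), spacing: float | None = None) -> LatticeVTV:
    """Deterministic greedy packing of initial (8 mm) vertices.

    Candidates are voxel centers whose interior depth allows the initial
    sphere and whose would-be sphere surface clears every OAR by the
    configured margin; they are visited by decreasing interior depth
    (flat voxel index ascending as the tie-break) and accepted when at
    least ``spacing`` from every accepted center. Packing stops when the
    rasterized VTV would exceed the VGR cap.
    """
    if gtv.is_empty:
        raise ValueError("place_vertices requires a non-empty GTV")
    spacing = config.spacing_initial if spacing is None else float(spacing)
    grid = gtv.grid
    r0 = config.initial_radius

    depth = interior_distance(gtv)
    oar_dist = _oar_distance(grid, oars)
    feasible = (depth >= r0) & (oar_dist >= config.oar_clearance + r0)
    if not feasible.any():
        return LatticeVTV([], StructureMask(grid, "VTV", np.zeros(grid.shape, bool)),
                          warnings=["no candidate satisfies the radius/clearance constraints"])

    flat = np.flatnonzero(feasible.ravel())
    order = np.lexsort((flat, -depth.ravel()[flat]))
    idx = np.array(np.unravel_index(flat[order], grid.shape)).T  # (N, 3), greedy order
    coords = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)

    cap_mm3 = config.vgr_cap * gtv.volume_cc * 1000.0
    accepted: list[Vertex] = []
    vtv_data = np.zeros(grid.shape, bool)
    vtv_mm3 = 0.0
    remaining = coords
    while remaining.shape[0]:
        center = tuple(float(c) for c in remaining[0])
        vertex = Vertex(center=center, diameter=2 * r0)
        sphere = _vertex_sphere(grid, vertex)
        new_mm3 = vtv_mm3 + sphere.volume_cc * 1000.0  # disjoint: spacing >= diameter
        if new_mm3 > cap_mm3:
            break
        accepted.append(vertex)
        vtv_data |= sphere.data
        vtv_mm3 = new_mm3
        dist = np.linalg.norm(remaining - np.asarray(center), axis=1)
        remaining = remaining[dist >= spacing]

    return LatticeVTV(accepted, StructureMask(grid, "VTV", vtv_data), containment="GTV")


def diameter_for_depth(depth_mm: float, config: LatticePlacementConfig,
                       oar_dist_mm: float = math.inf) -> float:
    """Expanded diameter rule: whole-mm diameter bounded by twice the local
    interior depth, the OAR clearance, and the configured 8-15 mm range."""
    d = min(config.diameter_max, math.floor(2.0 * depth_mm))
    if math.isfinite(oar_dist_mm):
        d = min(d, math.floor(2.0 * (oar_dist_mm - config.oar_clearance)))
    return float(max(config.diameter_min, d))


def expand_vertices(lattice: LatticeVTV, gtv: StructureMask,
                    config: LatticePlacementConfig = LatticePlacementConfig(),
                    oars=()) -> LatticeVTV:
    """Grow each vertex (placement order) toward 15 mm as far as the tumor
    thickness, OAR clearance and the VGR cap allow; the first vertex that
    would cross the cap is left at its prior size and growth stops."""
    if not lattice.vertices:
        return lattice
    grid = gtv.grid
    depth = interior_distance(gtv)
    oar_dist = _oar_distance(grid, oars)
    spacing_arr = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)

    cap_mm3 = config.vgr_cap * gtv.volume_cc * 1000.0
    new_vertices = [replace(v) for v in lattice.vertices]
    volumes = [_vertex_sphere(grid, v).volume_cc * 1000.0 for v in new_vertices]
    total = sum(volumes)
    for i, v in enumerate(new_vertices):
        idx = tuple(np.round((np.asarray(v.center) - origin) / spacing_arr).astype(int))
        d_new = diameter_for_depth(float(depth[idx]), config, float(oar_dist[idx]))
        if d_new <= v.diameter:
            continue
        grown = replace(v, diameter=d_new)
        grown_mm3 = _vertex_sphere(grid, grown).volume_cc * 1000.0
        if total - volumes[i] + grown_mm3 > cap_mm3:
            break  # leave at prior size; stop growing
        total += grown_mm3 - volumes[i]
        volumes[i] = grown_mm3
        new_vertices[i] = grown
    vtv = rasterize_vtv(grid, new_vertices)
    return replace(lattice, vertices=new_vertices, vtv_mask=vtv)


def crop_vtv(lattice: LatticeVTV, gtv: StructureMask) -> LatticeVTV:
    """Crop the VTV to GTV + 2 mm (fallback when OAR constraints are unmet);
    clipped vertices keep their metadata with a flag."""
    if not lattice.vertices:
        return replace(lattice, containment="GTV_2mm")
    region = expand(gtv, +2.0)
    cropped = boolean(lattice.vtv_mask, region, "intersect").with_name("VTV")
    vertices = []
    for v in lattice.vertices:
        sphere = _vertex_sphere(gtv.grid, v)
        clipped = bool((sphere.data & ~region.data).any())
        vertices.append(replace(v, clipped=clipped))
    return replace(lattice, vertices=vertices, vtv_mask=cropped, containment="GTV_2mm")


def tune_lattice(gtv: StructureMask, config: LatticePlacementConfig = LatticePlacementConfig(),
                 oars=(), evaluator=None) -> LatticeVTV:
    """Spacing sweep standing in for manual resize/reposition iterations.

    ``evaluator(lattice) -> ring V5Gy fraction``. Sweeps spacing from
    spacing_initial to spacing_max in 2.5 mm steps (re-placing and
    re-expanding each time) and returns the first lattice meeting the
    valley goal; otherwise the best-effort lattice with ``goal_met=False``.
    """
    if evaluator is None:
        raise ValueError("tune_lattice requires an evaluator callback")
    trace: list[dict] = []
    best: LatticeVTV | None = None
    best_v5 = math.inf
    spacings = np.arange(config.spacing_initial, config.spacing_max + 1e-9, 2.5)
    for s in spacings:
        lat = place_vertices(gtv, config, oars=oars, spacing=float(s))
        lat = expand_vertices(lat, gtv, config, oars=oars)
        v5 = float(evaluator(lat))
        trace.append({"spacing_mm": float(s), "ring_v5_fraction": v5,
                      "n_vertices": lat.n_vertices})
        if v5 <= config.ring_v5_goal:
            return replace(lat, tuning_trace=trace, goal_met=True)
        if v5 < best_v5:
            best, best_v5 = lat, v5
    assert best is not None
    best = replace(best, tuning_trace=trace, goal_met=False)
    best.warnings.append(
        f"valley goal {config.ring_v5_goal:.0%} not met; best ring V5Gy {best_v5:.1%}"
    )
    return best


def lattice_metrics(lattice: LatticeVTV, gtv: StructureMask) -> LatticeMetrics:
    """Mean vertex diameter (MVD), mean nearest-neighbor spacing, the
    spacing-to-diameter ratio (VDSR), and the VTV-to-GTV ratio (VGR).
    Spacing and VDSR are undefined (None) for single-vertex lattices."""
    if not lattice.vertices:
        raise ValueError("lattice_metrics requires at least one vertex")
    diameters = np.array([v.diameter for v in lattice.vertices])
    mvd = float(diameters.mean())
    mean_spacing = vdsr = None
    if len(lattice.vertices) >= 2:
        centers = np.array([v.center for v in lattice.vertices])
        dists = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        mean_spacing = float(dists.min(axis=1).mean())
        vdsr = mean_spacing / mvd
    vgr = lattice.vtv_mask.volume_cc / gtv.volume_cc
    return LatticeMetrics(n_vertices=lattice.n_vertices, mvd=mvd,
                          mean_spacing=mean_spacing, vdsr=vdsr, vgr=vgr)
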