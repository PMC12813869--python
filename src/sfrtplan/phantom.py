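"""Synthetic cranial phantoms.

Stands in for patient CT and contours: an irregular gross tumor volume
(ellipsoidal, strip-like, or star-shaped), a planning target volume obtained
by a 2-15 mm expansion, a surrounding brain ellipsoid, and organ-at-risk
surrogates (a brainstem-like cylinder and a chiasm-like box) placed at a
configurable offset from the tumor. Everything is seeded and reproducible.

The generator emulates the geometry the planning rules operate on - tumor
volume, shape irregularity, and target/OAR adjacency - not image intensity,
tissue heterogeneity, or deliverability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import StructureMask, VoxelGrid, boolean, ellipsoid_mask, expand

GTV_MIN_CC = 3.0  # targets below this are excluded from planning

_ASPECTS = {
    "ellipsoid": (2.0, 1.0, 1.0),
    "strip": (3.5, 1.0, 0.6),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic patient geometry.

    gtv_shape: 'ellipsoid', 'strip', or 'star' (union of k random
    ellipsoids sharing one center). gtv_scale is the target GTV volume in
    cc (generated volume lands within 10%). ptv_margin follows the cohort's
    2-15 mm CTV+PTV margins. oar_gap_mm is the surface gap between the GTV
    and each OAR surrogate.
    """

    gtv_shape: str = "ellipsoid"
    gtv_scale: float = 30.0
    ptv_margin: float = 3.0
    oar_gap_mm: float = 15.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.gtv_shape not in ("ellipsoid", "strip", "star"):
            raise ValueError(f"unknown gtv_shape {self.gtv_shape!r}")
        if self.gtv_scale < GTV_MIN_CC:
            raise ValueError(
                f"gtv_scale {self.gtv_scale} cc is below the {GTV_MIN_CC} cc planning floor"
            )
        if not 2.0 <= self.ptv_margin <= 15.0:
            raise ValueError(f"ptv_margin must be in [2, 15] mm, got {self.ptv_margin}")


@dataclass
class Phantom:
    grid: VoxelGrid
    structures: dict[str, StructureMask]
    spec: PhantomSpec
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> StructureMask:
        return self.structures[name]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _star_lobes(rng: np.random.Generator, k: int):
    lobes = []
    for _ in range(k):
        rot = _random_rotation(rng)
        aspect = (rng.uniform(1.8, 2.8), rng.uniform(0.55, 0.85), rng.uniform(0.55, 0.85))
        lobes.append((rot, aspect))
    return lobes


def _rasterize_gtv(spec: PhantomSpec, grid: VoxelGrid, scale: float, lobes) -> np.ndarray:
    if spec.gtv_shape in _ASPECTS:
        aspect = _ASPECTS[spec.gtv_shape]
        semi = tuple(scale * a for a in aspect)
        return ellipsoid_mask(grid, (0, 0, 0), semi, "GTV").data
    data = np.zeros(grid.shape, bool)
    for rot, aspect in lobes:
        semi = tuple(scale * a for a in aspect)
        data |= ellipsoid_mask(grid, (0, 0, 0), semi, "lobe", rotation=rot).data
    return data


def _analytic_scale(spec: PhantomSpec) -> float:
    """Unit scale for the deterministic shapes; star starts from a sphere."""
    target_mm3 = spec.gtv_scale * 1000.0
    if spec.gtv_shape in _ASPECTS:
        prod = float(np.prod(_ASPECTS[spec.gtv_shape]))
        return (target_mm3 / (4.0 / 3.0 * np.pi * prod)) ** (1.0 / 3.0)
    return (target_mm3 / (4.0 / 3.0 * np.pi)) ** (1.0 / 3.0)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the structure set (GTV, PTV, brain, brainstem, chiasm).

    GTV subset of PTV subset of brain; OAR surrogates are disjoint from the
    GTV with >= oar_gap_mm surface clearance by construction.
    """
    rng = np.random.default_rng(spec.seed)
    lobes = _star_lobes(rng, int(rng.integers(3, 6))) if spec.gtv_shape == "star" else None
    scale = _analytic_scale(spec)

    # per-axis grid sizing: GTV + PTV margin + 10 mm ring + OAR surrogates +
    # brain rim, with a small calibration allowance on the GTV extents
    if spec.gtv_shape == "star":
        est_half = np.full(3, scale * 2.8 * 1.15)
    else:
        est_half = scale * np.array(_ASPECTS[spec.gtv_shape]) * 1.10
    half_x = est_half[0] + spec.oar_gap_mm + 16.0 + 14.0   # brainstem side
    half_y = est_half[1] + spec.oar_gap_mm + 8.0 + 14.0    # chiasm side
    half_z = max(est_half[2] + spec.ptv_margin, 20.0) + 14.0
    grid = VoxelGrid.centered((half_x, half_y, half_z), spec.spacing)

    target_mm3 = spec.gtv_scale * 1000.0
    gtv_data = _rasterize_gtv(spec, grid, scale, lobes)
    for _ in range(6):
        vol = gtv_data.sum() * grid.voxel_volume_mm3
        if vol > 0 and abs(vol - target_mm3) / target_mm3 <= 0.05:
            break
        scale *= (target_mm3 / max(vol, 1.0)) ** (1.0 / 3.0)
        gtv_data = _rasterize_gtv(spec, grid, scale, lobes)
    gtv = StructureMask(grid, "GTV", gtv_data)
    vol_cc = gtv.volume_cc
    if abs(vol_cc - spec.gtv_scale) / spec.gtv_scale > 0.10:
        raise ValueError(
            f"could not realize {spec.gtv_scale} cc on this grid (got {vol_cc:.2f} cc)"
        )

    ptv = expand(gtv, spec.ptv_margin).with_name("PTV")

    # GTV half-extents along each axis, for OAR and brain placement
    idx = np.argwhere(gtv_data)
    lo = grid.index_to_world(idx.min(axis=0))
    hi = grid.index_to_world(idx.max(axis=0))
    half_ext = np.maximum(np.abs(lo), np.abs(hi))

    bs_radius, bs_halflen = 8.0, 20.0
    bs_cx = -(half_ext[0] + spec.oar_gap_mm + bs_radius)
    brainstem = _cylinder(grid, (bs_cx, 0.0, 0.0), bs_radius, bs_halflen, "brainstem")
    ch_half = (6.0, 4.0, 2.0)
    ch_cy = +(half_ext[1] + spec.oar_gap_mm + ch_half[1])
    chiasm = _box(grid, (0.0, ch_cy, 0.0), ch_half, "chiasm")

    brain_semi = (
        max(half_ext[0] + spec.ptv_margin, abs(bs_cx) + bs_radius) + 12.0,
        max(half_ext[1] + spec.ptv_margin, ch_cy + ch_half[1]) + 12.0,
        max(half_ext[2] + spec.ptv_margin, bs_halflen) + 12.0,
    )
    brain = ellipsoid_mask(grid, (0, 0, 0), brain_semi, "brain")

    for oar in (brainstem, chiasm):
        if boolean(oar, gtv, "intersect").data.any():
            raise ValueError(f"OAR surrogate {oar.name} overlaps the GTV")
    structures = {"GTV": gtv, "PTV": ptv, "brain": brain,
                  "brainstem": brainstem, "chiasm": chiasm}
    meta = {"scale_mm": scale, "gtv_volume_cc": vol_cc,
            "brain_semiaxes_mm": brain_semi, "seed": spec.seed}
    return Phantom(grid=grid, structures=structures, spec=spec, meta=meta)


def _cylinder(grid, center, radius, half_length, name) -> StructureMask:
    x, y, z = grid.axis_coords()
    radial = ((x - center[0])[:, None] ** 2 + (y - center[1])[None, :] ** 2) <= radius ** 2
    axial = np.abs(z - center[2]) <= half_length
    return StructureMask(grid, name, radial[:, :, None] & axial[None, None, :])


def _box(grid, center, half_sizes, name) -> StructureMask:
    x, y, z = grid.axis_coords()
    inside = (
        (np.abs(x - center[0]) <= half_sizes[0])[:, None, None]
        & (np.abs(y - center[1]) <= half_sizes[1])[None, :, None]
        & (np.abs(z - center[2]) <= half_sizes[2])[None, None, :]
    )
    return StructureMask(grid, name, inside)
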