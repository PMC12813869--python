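# Methods

## Scope and intent

`sfrtplan` models the dosimetric workflow of spatially fractionated
radiotherapy (SFRT) as an upfront boost for recurrent glioblastoma
re-irradiation: deriving vertex target volumes (VTVs) from target contours,
producing a plausible single-fraction SFRT dose field, accumulating it with
two conventional courses in EQD2, and scoring plan quality and
reirradiation safety. Everything runs on synthetic phantoms; there is no
beam transport, inverse optimization, deliverability model, or
inter-course registration. Both treatment courses are assumed to live on
one frame of reference, and no dose-forgiveness or repair-kinetics factor
is applied between courses.

## Voxel geometry

Structures are binary masks on a shared regular grid (default 1 mm
isotropic). A voxel belongs to a mask when its **center** satisfies the
defining predicate. Analytic shapes (ellipsoids, cylinders, boxes) use the
closed inequality; vertex spheres use the **open** ball `‖x−c‖ < r`. The
open convention matters for the diameter-expansion rule below: a vertex
whose diameter exactly saturates twice the local interior depth would
otherwise swallow the nearest background voxel and violate the
sphere-inside-tumor containment guarantee.

Margins are physical (mm) and computed by Euclidean distance-transform
(EDT) thresholding, so anisotropic spacing is handled correctly. The EDT
measures distances between voxel centers, which systematically
overestimates the distance to the voxelized surface by a direction-dependent
fraction of a voxel; `expand` therefore applies a quarter-voxel surface
offset (0.25 × mean spacing) to the threshold. With this offset, margins on
analytic spheres at 1 mm voxels reproduce analytic volumes to within about
2.5 % for expansions; contractions remain a few percent conservative
(smaller than analytic). Masks never auto-resample: any cross-grid operation
raises an error.

`min_surface_separation` is the minimum center-to-center distance between
the outermost voxel layers of two masks; coincident or overlapping
boundaries give 0. Its resolution is one voxel.

### The ring structure

The valley-dose ring is built from the VTV with a +10 mm outer and −5 mm
inner margin. Two readings of the inner margin exist and both are
implemented behind a mode flag:

* `literal` — expand(+10) minus expand(−5): the erosion empties vertices
  of ≤ 10 mm diameter, so the 15 Gy cores can remain inside the ring;
* `shell` (default) — expand(+10) minus expand(+5): the tissue shell
  5–10 mm outside the VTV.

The shell reading is the default because the valley goal (ring V5Gy below
10–12 %) is ill-posed when the peak cores are part of the ring. Every
report records which mode produced its V5Gy figure.

## LATTICE vertex placement

Group-1 targets (GTV > 15 cc) receive a deterministic greedy packing:

1. Candidates are voxel centers with interior depth ≥ 4 mm (the initial
   vertex radius) whose would-be sphere surface clears every critical OAR
   by ≥ 10 mm. The OAR test is surface-to-surface (center distance ≥
   clearance + radius), so the clearance survives later diameter growth.
2. Candidates are visited by decreasing interior depth, flat voxel index
   ascending as the tie-break, and accepted when ≥ spacing (default 25 mm)
   from every accepted center. Packing stops when the rasterized VTV would
   exceed 10 % of the GTV volume.
3. Each vertex then grows in placement order to
   `clamp(floor(2·depth), 8, 15)` mm — whole-millimetre diameters, matching
   contouring practice — further capped by the OAR clearance and by the
   VGR cap (the vertex that would cross the cap keeps its prior size and
   growth stops).

Because minimum spacing (20 mm) is at least the maximum diameter (15 mm),
vertex spheres never overlap, volumes add exactly, and surface gaps are
non-negative. The manual resize/reposition iterations of clinical planning
are replaced by `tune_lattice`: a sweep of spacing from 25 to 40 mm in
2.5 mm steps that returns the first lattice whose ring V5Gy meets the 12 %
goal, or the best-effort lattice with a failure flag.

Descriptors: MVD is the mean diameter; mean spacing is the mean
nearest-neighbour center distance (an all-pairs mean would inflate with
vertex count); VDSR is spacing/MVD — the ratio is named
"diameter-to-spacing" in clinical usage but its conventional value (~3 at
8 mm vertices on 25 mm spacing) is spacing over diameter, so that is what
is computed; VGR is VTV volume over GTV volume. Spacing and VDSR are
undefined (None) for single-vertex lattices. If OAR limits are violated
downstream, the VTV is cropped to GTV + 2 mm and clipped vertices keep
their metadata with a flag.

## SCART derivation

Group-2 targets (3–15 cc) take a single central core. The PTV–GTV margin
is measured as the **minimum surface separation** (worst case), which keeps
the rule well-defined for anisotropic margins: margin > 3 mm → VTV =
GTV ⊖ 2 mm, else VTV = PTV ⊖ 5 mm. The achieved PTV–VTV separation is
checked to be ≥ 5 mm up to one voxel — the strict "> 5 mm" of the clinical
rule is not achievable exactly at the stated contraction on a voxel grid.
An emptied contraction raises a structured error (target too small).

## Synthetic phantoms

`make_phantom` emulates the geometry the planning rules operate on:

* GTV shapes — `ellipsoid` (2:1:1 aspect), `strip` (3.5:1:0.6), `star`
  (union of 3–5 randomly oriented ellipsoids sharing one center, hence
  connected). The shape scale is calibrated by rasterize–measure–rescale
  iterations until the volume is within 5 % of the requested value
  (the contract allows 10 %).
* PTV = GTV expanded by 2–15 mm (default 3 mm, a common high-risk margin).
* OAR surrogates — a brainstem-like cylinder (r = 8 mm, length 40 mm) and
  a chiasm-like box (12 × 8 × 4 mm) placed 15 mm (configurable) from the
  GTV surface; a brain ellipsoid encloses everything.
* Defaults: 30 cc GTV (a mid-size group-1 tumor; the clinical cohort
  spans ~4–118 cc), 1 mm grid, seeded `numpy` randomness — identical seeds
  give byte-identical masks.

The phantoms reproduce volume, shape irregularity, and target–OAR
adjacency. They do **not** reproduce CT intensity, tissue heterogeneity,
realistic organ shapes, or contouring noise — so passing tests demonstrate
the correctness and internal consistency of the planning arithmetic, not
clinical performance on patient anatomy.

## Synthetic dose engine

The treatment planning system is replaced by analytic fields:

* SFRT fraction: `dose(v) = bath + Σᵢ peak · exp(−(sᵢ/σ)²)` with
  `sᵢ = max(0, ‖v−cᵢ‖ − rᵢ)`; inside any vertex the kernel term equals the
  full peak. For an arbitrary (SCART) core the same kernel runs on the EDT
  distance to the VTV mask. σ = 2.5 mm makes a 15 Gy peak fall below 1 Gy
  within ~5 mm of the surface, so the < 5 Gy valley at ≥ 20 mm spacing
  holds by construction; σ is exposed because no dose model is canonical
  here. Defaults: peak 15 Gy, bath 4 Gy.
* Conventional fraction: prescription inside the target, Gaussian penumbra
  (default σ = 5 mm) outside.
* The SFRT-course bath is the second-course prescription per fraction
  capped at 4 Gy; the clinical wording is ambiguous about prescriptions in
  the (4, 5] Gy band, and the cap-everything-above-4 reading is adopted.
* The **reference plan** used for acceptance applies the bath uniformly
  across the grid (simple, and conservative for ring V5Gy); the two-course
  **pipeline** gives the SFRT fraction a PTV-conformal bath so that, away
  from the tumor, the replaced fraction resembles the fraction it replaces.

## EQD2 accumulation

EQD2 of a segment of n fractions of voxel dose d: `n·d·(d+α/β)/(2+α/β)` —
exact under uniform-per-segment fractionation, which all modeled courses
satisfy. α/β = 8 Gy for GTV+2 mm (the target structure for cumulative
dose, capturing subclinical spread plus minimal setup error), 2 Gy for
normal brain (brain minus GTV+2 mm), brainstem, and chiasm. The SFRT sum
plan = EQD2(course 1) + EQD2(course 2 with fraction 1 replaced by the SFRT
fraction); the original sum plan keeps course 2 intact. Accumulation is
voxelwise first, masking after. The single-fraction headroom solver returns
the positive root of `d(d+α/β)/(2+α/β) = limit − existing`, plus its floor
in whole Gy.

## DVH and gamma conventions

DVH curves use exact voxel counting, at-or-above convention, 0.01 Gy bins
(interpolation error ≪ the 1 % dose criteria on ≤ 130 Gy sums). Dx% and
Dx_cc interpolate linearly on the cumulative curve; VxGy counts voxels
exactly. The DVH gamma comparison runs on absolute-volume (cc) axes:
reference = original sum plan, evaluated = SFRT sum plan; the dose
criterion is 1 % of the global maximum of the SFRT sum EQD2 fields (value
recorded in the report), the volume criterion 1 % of the structure volume.
The evaluated curve is sampled at dose-criterion intervals plus its
terminal point; each sample's gamma is the exact minimum distance to the
reference polyline in criterion-normalized space (no dense resampling
needed), and pass rates below 90 % raise an inspect flag. The sampling
density is a package convention — published DVH-gamma variants do not fix
one — and is configurable through the criteria.

PVDR = D5%/D95% of the GTV for LATTICE plans; for SCART plans the PTV is
used instead (the GTV D95% sits on the peak shoulder, not in the valley).
A D95% at or below one DVH bin marks the ratio undefined rather than
returning an unbounded number.

## Problem sizes and reproducibility

The reference plan runs on a 113 × 73 × 73 voxel grid (~0.6 M voxels,
about a second); pipeline phantoms occupy 1–3 M voxels and a full
phantom-to-safety-report run takes a few seconds. The analysis drivers use
a six-phantom cohort (three shapes × two size groups). All randomness flows
through seeded `numpy` generators; a run's config plus seed reproduces its
report byte-identically.

## Known limitations

* The Gaussian-in-distance kernel ignores beam geometry: no arc entrance
  dose, no MLC penumbra anisotropy, no tissue heterogeneity — absolute
  valley and bath figures are idealized (e.g., ring V5Gy of 0 % on the
  reference plan, versus single-digit percentages for deliverable plans).
* Cohort statistics of the clinical study (means ± SD over 14 patients)
  depend on patient anatomy and are out of scope; the toolkit reproduces
  the per-plan rules, bounds, and worked examples instead.
* SCART VGR on compact synthetic shapes (~40–55 %) sits above typical
  clinical values (~26 ± 10 %), because a 2 mm contraction of a smooth
  ellipsoid retains more core volume than the irregular clinical targets.
* Margin operations are accurate to a fraction of a voxel, not sub-voxel
  exact; all geometric guarantees are stated up to one voxel.
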