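"""Independent brute-force references the fast implementations are checked
against. These stay deliberately naive: plain loops and sorts, no shared
code with the package internals beyond the data containers."""

import numpy as np
from scipy import ndimage


def naive_greedy_placement(gtv, config, spacing, oars=()):
    """Literal candidate-scan greedy packing: visit candidates deepest-first
    (flat index tie-break), accept iff far from every accepted center."""
    grid = gtv.grid
    depth = ndimage.distance_transform_edt(gtv.data, sampling=grid.spacing)
    if oars:
        combined = np.zeros(grid.shape, bool)
        for o in oars:
            combined |= o.data
        oar_d = ndimage.distance_transform_edt(~combined, sampling=grid.spacing)
    else:
        oar_d = np.full(grid.shape, np.inf)
    r0 = config.initial_radius
    feasible = (depth >= r0) & (oar_d >= config.oar_clearance + r0)
    flats = np.flatnonzero(feasible.ravel())
    order = sorted(zip(depth.ravel()[flats], flats), key=lambda t: (-t[0], t[1]))
    cap_mm3 = config.vgr_cap * gtv.data.sum() * grid.voxel_volume_mm3

    def sphere_voxels(center):
        d2 = grid.distance_sq_to(center)
        return d2 < r0 * r0

    accepted = []
    vtv_mm3 = 0.0
    for _, flat in order:
        idx = np.unravel_index(flat, grid.shape)
        center = grid.index_to_world(idx)
        if all(np.linalg.norm(np.subtract(center, a)) >= spacing for a in accepted):
            add = sphere_voxels(center).sum() * grid.voxel_volume_mm3
            if vtv_mm3 + add > cap_mm3:
                break
            accepted.append(center)
            vtv_mm3 += add
    return accepted


def sort_dose_at_volume(dose_values, voxel_cc, target_cc):
    """Dose exceeded by the hottest target_cc, by descending sort with
    linear interpolation on the cumulative absolute-volume axis."""
    hot = np.sort(np.asarray(dose_values, float))[::-1]
    cum = (np.arange(hot.size) + 1) * voxel_cc
    return float(np.interp(target_cc, cum, hot))


def sort_volume_at_dose(dose_values, voxel_cc, dose_gy):
    return float((np.asarray(dose_values) >= dose_gy).sum() * voxel_cc)


def brute_force_gamma(ref_points, eval_points, delta_d, delta_v):
    """Gamma pass rate by dense resampling of the reference polyline."""
    ref = np.asarray(ref_points, float)
    dense = []
    for a, b in zip(ref[:-1], ref[1:]):
        for t in np.linspace(0, 1, 200):
            dense.append(a + t * (b - a))
    dense = np.asarray(dense)
    passes = 0
    for p in np.asarray(eval_points, float):
        g = np.sqrt(((p[0] - dense[:, 0]) / delta_d) ** 2
                    + ((p[1] - dense[:, 1]) / delta_v) ** 2).min()
        if g <= 1.0 + 1e-6:
            passes += 1
    return 100.0 * passes / len(eval_points)


def voxel_loop_sum_plans(course1, course2, sfrt_fraction, alpha_beta):
    """EQD2 sum plans by an explicit per-voxel python loop on a flattened
    sample of voxels; returns (original, sfrt) flat arrays."""
    def eqd2_vox(d, n, ab):
        return n * d * (d + ab) / (2.0 + ab)

    c1 = [(dg.data.ravel(), n) for dg, n in course1.segments]
    c2 = [(dg.data.ravel(), n) for dg, n in course2.segments]
    sf = sfrt_fraction.data.ravel()
    size = sf.size
    orig = np.empty(size)
    sfrt = np.empty(size)
    for i in range(size):
        base = sum(eqd2_vox(seg[i], n, alpha_beta) for seg, n in c1)
        orig[i] = base + sum(eqd2_vox(seg[i], n, alpha_beta) for seg, n in c2)
        first, n0 = c2[0]
        rest = sum(eqd2_vox(seg[i], n, alpha_beta) for seg, n in c2[1:])
        sfrt[i] = (base + eqd2_vox(sf[i], 1, alpha_beta)
                   + eqd2_vox(first[i], n0 - 1, alpha_beta) + rest)
    return orig, sfrt
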