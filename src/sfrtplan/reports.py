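"""Plan-quality and reirradiation-safety reporting.

Covers the peak-to-valley dose ratio (PVDR = D5%/D95% of the GTV, or of
the PTV for SCART plans), target coverage, ring V5Gy, the cumulative-dose
comparison between the original and SFRT sum plans (D0.03cc, V120/V100/V80)
against the reirradiation limits (brain 120 / brainstem 100 / chiasm
75 Gy EQD2), and the per-OAR DVH gamma pass rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseGrid
from .dvh import DVHCurve, compute_dvh, dose_at_volume, dvh_gamma, volume_at_dose
from .radiobio import EQD2Grid, REIRRADIATION_LIMITS_GY
from .volumes import StructureMask

GAMMA_INSPECT_THRESHOLD_PCT = 90.0


@dataclass
class PVDRResult:
    value: float | None
    structure: str        # GTV for LATTICE, PTV for SCART
    d5_gy: float
    d95_gy: float
    defined: bool = True


def pvdr(dose: DoseGrid, gtv: StructureMask, ptv: StructureMask, technique: str) -> PVDRResult:
    """Peak-to-valley dose ratio D5%/D95%, on the GTV for LATTICE plans and
    on the PTV for SCART plans (where the GTV D95% sits above the valley)."""
    if technique not in ("LATTICE", "SCART"):
        raise ValueError(f"unknown technique {technique!r}")
    structure = gtv if technique == "LATTICE" else ptv
    curve = compute_dvh(dose, structure)
    d5 = dose_at_volume(curve, pct=5.0)
    d95 = dose_at_volume(curve, pct=95.0)
    bin_width = float(curve.edges[1] - curve.edges[0])
    if d95 <= bin_width:  # valley at zero up to interpolation resolution
        return PVDRResult(value=None, structure=structure.name, d5_gy=d5, d95_gy=d95,
                          defined=False)
    return PVDRResult(value=d5 / d95, structure=structure.name, d5_gy=d5, d95_gy=d95)


def coverage(dose: DoseGrid, target: StructureMask, rx_gy: float) -> float:
    """Percent of the target receiving at least the prescription."""
    pct, _ = volume_at_dose(compute_dvh(dose, target), rx_gy)
    return pct


@dataclass
class PlanQualityReport:
    technique: str
    pvdr: PVDRResult
    vtv_v15gy_pct: float
    ring_v5gy_pct: float
    ring_mode: str
    ptv_d0_1cc_gy: float
    gtv_coverage_pct: float
    ptv_coverage_pct: float
    vgr: float

    def as_dict(self) -> dict:
        return {
            "technique": self.technique,
            "pvdr": self.pvdr.value,
            "pvdr_structure": self.pvdr.structure,
            "pvdr_d5_gy": self.pvdr.d5_gy,
            "pvdr_d95_gy": self.pvdr.d95_gy,
            "vtv_v15gy_pct": self.vtv_v15gy_pct,
            "ring_v5gy_pct": self.ring_v5gy_pct,
            "ring_mode": self.ring_mode,
            "ptv_d0_1cc_gy": self.ptv_d0_1cc_gy,
            "gtv_coverage_pct": self.gtv_coverage_pct,
            "ptv_coverage_pct": self.ptv_coverage_pct,
            "vgr": self.vgr,
        }


def evaluate_plan(dose: DoseGrid, gtv: StructureMask, ptv: StructureMask,
                  vtv: StructureMask, ring: StructureMask, technique: str,
                  peak_gy: float = 15.0, valley_gy: float = 5.0, rx_gy: float = 4.0,
                  ring_mode: str = "shell") -> PlanQualityReport:
    """The SFRT-fraction quality battery: PVDR, VTV peak coverage, ring
    valley metric, PTV hot spot, and coverage at the bath prescription."""
    ring_v5 = volume_at_dose(compute_dvh(dose, ring), valley_gy)[0] if not ring.is_empty else 0.0
    return PlanQualityReport(
        technique=technique,
        pvdr=pvdr(dose, gtv, ptv, technique),
        vtv_v15gy_pct=volume_at_dose(compute_dvh(dose, vtv), peak_gy)[0],
        ring_v5gy_pct=ring_v5,
        ring_mode=ring_mode,
        ptv_d0_1cc_gy=dose_at_volume(compute_dvh(dose, ptv), cc=0.1),
        gtv_coverage_pct=coverage(dose, gtv, rx_gy),
        ptv_coverage_pct=coverage(dose, ptv, rx_gy),
        vgr=vtv.volume_cc / gtv.volume_cc,
    )


@dataclass
class StructureComparison:
    d003cc_original_gy: float
    d003cc_sfrt_gy: float
    d003cc_diff_pct: float
    limit_gy: float | None = None
    limit_violated: bool | None = None
    gamma_pass_rate_pct: float | None = None
    gamma_inspect: bool | None = None


@dataclass
class SafetyReport:
    structures: dict[str, StructureComparison] = field(default_factory=dict)
    vx_cc: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    absent: list[str] = field(default_factory=list)
    gamma_dose_criterion_gy: float = 0.0
    gamma_volume_criterion_note: str = "1% of structure volume (cc)"
    sfrt_sum_max_gy: float = 0.0

    def as_dict(self) -> dict:
        return {
            "structures": {k: vars(v) for k, v in self.structures.items()},
            "vx_cc": self.vx_cc,
            "absent": self.absent,
            "gamma_dose_criterion_gy": self.gamma_dose_criterion_gy,
            "gamma_volume_criterion": self.gamma_volume_criterion_note,
            "sfrt_sum_max_gy": self.sfrt_sum_max_gy,
        }


def _masked_curve(sums: dict[str, EQD2Grid], label: str, mask: StructureMask) -> DVHCurve:
    eq = sums[label]
    return compute_dvh(DoseGrid(eq.grid, eq.data, label), mask)


def compare_sum_plans(original_sum: dict[str, EQD2Grid], sfrt_sum: dict[str, EQD2Grid],
                      structures: dict[str, StructureMask],
                      limits: dict[str, float] | None = None,
                      gamma_structures=("brainstem", "chiasm", "brain_minus_gtv2mm"),
                      volume_structures=("brain", "brain_minus_gtv2mm"),
                      volume_levels_gy=(120.0, 100.0, 80.0)) -> SafetyReport:
    """Compare the original and SFRT cumulative EQD2 sum plans.

    Per structure: D0.03cc for both sums and its percent change, the
    reirradiation-limit flag, and (for critical OARs) the 1%/1% DVH gamma
    pass rate with an inspect flag below 90%. V120/V100/V80 (cc) are
    tabulated for the brain and normal-brain structures. A structure
    missing from the sums or the mask set is listed as absent, not fatal.
    """
    limits = dict(REIRRADIATION_LIMITS_GY) if limits is None else limits
    report = SafetyReport()
    report.sfrt_sum_max_gy = max(float(eq.data.max()) for eq in sfrt_sum.values())
    delta_d = report.sfrt_sum_max_gy / 100.0  # 1% of the SFRT sum plan maximum
    report.gamma_dose_criterion_gy = delta_d

    for label in sfrt_sum:
        mask = structures.get(label)
        if mask is None or mask.is_empty or label not in original_sum:
            report.absent.append(label)
            continue
        curve_orig = _masked_curve(original_sum, label, mask)
        curve_sfrt = _masked_curve(sfrt_sum, label, mask)
        d_orig = dose_at_volume(curve_orig, cc=min(0.03, mask.volume_cc))
        d_sfrt = dose_at_volume(curve_sfrt, cc=min(0.03, mask.volume_cc))
        diff_pct = (d_sfrt - d_orig) / d_orig * 100.0 if d_orig > 0 else float("inf")
        comp = StructureComparison(d003cc_original_gy=d_orig, d003cc_sfrt_gy=d_sfrt,
                                   d003cc_diff_pct=diff_pct)
        if label in limits:
            comp.limit_gy = limits[label]
            comp.limit_violated = d_sfrt > limits[label]
        if label in gamma_structures:
            rate = dvh_gamma(curve_orig, curve_sfrt, dose_criterion=delta_d,
                             volume_criterion=mask.volume_cc / 100.0)
            comp.gamma_pass_rate_pct = rate
            comp.gamma_inspect = rate < GAMMA_INSPECT_THRESHOLD_PCT
        report.structures[label] = comp

        if label in volume_structures:
            entry: dict[str, dict[str, float]] = {}
            for level in volume_levels_gy:
                v_orig = volume_at_dose(curve_orig, level)[1]
                v_sfrt = volume_at_dose(curve_sfrt, level)[1]
                entry[f"V{level:g}Gy"] = {"original_cc": v_orig, "sfrt_cc": v_sfrt,
                                          "diff_cc": v_sfrt - v_orig}
            report.vx_cc[label] = entry
    return report
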