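"""End-to-end planning-study pipeline on synthetic inputs.

phantom -> technique selection -> VTV (LATTICE spacing sweep or SCART
margin rules) -> single-fraction SFRT dose + conventional courses ->
two-course EQD2 sum plans -> plan-quality and safety reports. Every stage
writes its intermediates so each report value is recomputable; a fixed
seed reproduces the artifact set byte-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import io as sfio
from .dose import (DoseGrid, SfrtKernelParams, cap_prescription, conventional_dose,
                   sfrt_dose)
from .dvh import compute_dvh, volume_at_dose
from .lattice import (LatticePlacementConfig, crop_vtv, lattice_metrics,
                      select_technique, tune_lattice)
from .phantom import PhantomSpec, make_phantom
from .radiobio import RadiobioParams, CoursePlan, build_sum_plans, headroom_single_fraction, eqd2_scalar
from .reports import compare_sum_plans, evaluate_plan
from .scart import ScartConfig, derive_scart_vtv
from .volumes import boolean, build_ring, expand


@dataclass
class RunConfig:
    """Fully serializable run recipe; config + seed reproduce a run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    technique_override: str | None = None
    lattice: LatticePlacementConfig = field(default_factory=LatticePlacementConfig)
    scart: ScartConfig = field(default_factory=ScartConfig)
    kernel: SfrtKernelParams = field(default_factory=SfrtKernelParams)
    radiobio: RadiobioParams = field(default_factory=RadiobioParams)
    course1_total_gy: float = 60.0
    course1_fractions: int = 30
    course2_total_gy: float = 35.0
    course2_fractions: int = 10
    penumbra_sigma: float = 5.0
    ring_mode: str = "shell"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return RunConfig(
            phantom=PhantomSpec(**{**raw["phantom"],
                                   "spacing": tuple(raw["phantom"]["spacing"])}),
            technique_override=raw.get("technique_override"),
            lattice=LatticePlacementConfig(**raw["lattice"]),
            scart=ScartConfig(**raw["scart"]),
            kernel=SfrtKernelParams(**raw["kernel"]),
            radiobio=RadiobioParams(**raw["radiobio"]),
            course1_total_gy=raw["course1_total_gy"],
            course1_fractions=raw["course1_fractions"],
            course2_total_gy=raw["course2_total_gy"],
            course2_fractions=raw["course2_fractions"],
            penumbra_sigma=raw["penumbra_sigma"],
            ring_mode=raw["ring_mode"],
        )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _ring_v5_evaluator(config: RunConfig):
    """Ring V5Gy fraction of a candidate lattice under the analytic kernel."""
    def evaluate(lat):
        if lat.vtv_mask.is_empty:
            return float("inf")
        dose = sfrt_dose(lat.vtv_mask.grid, vertices=lat.vertices, kernel=config.kernel)
        ring = build_ring(lat.vtv_mask, 10.0, -5.0, mode=config.ring_mode)
        if ring.is_empty:
            return 0.0
        return volume_at_dose(compute_dvh(dose, ring), 5.0)[0] / 100.0
    return evaluate


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full study on one synthetic patient; returns the report
    dict and writes all intermediates under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stage = "phantom"
    try:
        phantom = make_phantom(config.phantom)
        gtv, ptv, brain = phantom["GTV"], phantom["PTV"], phantom["brain"]
        oars = [phantom["brainstem"], phantom["chiasm"]]

        stage = "select_technique"
        technique = config.technique_override or select_technique(gtv)

        stage = "vtv"
        scart_provenance = None
        if technique == "LATTICE":
            lat = tune_lattice(gtv, config.lattice, oars=oars,
                               evaluator=_ring_v5_evaluator(config))
            vtv = lat.vtv_mask
            metrics = lattice_metrics(lat, gtv) if lat.vertices else None
        else:
            res = derive_scart_vtv(gtv, ptv, config.scart)
            vtv, lat, metrics = res.vtv, None, None
            scart_provenance = {"branch": res.branch,
                                "ptv_gtv_margin_mm": res.ptv_gtv_margin_mm,
                                "ptv_vtv_separation_mm": res.ptv_vtv_separation_mm}

        stage = "sfrt_dose"
        rx2_per_fx = config.course2_total_gy / config.course2_fractions
        bath = cap_prescription(rx2_per_fx)
        # SFRT fraction = PTV-conformal bath at the capped prescription plus
        # the peak kernels (peaks alone via a zero-bath kernel)
        peaks_kernel = replace(config.kernel, bath_dose=0.0)
        bath_field = conventional_dose(ptv, bath, config.penumbra_sigma)
        if technique == "LATTICE" and lat is not None and lat.vertices:
            peaks = sfrt_dose(gtv.grid, vertices=lat.vertices, kernel=peaks_kernel)
        else:
            peaks = sfrt_dose(gtv.grid, vtv=vtv, kernel=peaks_kernel)
        sfrt_fx = DoseGrid(gtv.grid, bath_field.data + peaks.data, "sfrt_fraction")
        ring = build_ring(vtv, 10.0, -5.0, mode=config.ring_mode) if not vtv.is_empty \
            else vtv

        stage = "courses"
        c1_fx = conventional_dose(ptv, config.course1_total_gy / config.course1_fractions,
                                  config.penumbra_sigma)
        c2_fx = conventional_dose(ptv, rx2_per_fx, config.penumbra_sigma)
        course1 = CoursePlan([(c1_fx, config.course1_fractions)], "course1")
        course2 = CoursePlan([(c2_fx, config.course2_fractions)], "course2")

        stage = "sum_plans"
        original_sum, sfrt_sum = build_sum_plans(course1, course2, sfrt_fx, config.radiobio)

        stage = "evaluate"
        gtv2 = expand(gtv, 2.0).with_name("GTV_2mm")
        structures = {
            "GTV_2mm": gtv2,
            "brain": brain,
            "brain_minus_gtv2mm": boolean(brain, gtv2, "subtract").with_name("brain_minus_gtv2mm"),
            "brainstem": phantom["brainstem"],
            "chiasm": phantom["chiasm"],
        }
        quality = evaluate_plan(sfrt_fx, gtv, ptv, vtv, ring, technique,
                                peak_gy=config.kernel.peak_dose, rx_gy=bath,
                                ring_mode=config.ring_mode)
        safety = compare_sum_plans(original_sum, sfrt_sum, structures,
                                   gamma_structures=("brainstem", "chiasm",
                                                     "brain_minus_gtv2mm"))

        # fallback of the planning procedure: crop the VTV to GTV + 2 mm
        # when a cumulative OAR limit is violated, then re-evaluate
        cropped = False
        violated = any(c.limit_violated for c in safety.structures.values()
                       if c.limit_violated is not None)
        if violated and technique == "LATTICE" and lat is not None and lat.vertices:
            cropped = True
            lat = crop_vtv(lat, gtv)
            vtv = lat.vtv_mask
            peaks = sfrt_dose(gtv.grid, vtv=vtv, kernel=peaks_kernel)
            sfrt_fx = DoseGrid(gtv.grid, bath_field.data + peaks.data, "sfrt_fraction")
            ring = build_ring(vtv, 10.0, -5.0, mode=config.ring_mode)
            original_sum, sfrt_sum = build_sum_plans(course1, course2, sfrt_fx,
                                                     config.radiobio)
            quality = evaluate_plan(sfrt_fx, gtv, ptv, vtv, ring, technique,
                                    peak_gy=config.kernel.peak_dose, rx_gy=bath,
                                    ring_mode=config.ring_mode)
            safety = compare_sum_plans(original_sum, sfrt_sum, structures)

        stage = "headroom"
        existing = (eqd2_scalar(config.course1_total_gy / config.course1_fractions,
                                config.course1_fractions, 8.0)
                    + eqd2_scalar(rx2_per_fx, config.course2_fractions, 8.0))
        head = headroom_single_fraction(existing, 120.0, 8.0)

        stage = "write_outputs"
        for name, mask in {**phantom.structures, "VTV": vtv, "ring": ring}.items():
            sfio.write_mask(out / f"{name}.nrrd", mask)
        sfio.write_dose(out / "sfrt_fraction.nrrd", sfrt_fx)
        report = {
            "seed": config.phantom.seed,
            "technique": technique,
            "gtv_volume_cc": gtv.volume_cc,
            "vtv_volume_cc": vtv.volume_cc,
            "bath_dose_gy": bath,
            "cropped_to_gtv2mm": cropped,
            "scart": scart_provenance,
            "lattice_metrics": (None if metrics is None else vars(metrics)),
            "tuning_trace": (lat.tuning_trace if lat is not None else None),
            "quality": quality.as_dict(),
            "safety": safety.as_dict(),
            "headroom_single_fraction": vars(head),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        config.to_yaml(out / "config.yaml")
        log = {"elapsed_s": time.perf_counter() - t0, "stages": "ok",
               "seed": config.phantom.seed}
        (out / "log.json").write_text(json.dumps(log, indent=2))
        return report
    except Exception as exc:  # persist the failing stage name
        (out / "log.json").write_text(json.dumps({"failed_stage": stage,
                                                  "error": str(exc)}, indent=2))
        raise PipelineError(stage, exc) from exc
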