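"""End-to-end cohort pipeline: phantom -> segmentation -> geometry -> stats.

For every case and posture of the per-case clinical tables, a phantom stack
is rendered with the printed gas volume fraction and supraduction angle,
then fed through the same measurement chain a reader would apply to a real
acquisition: per-slice Otsu segmentation and volume integration, slice
selection by axial length, limbus/landmark placement, four-part contact
rates, and the supraduction angle.  Cohort-level summaries and
prone-vs-supine tests are computed from the measured values, and a run
manifest records parameters, seeds and output checksums so that re-running
a manifest reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .geometry import (
    PART_NAMES,
    EyeModel,
    GasBubble,
    analytic_contact_rates,
)
from .landmarks import (
    SliceGeometry,
    axis_from_angle_points,
    circle_contour,
    locate_meniscus,
    measure_contact,
    measure_contact_plane,
    measure_supraduction,
    partition_retina,
    select_slice,
)
from .phantom import ImagingParams, Scenario, cohort_from_table3, render_stack
from .segmentation import segment_stack
from .stats import prone_supine_comparison, summarize, wilcoxon_signed_rank

log = logging.getLogger("oculogas.pipeline")

__all__ = ["PipelineConfig", "CaseMeasurement", "CohortResult", "run_case", "run_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    """Reproducible configuration of one cohort run."""

    seed: int = 0
    out_dir: str | None = None
    noise_sd: float = 0.0
    blur_sigma_px: float = 1.0
    matrix: int = 320
    n_slices: int = 11
    contact_tolerance_px: float = 1.5
    contact_step_mm: float = 0.05
    write_stacks: bool = False
    limbus_offset_mm: float = 6.0
    anterior_offset_mm: float = 1.6

    def imaging(self, scenario_seed: int) -> ImagingParams:
        return ImagingParams(
            matrix=self.matrix,
            n_slices=self.n_slices,
            noise_sd=self.noise_sd,
            blur_sigma_px=self.blur_sigma_px,
            seed=scenario_seed,
        )


@dataclass
class CaseMeasurement:
    """Measured and analytic quantities for one case in one posture."""

    case_id: int
    posture: str
    true_gas_pct: float
    measured_gas_pct: float
    true_angle_deg: float
    measured_angle_deg: float
    measured_rates: dict
    analytic_rates: dict
    slice_index: int
    flags: list = field(default_factory=list)

    def as_row(self) -> dict:
        row = {
            "case_id": self.case_id,
            "posture": self.posture,
            "gas_pct_true": self.true_gas_pct,
            "gas_pct": self.measured_gas_pct,
            "angle_deg_true": self.true_angle_deg,
            "angle_deg": self.measured_angle_deg,
            "slice_index": self.slice_index,
            "flags": ";".join(self.flags),
        }
        for name in PART_NAMES:
            row[f"rate_{name}"] = self.measured_rates[name]
            row[f"rate_{name}_analytic"] = self.analytic_rates[name]
        return row


def _scenario_seed(base_seed: int, scenario: Scenario) -> int:
    h = hashlib.sha256(
        f"{base_seed}:{scenario.case_id}:{scenario.posture}".encode()
    ).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_case(scenario: Scenario, config: PipelineConfig) -> CaseMeasurement:
    """Render one scenario and measure everything on the rendered stack."""
    t0 = time.perf_counter()
    eye = EyeModel.from_clinical(
        scenario.axial_length_mm,
        posture=scenario.posture,
        supraduction_deg=scenario.supraduction_deg,
        anterior_offset_mm=config.anterior_offset_mm,
        limbus_offset_mm=config.limbus_offset_mm,
    )
    bubble = GasBubble(scenario.fill_fraction)
    params = config.imaging(_scenario_seed(config.seed, scenario))
    stack, truth = render_stack(eye, bubble, params, scenario.posture, scenario.supraduction_deg)

    if config.write_stacks and config.out_dir is not None:
        stacks_dir = Path(config.out_dir) / "stacks"
        stacks_dir.mkdir(parents=True, exist_ok=True)
        stack.save(stacks_dir / f"case{scenario.case_id}_{scenario.posture}.tiff", truth)

    seg = segment_stack(stack)
    gas_pct = seg.gas_volume_pct
    k = select_slice(seg, scenario.axial_length_mm, anterior_offset_mm=config.anterior_offset_mm)
    sl = seg.slices[k]

    contour = circle_contour(sl.circle_xy_mm, sl.circle_r_mm)
    angle_sup = np.asarray(truth.landmarks_xy_mm["angle_superior"])
    angle_inf = np.asarray(truth.landmarks_xy_mm["angle_inferior"])
    axis_point, axis_dir, superior_dir = axis_from_angle_points(
        angle_sup, angle_inf, sl.circle_xy_mm
    )
    geom = SliceGeometry(
        contour=contour,
        axis_point=np.asarray(sl.circle_xy_mm),
        axis_dir=axis_dir,
        superior_dir=superior_dir,
        angle_superior=angle_sup,
        angle_inferior=angle_inf,
        pixel_spacing_mm=stack.pixel_spacing_mm,
    )
    angle = measure_supraduction(axis_dir, scenario.posture)
    partition = partition_retina(geom)
    meniscus = locate_meniscus(
        stack.data[k], sl.threshold, sl.circle_xy_mm, sl.circle_r_mm, stack.pixel_spacing_mm
    )
    if meniscus is not None:
        measured = measure_contact_plane(
            partition,
            meniscus[0],
            meniscus[1],
            posture=scenario.posture,
            case_id=scenario.case_id,
        )
    else:
        # No interface on the slice (all gas or all fluid): probe the mask.
        measured = measure_contact(
            partition,
            sl.gas_mask,
            stack.pixel_spacing_mm,
            tolerance_px=config.contact_tolerance_px,
            step_mm=config.contact_step_mm,
            posture=scenario.posture,
            case_id=scenario.case_id,
        )
    analytic = analytic_contact_rates(eye, bubble, posture=scenario.posture,
                                      case_id=scenario.case_id)
    log.info(
        "case %s %s: gas %.1f%% (true %.1f), angle %.1f deg (true %.1f) [%.2f s]",
        scenario.case_id, scenario.posture, gas_pct, 100 * scenario.fill_fraction,
        angle.degrees, scenario.supraduction_deg, time.perf_counter() - t0,
    )
    return CaseMeasurement(
        case_id=scenario.case_id,
        posture=scenario.posture,
        true_gas_pct=100.0 * scenario.fill_fraction,
        measured_gas_pct=gas_pct,
        true_angle_deg=scenario.supraduction_deg,
        measured_angle_deg=angle.degrees,
        measured_rates=measured.rate_pct,
        analytic_rates=analytic.rate_pct,
        slice_index=k,
        flags=[fl for s in seg.slices for fl in s.flags],
    )


@dataclass
class CohortResult:
    """Per-case rows, posture summaries, tests, and the run manifest."""

    cases: pd.DataFrame
    summary: pd.DataFrame
    tests: dict
    manifest: dict

    def mean_rate(self, part: str, posture: str) -> float:
        sel = self.cases[self.cases["posture"] == posture]
        return float(sel[f"rate_{part}"].mean())


_METRICS = ["gas_pct", "angle_deg"] + [f"rate_{p}" for p in PART_NAMES]


def run_cohort(config: PipelineConfig, scenarios: list[Scenario] | None = None) -> CohortResult:
    """Run the full cohort and assemble summary tables and tests.

    Scenarios default to the printed eight-case cohort in both postures.
    """
    if scenarios is None:
        scenarios = cohort_from_table3(datasets.load_gas_angle(), datasets.load_patients())
    rows = []
    for sc in scenarios:
        try:
            rows.append(run_case(sc, config).as_row())
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at case {sc.case_id} ({sc.posture}): {exc}"
            ) from exc
    cases = pd.DataFrame(rows).sort_values(["case_id", "posture"]).reset_index(drop=True)

    summary_rows = []
    tests = {}
    for metric in _METRICS:
        prone = cases.loc[cases["posture"] == "prone", metric].to_numpy()
        supine = cases.loc[cases["posture"] == "supine", metric].to_numpy()
        if len(prone) >= 2 and len(supine) >= 2:
            comp = prone_supine_comparison(prone, supine)
        else:  # smoke runs with a single case: summaries only
            comp = None
        tests[metric] = comp
        summary_rows.append(
            {
                "metric": metric,
                "prone_mean": prone.mean(),
                "prone_se": (prone.std(ddof=1) / np.sqrt(len(prone))
                             if len(prone) > 1 else np.nan),
                "supine_mean": supine.mean(),
                "supine_se": (supine.std(ddof=1) / np.sqrt(len(supine))
                              if len(supine) > 1 else np.nan),
                "mwu_p": comp["mann_whitney"].p_value if comp else np.nan,
                "wilcoxon_p": (
                    comp["paired_wilcoxon"].p_value
                    if comp and comp["paired_wilcoxon"] else np.nan
                ),
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("metric")

    manifest = {
        "config": dataclasses.asdict(config),
        "n_scenarios": len(scenarios),
        "scenario_seeds": {
            f"case{sc.case_id}_{sc.posture}": _scenario_seed(config.seed, sc)
            for sc in scenarios
        },
        "cases_sha256": hashlib.sha256(
            cases.to_csv(index=False, float_format="%.10g").encode()
        ).hexdigest(),
    }

    result = CohortResult(cases=cases, summary=summary, tests=tests, manifest=manifest)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cases.to_csv(out / "cohort_cases.csv", index=False, float_format="%.10g")
        summary.to_csv(out / "cohort_summary.csv", float_format="%.10g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return result


def bcva_change_test() -> dict:
    """Pre- vs post-operative BCVA (logMAR), paired Wilcoxon signed-rank."""
    t2 = datasets.load_outcomes()
    res = wilcoxon_signed_rank(
        t2["bcva_preop_logmar"].to_numpy(), t2["bcva_postop_logmar"].to_numpy()
    )
    return {"test": res, "n": len(t2)}
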