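"""Render the 16 phantom stacks of the printed cohort (8 cases x 2 postures).

Each phantom is driven by a printed case: gas fill fraction and supraduction
angle from the per-case gas/angle table, axial length from the patient
table.  Stacks (multi-page TIFF + ground-truth JSON sidecar) are written
under scratch/stacks/ — they are binary intermediates; everything the later
steps need can also be regenerated in memory.
"""

import warnings
from pathlib import Path

from oculogas import datasets
from oculogas.geometry import EyeModel, GasBubble
from oculogas.phantom import cohort_from_table3, render_stack
from oculogas.pipeline import PipelineConfig, _scenario_seed

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "stacks"
SEED = 1


def main():
    warnings.filterwarnings("ignore", message="multiple dark components")
    SCRATCH.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(seed=SEED, noise_sd=0.0)
    scenarios = cohort_from_table3(datasets.load_gas_angle(), datasets.load_patients())
    for sc in scenarios:
        eye = EyeModel.from_clinical(sc.axial_length_mm, sc.posture, sc.supraduction_deg)
        stack, truth = render_stack(
            eye, GasBubble(sc.fill_fraction),
            config.imaging(_scenario_seed(SEED, sc)), sc.posture, sc.supraduction_deg,
        )
        path = SCRATCH / f"case{sc.case_id}_{sc.posture}.tiff"
        stack.save(path, truth)
        print(
            f"case {sc.case_id:>2} {sc.posture:<6}: fill {100 * sc.fill_fraction:5.1f}%, "
            f"angle {sc.supraduction_deg:+6.1f} deg, AL {sc.axial_length_mm} mm -> {path.name}"
        )
    print(f"\n16 stacks under {SCRATCH}")


if __name__ == "__main__":
    main()
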