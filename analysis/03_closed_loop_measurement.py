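"""Measure every phantom with the pixel pipeline and check the closed loop.

Runs segmentation (per-slice Otsu + cavity circle), slice selection by
axial length, landmark placement, contact rates and supraduction angle for
all 16 phantom conditions, and reports the recovery errors against the
driving printed values and the analytic contact-rate oracle.  Writes
results/cohort_cases.csv, results/cohort_summary.csv and a manifest.
"""

import warnings
from pathlib import Path

import numpy as np

from oculogas.geometry import PART_NAMES
from oculogas.pipeline import PipelineConfig, run_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    warnings.filterwarnings("ignore", message="multiple dark components")
    config = PipelineConfig(seed=SEED, noise_sd=0.0, out_dir=str(OUT))
    result = run_cohort(config)
    cases = result.cases
    gas_err = (cases["gas_pct"] - cases["gas_pct_true"]).abs()
    ang_err = (cases["angle_deg"] - cases["angle_deg_true"]).abs()
    rate_dev = np.abs(
        np.concatenate(
            [cases[f"rate_{p}"] - cases[f"rate_{p}_analytic"] for p in PART_NAMES]
        )
    )
    print(cases[["case_id", "posture", "gas_pct_true", "gas_pct",
                 "angle_deg_true", "angle_deg"]].to_string(index=False))
    print(f"\ngas volume recovery:   max |error| = {gas_err.max():.2f} points "
          f"(driving values 34.5-70.8%)")
    print(f"supraduction recovery: max |error| = {ang_err.max():.3f} deg")
    print(f"contact rates vs analytic oracle: max |deviation| = {rate_dev.max():.2f} points")
    print(f"\nwrote {OUT / 'cohort_cases.csv'}, {OUT / 'cohort_summary.csv'}, "
          f"{OUT / 'manifest.json'}")


if __name__ == "__main__":
    main()
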