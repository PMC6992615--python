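"""Packaged per-case clinical tables of the eight-eye cohort.

Three small CSVs ship with the package: patient characteristics (age, sex,
axial length, break counts), postoperative outcomes (pre/post BCVA in
logMAR), and the per-case gas volume percentage and supraduction angle in
each posture.  They drive the phantom cohort and the summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_patients", "load_outcomes", "load_gas_angle"]

_FILES = {
    "patients": "table1_patients.csv",
    "outcomes": "table2_outcomes.csv",
    "gas_angle": "table3_gas_angle.csv",
}


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("oculogas").joinpath("data", _FILES[name])
    with ref.open("rb") as fh:
        return pd.read_csv(fh)


def load_patients() -> pd.DataFrame:
    """Per-case patient characteristics (axial length in mm, breaks, etc.)."""
    return _load("patients")


def load_outcomes() -> pd.DataFrame:
    """Per-case postoperative outcomes (BCVA in logMAR, reattachment)."""
    return _load("outcomes")


def load_gas_angle() -> pd.DataFrame:
    """Per-case gas volume (%) and supraduction angle (deg), both postures."""
    return _load("gas_angle")
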