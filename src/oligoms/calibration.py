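"""Traveling-wave drift-time to collision-cross-section calibration.

T-wave drift times have no closed-form relation to mobility, so Omega is
obtained by calibration against denatured protein standards of known
cross-section. The protocol:

1. correct each drift time for the mass-dependent flight time after the
   mobility cell: ``t_d' = t_d - c * sqrt(m/z) / 1000``;
2. normalise reference cross-sections for charge and reduced mass:
   ``Omega' = Omega_ref / (z * sqrt(1/mu))`` with
   ``mu = m*M_gas / (m + M_gas)``;
3. fit the power law ``ln Omega' = ln A + X * ln t_d'``;
4. for an unknown, ``Omega = A * t_d'^X * z * sqrt(1/mu)``, valid only
   for corrected drift times inside the calibrated range.

The calibration record carries every fitted constant (c, A, X, r2, gas,
validity range) — nothing is hidden.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import GAS_MASS

__all__ = [
    "CalibrantIon",
    "CcsCalibration",
    "correct_drift_time",
    "fit_calibration",
    "ccs_from_drift",
    "load_default_calibrants",
    "average_ccs",
]


@dataclass(frozen=True)
class CalibrantIon:
    """One charge state of a calibrant protein with reference Omega."""

    protein: str
    charge: int
    mass: float  # Da
    ccs_ref: float  # Angstrom^2
    drift_time: float  # ms

    def __post_init__(self) -> None:
        if min(self.charge, self.mass, self.ccs_ref, self.drift_time) <= 0:
            raise ValueError("calibrant fields must all be positive")


@dataclass
class CcsCalibration:
    """Fitted power-law calibration record."""

    c: float  # EDC-style mass-dependent correction constant
    exponent: float  # X
    scale: float  # A
    r_squared: float
    td_range: tuple[float, float]  # corrected drift time validity, ms
    gas: str = "N2"

    def __post_init__(self) -> None:
        if self.exponent <= 0 or self.scale <= 0:
            raise ValueError("exponent and scale must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.td_range[0] >= self.td_range[1]:
            raise ValueError("validity range must have min < max")

    def to_json(self) -> str:
        d = asdict(self)
        d["td_range"] = list(self.td_range)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CcsCalibration":
        d = json.loads(text)
        d["td_range"] = tuple(d["td_range"])
        return cls(**d)


def correct_drift_time(t_d: float, mz: float, c: float) -> float:
    """Remove the mass-dependent post-mobility flight time.

    ``t_d' = t_d - c * sqrt(m/z) / 1000`` with t_d in ms and c the
    instrument's EDC delay coefficient.
    """
    if t_d <= 0:
        raise ValueError("drift time must be positive")
    t_corr = t_d - c * math.sqrt(mz) / 1000.0
    if t_corr <= 0:
        raise ValueError(
            f"mass-dependent correction ({c * math.sqrt(mz) / 1000.0:.4f} ms) "
            f"exceeds the drift time ({t_d} ms)"
        )
    return t_corr


def _reduced_mass(ion_mass: float, gas_mass: float) -> float:
    return ion_mass * gas_mass / (ion_mass + gas_mass)


def fit_calibration(
    calibrants: Sequence[CalibrantIon],
    gas: str = "N2",
    c: float = 1.41,
) -> CcsCalibration:
    """Log-log power-law fit of normalised Omega against corrected t_d."""
    if len(calibrants) < 3:
        raise ValueError("need at least 3 calibrant ions")
    gas_mass = GAS_MASS[gas] if gas in GAS_MASS else float(gas)
    td_corr = np.array(
        [
            correct_drift_time(
                ion.drift_time, (ion.mass + ion.charge * 1.007276) / ion.charge, c
            )
            for ion in calibrants
        ]
    )
    if np.ptp(td_corr) == 0:
        raise ValueError("degenerate corrected drift times")
    if td_corr.max() / td_corr.min() < 1.2:
        raise ValueError(
            "calibrants must span more than a 1.2x range in corrected drift time"
        )
    omega_prime = np.array(
        [
            ion.ccs_ref
            / (ion.charge * math.sqrt(1.0 / _reduced_mass(ion.mass, gas_mass)))
            for ion in calibrants
        ]
    )
    res = stats.linregress(np.log(td_corr), np.log(omega_prime))
    return CcsCalibration(
        c=c,
        exponent=float(res.slope),
        scale=float(math.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        td_range=(float(td_corr.min()), float(td_corr.max())),
        gas=gas,
    )


def ccs_from_drift(
    cal: CcsCalibration,
    t_d: float,
    charge: int,
    mass: float,
    extrapolate: bool = False,
) -> float:
    """Omega (Angstrom^2) of an unknown ion from its drift time.

    The corrected drift time must fall inside the calibrated range;
    extrapolating a T-wave power law is not quantitatively meaningful,
    so out-of-range values are rejected rather than extrapolated.
    ``extrapolate=True`` lifts the guard for qualitative uses (candidate
    plausibility ranking); never report an extrapolated value as a
    measured cross-section.
    """
    gas_mass = GAS_MASS[cal.gas] if cal.gas in GAS_MASS else float(cal.gas)
    mz = (mass + charge * 1.007276) / charge
    td_corr = correct_drift_time(t_d, mz, cal.c)
    lo, hi = cal.td_range
    if not extrapolate and not lo <= td_corr <= hi:
        raise ValueError(
            f"corrected drift time {td_corr:.4f} ms lies outside the "
            f"calibrated range [{lo:.4f}, {hi:.4f}] ms; cross-sections are "
            "only derived for drift times falling within the calibration curve"
        )
    return (
        cal.scale
        * td_corr**cal.exponent
        * charge
        * math.sqrt(1.0 / _reduced_mass(mass, gas_mass))
    )


def average_ccs(values: Sequence[float]) -> tuple[float, float]:
    """Mean +/- sample s.d. of Omega across replicate calibrations.

    Replicate wave heights are treated as independent calibrations whose
    Omega estimates are averaged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def load_default_calibrants(drift_times: dict | None = None) -> pd.DataFrame:
    """The packaged denatured-calibrant reference table.

    Denatured ubiquitin (+9 to +11), myoglobin (+15 to +22) and
    cytochrome C (+11 to +18): 19 charge states in total. Reference
    cross-sections are literature-derived (helium drift-tube
    measurements of denatured charge states) and intended as replaceable
    defaults — supply your own table for quantitative work.

    ``drift_times`` optionally maps ``(protein, charge)`` to a measured
    drift time (ms), filling the ``drift_time`` column.
    """
    ref = resources.files("oligoms.data").joinpath("calibrants_denatured_he.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if drift_times is not None:
        df["drift_time"] = [
            drift_times.get((row.protein, row.charge), float("nan"))
            for row in df.itertuples()
        ]
    return df
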