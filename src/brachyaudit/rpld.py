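"""RPLD signal-to-dose conversion.

A radiophotoluminescent glass dosimeter (RPLD) reading is converted to
absorbed dose in two steps.  First the raw reader signal is corrected for
background, individual dosimeter sensitivity, fading and readout tray
position:

    M = (raw - background) * sensitivity * fading * tray

then dose is determined through the system calibration coefficient N
(established in a Co-60 reference beam) and the audit correction factors:

    D = M * N * k_Q * k_s * k_m

Sensitivity, fading and tray factors are caller-supplied multiplicative
corrections from the audit system's standing characterization; no fading
model is implemented here (audit irradiations are scheduled inside a
three-day window over which fading is negligible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RPLDReading",
    "CalibrationModel",
    "corrected_signal",
    "determine_dose",
    "combine_duplicates",
    "read_rpld_csv",
]


@dataclass(frozen=True)
class RPLDReading:
    """One raw RPLD readout with its per-dosimeter correction factors."""

    dosimeter_id: str
    raw_signal: float
    sensitivity_factor: float = 1.0
    fading_factor: float = 1.0
    tray_position_factor: float = 1.0
    background_signal: float = 0.0

    def __post_init__(self):
        if self.background_signal < 0:
            raise ValueError("background signal must be non-negative")
        if self.raw_signal < self.background_signal:
            raise ValueError("raw signal below background")
        for name in ("sensitivity_factor", "fading_factor",
                     "tray_position_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """System calibration coefficient N (Gy per corrected signal unit),
    referenced to a Co-60 EBRT beam."""

    N_Gy_per_signal: float
    reference_quality: str = "Co-60 EBRT"

    def __post_init__(self):
        if self.N_Gy_per_signal <= 0:
            raise ValueError("calibration coefficient must be positive")


def corrected_signal(reading: RPLDReading) -> float:
    """Background-subtracted signal times the multiplicative corrections.

    Background is subtracted from the raw signal first; the sensitivity,
    fading and tray factors then apply in any order (pure product).
    """
    net = reading.raw_signal - reading.background_signal
    return (net * reading.sensitivity_factor * reading.fading_factor
            * reading.tray_position_factor)


def determine_dose(M: float, N: float, kQ: float, ks: float, km: float,
                   relative_us: tuple[float, ...] | None = None):
    """Audit dose D = M * N * kQ * ks * km (Gy).

    If ``relative_us`` is given (relative standard uncertainties of any of
    the inputs), returns ``(dose, u_dose)`` with the relative components
    combined in quadrature.
    """
    for name, v in (("M", M), ("N", N), ("kQ", kQ), ("ks", ks), ("km", km)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    dose = M * N * kQ * ks * km
    if relative_us is None:
        return dose
    rel = math.sqrt(sum(u**2 for u in relative_us))
    return dose, dose * rel


def combine_duplicates(d1: float, d2: float) -> tuple[float, float]:
    """Average the two duplicate-irradiation doses of one audit set.

    Returns ``(mean, intra-set relative difference in %)`` with the
    difference defined as |d1 - d2| / mean * 100.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("doses must be positive")
    mean = (d1 + d2) / 2.0
    return mean, abs(d1 - d2) / mean * 100.0


def read_rpld_csv(path) -> list[RPLDReading]:
    """Read RPLD readings from CSV with columns dosimeter_id, raw_signal
    and optional background_signal, sensitivity_factor, fading_factor,
    tray_position_factor."""
    df = pd.read_csv(path)
    if not {"dosimeter_id", "raw_signal"}.issubset(df.columns):
        raise ValueError("RPLD CSV needs dosimeter_id and raw_signal columns")
    defaults = {"background_signal": 0.0, "sensitivity_factor": 1.0,
                "fading_factor": 1.0, "tray_position_factor": 1.0}
    out = []
    for _, row in df.iterrows():
        kwargs = {k: float(row[k]) if k in df.columns else v
                  for k, v in defaults.items()}
        out.append(RPLDReading(dosimeter_id=str(row["dosimeter_id"]),
                               raw_signal=float(row["raw_signal"]), **kwargs))
    return out
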