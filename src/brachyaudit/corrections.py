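"""Audit correction factors: lack of scatter, phantom material, beam quality.

The postal audit setup (a compact PMMA phantom on a table) deviates from
the full-scatter, water-equivalent conditions assumed by TG-43.  Three
multiplicative correction factors restore the equivalence, each estimated
as the ratio of mean RPLD doses between two experimental setups:

* ``k_s``  (lack of scatter)        = D(phantom in water) / D(phantom on table)
* ``k_m``  (non-water equivalence)  = D(water-equivalent phantom in water)
                                      / D(PMMA phantom in water)
* ``k_Q``  (beam quality)           = D(Co-60 reference beam)
                                      / D(water-equivalent phantom in water)

The total correction applied in the audit averages the experimental and
Monte-Carlo estimates of ``k_m`` and ``k_s`` and multiplies by ``k_Q``:

    k_tot = mean(k_m_exp, k_m_mc) * mean(k_s_exp, k_s_mc) * k_Q

Each factor carries a standard (k = 1) uncertainty.  Ratios are formed as
ratios of set means (the dosimeters are unpaired), with the uncertainty of
each mean taken as the standard error SD/sqrt(n) and relative
uncertainties combined in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementSet",
    "CorrectionFactor",
    "AgreementReport",
    "ratio_factor",
    "combine_total",
    "validate_against_reference",
    "read_measurement_sets",
]

SETUP_LABELS = ("A", "B_pmma_in_water", "C_plasticwater_in_water",
                "reference_co60")
FACTOR_KINDS = ("k_s", "k_m", "k_Q", "k_tot")


@dataclass(frozen=True)
class MeasurementSet:
    """A labelled group of RPLD dose readings for one irradiation setup."""

    setup_label: str
    radionuclide: str
    readings_Gy: np.ndarray

    def __post_init__(self):
        if self.setup_label not in SETUP_LABELS:
            raise ValueError(f"unknown setup label {self.setup_label!r}")
        readings = np.asarray(self.readings_Gy, dtype=float)
        if readings.size < 2:
            raise ValueError("a measurement set needs at least 2 readings")
        if np.any(readings <= 0):
            raise ValueError("all dose readings must be positive")
        object.__setattr__(self, "readings_Gy", readings)

    @property
    def n(self) -> int:
        return int(self.readings_Gy.size)

    @property
    def mean(self) -> float:
        return float(self.readings_Gy.mean())

    @property
    def sem(self) -> float:
        """Standard error of the mean, SD/sqrt(n) (sample SD, ddof=1)."""
        return float(self.readings_Gy.std(ddof=1) / math.sqrt(self.n))


@dataclass(frozen=True)
class CorrectionFactor:
    """A correction factor value with standard (k = 1) uncertainty."""

    kind: str
    value: float
    u: float
    provenance: str = "experimental"    # experimental | mc | combined

    def __post_init__(self):
        if self.kind not in FACTOR_KINDS:
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError("factor value must be positive")
        if self.u < 0:
            raise ValueError("standard uncertainty must be non-negative")

    @property
    def relative_u(self) -> float:
        return self.u / self.value

    def __str__(self) -> str:
        return f"{self.kind} = {self.value:.3f} ± {self.u:.3f}"


def ratio_factor(numerator: MeasurementSet, denominator: MeasurementSet,
                 kind: str) -> CorrectionFactor:
    """Correction factor as the ratio of two measurement-set means.

    Uncertainty: u = value * sqrt((SEM_num/mean_num)^2 +
    (SEM_den/mean_den)^2).  Sets must share a radionuclide except for the
    beam-quality factor, whose numerator is the Co-60 reference-beam set.
    """
    if kind != "k_Q" and numerator.radionuclide != denominator.radionuclide:
        raise ValueError("measurement sets were made with different sources")
    if denominator.mean == 0:
        raise ArithmeticError("denominator set has zero mean")
    value = numerator.mean / denominator.mean
    rel = math.hypot(numerator.sem / numerator.mean,
                     denominator.sem / denominator.mean)
    return CorrectionFactor(kind=kind, value=value, u=value * rel,
                            provenance="experimental")


def combine_total(km_exp: CorrectionFactor, km_mc: CorrectionFactor,
                  ks_exp: CorrectionFactor, ks_mc: CorrectionFactor,
                  kQ: CorrectionFactor) -> CorrectionFactor:
    """Total correction: mean(k_m pair) * mean(k_s pair) * k_Q.

    Each pair mean carries u = sqrt(u1^2 + u2^2)/2 (uncorrelated inputs);
    the relative uncertainties of the two pair means and of k_Q then
    combine in quadrature.
    """
    for f, want in ((km_exp, "k_m"), (km_mc, "k_m"),
                    (ks_exp, "k_s"), (ks_mc, "k_s"), (kQ, "k_Q")):
        if f.kind != want:
            raise ValueError(f"expected a {want} factor, got {f.kind}")
    km = (km_exp.value + km_mc.value) / 2.0
    ks = (ks_exp.value + ks_mc.value) / 2.0
    u_km = math.hypot(km_exp.u, km_mc.u) / 2.0
    u_ks = math.hypot(ks_exp.u, ks_mc.u) / 2.0
    value = km * ks * kQ.value
    rel = math.sqrt((u_km / km) ** 2 + (u_ks / ks) ** 2
                    + kQ.relative_u ** 2)
    return CorrectionFactor(kind="k_tot", value=value, u=value * rel,
                            provenance="combined")


@dataclass(frozen=True)
class AgreementReport:
    """Comparison of an experimental factor against a reference value."""

    kind: str
    difference_pct: float
    tolerance_pct: float
    within_tolerance: bool
    within_expanded_uncertainty: bool
    coverage_k: float = 2.0


def validate_against_reference(exp: CorrectionFactor, ref: CorrectionFactor,
                               tolerance_pct: float,
                               coverage_k: float = 2.0) -> AgreementReport:
    """Report |exp/ref - 1| in percent, against a stated tolerance and
    against the combined expanded uncertainty at coverage factor k."""
    if exp.kind != ref.kind:
        raise ValueError("cannot compare factors of different kinds")
    diff_pct = abs(exp.value / ref.value - 1.0) * 100.0
    u_comb = math.hypot(exp.u, ref.u)
    return AgreementReport(
        kind=exp.kind,
        difference_pct=diff_pct,
        tolerance_pct=tolerance_pct,
        within_tolerance=diff_pct <= tolerance_pct,
        within_expanded_uncertainty=(abs(exp.value - ref.value)
                                     <= coverage_k * u_comb),
        coverage_k=coverage_k)


def read_measurement_sets(path) -> dict[tuple[str, str], MeasurementSet]:
    """Read measurement sets from CSV with columns setup_label,
    radionuclide, reading_Gy (one row per dosimeter); keyed by
    (setup_label, radionuclide)."""
    df = pd.read_csv(path)
    required = {"setup_label", "radionuclide", "reading_Gy"}
    if not required.issubset(df.columns):
        raise ValueError(f"measurement CSV must have columns {sorted(required)}")
    out = {}
    for (label, nuclide), grp in df.groupby(["setup_label", "radionuclide"]):
        out[(label, nuclide)] = MeasurementSet(
            setup_label=label, radionuclide=nuclide,
            readings_Gy=grp["reading_Gy"].to_numpy())
    return out
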