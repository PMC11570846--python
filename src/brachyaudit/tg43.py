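"""AAPM TG-43 dose engine for HDR brachytherapy sources.

The TG-43 formalism expresses the dose rate to water around a sealed
photon-emitting source as

    Ddot(r, theta) = S_K * Lambda * [G(r, theta) / G(r0, theta0)]
                     * g(r) * F(r, theta)

with ``S_K`` the air-kerma strength (numerically equal to the reference air
kerma rate, RAKR, when both are expressed in U = uGy m^2 h^-1), ``Lambda``
the dose-rate constant in cGy h^-1 U^-1, ``G`` the geometry function
(``1/r^2`` for a point source, ``beta / (L r sin theta)`` for a line source
of active length ``L``), ``g(r)`` the radial dose function and
``F(r, theta)`` the 2-D anisotropy function.  The reference point is
``r0 = 1 cm``, ``theta0 = 90 deg``.

Source characterization data (``Lambda``, ``L``, ``g`` table, ``F`` grid)
are carried by :class:`SourceDataset` and can be loaded from JSON.  Three
datasets are bundled: an idealized unit-strength point source (``toy``) for
analytic cross-checks, and generic Ir-192 / Co-60 line sources with
representative, synthetic consensus-style tables (see the files'
``provenance`` metadata; they are not vendor characterizations).

Distances are given in mm in the laboratory (phantom) frame and converted
to cm internally; dwell times are seconds; doses are Gy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "SourceDataset",
    "DwellPoint",
    "DoseSample",
    "geometry_function",
    "interpolate_radial",
    "dose_rate_at",
    "accumulate_dose",
    "load_source",
    "bundled_sources",
]

MM_PER_CM = 10.0
GY_PER_CGY = 0.01
#: reference point of the formalism: r0 = 1 cm, theta0 = 90 degrees
R0_CM = 1.0
THETA0_DEG = 90.0

_RADIONUCLIDES = ("Ir-192", "Co-60", "toy")
_GEOMETRY_MODELS = ("point", "line")


def geometry_function(r_cm, theta_deg, active_length_mm: float = 0.0,
                      model: str = "point"):
    """Evaluate the TG-43 geometry function G(r, theta) in cm^-2.

    Parameters
    ----------
    r_cm : float or array
        Distance from the source centre, cm. Must be positive.
    theta_deg : float or array
        Polar angle from the source long axis, degrees in (0, 180].
        Ignored in point mode.
    active_length_mm : float
        Active source length L, mm; required positive in line mode.
    model : {"point", "line"}
        ``point`` returns ``1/r^2``; ``line`` returns
        ``beta / (L r sin theta)`` with ``beta`` the angle subtended by the
        active length at the calculation point.  On the long axis
        (``sin theta -> 0``) the documented limit ``1/(r^2 - L^2/4)`` is
        used, which is the analytic continuation of the line form.
    """
    r = np.asarray(r_cm, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("geometry function is undefined at r <= 0")
    if model == "point":
        out = 1.0 / r**2
        return out.item() if out.ndim == 0 else out
    if model != "line":
        raise ValueError(f"unknown geometry model {model!r}")
    if active_length_mm <= 0.0:
        raise ValueError("line-source geometry requires active_length_mm > 0")

    L = active_length_mm / MM_PER_CM
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    r, theta = np.broadcast_arrays(r, theta)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    # beta = angle at the point between the two ends of the active length
    y = r * sin_t
    x = r * cos_t
    beta = np.arctan2(y, x - L / 2.0) - np.arctan2(y, x + L / 2.0)

    on_axis = np.abs(sin_t) < 1.0e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        g_line = beta / (L * r * sin_t)
    g_axis = 1.0 / (r**2 - L**2 / 4.0)
    if np.any(on_axis & (r <= L / 2.0)):
        raise ValueError("on-axis geometry function undefined for r <= L/2")
    out = np.where(on_axis, g_axis, g_line)
    return out.item() if out.ndim == 0 else out


def interpolate_radial(table: np.ndarray, r_cm) -> np.ndarray | float:
    """Linearly interpolate a radial dose table ``[[r_cm, g], ...]`` at r.

    Outside the tabulated range the nearest value is returned and a
    warning is emitted; more than 20 % beyond either end is a hard error
    (the clamp would no longer be a small extrapolation).
    """
    table = np.asarray(table, dtype=float)
    if table.size == 0:
        raise ValueError("empty radial dose table")
    radii, values = table[:, 0], table[:, 1]
    r = np.asarray(r_cm, dtype=float)
    if np.any(r < radii[0] / 1.2) or np.any(r > radii[-1] * 1.2):
        raise ValueError(
            f"r outside supported range [{radii[0] / 1.2:g}, "
            f"{radii[-1] * 1.2:g}] cm")
    if np.any(r < radii[0]) or np.any(r > radii[-1]):
        warnings.warn(
            "radius outside radial dose table; clamping to nearest value",
            stacklevel=2)
    out = np.interp(r, radii, values)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class SourceDataset:
    """TG-43 characterization of one HDR source model."""

    label: str
    radionuclide: str
    dose_rate_constant: float          # Lambda, cGy h^-1 U^-1
    active_length_mm: float
    geometry_model: str                # "point" or "line"
    radial_dose: np.ndarray            # (N, 2) array of [r_cm, g(r)]
    anisotropy_r: np.ndarray           # (Nr,) radii, cm
    anisotropy_theta: np.ndarray       # (Nt,) angles, degrees
    anisotropy_F: np.ndarray           # (Nr, Nt) grid of F(r, theta)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "radial_dose",
                           np.asarray(self.radial_dose, dtype=float))
        object.__setattr__(self, "anisotropy_r",
                           np.asarray(self.anisotropy_r, dtype=float))
        object.__setattr__(self, "anisotropy_theta",
                           np.asarray(self.anisotropy_theta, dtype=float))
        object.__setattr__(self, "anisotropy_F",
                           np.asarray(self.anisotropy_F, dtype=float))
        if self.radionuclide not in _RADIONUCLIDES:
            raise ValueError(f"unknown radionuclide {self.radionuclide!r}")
        if self.geometry_model not in _GEOMETRY_MODELS:
            raise ValueError(f"unknown geometry model {self.geometry_model!r}")
        if self.dose_rate_constant <= 0:
            raise ValueError("dose_rate_constant must be positive")
        if self.geometry_model == "line" and self.active_length_mm <= 0:
            raise ValueError("line source requires active_length_mm > 0")
        radii = self.radial_dose[:, 0]
        if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
            raise ValueError("radial dose radii must be positive, increasing")
        g1 = float(np.interp(1.0, radii, self.radial_dose[:, 1]))
        if abs(g1 - 1.0) > 1.0e-9:
            raise ValueError(f"g(1 cm) must equal 1, got {g1}")
        if self.anisotropy_F.shape != (self.anisotropy_r.size,
                                       self.anisotropy_theta.size):
            raise ValueError("anisotropy grid shape mismatch")
        i90 = np.searchsorted(self.anisotropy_theta, 90.0)
        if (i90 >= self.anisotropy_theta.size
                or self.anisotropy_theta[i90] != 90.0
                or not np.allclose(self.anisotropy_F[:, i90], 1.0,
                                   atol=1.0e-9)):
            raise ValueError("anisotropy table must satisfy F(r, 90 deg) = 1")
        interp = RegularGridInterpolator(
            (self.anisotropy_r, self.anisotropy_theta), self.anisotropy_F,
            method="linear", bounds_error=False, fill_value=None)
        object.__setattr__(self, "_F_interp", interp)

    # -- table evaluation ---------------------------------------------------

    def radial_dose_function(self, r_cm):
        """g(r) by linear interpolation; clamped outside the table."""
        return interpolate_radial(self.radial_dose, r_cm)

    def anisotropy(self, r_cm, theta_deg):
        """F(r, theta) by bilinear interpolation, clamped to the grid."""
        r = np.clip(np.asarray(r_cm, dtype=float),
                    self.anisotropy_r[0], self.anisotropy_r[-1])
        t = np.clip(np.asarray(theta_deg, dtype=float),
                    self.anisotropy_theta[0], self.anisotropy_theta[-1])
        r, t = np.broadcast_arrays(r, t)
        out = self._F_interp(np.stack([r, t], axis=-1))
        return out.item() if out.ndim == 0 else out

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_json(cls, path) -> "SourceDataset":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            label=raw["label"],
            radionuclide=raw["radionuclide"],
            dose_rate_constant=raw["lambda_cGy_per_h_per_U"],
            active_length_mm=raw["active_length_mm"],
            geometry_model=raw["geometry_model"],
            radial_dose=np.asarray(raw["radial_dose"], dtype=float),
            anisotropy_r=np.asarray(raw["anisotropy"]["r_cm"], dtype=float),
            anisotropy_theta=np.asarray(raw["anisotropy"]["theta_deg"],
                                        dtype=float),
            anisotropy_F=np.asarray(raw["anisotropy"]["F"], dtype=float),
            metadata=raw.get("metadata", {}),
        )

    def to_json(self, path) -> None:
        payload = {
            "label": self.label,
            "radionuclide": self.radionuclide,
            "lambda_cGy_per_h_per_U": self.dose_rate_constant,
            "active_length_mm": self.active_length_mm,
            "geometry_model": self.geometry_model,
            "radial_dose": self.radial_dose.tolist(),
            "anisotropy": {
                "r_cm": self.anisotropy_r.tolist(),
                "theta_deg": self.anisotropy_theta.tolist(),
                "F": self.anisotropy_F.tolist(),
            },
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class DwellPoint:
    """One source stopping point: position (mm), dwell time (s), axis.

    ``axis`` is the unit direction of the catheter at the dwell; the TG-43
    polar angle is measured from it.
    """

    position_mm: tuple[float, float, float]
    dwell_time_s: float
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.dwell_time_s < 0:
            raise ValueError("dwell time must be non-negative")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("dwell axis must be a non-zero vector")
        object.__setattr__(self, "axis", tuple(a / n))


@dataclass
class DoseSample:
    """A sampling position (mm) with its accumulated dose (Gy)."""

    position_mm: tuple[float, float, float]
    dose_Gy: float = 0.0

    def __post_init__(self):
        if self.dose_Gy < 0:
            raise ValueError("dose must be non-negative")


def _dose_rate_matrix(points_mm: np.ndarray, dwells: Sequence[DwellPoint],
                      source: SourceDataset, rakr_U: float) -> np.ndarray:
    """(N points, M dwells) matrix of TG-43 dose rates, Gy/h."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    dpos = np.asarray([d.position_mm for d in dwells], dtype=float)
    axes = np.asarray([d.axis for d in dwells], dtype=float)
    disp = (pts[:, None, :] - dpos[None, :, :]) / MM_PER_CM   # cm
    r = np.linalg.norm(disp, axis=-1)
    if np.any(r == 0.0):
        raise ValueError("calculation point coincides with a dwell position")
    cos_t = np.clip(np.einsum("nmk,mk->nm", disp, axes) / r, -1.0, 1.0)
    theta = np.rad2deg(np.arccos(cos_t))

    G = geometry_function(r, theta, source.active_length_mm,
                          source.geometry_model)
    G0 = geometry_function(R0_CM, THETA0_DEG, source.active_length_mm,
                           source.geometry_model)
    g = source.radial_dose_function(r)
    F = source.anisotropy(r, theta)
    rate_cGy_h = rakr_U * source.dose_rate_constant * (G / G0) * g * F
    return rate_cGy_h * GY_PER_CGY


def dose_rate_at(point_mm, dwell: DwellPoint, source: SourceDataset,
                 rakr_U: float) -> float:
    """TG-43 dose rate (Gy/h) at one point from one dwell position.

    ``rakr_U`` is the reference air kerma rate in U, treated as numerically
    equal to the air-kerma strength S_K.
    """
    if rakr_U <= 0:
        raise ValueError("rakr_U must be positive")
    return float(_dose_rate_matrix(np.asarray(point_mm, dtype=float),
                                   [dwell], source, rakr_U)[0, 0])


def accumulate_dose(points_mm, dwells: Sequence[DwellPoint],
                    source: SourceDataset, rakr_U: float) -> np.ndarray:
    """Superpose dose (Gy) at each point over all dwells: sum of
    rate x dwell time."""
    if rakr_U <= 0:
        raise ValueError("rakr_U must be positive")
    times_h = np.asarray([d.dwell_time_s for d in dwells], dtype=float) / 3600.0
    if not np.all(np.isfinite(times_h)):
        raise ValueError("dwell times must be finite")
    rates = _dose_rate_matrix(points_mm, dwells, source, rakr_U)
    return rates @ times_h


# -- bundled datasets -------------------------------------------------------

def bundled_sources() -> list[str]:
    """Labels of the source datasets shipped with the package."""
    pkg = resources.files("brachyaudit.data")
    return sorted(p.name[len("source_"):-len(".json")]
                  for p in pkg.iterdir()
                  if p.name.startswith("source_") and p.name.endswith(".json"))


def load_source(name_or_path: str | Path) -> SourceDataset:
    """Load a source dataset from a JSON file or by bundled name
    (``toy``, ``ir192_generic``, ``co60_generic``)."""
    path = Path(name_or_path)
    if path.exists():
        return SourceDataset.from_json(path)
    pkg = resources.files("brachyaudit.data")
    candidate = pkg / f"source_{name_or_path}.json"
    if candidate.is_file():
        with resources.as_file(candidate) as fh:
            return SourceDataset.from_json(fh)
    raise FileNotFoundError(
        f"no such source dataset: {name_or_path!r} "
        f"(bundled: {', '.join(bundled_sources())})")
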