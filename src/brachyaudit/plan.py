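"""Standardized two-catheter audit plan and RPLD volume dose metrics.

The audit phantom is a 160 x 80 x 30 mm PMMA block with two parallel
catheter channels 40 mm apart and a cylindrical RPLD (12 mm x 1.5 mm
diameter) centred between them.  The reference plan steps the source
through 13 dwell positions per catheter at 5 mm spacing with one uniform
dwell time, chosen so that the accumulated TG-43 dose at a control point at
the centre of the RPLD sensitive volume equals the 2 Gy prescription.

Coordinate frame: origin at the phantom centre (= RPLD centre = control
point); catheters run along +x at y = +-20 mm, z = 0; dwells span
x = -30 ... +30 mm, symmetric about the control point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from brachyaudit.tg43 import (DwellPoint, SourceDataset, _dose_rate_matrix,
                              accumulate_dose)

__all__ = [
    "PhantomGeometry",
    "ReferencePlan",
    "VolumeDoseMetrics",
    "build_reference_plan",
    "rpld_dose_metrics",
]


@dataclass(frozen=True)
class PhantomGeometry:
    """Audit phantom dimensions (mm)."""

    outer_mm: tuple[float, float, float] = (160.0, 80.0, 30.0)
    channel_separation_mm: float = 40.0
    rpld_length_mm: float = 12.0
    rpld_diameter_mm: float = 1.5
    #: length of the RPLD sensitive volume used for dose metrics; the full
    #: glass rod is 12 mm but only a central section is read out.
    sensitive_length_mm: float = 6.0

    def __post_init__(self):
        if self.channel_separation_mm <= self.rpld_diameter_mm:
            raise ValueError("channels must clear the RPLD diameter")
        if not 0 < self.sensitive_length_mm <= self.rpld_length_mm:
            raise ValueError("sensitive length must be in (0, rpld_length]")


@dataclass(frozen=True)
class ReferencePlan:
    """The solved audit plan: 26 dwells with one uniform dwell time."""

    dwells: tuple[DwellPoint, ...]
    step_mm: float
    dwells_per_catheter: int
    uniform_dwell_time_s: float
    prescription_Gy: float
    control_point_mm: tuple[float, float, float]
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)

    def __post_init__(self):
        if len(self.dwells) != 2 * self.dwells_per_catheter:
            raise ValueError("plan must hold two full catheters of dwells")
        times = {d.dwell_time_s for d in self.dwells}
        if len(times) != 1:
            raise ValueError("reference plan dwell times must be uniform")


def _dwell_positions(geometry: PhantomGeometry, n_per_catheter: int = 13,
                     step_mm: float = 5.0) -> np.ndarray:
    half_span = (n_per_catheter - 1) / 2.0 * step_mm
    xs = -half_span + step_mm * np.arange(n_per_catheter)
    y = geometry.channel_separation_mm / 2.0
    pos = [(x, sy * y, 0.0) for sy in (+1.0, -1.0) for x in xs]
    return np.asarray(pos)


def build_reference_plan(source: SourceDataset, rakr_U: float,
                         geometry: PhantomGeometry | None = None,
                         prescription_Gy: float = 2.0) -> ReferencePlan:
    """Solve the uniform dwell time delivering the prescription to the
    control point at the phantom centre.

    The dose at the control point is linear in the common dwell time t:
    D = t * sum_i Ddot_i, so t = prescription / sum of dose rates.
    """
    if rakr_U <= 0:
        raise ValueError("rakr_U must be positive")
    geometry = geometry or PhantomGeometry()
    positions = _dwell_positions(geometry)
    probe = [DwellPoint(tuple(p), 0.0) for p in positions]
    control = (0.0, 0.0, 0.0)
    rates = _dose_rate_matrix(np.asarray([control]), probe, source, rakr_U)
    total_rate_Gy_h = float(rates.sum())
    if total_rate_Gy_h <= 0:
        raise ArithmeticError("total dose rate at the control point is zero")
    t_s = prescription_Gy / total_rate_Gy_h * 3600.0
    dwells = tuple(DwellPoint(tuple(p), t_s) for p in positions)
    return ReferencePlan(
        dwells=dwells, step_mm=5.0, dwells_per_catheter=13,
        uniform_dwell_time_s=t_s, prescription_Gy=prescription_Gy,
        control_point_mm=control, geometry=geometry)


@dataclass(frozen=True)
class VolumeDoseMetrics:
    d_min_Gy: float
    d_max_Gy: float
    d_mean_Gy: float
    n_samples: int

    def __post_init__(self):
        if not self.d_min_Gy <= self.d_mean_Gy <= self.d_max_Gy:
            raise ValueError("dose metrics must satisfy min <= mean <= max")


def _cylinder_grid(length_mm: float, diameter_mm: float,
                   resolution_mm: float) -> np.ndarray:
    """Regular Cartesian grid clipped to a cylinder along x, centred at
    the origin."""
    half_l, radius = length_mm / 2.0, diameter_mm / 2.0

    def sym(half):
        # symmetric about 0 so the control point itself is always sampled
        pos = np.arange(0.0, half + resolution_mm / 2.0, resolution_mm)
        return np.concatenate([-pos[:0:-1], pos])

    ax, tr = sym(half_l), sym(radius)
    X, Y, Z = np.meshgrid(ax, tr, tr, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    return pts[pts[:, 1] ** 2 + pts[:, 2] ** 2 <= radius**2 + 1e-12]


def rpld_dose_metrics(plan: ReferencePlan, source: SourceDataset,
                      rakr_U: float,
                      sampling_resolution_mm: float = 0.1) -> VolumeDoseMetrics:
    """Min/max/mean dose over the RPLD sensitive volume.

    Samples the cylinder (``sensitive_length_mm`` long,
    ``rpld_diameter_mm`` across, axis along x, centred at the control
    point) on a regular grid and accumulates the plan dose at each sample.
    """
    if sampling_resolution_mm > 0.25:
        raise ValueError("sampling resolution must be <= 0.25 mm")
    g = plan.geometry
    pts = _cylinder_grid(g.sensitive_length_mm, g.rpld_diameter_mm,
                         sampling_resolution_mm)
    if pts.size == 0:
        raise ValueError("empty sensitive-volume sample set")
    pts = pts + np.asarray(plan.control_point_mm)
    doses = accumulate_dose(pts, plan.dwells, source, rakr_U)
    return VolumeDoseMetrics(
        d_min_Gy=float(doses.min()), d_max_Gy=float(doses.max()),
        d_mean_Gy=float(doses.mean()), n_samples=int(doses.size))
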