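"""Seeded synthetic-data generators for the audit chain.

These generators produce every input the analysis modules consume — RPLD
measurement sets, scanned-film rasters with a known injected source-track
shift, and whole audit cohorts — so the full pipeline can be exercised,
and its recovery of known ground truth quantified, without physical
measurements.  All generators are pure functions of their parameters and
a seed.

Default cohort parameters reproduce the stated world of a multicentre
pilot of 59 dosimeter sets: dose ratios Normal(1.008, 0.014), film shifts
Normal(1.2 mm, 2.5 mm), mean intra-set RPLD difference 1.6 %, and 45 of
59 sets irradiated with Ir-192 (the rest Co-60).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from brachyaudit.cohort import AuditRecord
from brachyaudit.corrections import MeasurementSet
from brachyaudit.film import FilmImage

__all__ = [
    "CohortModel",
    "simulate_measurement_set",
    "render_film",
    "save_film",
    "simulate_cohort",
]


def simulate_measurement_set(true_dose_Gy: float, cv_pct: float, n: int,
                             seed: int, setup_label: str = "A",
                             radionuclide: str = "Ir-192",
                             distribution: str = "lognormal",
                             ) -> MeasurementSet:
    """Simulate one RPLD measurement set.

    Readings are drawn with mean ``true_dose_Gy`` and coefficient of
    variation ``cv_pct`` percent, lognormal by default (doses are
    positive) or truncated-normal.  Deterministic for a fixed seed.
    """
    if cv_pct < 0:
        raise ValueError("cv_pct must be non-negative")
    if n < 2:
        raise ValueError("a measurement set needs n >= 2")
    rng = np.random.default_rng(seed)
    cv = cv_pct / 100.0
    if cv == 0:
        readings = np.full(n, true_dose_Gy)
    elif distribution == "lognormal":
        sigma2 = np.log1p(cv**2)
        mu = np.log(true_dose_Gy) - sigma2 / 2.0
        readings = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    elif distribution == "truncnorm":
        readings = np.abs(rng.normal(true_dose_Gy, cv * true_dose_Gy, size=n))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return MeasurementSet(setup_label=setup_label, radionuclide=radionuclide,
                          readings_Gy=readings)


def render_film(shift_mm: float, dpi: float = 300.0,
                track_length_mm: float = 60.0, noise_sd: float = 0.02,
                seed: int = 0, strip_mm: tuple[float, float] = (32.0, 140.0),
                track_width_mm: float = 4.0, edge_sigma_mm: float = 0.5,
                background: float = 0.85, contrast: float = 0.5,
                ) -> tuple[FilmImage, dict]:
    """Render a synthetic scanned film strip with an injected track shift.

    The strip raster matches the physical 32 x 140 mm film at the
    requested dpi.  The fiducial sits at the strip centre; the darkened
    band (smooth error-function edges, additive Gaussian pixel noise) is
    centred ``shift_mm`` proximal of it.  Returns the image together with
    a ground-truth dictionary.
    """
    height_mm, width_mm = strip_mm
    fiducial_mm = width_mm / 2.0
    mid_mm = fiducial_mm + shift_mm       # axis coordinate grows proximally
    e1, e2 = mid_mm - track_length_mm / 2.0, mid_mm + track_length_mm / 2.0
    margin = 3.0 * edge_sigma_mm
    if e1 - margin < 0 or e2 + margin > width_mm:
        raise ValueError("track does not fit inside the film strip")

    rng = np.random.default_rng(seed)
    scale = 25.4 / dpi
    n_rows = int(round(height_mm / scale))
    n_cols = int(round(width_mm / scale))
    x = np.arange(n_cols) * scale                  # mm along the catheter
    y = np.arange(n_rows) * scale

    s = edge_sigma_mm * np.sqrt(2.0)
    along = 0.5 * (erf((x - e1) / s) - erf((x - e2) / s))
    y_mid = height_mm / 2.0
    w1, w2 = y_mid - track_width_mm / 2.0, y_mid + track_width_mm / 2.0
    across = 0.5 * (erf((y - w1) / s) - erf((y - w2) / s))

    img = background - contrast * np.outer(across, along)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.round(img * 65535).astype(np.uint16)

    fiducial_px = (n_rows / 2.0, fiducial_mm / scale)
    image = FilmImage(pixels=pixels, dpi=dpi, fiducial_px=fiducial_px,
                      axis=1, axis_points_proximal=True)
    truth = {"shift_mm": shift_mm, "track_midpoint_mm": mid_mm,
             "fiducial_mm": fiducial_mm, "track_length_mm": track_length_mm,
             "dpi": dpi, "noise_sd": noise_sd, "seed": seed}
    return image, truth


def save_film(image: FilmImage, truth: dict, png_path, meta_path=None) -> None:
    """Write the film raster as 16-bit PNG plus a JSON metadata sidecar
    (dpi, fiducial pixel coordinates, axis, orientation, ground truth)."""
    import imageio.v3 as iio

    png_path = Path(png_path)
    iio.imwrite(png_path, image.pixels)
    meta = {
        "dpi": image.dpi,
        "fiducial_px": list(image.fiducial_px),
        "axis": image.axis,
        "axis_points_proximal": image.axis_points_proximal,
        "ground_truth": truth,
    }
    meta_path = Path(meta_path) if meta_path else png_path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=1))


@dataclass(frozen=True)
class CohortModel:
    """Generative model of a multicentre audit cohort."""

    n_sets: int = 59
    ratio_mean: float = 1.008
    ratio_sd: float = 0.014
    shift_mean_mm: float = 1.2
    shift_sd_mm: float = 2.5
    #: mean absolute relative difference between the two RPLD doses of a set
    intra_set_diff_pct: float = 1.6
    d_user_Gy: float = 2.0
    #: per-film repeat SD around the set-level true shift
    film_sd_mm: float = 0.2
    ir_fraction: float = 45.0 / 59.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be at least 1")
        for name in ("ratio_sd", "shift_sd_mm", "intra_set_diff_pct",
                     "film_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_cohort(model: CohortModel) -> list[AuditRecord]:
    """Draw one audit cohort from the model, deterministically per seed.

    Per set: the dose ratio and the set-level shift are normal draws; the
    two RPLD doses split the set dose with a relative difference whose
    mean magnitude equals ``intra_set_diff_pct``; the two film shifts
    scatter around the set shift with SD ``film_sd_mm``.
    """
    rng = np.random.default_rng(model.seed)
    ratios = rng.normal(model.ratio_mean, model.ratio_sd, model.n_sets)
    shifts = rng.normal(model.shift_mean_mm, model.shift_sd_mm, model.n_sets)
    # half-normal |delta| has mean sigma*sqrt(2/pi); invert for sigma
    sigma_delta = model.intra_set_diff_pct / 100.0 * np.sqrt(np.pi / 2.0)
    deltas = rng.normal(0.0, sigma_delta, model.n_sets)
    film_err = rng.normal(0.0, model.film_sd_mm, (model.n_sets, 2))
    is_ir = rng.random(model.n_sets) < model.ir_fraction

    records = []
    for i in range(model.n_sets):
        mean_dose = max(ratios[i], 1e-6) * model.d_user_Gy
        d1 = mean_dose * (1.0 + deltas[i] / 2.0)
        d2 = mean_dose * (1.0 - deltas[i] / 2.0)
        records.append(AuditRecord(
            centre_id=f"C{i + 1:03d}",
            radionuclide="Ir-192" if is_ir[i] else "Co-60",
            d_user_Gy=model.d_user_Gy,
            rpld_doses_Gy=(d1, d2),
            film_shifts_mm=(shifts[i] + film_err[i, 0],
                            shifts[i] + film_err[i, 1])))
    return records
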