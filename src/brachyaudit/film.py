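"""Source-position verification from radiochromic film strips.

Each audit set contains two self-developing film strips taped over one
catheter channel.  Stepping the source darkens a band along the dwell
span; a fiducial mark on the strip indicates where the centre of the RPLD
sensitive volume lies.  The scanned strip (reflective scan, so darker film
gives lower pixel values) is reduced to a one-dimensional darkening
profile along the catheter axis, the track edges are located at 50 % of
the profile plateau with sub-pixel linear interpolation, and the track
bisection (midpoint of the two edges) is compared to the fiducial:

    shift = (midpoint - fiducial) * s

with the sign arranged so that positive shifts point toward the proximal
end of the catheter (the afterloader).  ``s`` is +1 when the image axis
coordinate increases toward the proximal end (the default orientation of
the scanning protocol) and -1 otherwise.

The two films of a set are analysed independently and averaged; the
position uncertainty combines the fixed +-0.3 mm film-analysis procedure
uncertainty with the sample SD of the two measurements, so it can never
fall below 0.3 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FilmImage",
    "TrackMeasurement",
    "PositionResult",
    "NoTrackError",
    "detect_track",
    "measure_shift",
    "combine_films",
    "classify_shift",
    "MM_PER_INCH",
    "PROCEDURE_UNCERTAINTY_MM",
]

MM_PER_INCH = 25.4
#: fixed Type-B uncertainty of the film analysis procedure (mm, k = 1)
PROCEDURE_UNCERTAINTY_MM = 0.3


class NoTrackError(ValueError):
    """Raised when no darkened track exceeds the contrast minimum."""


@dataclass(frozen=True)
class FilmImage:
    """A scanned film strip with its scan metadata.

    ``pixels`` is a 2-D grayscale raster; integer images are normalized by
    their dtype maximum on analysis.  ``fiducial_px`` is the (row, col)
    pixel position of the fiducial marking the RPLD sensitive-volume
    centre.  ``axis`` is the image axis running along the catheter
    (1 = columns).  ``axis_points_proximal`` records whether that axis
    coordinate increases toward the afterloader.
    """

    pixels: np.ndarray
    dpi: float
    fiducial_px: tuple[float, float]
    axis: int = 1
    axis_points_proximal: bool = True

    def __post_init__(self):
        pix = np.asarray(self.pixels)
        if pix.ndim == 3:   # colour scan: collapse to luminance
            pix = pix[..., :3].mean(axis=-1)
        if pix.ndim != 2:
            raise ValueError("film image must be a 2-D grayscale raster")
        object.__setattr__(self, "pixels", pix)
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 or 1")
        row, col = self.fiducial_px
        if not (0 <= row < pix.shape[0] and 0 <= col < pix.shape[1]):
            raise ValueError("fiducial outside image bounds")

    @property
    def mm_per_px(self) -> float:
        return MM_PER_INCH / self.dpi

    @property
    def fiducial_mm(self) -> float:
        """Fiducial position in mm along the catheter axis."""
        return float(self.fiducial_px[self.axis]) * self.mm_per_px


@dataclass(frozen=True)
class TrackMeasurement:
    """Track edges and bisection in mm along the image axis
    (edge_start_mm < edge_end_mm in axis coordinates)."""

    edge_start_mm: float
    edge_end_mm: float
    midpoint_mm: float

    def __post_init__(self):
        if not self.edge_start_mm < self.edge_end_mm:
            raise ValueError("track edges out of order")
        expected = (self.edge_start_mm + self.edge_end_mm) / 2.0
        if abs(self.midpoint_mm - expected) > 1e-9:
            raise ValueError("midpoint must bisect the edges")

    @property
    def length_mm(self) -> float:
        return self.edge_end_mm - self.edge_start_mm


@dataclass(frozen=True)
class PositionResult:
    """Mean source-position shift of one audit set with k = 1 uncertainty."""

    mean_shift_mm: float
    u_mm: float

    def __post_init__(self):
        if self.u_mm < PROCEDURE_UNCERTAINTY_MM - 1e-12:
            raise ValueError("uncertainty below the procedure floor")


def _normalize(pixels: np.ndarray) -> np.ndarray:
    if np.issubdtype(pixels.dtype, np.integer):
        return pixels.astype(float) / np.iinfo(pixels.dtype).max
    return pixels.astype(float)


def _half_crossing(profile: np.ndarray, half: float, idx: np.ndarray,
                   rising: bool) -> float:
    """Sub-pixel 50 %-crossing position by linear interpolation."""
    i = idx[0] if rising else idx[-1]
    if rising:
        if i == 0:
            return float(i)
        lo, hi = profile[i - 1], profile[i]
        return (i - 1) + (half - lo) / (hi - lo)
    if i == profile.size - 1:
        return float(i)
    hi, lo = profile[i], profile[i + 1]
    return i + (hi - half) / (hi - lo)


def detect_track(image: FilmImage, contrast_min: float = 0.05,
                 band_fraction: float = 0.5) -> TrackMeasurement:
    """Locate the darkened source track along the image axis.

    The image is collapsed to a per-column (along-axis) mean net-darkening
    profile over the band of rows where the track runs; the band is the
    set of cross-axis lines whose mean darkening exceeds
    ``band_fraction`` of the strongest line.  Edges sit at 50 % of the
    profile plateau, interpolated to sub-pixel precision; positions are
    converted to mm by 25.4/dpi.

    Raises :class:`NoTrackError` when the plateau darkening does not
    exceed ``contrast_min`` (in normalized pixel units).
    """
    pix = _normalize(image.pixels)
    if image.axis == 0:
        pix = pix.T
    # net darkening relative to the unexposed background (image median:
    # the track covers a minority of the strip area)
    dark = np.clip(np.median(pix) - pix, 0.0, None)

    row_strength = dark.mean(axis=1)
    peak = row_strength.max()
    if peak <= 0:
        raise NoTrackError("no track detected: image is uniform")
    band = row_strength >= band_fraction * peak
    profile = dark[band].mean(axis=0)

    plateau_cand = profile[profile >= 0.8 * profile.max()]
    plateau = float(np.median(plateau_cand))
    if plateau < contrast_min:
        raise NoTrackError(
            f"no track detected: plateau darkening {plateau:.4f} below "
            f"contrast minimum {contrast_min}")
    half = plateau / 2.0
    above = np.nonzero(profile >= half)[0]
    start_px = _half_crossing(profile, half, above, rising=True)
    end_px = _half_crossing(profile, half, above, rising=False)

    scale = image.mm_per_px
    start_mm, end_mm = start_px * scale, end_px * scale
    return TrackMeasurement(edge_start_mm=start_mm, edge_end_mm=end_mm,
                            midpoint_mm=(start_mm + end_mm) / 2.0)


def measure_shift(track: TrackMeasurement, fiducial_mm: float,
                  axis_points_proximal: bool = True) -> float:
    """Signed source-position shift (mm): track bisection minus fiducial,
    positive toward the proximal end (afterloader)."""
    sign = 1.0 if axis_points_proximal else -1.0
    return (track.midpoint_mm - fiducial_mm) * sign


def combine_films(shift1_mm: float, shift2_mm: float) -> PositionResult:
    """Average the two film shifts of a set; u combines the 0.3 mm
    procedure floor with the sample SD of the two values in quadrature."""
    mean = (shift1_mm + shift2_mm) / 2.0
    sd = abs(shift1_mm - shift2_mm) / math.sqrt(2.0)    # ddof=1 SD of a pair
    return PositionResult(mean_shift_mm=mean,
                          u_mm=math.hypot(PROCEDURE_UNCERTAINTY_MM, sd))


def classify_shift(result: PositionResult | float) -> tuple[str, str]:
    """Classify |mean shift| against the +-3 / +-5 mm action levels.

    Returns ``(category, direction)`` with category one of ``within_3mm``,
    ``within_5mm``, ``beyond_5mm`` (boundaries inclusive) and direction
    ``proximal`` (positive), ``distal`` (negative) or ``centred``.
    """
    shift = (result.mean_shift_mm if isinstance(result, PositionResult)
             else float(result))
    mag = abs(shift)
    eps = 1e-12   # boundary-inclusive despite representation noise
    if mag <= 3.0 + eps:
        category = "within_3mm"
    elif mag <= 5.0 + eps:
        category = "within_5mm"
    else:
        category = "beyond_5mm"
    direction = "centred" if shift == 0 else (
        "proximal" if shift > 0 else "distal")
    return category, direction
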