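"""Multicentre audit aggregation.

One audit record is a single dosimeter set: the centre's stated delivered
dose, two RPLD audit doses from the duplicate irradiations and two film
shifts.  The audit endpoint per set is the dose ratio

    D_audit / D_user = mean(RPLD dose 1, RPLD dose 2) / user-stated dose

together with the averaged film shift.  Cohort statistics are computed
per dosimeter set (a centre can contribute several sets) and sets are
classified against the +-3 % / +-5 % dose and +-3 mm / +-5 mm position
action levels, boundaries inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from brachyaudit.film import classify_shift, combine_films
from brachyaudit.rpld import combine_duplicates

__all__ = [
    "AuditRecord",
    "CohortSummary",
    "dose_ratio",
    "summarize_cohort",
    "read_cohort_csv",
    "write_cohort_report",
]


@dataclass(frozen=True)
class AuditRecord:
    """One centre's dosimeter set."""

    centre_id: str
    radionuclide: str
    d_user_Gy: float
    rpld_doses_Gy: tuple[float, float]
    film_shifts_mm: tuple[float, float]

    def __post_init__(self):
        if self.d_user_Gy <= 0:
            raise ValueError("user-stated dose must be positive")
        if len(self.rpld_doses_Gy) != 2 or len(self.film_shifts_mm) != 2:
            raise ValueError("a set holds exactly two RPLD doses and "
                             "two film shifts")
        if any(d <= 0 for d in self.rpld_doses_Gy):
            raise ValueError("RPLD doses must be positive")


def dose_ratio(record: AuditRecord) -> float:
    """Audit dose ratio: mean of the two RPLD doses over the user dose."""
    mean_dose, _ = combine_duplicates(*record.rpld_doses_Gy)
    return mean_dose / record.d_user_Gy


@dataclass(frozen=True)
class CohortSummary:
    n_sets: int
    ratio_mean: float
    ratio_sd: float
    ratio_min: float
    ratio_max: float
    n_within_3pct: int
    n_within_5pct: int
    shift_mean_mm: float
    shift_sd_mm: float
    n_within_3mm: int
    n_within_5mm: int
    n_proximal_beyond_3mm: int
    intra_set_diff_mean_pct: float
    ratio_mean_by_radionuclide: dict[str, float] = field(default_factory=dict)
    insufficient_n: bool = False

    def __post_init__(self):
        if not (self.ratio_min <= self.ratio_mean <= self.ratio_max):
            raise ValueError("summary must satisfy min <= mean <= max")
        counts = (self.n_within_3pct, self.n_within_5pct,
                  self.n_within_3mm, self.n_within_5mm)
        if any(c > self.n_sets for c in counts):
            raise ValueError("classification counts cannot exceed n_sets")

    def to_dict(self) -> dict:
        return asdict(self)


def _sd(values: np.ndarray) -> tuple[float, bool]:
    """Sample SD; for n = 1 it is undefined and reported as 0 with a flag."""
    if values.size < 2:
        return 0.0, True
    return float(values.std(ddof=1)), False


def summarize_cohort(records: list[AuditRecord]) -> CohortSummary:
    """Descriptive statistics and action-level classification of a cohort.

    Statistics are per dosimeter set; SDs are sample SDs.  Dose sets are
    within +-p % when |ratio - 1| <= p/100 (boundary inclusive); position
    classification shares the inclusive rule of
    :func:`brachyaudit.film.classify_shift`.
    """
    if not records:
        raise ValueError("cohort must contain at least one record")
    ratios = np.asarray([dose_ratio(r) for r in records])
    shifts = np.asarray([combine_films(*r.film_shifts_mm).mean_shift_mm
                         for r in records])
    diffs = np.asarray([combine_duplicates(*r.rpld_doses_Gy)[1]
                        for r in records])

    ratio_sd, flag_r = _sd(ratios)
    shift_sd, flag_s = _sd(shifts)

    cats = [classify_shift(s) for s in shifts]
    n_3mm = sum(c == "within_3mm" for c, _ in cats)
    n_5mm = sum(c in ("within_3mm", "within_5mm") for c, _ in cats)
    n_prox = sum(1 for s in shifts if abs(s) > 3.0 and s > 0)

    by_nuclide = {
        nuc: float(np.mean([dose_ratio(r) for r in records
                            if r.radionuclide == nuc]))
        for nuc in sorted({r.radionuclide for r in records})}

    return CohortSummary(
        n_sets=len(records),
        ratio_mean=float(ratios.mean()),
        ratio_sd=ratio_sd,
        ratio_min=float(ratios.min()),
        ratio_max=float(ratios.max()),
        # boundary inclusive; epsilon guards the exact-boundary case
        # against floating-point representation noise
        n_within_3pct=int(np.sum(np.abs(ratios - 1.0) <= 0.03 + 1e-12)),
        n_within_5pct=int(np.sum(np.abs(ratios - 1.0) <= 0.05 + 1e-12)),
        shift_mean_mm=float(shifts.mean()),
        shift_sd_mm=shift_sd,
        n_within_3mm=n_3mm,
        n_within_5mm=n_5mm,
        n_proximal_beyond_3mm=n_prox,
        intra_set_diff_mean_pct=float(diffs.mean()),
        ratio_mean_by_radionuclide=by_nuclide,
        insufficient_n=flag_r or flag_s)


def read_cohort_csv(path) -> list[AuditRecord]:
    """Read audit records from CSV with columns centre_id, radionuclide,
    d_user_Gy, rpld1_Gy, rpld2_Gy, shift1_mm, shift2_mm."""
    df = pd.read_csv(path)
    required = {"centre_id", "radionuclide", "d_user_Gy", "rpld1_Gy",
                "rpld2_Gy", "shift1_mm", "shift2_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort CSV must have columns {sorted(required)}")
    return [AuditRecord(centre_id=str(r.centre_id),
                        radionuclide=str(r.radionuclide),
                        d_user_Gy=float(r.d_user_Gy),
                        rpld_doses_Gy=(float(r.rpld1_Gy), float(r.rpld2_Gy)),
                        film_shifts_mm=(float(r.shift1_mm),
                                        float(r.shift2_mm)))
            for r in df.itertuples()]


def write_cohort_report(records: list[AuditRecord], out_dir,
                        plots: bool = True) -> CohortSummary:
    """Write summary JSON, a per-set CSV and (optionally) the shift and
    dose-ratio scatter plots into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = summarize_cohort(records)
    (out / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=1))

    rows = []
    for r in records:
        pos = combine_films(*r.film_shifts_mm)
        cat, direction = classify_shift(pos)
        mean_dose, diff_pct = combine_duplicates(*r.rpld_doses_Gy)
        rows.append({
            "centre_id": r.centre_id, "radionuclide": r.radionuclide,
            "d_user_Gy": r.d_user_Gy, "d_audit_Gy": mean_dose,
            "dose_ratio": dose_ratio(r), "intra_set_diff_pct": diff_pct,
            "shift_mm": pos.mean_shift_mm, "shift_u_mm": pos.u_mm,
            "shift_category": cat, "shift_direction": direction})
    per_set = pd.DataFrame(rows)
    per_set.to_csv(out / "per_set.csv", index=False)

    if plots:
        _scatter_plots(per_set, out)
    return summary


def _scatter_plots(per_set: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(per_set)) + 1

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.errorbar(x, per_set["shift_mm"], yerr=per_set["shift_u_mm"],
                fmt="D", ms=4, lw=0, elinewidth=1, capsize=2, color="k")
    for level, colour in ((3, "orange"), (5, "red")):
        ax.axhline(level, color=colour, lw=1)
        ax.axhline(-level, color=colour, lw=1)
    ax.set_xlabel("dosimeter set")
    ax.set_ylabel("source position shift (mm)")
    fig.tight_layout()
    fig.savefig(out / "shifts.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(x, per_set["dose_ratio"], "o", ms=4, color="k")
    ax.axhline(float(per_set["dose_ratio"].mean()), color="b", ls="--", lw=1)
    for level, colour in ((0.03, "orange"), (0.05, "red")):
        ax.axhline(1 + level, color=colour, lw=1)
        ax.axhline(1 - level, color=colour, lw=1)
    ax.set_xlabel("dosimeter set")
    ax.set_ylabel("dose ratio (audit / user)")
    fig.tight_layout()
    fig.savefig(out / "dose_ratios.png", dpi=150)
    plt.close(fig)
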