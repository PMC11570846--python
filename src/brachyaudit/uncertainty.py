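"""GUM-style measurement uncertainty budget for the RPLD audit system.

Components are relative standard uncertainties in percent (k = 1), tagged
Type A (statistical) or Type B (other means), and are combined in
uncorrelated quadrature:

    u_c = sqrt(sum_i u_i^2)

The default bundled budget lists the ten components of the postal
brachytherapy audit system (calibration, readout, dosimeter corrections,
RAKR, dose calculation in the RPLD volume and the total correction
factor); it combines to 2.24 % (k = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "UncertaintyComponent",
    "UncertaintyBudget",
    "combine_budget",
    "expand",
    "load_budget",
    "default_budget",
]


@dataclass(frozen=True)
class UncertaintyComponent:
    name: str
    percent: float                  # relative standard uncertainty, %
    gum_type: str = "A"             # "A" or "B"

    def __post_init__(self):
        if self.percent < 0:
            raise ValueError("uncertainty must be non-negative")
        if self.gum_type not in ("A", "B"):
            raise ValueError("GUM type must be 'A' or 'B'")


@dataclass(frozen=True)
class UncertaintyBudget:
    components: tuple[UncertaintyComponent, ...]

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")

    def combined(self) -> float:
        return combine_budget(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": [c.name for c in self.components],
            "percent": [c.percent for c in self.components],
            "gum_type": [c.gum_type for c in self.components],
        })


def combine_budget(budget: UncertaintyBudget) -> float:
    """Combined relative standard uncertainty in percent (k = 1),
    uncorrelated quadrature of all components."""
    if not budget.components:
        raise ValueError("cannot combine an empty budget")
    return math.sqrt(sum(c.percent**2 for c in budget.components))


def expand(combined_pct: float, coverage_k: float) -> float:
    """Expanded uncertainty: combined standard uncertainty times the
    coverage factor k."""
    if coverage_k <= 0:
        raise ValueError("coverage factor must be positive")
    return combined_pct * coverage_k


def load_budget(path) -> UncertaintyBudget:
    """Load a budget from CSV with columns name, percent, gum_type."""
    df = pd.read_csv(path)
    if not {"name", "percent"}.issubset(df.columns):
        raise ValueError("budget CSV needs name and percent columns")
    comps = tuple(
        UncertaintyComponent(name=str(r["name"]), percent=float(r["percent"]),
                             gum_type=str(r.get("gum_type", "A")))
        for _, r in df.iterrows())
    return UncertaintyBudget(components=comps)


def default_budget() -> UncertaintyBudget:
    """The bundled ten-component budget of the RPLD audit system."""
    ref = resources.files("brachyaudit.data") / "rpld_uncertainty_budget.csv"
    with resources.as_file(ref) as path:
        return load_budget(path)
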