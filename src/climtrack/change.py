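"""Percent change in occupancy and its regression on the species temperature index.

The headline analysis: for each species, the percent change in occupied-plot
count between the two survey eras is regressed (ordinary least squares) on
the species temperature index.  A positive slope means warmer-breeding
species are gaining occupancy in the study regions while colder-breeding
species lose it — the fingerprint of a northward community shift.

Species never observed in the early era have an undefined percent change
(baseline zero); they are carried through tables flagged ``included=False``
and rendered as the string ``"Inf"`` in exports, but a typed ``None`` keeps
them out of all arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .climate import SpeciesTemperatureIndex
from .errors import DegenerateDesignError, InsufficientDataError, JoinError, ValidationError
from .survey import SpeciesOccupancy


def percent_change(k_early: int, k_late: int) -> float | None:
    """Percent change in occupied-plot count, ``100 * (k_late - k_early) / k_early``.

    Returns ``None`` (undefined) when the early-era count is zero; both eras
    are assumed to cover the same plot set, so counts and occupancy
    fractions give identical changes.
    """
    if k_early < 0 or k_late < 0:
        raise ValidationError(f"occupied-plot counts must be non-negative, got ({k_early}, {k_late})")
    if k_early == 0:
        return None
    return 100.0 * (k_late - k_early) / k_early


@dataclass(frozen=True)
class OccupancyChange:
    """Per-species occupancy change between eras."""

    species: str
    occ_early_pct: float
    occ_late_pct: float
    pct_change: float | None

    @property
    def included(self) -> bool:
        return self.pct_change is not None


def assemble_change_table(
    occupancies: Iterable[SpeciesOccupancy],
    stis: Iterable[SpeciesTemperatureIndex],
) -> pd.DataFrame:
    """Join per-era occupancy with STI into the analysis table, sorted by STI.

    Columns: species, sti_degc, occ_early_pct, occ_late_pct, pct_change
    (NaN where undefined), included.  Every species must have both eras and
    an STI; otherwise a :class:`JoinError` names the offender.
    """
    by_species: dict[str, dict[str, SpeciesOccupancy]] = {}
    for occ in occupancies:
        by_species.setdefault(occ.species, {})[occ.era] = occ
    sti_map = {s.species: s.sti_degc for s in stis}

    rows = []
    for sp in sorted(set(by_species) | set(sti_map)):
        eras = by_species.get(sp, {})
        if "early" not in eras or "late" not in eras:
            raise JoinError(f"species {sp!r} is missing an era in the occupancy table")
        if sp not in sti_map:
            raise JoinError(f"species {sp!r} has no species temperature index")
        change = percent_change(eras["early"].n_occupied, eras["late"].n_occupied)
        rows.append(
            {
                "species": sp,
                "sti_degc": sti_map[sp],
                "occ_early_pct": eras["early"].occupancy_pct,
                "occ_late_pct": eras["late"].occupancy_pct,
                "pct_change": math.nan if change is None else change,
                "included": change is not None,
            }
        )
    return pd.DataFrame(rows).sort_values("sti_degc", kind="mergesort", ignore_index=True)


def format_change_table(table: pd.DataFrame, ndigits: int = 0) -> pd.DataFrame:
    """Display copy of a change table: undefined changes rendered ``"Inf"``."""
    out = table.copy()
    out["pct_change"] = [
        "Inf" if not inc else f"{round(pc):d}" if ndigits == 0 else f"{pc:.{ndigits}f}"
        for pc, inc in zip(out["pct_change"], out["included"])
    ]
    return out


@dataclass(frozen=True)
class OLSResults:
    """Simple-linear-regression results for the change-vs-STI model."""

    intercept: float
    slope: float
    slope_se: float
    t_value: float
    p_value: float
    r_squared: float
    adj_r_squared: float
    n: int

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def summary(self) -> str:
        return (
            f"OLS: pct_change ~ STI   n = {self.n}\n"
            f"  intercept  {self.intercept: .4f}\n"
            f"  slope      {self.slope: .4f}  (SE {self.slope_se:.4f})\n"
            f"  t = {self.t_value:.4f}  p = {self.p_value:.4g}  "
            f"R2 = {self.r_squared:.4f}  adj R2 = {self.adj_r_squared:.4f}"
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "t_value": self.t_value,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "n": self.n,
        }


class ClimateTrackingRegression:
    """OLS model of percent occupancy change on the species temperature index.

    Built either from explicit vectors or from an assembled change table
    (undefined-change species are dropped by construction, mirroring the
    exclusion of the never-detected-early species in the study).
    """

    def __init__(self, sti: Sequence[float], pct_change: Sequence[float]):
        x = np.asarray(sti, dtype=float)
        y = np.asarray(pct_change, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValidationError("sti and pct_change must be 1-D vectors of equal length")
        if np.any(~np.isfinite(y)):
            raise ValidationError("pct_change contains undefined values; filter by `included` first")
        if x.size < 3:
            raise InsufficientDataError(f"need at least 3 species with defined change, got {x.size}")
        if np.ptp(x) == 0:
            raise DegenerateDesignError("species temperature index is constant across species")
        self.x = x
        self.y = y

    @classmethod
    def from_change_table(cls, table: pd.DataFrame) -> "ClimateTrackingRegression":
        kept = table[table["included"]]
        return cls(kept["sti_degc"].to_numpy(), kept["pct_change"].to_numpy())

    def fit(self) -> OLSResults:
        x, y = self.x, self.y
        n = x.size
        xbar, ybar = x.mean(), y.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        sxy = float(np.sum((x - xbar) * (y - ybar)))
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        resid = y - intercept - slope * x
        rss = float(np.sum(resid**2))
        tss = float(np.sum((y - ybar) ** 2))
        sigma2 = rss / (n - 2)
        slope_se = math.sqrt(sigma2 / sxx)
        if slope_se > 0:
            t_value = slope / slope_se
            p_value = float(2.0 * stats.t.sf(abs(t_value), df=n - 2))
        else:  # exact interpolation: zero residual variance
            t_value = math.copysign(math.inf, slope) if slope != 0 else 0.0
            p_value = 0.0 if slope != 0 else 1.0
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        return OLSResults(
            intercept=intercept,
            slope=slope,
            slope_se=slope_se,
            t_value=t_value,
            p_value=p_value,
            r_squared=r2,
            adj_r_squared=adj_r2,
            n=n,
        )


def fit_ols(x: Sequence[float], y: Sequence[float]) -> OLSResults:
    """Functional wrapper: least-squares line of pct_change on STI."""
    return ClimateTrackingRegression(x, y).fit()


def plot_change_vs_sti(table: pd.DataFrame, fit: OLSResults | None = None, ax=None):
    """Scatter of percent change against STI with the fitted line.

    Excluded (undefined-change) species are omitted, as in the published
    figure.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    kept = table[table["included"]]
    ax.scatter(kept["sti_degc"], kept["pct_change"], color="k", zorder=3)
    for _, row in kept.iterrows():
        ax.annotate(row["species"], (row["sti_degc"], row["pct_change"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    if fit is not None:
        xs = np.linspace(kept["sti_degc"].min(), kept["sti_degc"].max(), 50)
        ax.plot(xs, fit.predict(xs), color="tab:blue")
    ax.axhline(0, color="grey", lw=0.6)
    ax.set_xlabel("Species temperature index (°C)")
    ax.set_ylabel("% change in occupancy")
    return ax
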