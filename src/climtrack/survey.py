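"""Plot-level shorebird survey data and the community response variables.

A *plot* is a 16-ha (400 x 400 m) survey unit searched once per *era*
(the early 1994-97 round or the 2019 resurvey).  From a set of plots this
module computes the three community responses modelled downstream:

* occupancy   — fraction of plots where a species (or any species) was
                detected at least once,
* richness    — number of species detected per plot,
* density     — total birds per km2 per plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConflictError, EmptyInputError, RegistryError, SchemaError, ValidationError
from .registry import SpeciesRegistry

ERAS = ("early", "late")
REGIONS = ("FoxeBasin", "Rasmussen")
HABITATS = ("lowland", "upland")

#: Columns of the canonical long-format survey CSV.
SURVEY_COLUMNS = ("plot_id", "region", "era", "habitat_upland_prop", "species_code", "count")


def classify_habitat(upland_prop: float) -> str:
    """Classify a plot as ``"upland"`` or ``"lowland"`` by the predominant cover.

    A plot is upland when more than half its area is upland habitat; the
    exact 0.5/0.5 tie is classified lowland (deterministic tie-break
    reflecting the wetland-weighted sampling design).
    """
    if not 0.0 <= upland_prop <= 1.0:
        raise ValidationError(f"upland proportion must be in [0, 1], got {upland_prop}")
    return "upland" if upland_prop > 0.5 else "lowland"


@dataclass(frozen=True)
class PlotSurvey:
    """One plot surveyed in one era."""

    plot_id: str
    region: str
    era: str
    habitat: str
    counts: Mapping[str, int]
    area_ha: float = 16.0

    def __post_init__(self):
        if self.era not in ERAS:
            raise ValidationError(f"era must be one of {ERAS}, got {self.era!r}")
        if self.habitat not in HABITATS:
            raise ValidationError(f"habitat must be one of {HABITATS}, got {self.habitat!r}")
        if not self.area_ha > 0:
            raise ValidationError(f"plot area must be positive, got {self.area_ha}")
        for code, n in self.counts.items():
            if int(n) != n or n < 0:
                raise ValidationError(f"count for {code!r} must be a non-negative integer, got {n}")
        object.__setattr__(self, "counts", MappingProxyType(dict(self.counts)))

    @property
    def total_birds(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def richness(self) -> int:
        return sum(1 for n in self.counts.values() if n >= 1)

    @property
    def density_per_km2(self) -> float:
        return self.total_birds / (self.area_ha / 100.0)


@dataclass(frozen=True)
class SpeciesOccupancy:
    """Occupied-plot tally for one species in one era."""

    species: str
    era: str
    n_occupied: int
    n_plots: int

    def __post_init__(self):
        if not 0 <= self.n_occupied <= self.n_plots:
            raise ValidationError(
                f"n_occupied={self.n_occupied} outside [0, n_plots={self.n_plots}] for {self.species}"
            )

    @property
    def occupancy_pct(self) -> float:
        return 100.0 * self.n_occupied / self.n_plots


@dataclass(frozen=True)
class CommunityMetrics:
    """Per-era community summary over all species combined."""

    era: str
    n_plots: int
    any_species_occupancy_pct: float
    richness_median: float
    richness_sd: float
    density_median: float
    density_sd: float

    def to_dict(self) -> dict:
        return {
            "era": self.era,
            "n_plots": self.n_plots,
            "any_species_occupancy_pct": self.any_species_occupancy_pct,
            "richness_median": self.richness_median,
            "richness_sd": self.richness_sd,
            "density_median": self.density_median,
            "density_sd": self.density_sd,
        }


def read_survey_table(
    path: str | Path,
    registry: SpeciesRegistry | None = None,
    default_area_ha: float = 16.0,
) -> list[PlotSurvey]:
    """Read a canonical long-format survey CSV into :class:`PlotSurvey` records.

    Expected columns: ``plot_id, region, era, habitat_upland_prop,
    species_code, count`` (an optional ``area_ha`` column overrides the
    16-ha default).  One record is produced per (plot, era); species that
    appear anywhere in the table but not in a given plot's rows get count 0.
    """
    registry = registry or SpeciesRegistry.open_registry()
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey table is missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"survey table {path} contains no rows")

    dup = df.duplicated(subset=["plot_id", "era", "species_code"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["plot_id", "era", "species_code"]].drop_duplicates()
        first = rows.iloc[0]
        raise ConflictError(
            f"duplicate survey rows for (plot={first.plot_id!r}, era={first.era!r}, "
            f"species={first.species_code!r})"
        )

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"count {df['count'].iloc[i]!r} (row {i}) is not a non-negative integer")
    df = df.assign(count=counts.astype(int))

    for code in df["species_code"].unique():
        registry.check(str(code))

    all_species = sorted(df["species_code"].unique())
    surveys: list[PlotSurvey] = []
    for (plot_id, era), grp in df.groupby(["plot_id", "era"], sort=True):
        props = grp["habitat_upland_prop"].unique()
        if len(props) > 1:
            raise ConflictError(f"plot {plot_id!r} era {era!r} has conflicting habitat proportions {props}")
        area = float(grp["area_ha"].iloc[0]) if "area_ha" in grp.columns else default_area_ha
        per_species = dict.fromkeys(all_species, 0)
        per_species.update(zip(grp["species_code"], grp["count"]))
        surveys.append(
            PlotSurvey(
                plot_id=str(plot_id),
                region=str(grp["region"].iloc[0]),
                era=str(era),
                habitat=classify_habitat(float(props[0])),
                counts=per_species,
                area_ha=area,
            )
        )
    return surveys


def _era_subset(surveys: Iterable[PlotSurvey], era: str) -> list[PlotSurvey]:
    subset = [s for s in surveys if s.era == era]
    if not subset:
        raise EmptyInputError(f"no plots surveyed in era {era!r}")
    return subset


def species_occupancy(surveys: Iterable[PlotSurvey], species: str, era: str) -> SpeciesOccupancy:
    """Occupancy of one species in one era: plots with >= 1 individual detected."""
    subset = _era_subset(surveys, era)
    known = set().union(*(s.counts.keys() for s in subset))
    if species not in known:
        raise RegistryError(f"species {species!r} not present in any survey record")
    n_occ = sum(1 for s in subset if s.counts.get(species, 0) >= 1)
    return SpeciesOccupancy(species=species, era=era, n_occupied=n_occ, n_plots=len(subset))


def plot_richness(plot: PlotSurvey) -> int:
    """Number of species detected (count >= 1) on a plot."""
    return plot.richness


def plot_density(plot: PlotSurvey) -> float:
    """Total birds per km2 on a plot (16 ha = 0.16 km2, so 7 birds -> 43.75)."""
    return plot.density_per_km2


def community_summary(surveys: Iterable[PlotSurvey], era: str) -> CommunityMetrics:
    """All-species community metrics for one era, pooled over both regions."""
    subset = _era_subset(surveys, era)
    richness = np.array([s.richness for s in subset], dtype=float)
    density = np.array([s.density_per_km2 for s in subset], dtype=float)
    occupied = sum(1 for s in subset if s.total_birds >= 1)

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")

    return CommunityMetrics(
        era=era,
        n_plots=len(subset),
        any_species_occupancy_pct=100.0 * occupied / len(subset),
        richness_median=float(np.median(richness)),
        richness_sd=_sd(richness),
        density_median=float(np.median(density)),
        density_sd=_sd(density),
    )


def occupancy_table(surveys: Iterable[PlotSurvey], species: Iterable[str] | None = None) -> pd.DataFrame:
    """Tidy per-species, per-era occupancy table.

    One row per (species, era) with ``n_occupied``, ``n_plots`` and
    ``occupancy_pct``; species defaults to every code observed anywhere.
    """
    surveys = list(surveys)
    if not surveys:
        raise EmptyInputError("no survey records")
    if species is None:
        species = sorted(set().union(*(s.counts.keys() for s in surveys)))
    eras = sorted({s.era for s in surveys}, key=ERAS.index)
    rows = []
    for sp in species:
        for era in eras:
            occ = species_occupancy(surveys, sp, era)
            rows.append(
                {
                    "species": sp,
                    "era": era,
                    "n_occupied": occ.n_occupied,
                    "n_plots": occ.n_plots,
                    "occupancy_pct": occ.occupancy_pct,
                }
            )
    return pd.DataFrame(rows)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention of the published tables)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)
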