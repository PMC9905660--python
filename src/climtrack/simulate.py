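"""Synthetic worlds implementing the conceptual range-shift model.

The generator encodes the study's conceptual picture: temperature declines
linearly with latitude; each species occupies a latitudinal band centred
where the temperature surface equals its species temperature index (STI);
plot occupancy is highest at the range centre and decays to zero at the
edges; and a between-era warming of ``warming_dt`` degrees displaces every
range centre poleward by ``warming_dt / |temp_gradient|`` degrees of
latitude (the climate-velocity displacement).  Species breeding warmer than
the study area therefore gain expected occupancy between eras, while
colder-breeding species lose it.

Default parameters are the study conditions: 12 species carrying the
published STI values, 64 plots (28 Rasmussen + 36 Foxe Basin) at mid-Arctic
latitudes, a -1 degC/deg-latitude meridional gradient, and 1.6 degC of
warming between eras.

Every draw flows through one seeded :class:`numpy.random.Generator`; no
function touches global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import box

from .change import ClimateTrackingRegression, percent_change
from .climate import ClimateRaster, GridGeoreference, RangePolygon, write_climate_raster, write_range_polygons
from .errors import InsufficientDataError, ScenarioError, ValidationError
from .registry import load_reference_table
from .survey import ERAS, PlotSurvey, classify_habitat, species_occupancy

_DEFAULT_STI = tuple(load_reference_table()["sti_degc"].tolist())


@dataclass(frozen=True)
class Scenario:
    """Generative parameters for one synthetic world.

    Temperatures in degC, latitudes in degrees north.  ``temp_gradient`` is
    degC per degree latitude (negative: colder northward); ``base_temp`` is
    the early-era temperature at ``lat_ref``.
    """

    n_species: int = 12
    sti_targets: tuple[float, ...] = _DEFAULT_STI
    temp_gradient: float = -1.0
    base_temp: float = 2.0
    lat_ref: float = 68.0
    range_halfwidth_deg: float = 7.0
    occupancy_peak: float = 0.22
    edge_decay: str = "linear"
    warming_dt: float = 1.6
    n_plots: int = 64
    habitat_split: float = 0.35
    mean_count: float = 3.0
    seed: int = 42
    # raster footprint (lon/lat degrees) and square cell size
    lon_bounds: tuple[float, float] = (-100.0, -80.0)
    lat_bounds: tuple[float, float] = (50.0, 88.0)
    cell_deg: float = 0.5

    def __post_init__(self):
        if self.n_species != len(self.sti_targets):
            raise ScenarioError("n_species must equal len(sti_targets)")
        if self.temp_gradient == 0:
            raise ValidationError("temp_gradient must be nonzero (range centers undefined)")
        if not 0 < self.occupancy_peak <= 1:
            raise ScenarioError("occupancy_peak must be in (0, 1]")
        if self.n_plots <= 0:
            raise ScenarioError("n_plots must be positive")
        if self.edge_decay not in ("linear", "gaussian"):
            raise ScenarioError(f"edge_decay must be 'linear' or 'gaussian', got {self.edge_decay!r}")
        if not 0 <= self.habitat_split <= 1:
            raise ScenarioError("habitat_split must be in [0, 1]")

    @property
    def species_codes(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_species))

    def era_warming(self, era: str) -> float:
        return self.warming_dt if era == "late" else 0.0

    def temperature_at(self, lat: np.ndarray | float, era: str = "early") -> np.ndarray | float:
        return self.base_temp + self.era_warming(era) + self.temp_gradient * (np.asarray(lat) - self.lat_ref)

    def range_center(self, species_index: int, era: str) -> float:
        """Latitude where the era's temperature surface equals the species STI."""
        sti = self.sti_targets[species_index]
        return self.lat_ref + (sti - self.base_temp - self.era_warming(era)) / self.temp_gradient

    def plot_latitudes(self) -> np.ndarray:
        """Fixed plot latitudes in two region blocks flanking ``lat_ref``."""
        n_ras = round(self.n_plots * 28 / 64) or 1
        n_fox = self.n_plots - n_ras
        lats = np.concatenate(
            [
                np.linspace(self.lat_ref - 1.4, self.lat_ref - 0.4, n_ras),
                np.linspace(self.lat_ref + 0.2, self.lat_ref + 1.4, max(n_fox, 1))[: n_fox],
            ]
        )
        return lats

    def plot_regions(self) -> list[str]:
        n_ras = round(self.n_plots * 28 / 64) or 1
        return ["Rasmussen"] * n_ras + ["FoxeBasin"] * (self.n_plots - n_ras)


@dataclass
class SimulatedWorld:
    """A generated raster + ranges + survey set, with the generating truth."""

    scenario: Scenario
    raster: ClimateRaster  # early era; late era = raster + warming_dt
    raster_late: ClimateRaster
    ranges_by_era: dict[tuple[str, str], RangePolygon]
    surveys: list[PlotSurvey]
    truth: dict


def make_climate_surface(scenario: Scenario, era: str = "early") -> ClimateRaster:
    """Deterministic linear meridional temperature surface for one era."""
    if era not in ERAS:
        raise ValidationError(f"era must be one of {ERAS}")
    cell = scenario.cell_deg
    lon0, lon1 = scenario.lon_bounds
    lat0, lat1 = scenario.lat_bounds
    ncols = round((lon1 - lon0) / cell)
    nrows = round((lat1 - lat0) / cell)
    geo = GridGeoreference(west=lon0, north=lat1, dx=cell, dy=cell)
    lat_centers = geo.lat_centers(nrows)
    col = scenario.temperature_at(lat_centers, era)
    values = np.tile(np.asarray(col)[:, None], (1, ncols))
    return ClimateRaster(values=values, geo=geo, nodata=None)


def make_range(scenario: Scenario, species_index: int, era: str) -> RangePolygon:
    """Latitudinal band centred on the species' era-specific isotherm."""
    if not 0 <= species_index < scenario.n_species:
        raise ValidationError(f"species_index {species_index} out of range")
    center = scenario.range_center(species_index, era)
    lat0, lat1 = scenario.lat_bounds
    if not lat0 <= center <= lat1:
        raise ScenarioError(
            f"range center {center:.2f} for species {species_index} ({era}) lies outside "
            f"the raster latitude extent {scenario.lat_bounds}"
        )
    hw = scenario.range_halfwidth_deg
    south = center - hw if math.isfinite(hw) else lat0
    north = center + hw if math.isfinite(hw) else lat1
    # clip to the raster footprint so geometry stays valid near the edges
    south, north = max(south, lat0), min(north, lat1)
    lon0, lon1 = scenario.lon_bounds
    return RangePolygon(
        species=scenario.species_codes[species_index],
        geometry=box(lon0, south, lon1, north),
        source_tag=f"synthetic:{era}",
    )


def occupancy_probability(
    scenario: Scenario, species_index: int, era: str, plot_lat: np.ndarray | float
) -> np.ndarray | float:
    """Occupancy probability: peaks at the range centre, zero at the edge.

    linear:   p = peak * max(0, 1 - |lat - c| / hw)
    gaussian: p = peak * exp(-(lat - c)^2 / (2 (hw/2)^2)), truncated at the edge
    """
    center = scenario.range_center(species_index, era)
    hw = scenario.range_halfwidth_deg
    d = np.abs(np.asarray(plot_lat, dtype=float) - center)
    if not math.isfinite(hw):
        p = np.full_like(d, scenario.occupancy_peak)
    elif scenario.edge_decay == "linear":
        p = scenario.occupancy_peak * np.clip(1.0 - d / hw, 0.0, None)
    else:
        p = np.where(d <= hw, scenario.occupancy_peak * np.exp(-(d**2) / (2 * (hw / 2.0) ** 2)), 0.0)
    return float(p) if np.isscalar(plot_lat) else p


def _habitat_pattern(n: int, upland_fraction: float) -> np.ndarray:
    """Deterministic evenly spread upland assignment (Bresenham spacing)."""
    idx = np.arange(n)
    return np.floor((idx + 1) * upland_fraction) > np.floor(idx * upland_fraction)


def simulate_surveys(scenario: Scenario) -> SimulatedWorld:
    """Generate the full synthetic world: raster, era ranges, surveys, truth.

    Presence of each species on each plot in each era is Bernoulli with the
    range-position probability; counts given presence are zero-truncated
    geometric with mean ``scenario.mean_count`` (overdispersed totals, as
    the negative-binomial community models assume).
    """
    rng = np.random.default_rng(scenario.seed)
    raster = make_climate_surface(scenario, "early")
    raster_late = make_climate_surface(scenario, "late")
    codes = scenario.species_codes
    ranges = {
        (codes[i], era): make_range(scenario, i, era) for i in range(scenario.n_species) for era in ERAS
    }

    lats = scenario.plot_latitudes()
    regions = scenario.plot_regions()
    upland = _habitat_pattern(scenario.n_plots, scenario.habitat_split)
    upland_props = np.where(upland, 0.8, 0.2)

    probs = {
        era: np.column_stack(
            [occupancy_probability(scenario, i, era, lats) for i in range(scenario.n_species)]
        )
        for era in ERAS
    }

    surveys: list[PlotSurvey] = []
    total_birds = {era: 0 for era in ERAS}
    for era in ERAS:
        present = rng.random((scenario.n_plots, scenario.n_species)) < probs[era]
        counts = np.where(
            present, rng.geometric(1.0 / scenario.mean_count, size=present.shape), 0
        )
        total_birds[era] = int(counts.sum())
        for p in range(scenario.n_plots):
            surveys.append(
                PlotSurvey(
                    plot_id=f"P{p + 1:03d}",
                    region=regions[p],
                    era=era,
                    habitat=classify_habitat(float(upland_props[p])),
                    counts={codes[i]: int(counts[p, i]) for i in range(scenario.n_species)},
                )
            )

    truth = {
        "species_codes": list(codes),
        "sti_targets": list(scenario.sti_targets),
        "range_centers": {
            era: [scenario.range_center(i, era) for i in range(scenario.n_species)] for era in ERAS
        },
        "plot_lats": lats.tolist(),
        "plot_upland_prop": upland_props.tolist(),
        "occupancy_probabilities": {era: probs[era].tolist() for era in ERAS},
        "expected_occupancy_pct": {
            era: (100.0 * probs[era].mean(axis=0)).tolist() for era in ERAS
        },
        "total_birds": total_birds,
        "seed": scenario.seed,
    }
    return SimulatedWorld(
        scenario=scenario,
        raster=raster,
        raster_late=raster_late,
        ranges_by_era=ranges,
        surveys=surveys,
        truth=truth,
    )


def surveys_to_frame(surveys: Iterable[PlotSurvey]) -> pd.DataFrame:
    """Canonical long-format survey table (one row per plot x era x species)."""
    rows = []
    for s in surveys:
        prop = 0.8 if s.habitat == "upland" else 0.2
        for code in sorted(s.counts):
            rows.append(
                {
                    "plot_id": s.plot_id,
                    "region": s.region,
                    "era": s.era,
                    "habitat_upland_prop": prop,
                    "species_code": code,
                    "count": s.counts[code],
                    "area_ha": s.area_ha,
                }
            )
    return pd.DataFrame(rows)


def write_world(world: SimulatedWorld, outdir: str | Path, raster_format: str = "tif") -> dict[str, Path]:
    """Write survey CSV, per-era rasters and ranges, and the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["surveys"] = outdir / "surveys.csv"
    surveys_to_frame(world.surveys).to_csv(paths["surveys"], index=False)
    for era, raster in (("early", world.raster), ("late", world.raster_late)):
        paths[f"raster_{era}"] = write_climate_raster(raster, outdir / f"climate_{era}.{raster_format}")
        era_ranges = [r for (sp, e), r in world.ranges_by_era.items() if e == era]
        paths[f"ranges_{era}"] = write_range_polygons(era_ranges, outdir / f"ranges_{era}.geojson")
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(world.truth, fh, indent=1)
    return paths


@dataclass(frozen=True)
class RecoveryResult:
    """Distribution of the change-vs-STI slope across simulated replicates."""

    n_replicates: int
    n_skipped: int
    alpha: float
    slope_mean: float
    slope_sd: float
    frac_slope_positive: float
    rejection_rate: float
    slopes: tuple[float, ...] = field(repr=False, default=())
    p_values: tuple[float, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_skipped": self.n_skipped,
            "alpha": self.alpha,
            "slope_mean": self.slope_mean,
            "slope_sd": self.slope_sd,
            "frac_slope_positive": self.frac_slope_positive,
            "rejection_rate": self.rejection_rate,
        }


def recovery_experiment(scenario: Scenario, n_replicates: int, alpha: float = 0.05) -> RecoveryResult:
    """Run occupancy -> percent change -> STI regression over many replicates.

    Each replicate re-simulates the surveys with an incremented seed and
    regresses per-species percent change on the *true* STI targets.
    Replicates with fewer than three defined-change species are skipped and
    counted.  Reports the slope distribution, the fraction of positive
    slopes, and the two-sided rejection rate at ``alpha``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    slopes, pvals = [], []
    n_skipped = 0
    for rep in range(n_replicates):
        world = simulate_surveys(replace(scenario, seed=scenario.seed + rep))
        x, y = [], []
        for i, code in enumerate(scenario.species_codes):
            occ_e = species_occupancy(world.surveys, code, "early")
            occ_l = species_occupancy(world.surveys, code, "late")
            change = percent_change(occ_e.n_occupied, occ_l.n_occupied)
            if change is not None:
                x.append(scenario.sti_targets[i])
                y.append(change)
        try:
            fit = ClimateTrackingRegression(x, y).fit()
        except InsufficientDataError:
            n_skipped += 1
            continue
        slopes.append(fit.slope)
        pvals.append(fit.p_value)
    if not slopes:
        raise InsufficientDataError("every replicate was skipped (no defined occupancy changes)")
    slopes_a = np.array(slopes)
    pvals_a = np.array(pvals)
    return RecoveryResult(
        n_replicates=n_replicates,
        n_skipped=n_skipped,
        alpha=alpha,
        slope_mean=float(slopes_a.mean()),
        slope_sd=float(slopes_a.std(ddof=1)) if slopes_a.size > 1 else float("nan"),
        frac_slope_positive=float(np.mean(slopes_a > 0)),
        rejection_rate=float(np.mean(pvals_a < alpha)),
        slopes=tuple(slopes),
        p_values=tuple(pvals),
    )
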