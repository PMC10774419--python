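"""Synthetic study world with known ground truth.

Generates a miniature version of the inputs the effort-reconstruction
pipeline consumes — national fleet time series with observation gaps and
noise, country covariates (population, GDP per capita), length-class and
gear compositions, engine power / tonnage / days-at-sea attributes, and
gridded catch concentrated near a synthetic coastline — together with
the generating parameters, so that every downstream stage can be tested
as a parameter-recovery problem.

The world is deliberately stylised: countries are contiguous blocks of
grid columns, the coast is the southern edge of the grid, and catch
intensity decays exponentially with distance from the coast.  Fleet
growth follows a carrying-capacity-limited logistic in each sector,
which is the structural assumption the reconstruction stage exploits.

Observation model: counts are perturbed by mean-one lognormal noise with
a configurable coefficient of variation and rounded to integers; a
configured fraction of years is removed uniformly at random, always
retaining the first and last year so reconstruction is interpolation-
dominated.  With ``noise_cv = 0`` observations equal the ground-truth
curve exactly (no rounding), which tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    LENGTH_CLASSES,
    SECTOR_ARTISANAL_MOTORIZED,
    SECTOR_ARTISANAL_UNMOTORIZED,
    SECTOR_INDUSTRIAL,
    SECTORS,
    SMALL_LENGTH_CLASSES,
)
from .grid import Grid

# Catch-side and effort-side gear vocabularies deliberately differ so the
# gear-matching cascade (exact -> family -> country) is exercised.
CATCH_GEARS = ("gillnets", "seines", "bottom_trawls", "longlines")
EFFORT_GEARS_BY_SECTOR = {
    SECTOR_INDUSTRIAL: {"bottom_trawls": 0.6, "longlines": 0.4},      # exact matches
    SECTOR_ARTISANAL_MOTORIZED: {"gillnets": 0.7, "handlines": 0.3},  # exact + family
    SECTOR_ARTISANAL_UNMOTORIZED: {"liftnets": 0.7, "traps": 0.3},    # family + country
}
FGROUPS = ("demersal", "pelagic")

#: Mean engine power of a motorized artisanal vessel in the synthetic
#: world, kW — a typical small outboard; used to build the total power
#: series entering motor-equivalence recovery.
P_ART_MOTOR_KW = 10.0

_POWER_BASE = {lc: p for lc, p in zip(LENGTH_CLASSES, (8.0, 40.0, 150.0, 500.0, 1500.0))}
_GT_BASE = {lc: g for lc, g in zip(LENGTH_CLASSES, (0.8, 8.0, 50.0, 250.0, 1200.0))}


@dataclass
class SectorTruth:
    """Logistic growth parameters and creep for one (country, sector)."""

    K: float
    r: float
    t0: float
    creep: float

    def curve(self, years: np.ndarray) -> np.ndarray:
        return self.K / (1.0 + np.exp(-self.r * (np.asarray(years, float) - self.t0)))


@dataclass
class WorldConfig:
    """Configuration and ground-truth parameters of a synthetic world."""

    n_countries: int = 5
    year_start: int = 1950
    year_end: int = 2017
    lat_min: float = 0.0
    lat_max: float = 8.0
    cell_size_deg: float = 0.5
    lon_cols_per_country: int = 4
    coastal_rows: int = 2          # southernmost rows flagged coastal
    trawl_ban_from_row: int = 12   # rows >= this are closed to trawling (depth proxy)
    catch_decay_rows: float = 3.0  # e-folding of catch intensity away from the coast
    gap_fraction: float = 0.3
    noise_cv: float = 0.05
    catch_noise_cv: float = 0.1
    rng_seed: int = 0

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def lon_min(self) -> float:
        return 0.0

    @property
    def lon_max(self) -> float:
        return self.n_countries * self.lon_cols_per_country * self.cell_size_deg

    def validate(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be positive")
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("year_range must span at least 3 years")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.noise_cv < 0 or self.catch_noise_cv < 0:
            raise ValueError("noise coefficients of variation must be non-negative")
        n_rows = (self.lat_max - self.lat_min) / self.cell_size_deg
        if abs(n_rows - round(n_rows)) > 1e-9:
            raise ValueError("cell_size_deg must divide the latitude extent evenly")
        if round(n_rows) * self.n_countries * self.lon_cols_per_country <= 1:
            raise ValueError("degenerate grid: a single cell is not allowed")


@dataclass
class World:
    """Output bundle of :func:`generate_world`."""

    config: WorldConfig
    grid: Grid
    countries: pd.DataFrame          # country, saup, region
    covariates: pd.DataFrame         # country, year, population, gdp_per_capita
    fleet_truth: pd.DataFrame        # country, sector, year, n_vessels (complete)
    fleet_obs: pd.DataFrame          # country, sector, year, n_vessels (gappy, noisy)
    catch_cells: pd.DataFrame        # year, country, gear, fgroup, lat, lon, catch
    artisanal_catch: pd.DataFrame    # country, year, catch  (for motor equivalence)
    length_shares_obs: pd.DataFrame  # country, sector, year, length_class, share
    gear_shares: pd.DataFrame        # country, sector, gear, share
    power_obs: pd.DataFrame          # country, length_class, year, power_kw
    tonnage_obs: pd.DataFrame        # country, length_class, gt
    das_table: pd.DataFrame          # country, sector, gear, year, das, activity
    truth: dict = field(default_factory=dict)
    country_cells: dict = field(default_factory=dict)  # country -> (lat, lon) arrays


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _sample_gaps(rng: np.random.Generator, years: np.ndarray, gap_fraction: float) -> np.ndarray:
    """Boolean keep-mask: remove round(f*n) interior years uniformly.

    The first and last year are always retained so that gap-filling is an
    interpolation problem; the number removed is capped at n-2.
    """
    n = len(years)
    n_remove = min(int(round(gap_fraction * n)), n - 2)
    keep = np.ones(n, dtype=bool)
    if n_remove > 0:
        interior = np.arange(1, n - 1)
        drop = rng.choice(interior, size=n_remove, replace=False)
        keep[drop] = False
    return keep


def generate_world(config: WorldConfig) -> World:
    """Generate a full synthetic world; deterministic under ``rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    years = config.years
    n_years = len(years)

    grid = Grid(
        lat_min=config.lat_min,
        lat_max=config.lat_max,
        lon_min=config.lon_min,
        lon_max=config.lon_max,
        cell_size=config.cell_size_deg,
    )
    grid.coastal[: config.coastal_rows, :] = True
    grid.trawl_ban[config.trawl_ban_from_row :, :] = True

    codes = [f"C{i + 1:02d}" for i in range(config.n_countries)]
    countries = pd.DataFrame(
        {
            "country": codes,
            "saup": np.arange(101, 101 + config.n_countries),
            "region": ["east" if i % 2 else "west" for i in range(config.n_countries)],
        }
    )

    truth: dict = {"sectors": {}, "ppv_eq": {}, "q_catch": {}}
    cov_rows, fleet_truth_rows, fleet_obs_rows = [], [], []
    catch_rows, art_catch_rows = [], []
    ls_rows, gear_rows, power_rows, gt_rows, das_rows = [], [], [], [], []
    country_cells: dict = {}

    for i, country in enumerate(codes):
        # --- covariates: smooth exponential population & GDP growth -------
        pop0 = rng.uniform(1e5, 5e6)
        pop_g = rng.uniform(0.005, 0.03)
        gdp0 = rng.uniform(500, 5000)
        gdp_g = rng.uniform(0.01, 0.04)
        population = pop0 * (1 + pop_g) ** (years - years[0])
        gdp = gdp0 * (1 + gdp_g) ** (years - years[0])
        cov_rows.append(
            pd.DataFrame(
                {"country": country, "year": years, "population": population, "gdp_per_capita": gdp}
            )
        )

        # --- ground-truth fleets ------------------------------------------
        # Unmotorized fleets are long established and saturate early;
        # industrial growth is mid-century; artisanal motorization is a
        # slow multi-decade transition, so the unmotorized share of the
        # artisanal fleet sweeps down through the 20-80% window.
        sectors = {
            SECTOR_INDUSTRIAL: SectorTruth(
                K=rng.uniform(300, 1500),
                r=rng.uniform(0.06, 0.15),
                t0=rng.uniform(1955, 1980),
                creep=0.014,
            ),
            SECTOR_ARTISANAL_MOTORIZED: SectorTruth(
                K=rng.uniform(1000, 4000),
                r=rng.uniform(0.05, 0.1),
                t0=rng.uniform(1970, 1990),
                creep=0.05,
            ),
            SECTOR_ARTISANAL_UNMOTORIZED: SectorTruth(
                K=rng.uniform(300, 1200),
                r=rng.uniform(0.1, 0.25),
                t0=rng.uniform(1930, 1945),
                creep=0.05,
            ),
        }
        truth["sectors"][country] = sectors

        obs_masks = {}
        for sector, st in sectors.items():
            curve = st.curve(years)
            fleet_truth_rows.append(
                pd.DataFrame(
                    {"country": country, "sector": sector, "year": years, "n_vessels": curve}
                )
            )
            keep = _sample_gaps(rng, years, config.gap_fraction)
            obs_masks[sector] = keep
            noise = _lognormal_noise(rng, config.noise_cv, n_years)
            observed = curve * noise
            if config.noise_cv > 0:
                observed = np.round(observed)
            fleet_obs_rows.append(
                pd.DataFrame(
                    {
                        "country": country,
                        "sector": sector,
                        "year": years[keep],
                        "n_vessels": observed[keep],
                    }
                )
            )

        # --- artisanal catch for motor equivalence (Eq-1 style) ----------
        ppv_eq = rng.uniform(4.0, 10.0)
        q = rng.uniform(0.05, 0.2)
        truth["ppv_eq"][country] = ppv_eq
        truth["q_catch"][country] = q
        nv_u = sectors[SECTOR_ARTISANAL_UNMOTORIZED].curve(years)
        nv_m = sectors[SECTOR_ARTISANAL_MOTORIZED].curve(years)
        p_m = nv_m * P_ART_MOTOR_KW
        catch_art = q * (nv_u * ppv_eq + p_m) * _lognormal_noise(rng, config.catch_noise_cv, n_years)
        art_catch_rows.append(pd.DataFrame({"country": country, "year": years, "catch": catch_art}))

        # --- compositions --------------------------------------------------
        for sector in SECTORS:
            if sector == SECTOR_ARTISANAL_UNMOTORIZED:
                start = np.array([0.7, 0.3, 0.0, 0.0, 0.0])
                end = np.array([0.5, 0.5, 0.0, 0.0, 0.0])
            elif sector == SECTOR_ARTISANAL_MOTORIZED:
                start = np.array([0.4, 0.4, 0.2, 0.0, 0.0])
                end = np.array([0.2, 0.4, 0.4, 0.0, 0.0])
            else:
                start = np.array([0.0, 0.2, 0.4, 0.3, 0.1])
                end = np.array([0.0, 0.1, 0.3, 0.4, 0.2])
            start = start * (1 + 0.1 * rng.uniform(-1, 1, 5) * (start > 0))
            start /= start.sum()
            frac = (years - years[0]) / (years[-1] - years[0])
            shares = start[None, :] * (1 - frac[:, None]) + end[None, :] * frac[:, None]
            shares /= shares.sum(axis=1, keepdims=True)
            keep = _sample_gaps(rng, years, max(config.gap_fraction, 0.5))
            for j, lc in enumerate(LENGTH_CLASSES):
                ls_rows.append(
                    pd.DataFrame(
                        {
                            "country": country,
                            "sector": sector,
                            "year": years[keep],
                            "length_class": lc,
                            "share": shares[keep, j],
                        }
                    )
                )
            for gear, share in EFFORT_GEARS_BY_SECTOR[sector].items():
                gear_rows.append(
                    {"country": country, "sector": sector, "gear": gear, "share": share}
                )

        # --- power / tonnage observations ---------------------------------
        pfac = rng.uniform(0.8, 1.2)
        for lc in LENGTH_CLASSES:
            for yr, growth in ((1960, 1.0), (2010, 1.6)):
                power_rows.append(
                    {
                        "country": country,
                        "length_class": lc,
                        "year": yr,
                        "power_kw": _POWER_BASE[lc] * pfac * growth,
                    }
                )
            gt_rows.append({"country": country, "length_class": lc, "gt": _GT_BASE[lc] * pfac})

        # --- days at sea / activity ---------------------------------------
        # Even-indexed countries carry full DAS and activity data; odd ones
        # have none and must fall back to donors / the 72% default.
        if i % 2 == 0:
            for sector in SECTORS:
                for gear in EFFORT_GEARS_BY_SECTOR[sector]:
                    das = rng.uniform(120, 240)
                    act = rng.uniform(0.6, 0.9)
                    das_rows.append(
                        {
                            "country": country,
                            "sector": sector,
                            "gear": gear,
                            "year": -1,  # applies to all years
                            "das": das,
                            "activity": act,
                        }
                    )

        # --- gridded catch -------------------------------------------------
        col0 = i * config.lon_cols_per_country
        cols = np.arange(col0, col0 + config.lon_cols_per_country)
        rows = np.arange(grid.nlat)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        w = np.exp(-rr / config.catch_decay_rows) * rng.uniform(0.5, 1.5, rr.shape)
        w = w.ravel() / w.sum()
        cell_lat = grid.lats[rr.ravel()]
        cell_lon = grid.lons[cc.ravel()]
        country_cells[country] = (cell_lat, cell_lon)
        fg_share = {"demersal": 0.6, "pelagic": 0.4}
        gear_share = {"gillnets": 0.3, "seines": 0.2, "bottom_trawls": 0.3, "longlines": 0.2}
        # thin to a decade-step catch atlas: the spatial pattern is what
        # matters for allocation, not the yearly resolution
        for year in years[:: max(1, n_years // 8)]:
            base = q * 1e3 * (1 + 0.01 * (year - years[0]))
            for gear, gs in gear_share.items():
                for fg, fs in fg_share.items():
                    catch_rows.append(
                        pd.DataFrame(
                            {
                                "year": year,
                                "country": country,
                                "gear": gear,
                                "fgroup": fg,
                                "lat": cell_lat,
                                "lon": cell_lon,
                                "catch": base * gs * fs * w,
                            }
                        )
                    )

    das_df = pd.DataFrame(das_rows, columns=["country", "sector", "gear", "year", "das", "activity"])
    world = World(
        config=config,
        grid=grid,
        countries=countries,
        covariates=pd.concat(cov_rows, ignore_index=True),
        fleet_truth=pd.concat(fleet_truth_rows, ignore_index=True),
        fleet_obs=pd.concat(fleet_obs_rows, ignore_index=True),
        catch_cells=pd.concat(catch_rows, ignore_index=True),
        artisanal_catch=pd.concat(art_catch_rows, ignore_index=True),
        length_shares_obs=pd.concat(ls_rows, ignore_index=True),
        gear_shares=pd.DataFrame(gear_rows),
        power_obs=pd.DataFrame(power_rows),
        tonnage_obs=pd.DataFrame(gt_rows),
        das_table=das_df,
        truth=truth,
        country_cells=country_cells,
    )
    return world


@dataclass
class AISDistortion:
    """Distortion applied to a mapped-effort table to mimic AIS coverage.

    ``noise_cv`` perturbs cell efforts multiplicatively; ``coverage_small``
    is the probability that a cell of a small-vessel (< 12 m) record is
    retained — AIS receiver coverage misses small vessels preferentially.
    """

    noise_cv: float = 0.0
    coverage_small: float = 1.0
    seed: int = 0


def generate_ais_like_grid(effort_grid: pd.DataFrame, distortion: AISDistortion | None = None) -> pd.DataFrame:
    """Return a distorted copy of a mapped-effort table.

    With no distortion the output equals the input.  Thinning zeroes the
    effort of dropped cells rather than removing rows, so comparisons stay
    cell-aligned.
    """
    out = effort_grid.copy()
    if distortion is None:
        return out
    rng = np.random.default_rng(distortion.seed)
    eff = out["NomActive"].to_numpy(float)
    eff = eff * _lognormal_noise(rng, distortion.noise_cv, len(out))
    if distortion.coverage_small < 1.0:
        small = out["Length_Category"].isin(SMALL_LENGTH_CLASSES).to_numpy()
        dropped = small & (rng.uniform(size=len(out)) >= distortion.coverage_small)
        eff[dropped] = 0.0
    out["NomActive"] = eff
    return out
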