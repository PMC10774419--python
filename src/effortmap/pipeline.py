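"""End-to-end driver: synthetic world → mapped-effort records.

Chains the pipeline stages: fleet reconstruction per (country, sector),
length-class and gear disaggregation, power/tonnage attachment, nominal
and effective effort, and catch-prorated spatial allocation with
constraint masks and Gaussian spreading.  Returns both the mapped
records (the 13-field output schema) and the intermediate segment table
so that conservation and equation-exactness can be audited.

Spatial patterns are computed once per (country, catch-atlas year,
sector, gear, functional group) and shared across years and length
classes — allocation is linear in the segment total, so only the scalar
differs — which keeps a multi-decade run fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import capacity, effort, mapping, reconstruction
from .constants import EFFORT_FIELDS, LENGTH_CLASSES, SECTORS
from .synthetic import World


@dataclass
class PipelineResult:
    records: pd.DataFrame                       # the 13-field mapped table
    segments: pd.DataFrame                      # national segment totals + DAS/R_act
    fleets: dict = field(default_factory=dict)  # (country, sector) -> reconstructed series
    fits: dict = field(default_factory=dict)    # (country, sector) -> [LogisticFit]


def reconstruct_fleets(world: World) -> tuple[dict, dict]:
    """Reconstruct every (country, sector) fleet series from observations."""
    year_range = (world.config.year_start, world.config.year_end)
    fleets, fits = {}, {}
    for (country, sector), obs in world.fleet_obs.groupby(["country", "sector"]):
        try:
            f, series = reconstruction.fit_logistic_series(obs, year_range)
        except reconstruction.InsufficientDataError:
            cov = world.covariates[world.covariates["country"] == country]
            series = reconstruction.reconstruct_by_proxy(obs, cov, year_range)
            f = []
        fleets[(country, sector)] = series
        fits[(country, sector)] = f
    return fleets, fits


def build_segments(world: World, fleets: dict) -> pd.DataFrame:
    """Disaggregate fleets and compute per-segment nominal/effective effort."""
    cfg = world.config
    year_range = (cfg.year_start, cfg.year_end)
    region_map = dict(zip(world.countries["country"], world.countries["region"]))

    skeletons = []
    for (country, sector), series in fleets.items():
        ls_obs = world.length_shares_obs[
            (world.length_shares_obs["country"] == country)
            & (world.length_shares_obs["sector"] == sector)
        ]
        wide = ls_obs.pivot(index="year", columns="length_class", values="share").reset_index()
        wide = wide[["year"] + [c for c in LENGTH_CLASSES if c in wide.columns]]
        for lc in LENGTH_CLASSES:
            if lc not in wide.columns:
                wide[lc] = 0.0
        shares = capacity.smooth_share_series(wide[["year"] + list(LENGTH_CLASSES)], year_range)
        gears = world.gear_shares[
            (world.gear_shares["country"] == country) & (world.gear_shares["sector"] == sector)
        ][["gear", "share"]]
        seg = capacity.disaggregate_fleet(series, shares, gears)
        seg.insert(0, "country", country)
        seg.insert(1, "sector", sector)
        skeletons.append(seg)
    skeleton = pd.concat(skeletons, ignore_index=True)
    skeleton = skeleton[skeleton["nv"] > 0].reset_index(drop=True)

    seg = capacity.attach_power_tonnage(skeleton, world.power_obs, world.tonnage_obs)

    # days at sea / activity: constant per (country, sector, gear) in this
    # world, so look each combination up once
    das_cache: dict = {}
    for key in seg[["country", "sector", "gear"]].drop_duplicates().itertuples(index=False):
        k = {"country": key.country, "sector": key.sector, "gear": key.gear}
        das, das_prov = effort.fill_days_at_sea(k, world.das_table, region_map)
        r_act, act_prov = effort.fill_activity_ratio(k, world.das_table, region_map)
        das_cache[tuple(k.values())] = (das, das_prov, r_act, act_prov)
    keys = list(zip(seg["country"], seg["sector"], seg["gear"]))
    seg["das"] = [das_cache[k][0] for k in keys]
    seg["das_provenance"] = [das_cache[k][1] for k in keys]
    seg["r_act"] = [das_cache[k][2] for k in keys]
    seg["r_act_provenance"] = [das_cache[k][3] for k in keys]

    seg["nominal"] = effort.nominal_effort(
        seg["p_total"].to_numpy(), seg["das"].to_numpy(), seg["r_act"].to_numpy()
    )
    for sector, chunk in seg.groupby("sector"):
        creep = effort.default_creep(sector)
        seg.loc[chunk.index, "effective"] = chunk["nominal"].to_numpy() * effort.creep_multipliers(
            chunk["year"].to_numpy(int), creep
        )
    return seg


def _build_patterns(world: World, sigma: float, families: dict) -> dict:
    """Normalized spatial pattern per (country, atlas year, sector, gear, fg).

    Each pattern is (lat array, lon array, weight array with Σw = 1, fg
    share of the matched catch).
    """
    patterns: dict = {}
    catch = world.catch_cells
    for country, cc in catch.groupby("country"):
        fallback = pd.DataFrame(
            {"lat": world.country_cells[country][0], "lon": world.country_cells[country][1]}
        )
        coastal = world.grid.coastal[
            world.grid.lat_index(fallback["lat"].to_numpy()),
            world.grid.lon_index(fallback["lon"].to_numpy()),
        ]
        fallback = fallback[coastal]
        for year, cy in cc.groupby("year"):
            catch_gears = set(cy["gear"].unique())
            for sector in SECTORS:
                for gear in world.gear_shares[world.gear_shares["sector"] == sector]["gear"].unique():
                    level, gears = mapping.match_gear(gear, catch_gears, families)
                    sub = cy[cy["gear"].isin(gears)]
                    fg_totals = sub.groupby("fgroup")["catch"].sum()
                    total = fg_totals.sum()
                    for fg, fg_catch in fg_totals.items():
                        if total > 0 and fg_catch == 0:
                            continue
                        fg_share = fg_catch / total if total > 0 else 1.0 / len(fg_totals)
                        cells = sub[sub["fgroup"] == fg]
                        try:
                            alloc = mapping.allocate_to_cells(1.0, cells[["lat", "lon", "catch"]])
                        except ValueError:
                            alloc = fallback.copy()
                            alloc["effort"] = 1.0 / len(alloc)
                        alloc = mapping.apply_constraints(
                            alloc, world.grid, sector, gear, families, fallback
                        )
                        alloc = mapping.smooth_spread(
                            alloc, world.grid, sigma, sector, gear, families
                        )
                        w = alloc["effort"].to_numpy(float)
                        patterns[(country, year, sector, gear, fg)] = (
                            alloc["lat"].to_numpy(float),
                            alloc["lon"].to_numpy(float),
                            w / w.sum(),
                            float(fg_share),
                            level,
                        )
    return patterns


def map_effort(world: World, segments: pd.DataFrame, sigma: float = 1.0) -> pd.DataFrame:
    """Allocate every national segment to grid cells and functional groups."""
    families = mapping.load_gear_families()
    patterns = _build_patterns(world, sigma, families)
    atlas_years = {
        c: np.sort(g["year"].unique()) for c, g in world.catch_cells.groupby("country")
    }
    saup = dict(zip(world.countries["country"], world.countries["saup"]))
    fgroups = sorted(world.catch_cells["fgroup"].unique())

    cols: dict[str, list] = {f: [] for f in EFFORT_FIELDS}
    for row in segments.itertuples(index=False):
        ay = atlas_years[row.country]
        nearest = int(ay[np.argmin(np.abs(ay - row.year))])
        for fg in fgroups:
            key = (row.country, nearest, row.sector, row.gear, fg)
            if key not in patterns:
                continue
            lat, lon, w, fg_share, _level = patterns[key]
            n = len(w)
            cols["Year"].append(np.full(n, row.year))
            cols["SAUP"].append(np.full(n, saup[row.country]))
            cols["NV"].append(row.nv * fg_share * w)
            cols["P"].append(row.p_total * fg_share * w)
            cols["GT"].append(row.gt_total * fg_share * w)
            cols["NomActive"].append(row.nominal * fg_share * w)
            cols["EffActive"].append(row.effective * fg_share * w)
            cols["Length_Category"].append(np.full(n, row.length_class, dtype=object))
            cols["Gear"].append(np.full(n, row.gear, dtype=object))
            cols["Lat"].append(lat)
            cols["Lon"].append(lon)
            cols["FGroup"].append(np.full(n, fg, dtype=object))
            cols["Sector"].append(np.full(n, row.sector, dtype=object))
    records = pd.DataFrame({f: np.concatenate(cols[f]) for f in EFFORT_FIELDS})
    records["Year"] = records["Year"].astype(int)
    records["SAUP"] = records["SAUP"].astype(int)
    return records


def run_pipeline(world: World, sigma: float = 1.0) -> PipelineResult:
    """Full run: reconstruction → disaggregation → effort → mapping."""
    fleets, fits = reconstruct_fleets(world)
    segments = build_segments(world, fleets)
    records = map_effort(world, segments, sigma)
    return PipelineResult(records=records, segments=segments, fleets=fleets, fits=fits)
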