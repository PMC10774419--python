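"""Catch-prorated spatial allocation of effort to grid cells.

National effort totals per (country, year, sector, length class, gear)
are placed on the 0.5° grid by prorating against previously mapped
catch: catch locations already encode habitat, depth and stock
information, so the relative catch of the matching (gear, functional
group) across cells is used as the spatial weight for effort.

Gear matching cascades from exact gear code, to the gear family (e.g.
nets = gillnets + liftnets + seines), to country level (all gears), so
every effort segment resolves somewhere.  Effort is first split across
functional groups (proportional to catch composition) and vessel
categories (proportional to tonnage), then across cells; gear- and
sector-specific constraint masks (trawl bans, coastal-only unmotorized
fleets) zero disallowed cells and redistribute; a Gaussian kernel
finally spreads effort into neighbouring allowed cells to avoid
single-cell hotspots.  Every stage renormalizes so the mapped total
equals the national segment total.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .grid import Grid


def load_gear_families(path: str | None = None) -> dict[str, str]:
    """Load the gear→family table (packaged default or a user YAML)."""
    if path is None:
        text = resources.files("effortmap.data").joinpath("gear_families.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table: dict[str, str] = {}
    for family, gears in raw.items():
        for g in gears:
            if g in table:
                raise ValueError(f"gear {g!r} mapped to more than one family")
            table[g] = family
    return table


def match_gear(
    effort_gear: str,
    catch_gears: set[str] | list[str],
    families: dict[str, str],
) -> tuple[str, set[str]]:
    """Resolve an effort-side gear against the catch-side gear vocabulary.

    Returns ``(level, gears)`` where level is ``exact``, ``family`` or
    ``country`` and ``gears`` is the set of catch gears to draw spatial
    weights from (all catch gears at country level).
    """
    catch_gears = set(catch_gears)
    if effort_gear in catch_gears:
        return "exact", {effort_gear}
    if effort_gear not in families:
        raise KeyError(f"unmapped gear code: {effort_gear!r}")
    fam = families[effort_gear]
    same_family = {g for g in catch_gears if families.get(g) == fam}
    if same_family:
        return "family", same_family
    return "country", catch_gears


def allocate_to_functional_groups(
    segment_effort: float,
    catch_by_fgroup: pd.Series,
    tonnage_shares: pd.Series,
) -> pd.DataFrame:
    """Split a segment's effort across (functional group, vessel category).

    effort[fg, cat] = segment_effort × (catch_fg / Σ catch) × tonnage
    share of the category, renormalized so the cells sum exactly to the
    segment total.  With all-zero catch the functional-group split is
    uniform (fallback), flagged in the ``fallback`` attribute.
    """
    total_catch = float(catch_by_fgroup.sum())
    if total_catch > 0:
        fg_w = catch_by_fgroup / total_catch
        fallback = False
    else:
        fg_w = pd.Series(1.0 / len(catch_by_fgroup), index=catch_by_fgroup.index)
        fallback = True
    ton_w = tonnage_shares / tonnage_shares.sum()
    out = pd.DataFrame(
        np.outer(fg_w.to_numpy(float), ton_w.to_numpy(float)) * segment_effort,
        index=fg_w.index,
        columns=ton_w.index,
    )
    scale = segment_effort / out.to_numpy().sum() if out.to_numpy().sum() > 0 else 1.0
    out *= scale
    out.attrs["fallback"] = fallback
    return out


def allocate_to_cells(effort: float, catch_cells: pd.DataFrame) -> pd.DataFrame:
    """Prorate an effort quantity across cells by their share of catch.

    ``catch_cells`` has columns ``lat``, ``lon``, ``catch``; rows with the
    same cell are pooled.  Returns ``lat``, ``lon``, ``effort`` summing to
    ``effort`` exactly.
    """
    pooled = catch_cells.groupby(["lat", "lon"], as_index=False)["catch"].sum()
    total = pooled["catch"].sum()
    if len(pooled) == 0 or total <= 0:
        raise ValueError("no catch to prorate against (caller should use the fallback path)")
    out = pooled.rename(columns={"catch": "effort"})
    out["effort"] = out["effort"] / total * effort
    return out


def _allowed_mask(grid: Grid, sector: str, gear: str, families: dict[str, str]) -> np.ndarray:
    """Constraint mask: unmotorized fleets are coastal; trawls respect bans."""
    mask = np.ones((grid.nlat, grid.nlon), dtype=bool)
    if sector == "UP":
        mask &= grid.coastal
    if families.get(gear) == "trawls":
        mask &= ~grid.trawl_ban
    return mask


def apply_constraints(
    cells: pd.DataFrame,
    grid: Grid,
    sector: str,
    gear: str,
    families: dict[str, str],
    fallback_cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Zero effort in disallowed cells and redistribute it proportionally.

    ``cells`` has columns ``lat``, ``lon``, ``effort`` for one segment.
    Disallowed effort is redistributed over the segment's remaining
    allowed cells in proportion to their effort; if no allowed cell
    carries effort, it is spread uniformly over ``fallback_cells``
    (typically the country's coastal cells).  The total is preserved.
    """
    mask = _allowed_mask(grid, sector, gear, families)
    allowed = mask[grid.lat_index(cells["lat"].to_numpy()), grid.lon_index(cells["lon"].to_numpy())]
    total = float(cells["effort"].sum())
    kept = cells.loc[allowed].copy()
    if kept["effort"].sum() > 0:
        kept["effort"] = kept["effort"] / kept["effort"].sum() * total
        return kept.reset_index(drop=True)
    if fallback_cells is None or len(fallback_cells) == 0:
        raise ValueError(f"all cells disallowed for segment (sector={sector}, gear={gear})")
    fb = fallback_cells[["lat", "lon"]].drop_duplicates().copy()
    fb_ok = mask[grid.lat_index(fb["lat"].to_numpy()), grid.lon_index(fb["lon"].to_numpy())]
    fb = fb.loc[fb_ok]
    if len(fb) == 0:
        raise ValueError(f"all fallback cells disallowed for segment (sector={sector}, gear={gear})")
    fb["effort"] = total / len(fb)
    return fb.reset_index(drop=True)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """2-D Gaussian kernel truncated at 3σ, normalized to sum to 1."""
    if sigma <= 0:
        return np.ones((1, 1))
    radius = int(np.ceil(3 * sigma))
    x = np.arange(-radius, radius + 1)
    g = np.exp(-(x**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_spread(
    cells: pd.DataFrame,
    grid: Grid,
    sigma: float = 1.0,
    sector: str = "I",
    gear: str = "",
    families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Spread a segment's cell efforts with a Gaussian kernel.

    The kernel (σ in cells, truncated at 3σ) is applied on the dense
    grid; mass landing in disallowed cells is removed and the result is
    rescaled to the original total, so smoothing never re-enters banned
    cells and conserves effort.  σ = 0 is the identity.
    """
    total = float(cells["effort"].sum())
    if sigma <= 0 or total == 0:
        return cells.copy().reset_index(drop=True)
    families = families or {}
    dense = np.zeros((grid.nlat, grid.nlon))
    ilat = grid.lat_index(cells["lat"].to_numpy())
    ilon = grid.lon_index(cells["lon"].to_numpy())
    np.add.at(dense, (ilat, ilon), cells["effort"].to_numpy(float))

    from scipy.signal import convolve2d

    sm = convolve2d(dense, gaussian_kernel(sigma), mode="same", boundary="fill")
    sm[~_allowed_mask(grid, sector, gear, families)] = 0.0
    s = sm.sum()
    if s == 0:  # kernel pushed everything into banned cells; keep original
        return cells.copy().reset_index(drop=True)
    sm *= total / s
    ii, jj = np.nonzero(sm)
    return pd.DataFrame({"lat": grid.lats[ii], "lon": grid.lons[jj], "effort": sm[ii, jj]})


def aggregate_by_region(
    effort: pd.DataFrame, region_of_cell: pd.DataFrame
) -> pd.DataFrame:
    """Sum mapped effort per region per year.

    ``region_of_cell`` maps (``lat``, ``lon``) to ``region``; unlabelled
    cells fall in region ``"none"``.  Regional sums plus the unlabelled
    sum equal the global total.
    """
    merged = effort.merge(region_of_cell, on=["lat", "lon"], how="left")
    merged["region"] = merged["region"].fillna("none")
    value_col = "NomActive" if "NomActive" in merged.columns else "effort"
    year_col = ["Year"] if "Year" in merged.columns else (["year"] if "year" in merged.columns else [])
    return merged.groupby(year_col + ["region"], as_index=False)[value_col].sum()
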