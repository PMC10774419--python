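"""Disaggregation of national fleets into length classes and gears.

A reconstructed national fleet (vessels per year) is split across the
five length-overall classes, then across gear types, and each resulting
segment is given an engine-power and gross-tonnage time series.  Share
series observed only in some years are completed by smoothing on an
additive log-ratio (ALR) scale, which keeps compositions on the simplex;
data-poor countries borrow the mean of configured "similar countries".

Vessel counts are apportioned to integer counts with largest-remainder
rounding so that class and gear totals add up to the national total
exactly — naive rounding would leak vessels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .constants import LENGTH_CLASSES

_EPS = 1e-9


def smooth_share_series(
    observed: pd.DataFrame, year_range: tuple[int, int]
) -> pd.DataFrame:
    """Complete a gappy compositional time series over a year range.

    Parameters
    ----------
    observed:
        Wide table: a ``year`` column plus one column per component, each
        row a composition summing to 1.
    year_range:
        Inclusive (first, last) output year.

    Components that are zero at *every* observation are structural zeros
    and stay exactly zero.  The remaining components are interpolated
    linearly on the ALR scale (log-ratio against the component with the
    largest mean share), held flat beyond the observed years, then
    back-transformed and renormalized so each year sums to 1.
    """
    if len(observed) == 0:
        raise ValueError("need at least one observed composition")
    obs = observed.sort_values("year").reset_index(drop=True)
    comp_cols = [c for c in obs.columns if c != "year"]
    years = np.arange(year_range[0], year_range[1] + 1)
    shares = obs[comp_cols].to_numpy(float)
    obs_years = obs["year"].to_numpy(float)

    if len(obs) == 1:
        warnings.warn("single observed composition: carried flat", stacklevel=2)
        out = pd.DataFrame({"year": years})
        for j, c in enumerate(comp_cols):
            out[c] = shares[0, j]
        return out

    structural_zero = (shares <= 0).all(axis=0)
    active = ~structural_zero
    ref = int(np.argmax(shares[:, active].mean(axis=0)))  # index within active set

    work = np.clip(shares[:, active], _EPS, None)
    work = work / work.sum(axis=1, keepdims=True)
    logratio = np.log(work) - np.log(work[:, [ref]])

    interp = np.empty((len(years), logratio.shape[1]))
    for j in range(logratio.shape[1]):
        interp[:, j] = np.interp(years, obs_years, logratio[:, j])

    expd = np.exp(interp)
    filled_active = expd / expd.sum(axis=1, keepdims=True)

    full = np.zeros((len(years), len(comp_cols)))
    full[:, active] = filled_active
    out = pd.DataFrame({"year": years})
    for j, c in enumerate(comp_cols):
        out[c] = full[:, j]
    return out


def impute_from_similar(
    donors: dict[str, pd.DataFrame], compositional: bool = True
) -> pd.DataFrame:
    """Impute a series for a data-poor country as the mean of donor series.

    ``donors`` maps donor-country name to a wide table (``year`` + value
    columns).  Years present in any donor are averaged over the donors
    that have them; compositional tables are renormalized to sum to 1.
    Returns the imputed table plus an ``n_donors`` column.
    """
    if not donors:
        raise ValueError("no similar countries configured")
    stacked = pd.concat(donors.values(), keys=donors.keys(), names=["donor"]).reset_index("donor")
    value_cols = [c for c in stacked.columns if c not in ("donor", "year")]
    grouped = stacked.groupby("year")
    out = grouped[value_cols].mean().reset_index()
    out["n_donors"] = grouped.size().to_numpy()
    if compositional:
        total = out[value_cols].sum(axis=1)
        out[value_cols] = out[value_cols].div(total.replace(0, np.nan), axis=0).fillna(0.0)
    return out


def apportion_integer(total: int, shares: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` units across shares.

    Output integers sum to ``total`` exactly.  Ties on remainders are
    broken toward the lower index (deterministic).
    """
    shares = np.asarray(shares, float)
    if total < 0:
        raise ValueError("total must be non-negative")
    s = shares.sum()
    if s <= 0:
        raise ValueError("shares must have a positive sum")
    quota = total * shares / s
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = total - base.sum()
    # stable argsort descending on remainder -> earlier index wins ties
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


def disaggregate_fleet(
    fleet: pd.DataFrame,
    length_shares: pd.DataFrame,
    gear_shares: pd.DataFrame,
) -> pd.DataFrame:
    """Split a complete national (one country, one sector) fleet series.

    Parameters
    ----------
    fleet:
        Columns ``year`` and ``n_vessels`` (complete series).
    length_shares:
        Wide table ``year`` + one column per length class, complete.
    gear_shares:
        Columns ``gear`` and ``share`` (constant over time) or ``year``,
        ``gear``, ``share``.

    National totals are rounded to whole vessels, apportioned to length
    classes, then to gears within each class, by largest remainder, so
    the segment counts sum exactly to the rounded national total.
    """
    ls = length_shares.set_index("year")
    by_year_gear = "year" in gear_shares.columns
    rows = []
    for _, rec in fleet.iterrows():
        year = int(rec["year"])
        total = int(round(rec["n_vessels"]))
        class_shares = ls.loc[year, list(LENGTH_CLASSES)].to_numpy(float)
        class_nv = apportion_integer(total, class_shares)
        gs = gear_shares[gear_shares["year"] == year] if by_year_gear else gear_shares
        gears = gs["gear"].to_numpy()
        gshares = gs["share"].to_numpy(float)
        for lc, nv_lc in zip(LENGTH_CLASSES, class_nv):
            if nv_lc == 0 and class_shares[list(LENGTH_CLASSES).index(lc)] == 0:
                continue
            gear_nv = apportion_integer(int(nv_lc), gshares)
            for gear, nv in zip(gears, gear_nv):
                rows.append({"year": year, "length_class": lc, "gear": gear, "nv": int(nv)})
    return pd.DataFrame(rows, columns=["year", "length_class", "gear", "nv"])


def attach_power_tonnage(
    skeleton: pd.DataFrame,
    power_obs: pd.DataFrame,
    tonnage_obs: pd.DataFrame,
    donor_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Attach per-vessel engine power and gross tonnage to fleet segments.

    ``skeleton`` has one row per (country, sector, year, length_class,
    gear) with column ``nv``.  Mean engine power per vessel varies with
    time: observations per (country, length_class) are interpolated
    linearly over years and held flat beyond them.  Gross tonnage is a
    vessel-geometry property and is kept constant per (country,
    length_class) (step-constant per period when ``period`` is present in
    ``tonnage_obs``).  Totals are means times vessel counts.

    A country with no observation for a length class borrows the pooled
    observations of its configured donors; with no donor either, the
    orphan segments are reported in the raised error.
    """
    donor_map = donor_map or {}
    out = skeleton.copy()
    out["power_kw"] = np.nan
    out["gt"] = np.nan

    def _power_series(country: str, lc: str) -> pd.DataFrame | None:
        sel = power_obs[(power_obs["country"] == country) & (power_obs["length_class"] == lc)]
        if len(sel):
            return sel
        pooled = [
            power_obs[(power_obs["country"] == d) & (power_obs["length_class"] == lc)]
            for d in donor_map.get(country, [])
        ]
        pooled = [p for p in pooled if len(p)]
        return pd.concat(pooled) if pooled else None

    def _tonnage(country: str, lc: str, year: int) -> float | None:
        sel = tonnage_obs[(tonnage_obs["country"] == country) & (tonnage_obs["length_class"] == lc)]
        if not len(sel):
            pooled = [
                tonnage_obs[(tonnage_obs["country"] == d) & (tonnage_obs["length_class"] == lc)]
                for d in donor_map.get(country, [])
            ]
            pooled = [p for p in pooled if len(p)]
            if not pooled:
                return None
            sel = pd.concat(pooled)
        if "period" in sel.columns and sel["period"].notna().any():
            sel = sel.sort_values("period")
            applicable = sel[sel["period"] <= year]
            return float((applicable if len(applicable) else sel).iloc[-1 if len(applicable) else 0]["gt"])
        return float(sel["gt"].mean())

    orphans = []
    for (country, lc), idx in out.groupby(["country", "length_class"]).groups.items():
        pser = _power_series(country, lc)
        years = out.loc[idx, "year"].to_numpy(float)
        if pser is None:
            orphans.append((country, lc))
            continue
        pser = pser.sort_values("year")
        out.loc[idx, "power_kw"] = np.interp(
            years, pser["year"].to_numpy(float), pser["power_kw"].to_numpy(float)
        )
        out.loc[idx, "gt"] = [_tonnage(country, lc, int(y)) for y in years]
    if orphans or out["gt"].isna().any():
        missing_gt = out.loc[out["gt"].isna(), ["country", "length_class"]].drop_duplicates()
        orphans = sorted(set(orphans) | set(map(tuple, missing_gt.to_numpy())))
        raise ValueError(f"no power/tonnage observation and no donor for segments: {orphans}")

    out["p_total"] = out["power_kw"] * out["nv"]
    out["gt_total"] = out["gt"] * out["nv"]
    return out
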