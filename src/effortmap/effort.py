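"""Effort computation: motor equivalence, nominal effort, creep.

Nominal fishing effort of a fleet segment is

    Eff_nom = P × DAS × R_act            [kW·days]

with P the segment's total engine power, DAS its days at sea per year
and R_act the fraction of the fleet active.  For unmotorized fleets an
engine-power *equivalent* per vessel (PPV_eq, in kW) is estimated from
the early-motorization period, assuming the CPUE of the total artisanal
fleet (catch per kW) is stable while motorization proceeds:

    Catch_y ∝ NV_unmotor,y × PPV_eq + P_motor,y

Only years in which the unmotorized fleet is 20–80% of the artisanal
vessel total enter the fit — earlier years overuse novel motors, later
years underuse obsolete craft.  The proportionality is resolved as a
two-coefficient, no-intercept least-squares fit Catch = a·NV + b·P;
PPV_eq = a/b cancels the unknown catchability.

Effective effort compounds technological creep (biomass-independent
annual catchability gain) geometrically from a 1949 baseline, where
effective equals nominal by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    CREEP_ARTISANAL,
    CREEP_BASELINE_YEAR,
    CREEP_INDUSTRIAL,
    DEFAULT_ACTIVITY_RATIO,
    SECTOR_INDUSTRIAL,
)


@dataclass
class MotorEquivalence:
    """Engine-power equivalent of one unmotorized vessel, in kW."""

    country: str
    ppv_eq: float
    years_used: list[int]
    window: tuple[float, float] = (0.2, 0.8)


def solve_motor_equivalence(
    catch: pd.DataFrame,
    unmotorized_nv: pd.DataFrame,
    motorized_p: pd.DataFrame,
    window: tuple[float, float] = (0.2, 0.8),
    country: str = "",
) -> MotorEquivalence:
    """Estimate PPV_eq from total artisanal catch over the motorization window.

    Parameters
    ----------
    catch, unmotorized_nv, motorized_p:
        Year-indexed tables with columns (``year``, ``catch``), (``year``,
        ``n_vessels``) and (``year``, ``p_total``, ``n_vessels``).  The
        share window is evaluated on vessel numbers; both endpoints are
        inclusive.
    """
    df = (
        catch.set_index("year")[["catch"]]
        .join(unmotorized_nv.set_index("year")["n_vessels"].rename("nv_u"), how="inner")
        .join(motorized_p.set_index("year")[["p_total", "n_vessels"]].rename(
            columns={"p_total": "p_m", "n_vessels": "nv_m"}), how="inner")
    )
    share = df["nv_u"] / (df["nv_u"] + df["nv_m"])
    lo, hi = window
    sel = df[(share >= lo) & (share <= hi)]
    if len(sel) < 2:
        raise ValueError(
            f"insufficient motorization overlap: {len(sel)} year(s) with unmotorized "
            f"share in [{lo}, {hi}] (need >= 2)"
        )
    if (sel["nv_u"] <= 0).any() or (sel["p_m"] <= 0).any():
        raise ValueError("NV and P must be positive in the windowed years")
    # No-intercept least squares Catch = a·NV + b·P, weighted for the
    # multiplicative error structure of catch data (minimise squared
    # *relative* residuals): regress 1 on NV/Catch and P/Catch.
    y = sel["catch"].to_numpy(float)
    if (y <= 0).any():
        raise ValueError("catch must be positive in the windowed years")
    X = sel[["nv_u", "p_m"]].to_numpy(float) / y[:, None]
    coef, *_ = np.linalg.lstsq(X, np.ones(len(y)), rcond=None)
    a, b = coef
    if b == 0 or a / b <= 0:
        raise ValueError(
            f"negative or undefined fitted power ratio (a={a:.4g}, b={b:.4g}); "
            "consider widening the share window"
        )
    return MotorEquivalence(
        country=country,
        ppv_eq=float(a / b),
        years_used=[int(v) for v in sel.index],
        window=window,
    )


def nominal_effort(p_kw: float | np.ndarray, das: float | np.ndarray, r_act: float | np.ndarray) -> float | np.ndarray:
    """Nominal effort P × DAS × R_act in kW·days."""
    p_kw = np.asarray(p_kw, float)
    das = np.asarray(das, float)
    r_act = np.asarray(r_act, float)
    if (p_kw < 0).any() or (das < 0).any() or (r_act < 0).any():
        raise ValueError("inputs must be non-negative")
    if (r_act > 1).any():
        raise ValueError("activity ratio cannot exceed 1")
    out = p_kw * das * r_act
    return float(out) if out.ndim == 0 else out


def fill_days_at_sea(
    key: dict,
    das_table: pd.DataFrame,
    region_map: dict[str, str] | None = None,
) -> tuple[float, str]:
    """Look up days at sea for a fleet segment, relaxing the key as needed.

    ``key`` holds ``country``, ``sector``, ``gear`` and optionally
    ``year``.  The lookup cascade is: exact (with year) → same segment any
    year → same country/sector any gear → same region (via ``region_map``)
    same sector.  Rows with ``year == -1`` apply to all years.  Returns
    (value, provenance) with provenance naming the fallback that fired.
    """
    if len(das_table) == 0:
        raise ValueError("days-at-sea table is empty")
    t = das_table
    seg = t[(t["country"] == key["country"]) & (t["sector"] == key["sector"]) & (t["gear"] == key["gear"])]
    if "year" in key and key["year"] is not None and len(seg):
        exact = seg[(seg["year"] == key["year"]) | (seg["year"] == -1)]
        if len(exact):
            return float(exact["das"].mean()), "exact"
    if len(seg):
        return float(seg["das"].mean()), "segment"
    cs = t[(t["country"] == key["country"]) & (t["sector"] == key["sector"])]
    if len(cs):
        return float(cs["das"].mean()), "country"
    if region_map:
        region = region_map.get(key["country"])
        donors = [c for c, r in region_map.items() if r == region and c != key["country"]]
        rs = t[t["country"].isin(donors) & (t["sector"] == key["sector"])]
        if len(rs):
            return float(rs["das"].mean()), "region"
        rs = t[t["country"].isin(donors)]
        if len(rs):
            return float(rs["das"].mean()), "region"
    return float(t["das"].mean()), "global"


def fill_activity_ratio(
    key: dict,
    das_table: pd.DataFrame,
    region_map: dict[str, str] | None = None,
    default: float = DEFAULT_ACTIVITY_RATIO,
) -> tuple[float, str]:
    """Activity ratio for a segment; the fleet-wide 72% default when unknown."""
    t = das_table.dropna(subset=["activity"]) if "activity" in das_table.columns else das_table.iloc[0:0]
    if len(t):
        seg = t[(t["country"] == key["country"]) & (t["sector"] == key["sector"]) & (t["gear"] == key["gear"])]
        if len(seg):
            return float(seg["activity"].mean()), "segment"
        cs = t[t["country"] == key["country"]]
        if len(cs):
            return float(cs["activity"].mean()), "country"
    return default, "default"


@dataclass
class CreepModel:
    """Annual technological creep for a scope, compounded from a baseline.

    The cumulative multiplier at year ``y`` is Π_{k=baseline+1..y}(1+c_k);
    it equals 1 at the baseline year (1949), where effective effort is
    defined to equal nominal effort.
    """

    rate: float
    scope: str = ""
    baseline_year: int = CREEP_BASELINE_YEAR
    n_years_used: int = 0
    method: str = "log-cpue-trend"

    def __post_init__(self) -> None:
        if self.rate <= -1:
            raise ValueError("creep rate must exceed -1")


def default_creep(sector: str) -> CreepModel:
    """Sector default creep when estimation is impossible (1.4% industrial, 5% artisanal)."""
    rate = CREEP_INDUSTRIAL if sector == SECTOR_INDUSTRIAL else CREEP_ARTISANAL
    return CreepModel(rate=rate, scope=sector, method="sector-default")


def estimate_creep(
    cpue: pd.DataFrame,
    biomass_index: pd.DataFrame | None = None,
    scope: str = "",
) -> CreepModel:
    """Estimate annual creep as the trend of log CPUE.

    ``cpue`` has columns ``year`` and ``cpue`` (catch per kW).  Non-
    positive values are dropped with a warning; at least 5 positive years
    are required.  When a biomass index is supplied it is included as a
    covariate so the year trend is biomass-independent; otherwise the raw
    log-CPUE trend is used (and labelled as such).  The creep rate is
    c = exp(slope) − 1.
    """
    df = cpue.copy()
    bad = df["cpue"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} non-positive CPUE value(s)", stacklevel=2)
        df = df[~bad]
    if len(df) < 5:
        raise ValueError(f"need >= 5 positive CPUE years, have {len(df)}")
    y = np.log(df["cpue"].to_numpy(float))
    X = df["year"].to_numpy(float)
    method = "log-cpue-trend"
    if biomass_index is not None:
        merged = df.merge(biomass_index, on="year", how="inner")
        if len(merged) < 5:
            raise ValueError("need >= 5 overlapping biomass-index years")
        y = np.log(merged["cpue"].to_numpy(float))
        A = np.column_stack(
            [np.ones(len(merged)), merged["year"].to_numpy(float), np.log(merged["biomass"].to_numpy(float))]
        )
        slope = np.linalg.lstsq(A, y, rcond=None)[0][1]
        method = "log-cpue-trend-biomass-adjusted"
        n_used = len(merged)
    else:
        slope = np.polyfit(X, y, 1)[0]
        n_used = len(df)
    return CreepModel(rate=float(np.expm1(slope)), scope=scope, n_years_used=n_used, method=method)


def creep_multipliers(years: np.ndarray, creep: CreepModel | dict[int, float]) -> np.ndarray:
    """Cumulative creep factor for each year relative to the 1949 baseline."""
    years = np.asarray(years, int)
    baseline = creep.baseline_year if isinstance(creep, CreepModel) else CREEP_BASELINE_YEAR
    if (years < baseline).any():
        raise ValueError(f"years before the {baseline} baseline are not defined")
    if isinstance(creep, CreepModel):
        return (1.0 + creep.rate) ** (years - baseline)
    mult = np.empty(len(years), float)
    for i, y in enumerate(years):
        mult[i] = float(np.prod([1.0 + creep[k] for k in range(baseline + 1, y + 1)]))
    return mult


def effective_effort(nominal: pd.DataFrame, creep: CreepModel | dict[int, float]) -> pd.DataFrame:
    """Apply cumulative creep to a nominal-effort series.

    ``nominal`` has columns ``year`` and ``nominal``; the output adds an
    ``effective`` column Eff_y = Nom_y × Π_{k=1950..y}(1 + c_k).  At the
    1949 baseline effective equals nominal exactly.
    """
    if (nominal["nominal"] < 0).any():
        raise ValueError("nominal effort must be non-negative")
    out = nominal.copy()
    out["effective"] = out["nominal"].to_numpy(float) * creep_multipliers(
        out["year"].to_numpy(int), creep
    )
    return out
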