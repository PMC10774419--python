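"""Gap-filling of national fleet time series.

National vessel-count records are typically patchy: censuses every few
years, gaps around political disruptions, and sparse coverage for small
fleets.  This module reconstructs complete annual series per (country,
sector) under the structural assumption that fleets follow carrying-
capacity-limited (logistic) growth, with two auxiliary strategies:

* proxy reconstruction scaling a sparse series by population growth, for
  fleets too data-poor to fit a curve; and
* the unmotorized-fleet rule set: the unmotorized fleet grows with the
  population up to its peak year ``Y_max`` and afterwards changes in
  proportion to the rate of change of the motorized artisanal fleet
  (sign-inverted by default — motorization replaces unmotorized craft).

The logistic is fitted per segment by nonlinear least squares; a series
is split into independently fitted segments at caller-supplied
disruption years (fleet destruction events), with no continuity
constraint across the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit


class InsufficientDataError(ValueError):
    """A segment has too few observations to fit."""


@dataclass
class LogisticFit:
    """One fitted logistic segment N(t) = K / (1 + exp(-r (t - t0)))."""

    K: float
    r: float
    t0: float
    year_start: int
    year_end: int
    mean_rel_error: float
    converged: bool = True
    method: str = "logistic-nls"

    def curve(self, years: np.ndarray) -> np.ndarray:
        return self.K / (1.0 + np.exp(-self.r * (np.asarray(years, float) - self.t0)))


def _logistic(t, K, r, t0):
    return K / (1.0 + np.exp(-r * (t - t0)))


def _fit_segment(years: np.ndarray, counts: np.ndarray, full_years: np.ndarray) -> tuple[LogisticFit, np.ndarray]:
    """Fit one segment, returning the fit and the curve over ``full_years``."""
    if len(years) < 3:
        raise InsufficientDataError(
            f"insufficient data: {len(years)} observed points in segment "
            f"{full_years[0]}-{full_years[-1]} (need >= 3)"
        )
    if np.any(counts < 0):
        raise ValueError("vessel counts must be non-negative")

    cmax = counts.max()
    if cmax == 0 or (cmax - counts.min()) <= 1e-12 * max(cmax, 1.0):
        # flat limit of the logistic: constant series
        fit = LogisticFit(
            K=float(cmax), r=0.0, t0=float(years[0]),
            year_start=int(full_years[0]), year_end=int(full_years[-1]),
            mean_rel_error=0.0, method="constant",
        )
        return fit, np.full(len(full_years), float(cmax))

    # Initialisation: K at 1.2x the observed maximum, t0 at the year the
    # series first crosses half of that, r at 0.1/yr.
    k0 = 1.2 * cmax
    half = counts >= 0.5 * cmax
    t0_0 = float(years[np.argmax(half)]) if half.any() else float(np.median(years))
    span = float(full_years[-1] - full_years[0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _logistic,
                years.astype(float),
                counts.astype(float),
                p0=(k0, 0.1, t0_0),
                bounds=(
                    (1e-9, -2.0, full_years[0] - 2 * span),
                    (1e6 * max(cmax, 1.0), 2.0, full_years[-1] + 2 * span),
                ),
                maxfev=20000,
            )
        K, r, t0 = (float(v) for v in popt)
        pred = _logistic(years.astype(float), K, r, t0)
        nz = counts > 0
        mre = float(np.mean(np.abs(pred[nz] - counts[nz]) / counts[nz])) if nz.any() else 0.0
        fit = LogisticFit(
            K=K, r=r, t0=t0,
            year_start=int(full_years[0]), year_end=int(full_years[-1]),
            mean_rel_error=mre,
        )
        return fit, np.maximum(fit.curve(full_years), 0.0)
    except RuntimeError:
        # fall back to shape-preserving monotone interpolation with flat
        # extrapolation beyond the observed range
        interp = PchipInterpolator(years.astype(float), counts.astype(float), extrapolate=False)
        curve = interp(full_years.astype(float))
        curve[full_years < years[0]] = counts[0]
        curve[full_years > years[-1]] = counts[-1]
        curve = np.maximum(curve, 0.0)
        pred = np.interp(years, full_years, curve)
        nz = counts > 0
        mre = float(np.mean(np.abs(pred[nz] - counts[nz]) / counts[nz])) if nz.any() else 0.0
        fit = LogisticFit(
            K=float(cmax), r=np.nan, t0=np.nan,
            year_start=int(full_years[0]), year_end=int(full_years[-1]),
            mean_rel_error=mre, converged=False, method="pchip-fallback",
        )
        return fit, curve


def fit_logistic_series(
    observations: pd.DataFrame,
    year_range: tuple[int, int],
    disruption_years: list[int] | None = None,
) -> tuple[list[LogisticFit], pd.DataFrame]:
    """Reconstruct a complete annual vessel-count series from gappy data.

    Parameters
    ----------
    observations:
        Columns ``year`` and ``n_vessels``; one (country, sector) at a time.
    year_range:
        Inclusive (first, last) year of the output series.
    disruption_years:
        Each listed year starts a new, independently fitted segment, with a
        discontinuity allowed at the split (fleet-destruction events).

    Returns
    -------
    (fits, series):
        ``fits`` holds one :class:`LogisticFit` per segment; ``series`` is a
        complete DataFrame with ``year``, ``n_vessels`` and ``provenance``
        (``observed`` where a record existed, ``reconstructed`` elsewhere).
    """
    obs = observations.sort_values("year")
    y0, y1 = year_range
    full_years = np.arange(y0, y1 + 1)
    breaks = sorted(y for y in (disruption_years or []) if y0 < y <= y1)
    bounds = [y0] + breaks + [y1 + 1]

    fits: list[LogisticFit] = []
    values = np.empty(len(full_years))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg_years = np.arange(lo, hi)
        in_seg = (obs["year"] >= lo) & (obs["year"] < hi)
        seg_obs = obs[in_seg]
        fit, curve = _fit_segment(
            seg_obs["year"].to_numpy(), seg_obs["n_vessels"].to_numpy(float), seg_years
        )
        fits.append(fit)
        values[np.isin(full_years, seg_years)] = curve

    series = pd.DataFrame({"year": full_years, "n_vessels": values, "provenance": "reconstructed"})
    obs_map = dict(zip(obs["year"], obs["n_vessels"]))
    mask = series["year"].isin(obs_map)
    series.loc[mask, "n_vessels"] = series.loc[mask, "year"].map(obs_map)
    series.loc[mask, "provenance"] = "observed"
    return fits, series


def _nearest_anchor(year: int, anchors: np.ndarray) -> int:
    """Nearest anchor year; ties broken toward the earlier year."""
    d = np.abs(anchors - year)
    return int(anchors[np.argmin(d)])  # argmin takes the first (earlier) on ties


def reconstruct_by_proxy(
    partial: pd.DataFrame,
    covariates: pd.DataFrame,
    year_range: tuple[int, int],
    proxy_col: str = "population",
) -> pd.DataFrame:
    """Scale a sparse series by a covariate, anchored at the nearest observation.

    NV_y = NV_anchor * proxy_y / proxy_anchor, where the anchor is the
    observed year nearest to y (ties toward the earlier year).
    """
    if len(partial) == 0:
        raise ValueError("no data for proxy scaling: at least one anchor point required")
    y0, y1 = year_range
    full_years = np.arange(y0, y1 + 1)
    proxy = covariates.set_index("year")[proxy_col]
    if not set(full_years).issubset(proxy.index):
        raise ValueError("covariates must cover the full year range")
    anchors = partial.sort_values("year")
    anchor_years = anchors["year"].to_numpy()
    anchor_vals = dict(zip(anchors["year"], anchors["n_vessels"]))

    values, prov = [], []
    for y in full_years:
        a = _nearest_anchor(y, anchor_years)
        values.append(anchor_vals[a] * proxy.loc[y] / proxy.loc[a])
        prov.append("observed" if y in anchor_vals else "reconstructed")
    out = pd.DataFrame({"year": full_years, "n_vessels": np.maximum(values, 0.0), "provenance": prov})
    out.loc[out["provenance"] == "observed", "n_vessels"] = out.loc[
        out["provenance"] == "observed", "year"
    ].map(anchor_vals)
    return out


@dataclass
class UnmotorizedModel:
    """Linear relation between a country's unmotorized-fleet peak year and GDP.

    ``Y_max = slope * gdp_per_capita + intercept``, fitted by OLS across
    data-rich countries; used to predict the peak year where it was never
    observed.
    """

    slope: float
    intercept: float
    stderr_slope: float = np.nan
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict_ymax(self, gdp_per_capita: float, year_range: tuple[int, int]) -> int:
        y = int(round(self.slope * gdp_per_capita + self.intercept))
        lo, hi = year_range
        if y < lo or y > hi:
            warnings.warn(f"predicted Y_max {y} outside year range; clipped", stacklevel=2)
            y = min(max(y, lo), hi)
        return y


def fit_ymax_gdp_relation(data_rich: pd.DataFrame) -> UnmotorizedModel:
    """OLS fit of peak year on GDP per capita at the peak.

    ``data_rich`` has columns ``y_max`` and ``gdp_at_ymax``, one row per
    country with an observed unmotorized-fleet maximum.
    """
    if len(data_rich) < 3:
        raise ValueError("need at least 3 (Y_max, GDP) points")
    gdp = data_rich["gdp_at_ymax"].to_numpy(float)
    if np.ptp(gdp) == 0:
        raise ValueError("degenerate design: all GDP values identical")
    X = sm.add_constant(gdp)
    res = sm.OLS(data_rich["y_max"].to_numpy(float), X).fit()
    return UnmotorizedModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr_slope=float(res.bse[1]),
        residuals=np.asarray(res.resid),
    )


def reconstruct_unmotorized(
    partial: pd.DataFrame,
    motorized: pd.DataFrame,
    covariates: pd.DataFrame,
    year_range: tuple[int, int],
    y_max: int | None = None,
    model: UnmotorizedModel | None = None,
    gdp_for_prediction: float | None = None,
    coupling: float = -1.0,
) -> pd.DataFrame:
    """Reconstruct an unmotorized artisanal fleet around its peak year.

    Before ``y_max`` the series follows population growth (proxy scaling
    anchored at the nearest observation at or before the peak).  After
    ``y_max`` it changes at ``coupling`` times the relative rate of change
    of the motorized artisanal fleet; the default ``coupling = -1`` makes
    motorization *replace* unmotorized craft, so a growing motorized fleet
    shrinks the unmotorized one.  The series is continuous at the peak.
    """
    if motorized is None or len(motorized) == 0:
        raise ValueError("motorized series is required")
    y0, y1 = year_range
    if y_max is None:
        if model is None or gdp_for_prediction is None:
            raise ValueError("y_max not given: need a fitted model and a GDP value to predict it")
        y_max = model.predict_ymax(gdp_for_prediction, year_range)
    if y_max < y0 or y_max > y1:
        warnings.warn(f"Y_max {y_max} outside year range; clipped", stacklevel=2)
        y_max = min(max(y_max, y0), y1)

    pre_obs = partial[partial["year"] <= y_max]
    anchor_src = pre_obs if len(pre_obs) else partial
    pre = reconstruct_by_proxy(anchor_src, covariates, (y0, y_max))

    m = motorized.set_index("year")["n_vessels"]
    full_years = np.arange(y0, y1 + 1)
    values = np.empty(len(full_years))
    values[: y_max - y0 + 1] = pre["n_vessels"].to_numpy()
    level = values[y_max - y0]
    for y in range(y_max, y1):
        m_rate = (m.loc[y + 1] - m.loc[y]) / m.loc[y] if m.loc[y] > 0 else 0.0
        level = max(level * (1.0 + coupling * m_rate), 0.0)
        values[y + 1 - y0] = level

    out = pd.DataFrame({"year": full_years, "n_vessels": values, "provenance": "reconstructed"})
    obs_years = set(partial["year"])
    out.loc[out["year"].isin(obs_years), "provenance"] = "observed"
    return out


def mean_relative_error(fitted: np.ndarray, observed: np.ndarray) -> float:
    """Mean of |fit - obs| / obs over observed points with obs > 0."""
    observed = np.asarray(observed, float)
    fitted = np.asarray(fitted, float)
    nz = observed > 0
    if not nz.any():
        return 0.0
    return float(np.mean(np.abs(fitted[nz] - observed[nz]) / observed[nz]))
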