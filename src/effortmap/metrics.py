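"""Comparison statistics for pairs of gridded effort maps.

Three complementary views of agreement between two maps on a common
grid (e.g. reconstructed effort vs an AIS-derived map):

* cell-by-cell Spearman rank correlation over the union of nonzero
  supports (coverage gaps are informative, so zeros are kept by
  default; switchable to the intersection);
* a V-measure comparison of the two maps viewed as regionalizations:
  cells are classed into per-grid deciles of log effort, and the
  homogeneity / completeness / V-measure of the two labelings are
  computed from the co-location contingency table;
* cosine similarity of the latitudinal and longitudinal marginals,
  which tolerates small spatial offsets that cell-wise measures punish.

All three are invariant to scaling either map by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import homogeneity_completeness_v_measure


@dataclass
class ComparisonReport:
    """Agreement statistics for one pair of grids (one scope/year)."""

    spearman_rho: float
    spearman_p: float
    vmeasure: float
    homogeneity: float
    completeness: float
    cosine_lat: float
    cosine_lon: float
    n_cells: int
    scope: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _align(grid_a: pd.DataFrame, grid_b: pd.DataFrame, inclusion: str) -> pd.DataFrame:
    """Outer-join two (lat, lon, effort) tables and apply the inclusion rule."""
    a = grid_a.groupby(["lat", "lon"])["effort"].sum().rename("a")
    b = grid_b.groupby(["lat", "lon"])["effort"].sum().rename("b")
    m = pd.concat([a, b], axis=1).fillna(0.0)
    if inclusion == "union":
        m = m[(m["a"] != 0) | (m["b"] != 0)]
    elif inclusion == "intersection":
        m = m[(m["a"] != 0) & (m["b"] != 0)]
    else:
        raise ValueError(f"unknown inclusion rule {inclusion!r}")
    return m


def spearman_cells(
    grid_a: pd.DataFrame, grid_b: pd.DataFrame, inclusion: str = "union"
) -> tuple[float, float, int]:
    """Cell-wise Spearman rank correlation (ties mid-ranked)."""
    m = _align(grid_a, grid_b, inclusion)
    if len(m) < 3:
        raise ValueError(f"need >= 3 cells to correlate, have {len(m)}")
    rho, p = spearmanr(m["a"], m["b"])
    return float(rho), float(p), len(m)


def _decile_labels(values: np.ndarray, n_classes: int) -> np.ndarray:
    """Quantile-bin log(effort + eps) into n_classes labels per grid."""
    logged = np.log(values + 1e-12)
    # rank-based quantile binning: rank fraction p lands in class ceil(p*n)-1,
    # so distinct values split into equal-count classes; ties share a class
    pct = pd.Series(logged).rank(method="average", pct=True).to_numpy()
    labels = np.ceil(pct * n_classes).astype(int) - 1
    return np.clip(labels, 0, n_classes - 1)


def vmeasure_maps(
    grid_a: pd.DataFrame,
    grid_b: pd.DataFrame,
    n_classes: int = 10,
    inclusion: str = "union",
) -> tuple[float, float, float]:
    """V-measure of the two maps' effort-class regionalizations.

    Each grid's included cells are classed into ``n_classes`` quantile
    bins of log effort; homogeneity = 1 − H(A|B)/H(A), completeness =
    1 − H(B|A)/H(B), V = their harmonic mean.  A single-class partition
    has zero entropy and scores 1 by convention.

    Returns ``(vmeasure, homogeneity, completeness)``.
    """
    m = _align(grid_a, grid_b, inclusion)
    if len(m) == 0:
        raise ValueError("no cells in common support")
    la = _decile_labels(m["a"].to_numpy(float), n_classes)
    lb = _decile_labels(m["b"].to_numpy(float), n_classes)
    h, c, v = homogeneity_completeness_v_measure(la, lb)
    return float(v), float(h), float(c)


def cosine_marginals(grid_a: pd.DataFrame, grid_b: pd.DataFrame) -> tuple[float, float]:
    """Cosine similarity of latitudinal and longitudinal effort marginals."""
    out = []
    for axis in ("lat", "lon"):
        a = grid_a.groupby(axis)["effort"].sum()
        b = grid_b.groupby(axis)["effort"].sum()
        m = pd.concat([a.rename("a"), b.rename("b")], axis=1).fillna(0.0)
        va, vb = m["a"].to_numpy(float), m["b"].to_numpy(float)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise ValueError(f"zero {axis} marginal vector")
        out.append(float(np.dot(va, vb) / (na * nb)))
    return out[0], out[1]


def compare_grids(
    grid_a: pd.DataFrame,
    grid_b: pd.DataFrame,
    n_classes: int = 10,
    inclusion: str = "union",
    scope: str = "",
) -> ComparisonReport:
    """Full comparison report for a pair of (lat, lon, effort) tables."""
    rho, p, n = spearman_cells(grid_a, grid_b, inclusion)
    v, h, c = vmeasure_maps(grid_a, grid_b, n_classes, inclusion)
    cl, cn = cosine_marginals(grid_a, grid_b)
    return ComparisonReport(
        spearman_rho=rho, spearman_p=p,
        vmeasure=v, homogeneity=h, completeness=c,
        cosine_lat=cl, cosine_lon=cn,
        n_cells=n, scope=scope,
    )


def reconstruction_error_report(
    fits: pd.DataFrame, observations: pd.DataFrame, keys: list[str]
) -> pd.DataFrame:
    """Mean relative error of reconstructed vs observed counts per key group.

    Both tables carry the key columns plus ``year``; ``fits`` has column
    ``fitted`` and ``observations`` has ``observed``.  Years with zero
    observation are excluded from the mean and counted separately.
    """
    merged = observations.merge(fits, on=keys + ["year"], how="inner")
    nz = merged["observed"] > 0
    merged.loc[nz, "rel_err"] = (
        (merged.loc[nz, "fitted"] - merged.loc[nz, "observed"]).abs() / merged.loc[nz, "observed"]
    )
    g = merged.groupby(keys)
    out = g.agg(
        mean_rel_error=("rel_err", "mean"),
        n_years=("year", "size"),
        n_zero_obs=("observed", lambda s: int((s == 0).sum())),
    ).reset_index()
    return out
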