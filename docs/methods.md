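# Methods

This note documents the models, estimators and design choices behind
`effortmap`, what the synthetic world does and does not emulate, and the
numerical conventions the implementation commits to.

## Fleet reconstruction

National vessel-count series per (country, sector) are assumed to follow
carrying-capacity-limited growth: `N(t) = K / (1 + exp(-r (t - t0)))`,
with `K` the fleet carrying capacity (vessels), `r` the growth rate
(yr⁻¹) and `t0` the midpoint year. The curve is fitted to the observed
years by nonlinear least squares (`scipy.optimize.curve_fit`) with
initialisation `K = 1.2 × max(obs)`, `r = 0.1/yr`, `t0 =` first year the
series crosses half its maximum, and broad bounds (`r ∈ [−2, 2]` so
declining segments are representable). Degenerate inputs are handled
explicitly: a constant series is returned as the flat limit of the
logistic; a segment with fewer than three observations raises
`InsufficientDataError` so the caller can fall back to proxy
reconstruction; solver non-convergence falls back to shape-preserving
monotone (PCHIP) interpolation with flat extrapolation, flagged in the
fit object. Observed years keep their observed values and an
`observed` provenance flag; the fitted curve fills the gaps and is
available separately. Disruption years split the series into segments
fitted independently, with no continuity constraint — the motivating
events are fleet destructions, where a jump is the point.

Proxy reconstruction scales the nearest observed anchor by a covariate:
`NV_y = NV_anchor × pop_y / pop_anchor`, with ties between anchors
broken toward the earlier year (deterministic and documented, rather
than an average of both).

The unmotorized artisanal fleet is reconstructed around its peak year
`Y_max`: population-proportional before the peak, and afterwards
changing at `coupling ×` the motorized fleet's relative rate of change.
The default `coupling = −1` encodes substitution — motorization replaces
unmotorized craft — and is the only sign consistent with `Y_max` being a
maximum while the motorized fleet still grows. Where `Y_max` was never
observed it is predicted from a cross-country ordinary-least-squares
relation between peak year and GDP per capita. That relation is fitted
on (peak year, GDP at the peak) pairs, which makes prediction slightly
circular (the GDP at an unknown peak is itself unknown); the
implementation therefore takes an explicit GDP scalar from the caller,
and the pipeline passes the country's mean GDP per capita over the
record. This is a documented open-design choice, configurable by
callers who prefer, e.g., a fixed reference year.

## Capacity disaggregation

Length-class and gear share series are compositions on the simplex.
Gappy share series are completed on the additive log-ratio (ALR) scale
— log-ratios against the component with the largest mean share —
interpolated linearly over years, held flat beyond the observed range,
back-transformed and renormalized. Components that are zero at every
observation are structural zeros and stay exactly zero; sporadic zeros
are clipped to 1e−9 before the transform. Data-poor countries take the
unweighted per-year mean of configured donor countries, renormalized.

Vessel counts are apportioned to integer counts by largest-remainder
rounding, first across length classes, then across gears within each
class, after rounding the national total to whole vessels; remainder
ties break toward the lower index. This makes vessel conservation exact
and testable — naive per-cell rounding leaks vessels.

Mean engine power per vessel varies with time (observations per
country × length class interpolated linearly, flat beyond), while gross
tonnage — a geometry property of the hull — is constant per country ×
length class, or step-constant across periods when period-tagged
observations exist. Totals are means × counts.

## Effort

Nominal effort per fleet segment is `Eff_nom = P × DAS × R_act`
(kW·days): total engine power × days at sea × the fraction of the fleet
active. Days at sea are looked up with an explicit key-relaxation
cascade — exact (country, sector, gear, year) → same segment any year →
same country/sector any gear → regional donors → global mean — with the
fallback recorded as provenance. The activity ratio defaults to 0.72
when a country has no activity data of its own.

The engine-power equivalent of an unmotorized vessel, `PPV_eq` (kW), is
solved from the stable-CPUE assumption of the early motorization period:
`Catch_y = q (NV_y × PPV_eq + P_y)` with unknown catchability `q`, over
the years in which the unmotorized fleet is 20–80% of the artisanal
vessel total (both endpoints inclusive, for determinism). The
proportionality is resolved as a two-coefficient, no-intercept
least-squares fit `Catch = a·NV + b·P` and `PPV_eq = a/b`, which cancels
`q`. Because catch errors are multiplicative, the fit minimises squared
*relative* residuals (equivalently, regresses 1 on `NV/Catch` and
`P/Catch`); on noise-free inputs this coincides with the unweighted fit
and is exact. Fewer than two windowed years, or a non-positive fitted
ratio, raise with a suggestion to widen the window.

**Identifiability limit.** With independent multiplicative noise of CV
σ on the annual catch series, the information about `PPV_eq` lives in
the variation of the unmotorized *catch fraction*
`f_y = PPV·NV_y / (PPV·NV_y + P_y)` across the windowed years; the
asymptotic relative error of any estimator is bounded below by
`σ / √Σ(f_y − f̄)²`. For realistic motorization histories (the 20–80%
window spanning two to five decades) this floor is roughly 5–15% of
`PPV_eq` at σ = 10%. The package's estimator sits essentially on that
floor (≈6% median error over 100 synthetic replicates at 10% noise), so
tighter recovery at that noise level should not be expected from any
method; with smaller noise, or noise that is partly a persistent
country-level bias (which cancels exactly in `a/b`), recovery is
correspondingly tighter.

Technological creep — the biomass-independent annual increase in
catchability — is estimated as `c = exp(slope) − 1` from a least-squares
line of log CPUE on year; when a biomass index is supplied it enters as
a log covariate so the year trend is biomass-independent, otherwise the
raw trend is used and labelled as such. Non-positive CPUE values are
dropped with a warning and at least five positive years are required.
When estimation is impossible the sector defaults apply: 1.4%/yr
industrial, 5%/yr artisanal (mean creep across scopes ≈3.5%/yr).
Effective effort compounds creep geometrically from the 1949 baseline,
`Eff_y = Nom_y × Π_{k=1950..y}(1 + c_k)`, so effective equals nominal
exactly in 1949; years before the baseline are rejected.

## Mapping

Effort is placed where catch is: previously mapped catch already encodes
depth, distance to coast and stock location, so the relative catch of
the matching (gear, functional group) across 0.5° cells is the spatial
weight for effort. Gear matching cascades: exact gear code → all catch
gears in the same family (the gear→family table ships as an editable
YAML: nets = gillnets/liftnets/seines, trawls, lines, …) → country level
(all the country's catch gears). The cascade is total — an effort gear
absent from the family table is an error, never a silent drop. Effort is
split across functional groups proportionally to catch composition and
across vessel categories proportionally to tonnage shares, then across
cells by catch weights; each step renormalizes to the segment total.

Constraint masks zero disallowed cells — unmotorized fleets are
restricted to coastal cells, trawl gears to cells without a trawl ban —
and redistribute the removed effort proportionally over the segment's
remaining allowed cells; a segment with no allowed effort anywhere falls
back to a uniform spread over the country's coastal cells (dropping the
effort would break conservation). Smoothing applies a 2-D Gaussian
kernel (default σ = 1 cell, truncated at 3σ) on the dense grid, removes
mass landing in disallowed cells, and rescales to the original total, so
spreading never re-enters banned cells; σ = 0 is the identity. Cell
coordinates are always cell *centres* — odd multiples of 0.25°.

Conservation is the load-bearing invariant: after allocation, masking
and smoothing, mapped nominal effort per (country, year, sector, length
class, gear) equals the national segment total to within 1e−6 relative
(in practice machine precision, since every stage renormalizes).

Because allocation is linear in the segment total, the pipeline computes
one normalized spatial pattern per (country, catch-atlas year, sector,
gear, functional group) and reuses it across years and length classes;
a multi-decade, multi-country run takes seconds.

## Output layout and schema

Mapped records carry 13 fields in fixed order: Year, SAUP (numeric
country code), NV, P (kW), GT, NomActive (kW·days), EffActive,
Length_Category (five labels: "less than 6", "6–12 m", "12–24 m",
"24–50 m", "over 50 m"), Gear, Lat, Lon, FGroup, Sector (I / APW / UP).
The writer produces `effort_mapped/` with one file per (year, sector) —
the Year column omitted, it is in the filename — and
`effort_mapped_country/` with one file per country. When a country
registry is supplied the country folder contains one file per registry
entry, header-only for countries without records, so the file count is
registry-driven. CSV is UTF-8, comma-separated, '.' decimal, with
shortest round-trippable float formatting: write→read round trips are
exact. A days-at-sea→fishing-hours conversion table (factors in (0, 24]
hours/day, per gear × length class, with an optional default) converts
record effort to kW·hours; derivation of such factors from AIS data is
out of scope, only application.

## Comparison metrics

Two maps on a common grid are compared over the union of their nonzero
supports by default — coverage gaps are informative — switchable to the
intersection. Cell-wise Spearman uses mid-ranked ties. The V-measure
treats each map as a regionalization: included cells are classed into
per-grid quantile bins (default deciles) of log(effort + 1e−12), using
rank-based binning so the measure is invariant to positive scaling, and
homogeneity `1 − H(A|B)/H(A)`, completeness `1 − H(B|A)/H(B)` and their
harmonic mean are computed from the co-location contingency table
(single-class partitions have zero entropy and score 1 by convention).
Cosine similarity of the latitude and longitude marginals tolerates
small spatial offsets that cell-wise measures punish. All three metrics
are symmetric where their definitions are, equal 1 on self-comparison,
and are invariant to multiplying either map by a positive scalar.

## The synthetic world

The generator emulates the features the pipeline depends on, with known
ground truth for recovery tests: logistic fleet growth per sector;
lognormal mean-one multiplicative observation noise on counts (CV
configurable, default 5%), rounded to integers; a configured fraction of
years removed uniformly at random (default 30%), always keeping the
first and last year so gap-filling is interpolation-dominated; linearly
drifting length-class compositions observed in some years; a
decade-step catch atlas per (country, gear, functional group) on the
grid, with catch decaying exponentially away from a synthetic coast
(the grid's southern rows); days-at-sea and activity tables present for
half the countries so the fallback cascade and the 72% default are
exercised; and an artisanal catch series generated exactly from the
motor-equivalence relation with known `PPV_eq` and 10% multiplicative
catch noise.

Chosen magnitudes, and why: unmotorized fleets are long established
(K ∈ [300, 1200] vessels, midpoints 1930–1945, so they are near
capacity by the 1950s); industrial growth is mid-century (K ∈ [300,
1500], r ∈ [0.06, 0.15]/yr, midpoints 1955–1980 — fleets in 1950 are
small but not near-zero, as real yearbook series are); artisanal
motorization is a slow multi-decade transition (K ∈ [1000, 4000],
r ∈ [0.05, 0.1]/yr, midpoints 1970–1990), sweeping the unmotorized
share down through the 20–80% estimation window; motorized artisanal
vessels carry ~10 kW (a typical outboard), comparable to the 4–10 kW
unmotorized power equivalents, so both fleet components contribute
materially to catch over that window — the premise of the equivalence
method. Countries are disjoint longitude blocks; no attempt is made to
mimic real coastlines, bathymetry, real fleet magnitudes, or
cross-country spatial overlap. Passing tests therefore demonstrate that
the algorithms are correct and the invariants hold, not that the method
is unbiased on real yearbook data, whose error structure (reporting
biases, definitional changes, autocorrelated gaps) the generator does
not model.

The AIS-like distortion multiplies cell efforts by mean-one lognormal
noise and zeroes small-vessel (<12 m) cells with configurable
probability, mimicking receiver-coverage loss; it keeps rows (zeroed,
not deleted) so comparisons stay cell-aligned.

## Problem sizes

The shipped validation run (`scripts/acceptance.py`) uses 3 countries ×
68 years × 3 sectors (≈700k mapped records) for the layout,
conservation and exactness checks; 100 single-country replicates for
motor-equivalence recovery; 8 countries for reconstruction error; and
a 10-point noise-free series for logistic recovery. The test suite uses
3 countries over 31 years for its shared fixtures. These sizes were
chosen so a full run completes in about a minute while every check
operates on the same code paths as a full-scale run; all counts scale
linearly with countries and years.

## Known limitations

- The logistic family cannot represent boom–bust fleets without
  disruption-year splits supplied by the caller.
- Donor-country similarity is configuration, not inference: no
  algorithmic "similar country" detection is attempted.
- Creep without a biomass index conflates technology gains with biomass
  trends; the estimate is labelled accordingly.
- `PPV_eq` recovery is bounded by the identifiability floor described
  above; at 10% i.i.d. catch noise, median errors below ~5–6% are not
  attainable in principle.
- The mapper never re-derives catch maps; catch placement errors
  propagate into effort placement by construction.
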