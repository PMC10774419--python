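"""Compare mapped effort with an AIS-like distorted copy, by length class.

Degrades the mapped grid the way satellite AIS coverage does — cell
noise plus preferential loss of small-vessel cells — then scores each
vessel length class for one year with the three comparison statistics:
cell-wise Spearman, V-measure of the effort-class regionalizations, and
cosine similarity of the lat/lon marginals.
"""

import effortmap as em
from effortmap import metrics
from effortmap.synthetic import AISDistortion, generate_ais_like_grid

world = em.generate_world(em.WorldConfig(n_countries=3, year_start=2000, year_end=2010, rng_seed=5))
run = em.run_pipeline(world)

ais = generate_ais_like_grid(
    run.records, AISDistortion(noise_cv=0.4, coverage_small=0.3, seed=9)
)

def as_grid(records):
    return records.rename(columns={"Lat": "lat", "Lon": "lon", "NomActive": "effort"})[
        ["lat", "lon", "effort"]
    ]

year = 2010
print(f"year {year}, per length class (AIS-like grid: 40% cell noise, "
      "70% of small-vessel cells lost):\n")
print(f"{'class':>12}  {'cells':>5}  {'Spearman':>8}  {'V-meas':>6}  "
      f"{'cos_lat':>7}  {'cos_lon':>7}")
for lc in em.LENGTH_CLASSES:
    mine = run.records.query("Year == @year and Length_Category == @lc")
    theirs = ais.query("Year == @year and Length_Category == @lc")
    if mine["NomActive"].sum() == 0:
        continue
    rep = metrics.compare_grids(as_grid(mine), as_grid(theirs), scope=lc)
    print(f"{lc:>12}  {rep.n_cells:>5}  {rep.spearman_rho:8.3f}  {rep.vmeasure:6.3f}  "
          f"{rep.cosine_lat:7.3f}  {rep.cosine_lon:7.3f}")

print("\nsmall classes score lower: AIS-style coverage drops their cells, while")
print("large-vessel classes survive nearly intact — marginal cosines stay higher")
print("than cell-wise scores because they aggregate over whole lat/lon bands.")
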