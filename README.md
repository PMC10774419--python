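# effortmap

Reconstruction and 0.5° mapping of fishing fleet capacity and effort.

Global analyses of fishing impacts need effort that is long-term (decades,
not the few years satellite AIS covers), complete across sectors (including
artisanal and unmotorized fleets AIS never sees), and spatially explicit.
National yearbooks record fleet capacity — vessel counts, engine power,
tonnage — but patchily, and only at country level. `effortmap` implements
the full chain from such records to gridded effort maps, exercised end to
end on a synthetic world with known ground truth:

1. **Fleet reconstruction** — gap-fill annual vessel counts per (country,
   sector) with a carrying-capacity-limited logistic,
   `N(t) = K / (1 + e^{-r(t-t0)})`, fitted by nonlinear least squares;
   series are split into independent segments at disruption years (wars,
   cyclones), and data-poor fleets are scaled by population growth instead.
   The unmotorized artisanal fleet follows population up to its peak year
   `Y_max`, then shrinks at the rate the motorized fleet grows
   (motorization replaces unmotorized craft).
2. **Capacity disaggregation** — split national fleets into five
   length-overall classes and ISSCFG gear types with compositional
   (additive log-ratio) smoothing of share series, donor-country
   imputation, and largest-remainder integer apportionment so vessels are
   conserved exactly; attach per-vessel engine power (time-varying) and
   gross tonnage (constant per class).
3. **Effort** — nominal effort per segment `Eff_nom = P × DAS × R_act`
   (kW·days: engine power × days at sea × activity ratio, default 72%
   where a country has no activity data); an engine-power equivalent for
   unmotorized vessels, `PPV_eq`, solved from
   `Catch_y ∝ NV_unmotor,y × PPV_eq + P_motor,y` over years when the
   unmotorized fleet is 20–80% of the artisanal total; technological creep
   `c` estimated as the trend of log CPUE (defaults 1.4%/yr industrial,
   5%/yr artisanal), compounded geometrically into effective effort
   `Eff_y = Nom_y × Π(1+c)` from a 1949 baseline.
4. **Mapping** — allocate each national segment to 0.5° cells by prorating
   against mapped catch, with a gear-matching cascade (exact gear → gear
   family → country level), functional-group splits proportional to catch
   composition, constraint masks (trawl bans, coastal-only unmotorized
   fleets), and Gaussian spreading — every stage renormalized so mapped
   effort sums back to the national totals.
5. **Validation metrics** — cell-wise Spearman, V-measure of effort-class
   regionalizations (with homogeneity and completeness), and cosine
   similarity of latitude/longitude marginals for comparing gridded maps,
   e.g. against AIS-derived effort.

## Worked example

```python
import effortmap as em

world = em.generate_world(em.WorldConfig(n_countries=3, year_start=1950,
                                         year_end=1960, rng_seed=1))
run = em.run_pipeline(world)
print(len(run.segments), len(run.records))
```

Running `python examples/04_map_effort.py` (the same run, plus the audit
and the writer) prints:

```
segments: 594 (country x sector x year x length x gear)
mapped records: 114048 rows, 192 distinct cells
conservation: max |mapped - national| / national = 3.84e-16 (every segment
total survives allocation, masking and smoothing)

wrote 33 per-(year, sector) files (11 years x 3 sectors) and 3 country files
schema check: passed=True, 13 fields
```

594 national segments (3 countries × 3 sectors × 11 years × the length
classes and gears each sector uses) become 114 048 gridded records — one
per (segment, functional group, cell) — whose per-segment sums match the
national effort totals to machine precision. The writer produces the
two-folder layout: one 12-column file per (year, sector) (the year lives
in the filename) and one 13-column file per country, and the schema
validator confirms the 13 fields, sector codes, length-class labels, and
that all coordinates are 0.5° cell centres.

The other scripts in `examples/` demonstrate one capability each:
world generation and its ground truth (`01`), logistic gap-filling and
parameter recovery (`02`), motor equivalence, creep and effective effort
(`03`), and AIS-style map comparison by length class (`05`).

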