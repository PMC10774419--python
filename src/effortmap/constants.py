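"""Field constants used across the pipeline.

These are the published defaults of the effort-reconstruction method:
the fleet-wide mean activity ratio applied to countries without activity
data, the sector-level technological-creep defaults, the creep baseline
year (effective effort equals nominal effort at the baseline), and the
spatial resolution of the output grid.
"""

#: Fraction of the fleet active in a typical year, applied when a country
#: has no activity data of its own.
DEFAULT_ACTIVITY_RATIO = 0.72

#: Default annual technological creep (catchability increase) by sector,
#: used when creep cannot be estimated from CPUE for a segment.
CREEP_INDUSTRIAL = 0.014
CREEP_ARTISANAL = 0.05

#: Mean creep across sectors/gears, the headline figure of the method.
CREEP_MEAN = 0.035

#: Effective effort equals nominal effort in this year (creep factor = 1).
CREEP_BASELINE_YEAR = 1949

#: Output grid resolution in degrees; cell coordinates are cell centres.
CELL_SIZE_DEG = 0.5

#: Sector codes used in the output schema.
SECTOR_INDUSTRIAL = "I"
SECTOR_ARTISANAL_MOTORIZED = "APW"
SECTOR_ARTISANAL_UNMOTORIZED = "UP"
SECTORS = (SECTOR_INDUSTRIAL, SECTOR_ARTISANAL_MOTORIZED, SECTOR_ARTISANAL_UNMOTORIZED)

#: Vessel length-overall classes, labelled as in the output schema.
LENGTH_CLASSES = ("less than 6", "6–12 m", "12–24 m", "24–50 m", "over 50 m")

#: Length classes counted as "small vessels" (< 12 m) for AIS-coverage
#: style thinning and comparisons.
SMALL_LENGTH_CLASSES = ("less than 6", "6–12 m")

#: The 13 fields of a mapped-effort record, in output order.
EFFORT_FIELDS = (
    "Year",
    "SAUP",
    "NV",
    "P",
    "GT",
    "NomActive",
    "EffActive",
    "Length_Category",
    "Gear",
    "Lat",
    "Lon",
    "FGroup",
    "Sector",
)
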