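# Gear -> family mapping used by the gear-matching cascade.
# Families follow the coarse ISSCFG groupings (nets, trawls, lines, ...);
# edit or extend per deployment. Every gear code used on either the
# effort or the catch side must appear exactly once.
nets:
  - gillnets
  - liftnets
  - seines
trawls:
  - bottom_trawls
  - midwater_trawls
lines:
  - longlines
  - handlines
  - pole_and_line
dredges:
  - dredges
traps:
  - traps
  - pots
other:
  - other
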