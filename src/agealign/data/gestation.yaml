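# Default gestation lengths (days) for the nine study species, from
# standard comparative life-history references.  Users may override any
# entry, or add species, by loading their own YAML with the same keys.
gestation_days:
  human: 270
  chimpanzee: 228
  bonobo: 230
  gorilla: 257
  orangutan: 245
  rhesus_macaque: 165
  gibbon: 210
  siamang: 231
  marmoset: 144
# Shift (days) applied when placing organoid incubation days on the
# days-post-conception axis.  0 aligns incubation day d with d days
# post conception.
organoid_offset_days: 0
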