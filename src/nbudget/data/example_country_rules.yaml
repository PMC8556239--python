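# Example country-specific edit rules for historical fodder-area records.
#
# These illustrate how national adjustments are expressed as declarative
# rules rather than code: splitting a lumped historical "hay" area among
# crop codes by fixed or reference-year shares, extrapolating small crops
# back in time, and replacing an unreliable series with a national one.
Poland:
  # 1960-1986 "hay" divided in fixed proportions: 29% temporary grassland,
  # 6% lucerne, 42% other forage legumes, remaining 23% other green fodder.
  - kind: proportional_split
    target: area.hay
    components: [area.G1000, area.G2100, area.G2900, area.G9000]
    shares:
      area.G1000: 0.29
      area.G2100: 0.06
      area.G2900: 0.42
      area.G9000: 0.23
    years: [1961, 1986]
Czechoslovakia:
  # "hay" split among forage legumes and other green fodder in proportion
  # to their 1987 areas; temporary grassland extrapolated constant back.
  - kind: proportional_split
    target: area.hay
    components: [area.G2100, area.G2900, area.G9000]
    reference_year: 1987
    years: [1961, 1986]
  - kind: extrapolate_const
    target: area.G1000
    direction: backward
Denmark:
  # fluctuating reported G9000 replaced by a national cereals-harvested-
  # green record supplied under its own variable name.
  - kind: replace
    target: area.G9000
    source: area.G9000_national
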