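data:
  path: forest.csv
objectives:
  - key: even_harvest
    label: Even-flow harvested volume
    indicator: harvested_volume
    temporal: min
  - key: deadwood_2116
    label: Deadwood at the end of the horizon
    indicator: deadwood_volume
    temporal: lastYear
  - key: recreation
    label: Mean recreation index
    indicator: recreation_index
    temporal: average
    spatial: areaWeightedMean
constraints:
  - key: ccf_on_peat
    kind: allowed_regimes
    label: Only CCF or set-aside on peatland
    allowed: [CCF_1, SA]
    flag: PEAT
    enabled: true
  - key: deadwood_no_decline
    kind: indicator_threshold
    indicator: deadwood_volume
    alpha: 1.0
    enabled: true
epsilon:
  even_harvest: 5.0
output: out
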