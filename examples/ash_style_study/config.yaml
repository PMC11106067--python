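tree: tree.nwk
tip_ranges: tip_ranges.tsv
temperature: temperature.csv
areas:
- WNA
- ENA
- JP
- EU
- EA
- CA
adjacent_pairs:
- - CA
  - EA
- - CA
  - EU
- - CA
  - JP
- - EA
  - JP
- - ENA
  - WNA
max_range_size: 6
epochs:
  boundaries:
  - 30.0
  - 5.0
  slices:
  - name: slice_0
    multipliers:
      WNA:
        ENA: 1.0
        JP: 1.0
        EU: 1.0
        EA: 1.0
        CA: 1.0
      ENA:
        JP: 1.0
        EU: 1.0
        EA: 1.0
        CA: 1.0
      JP:
        EU: 1.0
        EA: 1.0
        CA: 1.0
      EU:
        EA: 1.0
        CA: 1.0
      EA:
        CA: 1.0
  - name: slice_1
    multipliers:
      WNA:
        ENA: 1.0
        JP: 1.0
        EU: 0.5
        EA: 1.0
        CA: 1.0
      ENA:
        JP: 1.0
        EU: 1.0
        EA: 1.0
        CA: 1.0
      JP:
        EU: 1.0
        EA: 1.0
        CA: 1.0
      EU:
        EA: 1.0
        CA: 1.0
      EA:
        CA: 1.0
  - name: slice_2
    multipliers:
      WNA:
        ENA: 1.0
        JP: 1.0
        EU: 1.0
        EA: 0.5
        CA: 1.0
      ENA:
        JP: 1.0
        EU: 0.25
        EA: 1.0
        CA: 1.0
      JP:
        EU: 1.0
        EA: 1.0
        CA: 1.0
      EU:
        EA: 1.0
        CA: 1.0
      EA:
        CA: 1.0
models:
- family: DEC
  founder: false
- family: DEC
  founder: true
- family: BAYAREALIKE
  founder: false
- family: BAYAREALIKE
  founder: true
seed: 11
root_prior: uniform
event_times: midpoint
density:
  bandwidth: 2.0
  grid_step: 0.25
loess_span: 0.25
slope_delta: 0.1
periods:
  boundaries:
  - 34.0
  - 15.0
  - 5.0
  labels:
  - Warm I
  - Cold I
  - Warm II
  - Cold II
output: out
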