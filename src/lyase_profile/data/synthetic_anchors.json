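{
  "synthetic-anchor-HAL": {
    "family": "HAL",
    "mio_start": 152,
    "dyad_positions": [
      83,
      84
    ]
  },
  "synthetic-anchor-PAL": {
    "family": "PAL",
    "mio_start": 152,
    "dyad_positions": [
      83,
      84
    ]
  },
  "synthetic-anchor-TAL": {
    "family": "TAL",
    "mio_start": 152,
    "dyad_positions": [
      83,
      84
    ]
  }
}
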