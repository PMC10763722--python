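{
  "name": "titin isoform IC",
  "total_residues": 35991,
  "region_boundaries": [
    ["Z-disk", 1, 2100],
    ["I-band", 2101, 15967],
    ["I/A junction", 15968, 16500],
    ["A-band", 16501, 33900],
    ["M-band", 33901, 35991]
  ],
  "epitope_ranges": {
    "T12": [2174, 2437],
    "MIR": [15968, 16348],
    "A170": [33496, 33784],
    "M8M10": [35553, 35991]
  }
}
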