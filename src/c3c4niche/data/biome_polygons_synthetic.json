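{
  "version": "1.0",
  "description": "Synthetic, hand-digitized approximation of the classic Whittaker temperature-precipitation biome diagram. Vertices are [MAT degC, MAP mm]. Not traced from any published data file; intended for descriptive classification only.",
  "axes": {"MAT": "degC", "MAP": "mm"},
  "labels": {
    "TrRF": "tropical rainforest",
    "TeRF": "temperate rainforest",
    "TF": "temperate forest",
    "TSF": "tropical seasonal forest",
    "WGS": "woodland/grassland/shrubland",
    "S": "savanna",
    "D": "desert",
    "Ta": "taiga",
    "Tu": "tundra"
  },
  "polygons": {
    "Tu": [[-15, 0], [-5, 0], [-5, 800], [-15, 800]],
    "Ta": [[-5, 0], [3, 0], [3, 1300], [-5, 1300]],
    "D": [[3, 0], [32, 0], [32, 450], [3, 120]],
    "WGS": [[3, 120], [22, 336], [22, 900], [3, 600]],
    "S": [[22, 336], [32, 450], [32, 1700], [22, 1500]],
    "TF": [[3, 600], [22, 900], [22, 2400], [3, 2400]],
    "TeRF": [[3, 2400], [22, 2400], [22, 4500], [3, 4500]],
    "TSF": [[22, 1500], [32, 1700], [32, 2800], [22, 2800]],
    "TrRF": [[22, 2800], [32, 2800], [32, 4600], [22, 4600]]
  }
}
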