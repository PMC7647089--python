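{
  "nodata": 0,
  "FOR": 1,
  "SF": 2,
  "GF": 3,
  "RAG_PAST": 4,
  "RAG": 5,
  "IRR": 6,
  "PAST": 7,
  "WATER": 8,
  "URBAN": 9
}
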