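{
  "name": "rtk-demo",
  "category": ["demo", "synthetic", "non-biological", "RTK-like skeleton"],
  "nodes": [
    {"id": "RTK", "label": "RTK"},
    {"id": "PI3K", "label": "PI3K"},
    {"id": "AKT", "label": "AKT"},
    {"id": "RAF", "label": "RAF"},
    {"id": "MAP2K4", "label": "MAP2K4"},
    {"id": "NF1", "label": "NF1"},
    {"id": "PTEN", "label": "PTEN"},
    {"id": "JAK", "label": "JAK"},
    {"id": "JAK1", "label": "JAK1"},
    {"id": "JAK2", "label": "JAK2"},
    {"id": "JAK3", "label": "JAK3"},
    {"id": "TYK2", "label": "TYK2"}
  ],
  "edges": [
    {"source": "RTK", "target": "PI3K", "directed": true},
    {"source": "RTK", "target": "RAF", "directed": true},
    {"source": "RTK", "target": "JAK", "directed": true},
    {"source": "PI3K", "target": "AKT", "directed": true},
    {"source": "RAF", "target": "MAP2K4", "directed": true},
    {"source": "NF1", "target": "RAF", "directed": false},
    {"source": "PTEN", "target": "PI3K", "directed": false},
    {"source": "RTK", "target": "NF1", "directed": true},
    {"source": "RTK", "target": "PTEN", "directed": true}
  ],
  "families": {
    "JAK": ["JAK1", "JAK2", "JAK3", "TYK2"]
  }
}
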