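{
  "name": "notch-demo",
  "category": ["demo", "synthetic", "non-biological", "NOTCH-like skeleton"],
  "nodes": [
    {"id": "NOTCH1", "label": "NOTCH1"},
    {"id": "NOTCH3", "label": "NOTCH3"},
    {"id": "MAML3", "label": "MAML3"},
    {"id": "CDKN2A", "label": "CDKN2A"},
    {"id": "MDM2", "label": "MDM2"},
    {"id": "PAWR", "label": "PAWR"},
    {"id": "THAP1", "label": "THAP1"},
    {"id": "CCAR1", "label": "CCAR1"},
    {"id": "LATS2", "label": "LATS2"},
    {"id": "FLT3", "label": "FLT3"}
  ],
  "edges": [
    {"source": "NOTCH1", "target": "MAML3", "directed": true},
    {"source": "NOTCH3", "target": "MAML3", "directed": true},
    {"source": "NOTCH1", "target": "CDKN2A", "directed": true},
    {"source": "CDKN2A", "target": "MDM2", "directed": true},
    {"source": "PAWR", "target": "CCAR1", "directed": true},
    {"source": "THAP1", "target": "CCAR1", "directed": true},
    {"source": "NOTCH1", "target": "PAWR", "directed": true},
    {"source": "MAML3", "target": "LATS2", "directed": true},
    {"source": "NOTCH1", "target": "FLT3", "directed": false}
  ],
  "families": {}
}
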