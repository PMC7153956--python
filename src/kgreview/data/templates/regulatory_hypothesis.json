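{
  "description": "Length-four regulatory topology linking the fly NGLY1 ortholog (Pngl) to the human AQP1 gene through fly/human transcriptional regulation and orthology. Editable fixture: the published query topology is reconstructed, and slot-by-slot edge types can be adjusted to taste.",
  "nodes": [
    {"id": "FlyBase:FBgn0033050"},
    {"groups": ["GENE"], "taxon": "fly"},
    {"groups": ["GENE"], "taxon": "human"},
    {"groups": ["GENE"], "taxon": "human"},
    {"id": "HGNC:633"}
  ],
  "edges": [
    {"labels": ["interacts with"], "direction": "any"},
    {"labels": ["in orthology relationship with"], "direction": "any"},
    {"labels": ["regulates", "interacts with"], "direction": "any"},
    {"labels": ["regulates"], "direction": "any"}
  ]
}
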