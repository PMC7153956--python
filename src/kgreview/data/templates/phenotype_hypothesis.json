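{
  "description": "Topology relating candidate AQP1 regulators to disease phenotypes through shared phenotype annotations. Editable fixture reconstructing the published second query: AQP1 and a candidate gene meet at a phenotype via 'has phenotype' edges.",
  "nodes": [
    {"id": "HGNC:633"},
    {"groups": ["DISO"]},
    {"groups": ["GENE"]}
  ],
  "edges": [
    {"labels": ["has phenotype"], "direction": "any"},
    {"labels": ["has phenotype"], "direction": "any"}
  ]
}
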