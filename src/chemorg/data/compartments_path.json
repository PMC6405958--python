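{
  "compartments": [
    {"id": "1", "species": ["Inhibitor", "KinU"]},
    {"id": "2", "species": ["Inhibitor", "KinU"]},
    {"id": "3", "species": ["Inhibitor", "KinA"]},
    {"id": "4", "species": ["Inhibitor", "KinA"]},
    {"id": "5", "species": ["Activator", "KinA"]}
  ],
  "edges": [["1", "2"], ["2", "3"], ["3", "4"], ["4", "5"]],
  "kinetochore_exclusive": true
}
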