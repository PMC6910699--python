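{
  "name": "hiv",
  "comment": "Modified HIV dynamics model: target cells x1, infected cells x2, virus x3; y = x3.",
  "states": ["x1", "x2", "x3"],
  "params": ["p1", "p2", "p3", "p4", "p5"],
  "inputs": [],
  "outputs": ["y"],
  "odes": {
    "x1": "p1 - p2*x1 - p3*x1*x3",
    "x2": "p3*x1*x3 - p4*x2",
    "x3": "p1*p4*x2 - p5*x3"
  },
  "output_exprs": {
    "y": "x3"
  }
}
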