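{
  "name": "threecomp",
  "comment": "Three-compartment model with output in compartment 2; identifiable unless x3(0) = 0.",
  "states": ["x1", "x2", "x3"],
  "params": ["p12", "p13", "p21"],
  "inputs": ["u"],
  "outputs": ["y"],
  "odes": {
    "x1": "p13*x3 + p12*x2 - p21*x1 + u",
    "x2": "p21*x1 - p12*x2",
    "x3": "-p13*x3"
  },
  "output_exprs": {
    "y": "x2"
  }
}
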