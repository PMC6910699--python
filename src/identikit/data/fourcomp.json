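{
  "name": "fourcomp",
  "comment": "4-compartment model with input and output in compartment 1.",
  "states": ["x1", "x2", "x3", "x4"],
  "params": ["a11", "a12", "a21", "a22", "a23", "a33", "a34", "a42", "a43", "a44"],
  "inputs": ["u"],
  "outputs": ["y"],
  "odes": {
    "x1": "a11*x1 + a12*x2 + u",
    "x2": "a21*x1 + a22*x2 + a23*x3",
    "x3": "a33*x3 + a34*x4",
    "x4": "a42*x2 + a43*x3 + a44*x4"
  },
  "output_exprs": {
    "y": "x1"
  }
}
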