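{
  "name": "linear3",
  "comment": "Linear 3-compartment model: input and output in compartment 1, leaks from every compartment.",
  "states": ["x1", "x2", "x3"],
  "params": ["k01", "k02", "k03", "k12", "k13", "k21", "k32"],
  "inputs": ["u"],
  "outputs": ["y"],
  "odes": {
    "x1": "-(k01+k21)*x1 + k12*x2 + k13*x3 + u",
    "x2": "k21*x1 - (k02+k12+k32)*x2",
    "x3": "k32*x2 - (k03+k13)*x3"
  },
  "output_exprs": {
    "y": "x1"
  }
}
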