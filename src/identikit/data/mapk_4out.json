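{
  "name": "mapk_4out",
  "comment": "Mass-action two-site phosphorylation network (MAPK): kinase K and phosphatase F act on substrate phospho-forms S00/S01/S10/S11 through enzyme-substrate complexes; a/b/c are kinase binding/unbinding/catalysis rates, al/be/g the phosphatase counterparts.",
  "states": [
    "KS00",
    "KS01",
    "KS10",
    "FS01",
    "FS10",
    "FS11",
    "K",
    "F",
    "S00",
    "S01",
    "S10",
    "S11"
  ],
  "params": [
    "a00",
    "a01",
    "a10",
    "b00",
    "b01",
    "b10",
    "c0001",
    "c0010",
    "c0011",
    "c0111",
    "c1011",
    "al01",
    "al10",
    "al11",
    "be01",
    "be10",
    "be11",
    "g0100",
    "g1000",
    "g1100",
    "g1101",
    "g1110"
  ],
  "inputs": [],
  "outputs": [
    "y1",
    "y2",
    "y3",
    "y4"
  ],
  "odes": {
    "S00": "-a00*K*S00 + b00*KS00 + g0100*FS01 + g1000*FS10 + g1100*FS11",
    "S01": "-a01*K*S01 + b01*KS01 + c0001*KS00 - al01*F*S01 + be01*FS01 + g1101*FS11",
    "S10": "-a10*K*S10 + b10*KS10 + c0010*KS00 - al10*F*S10 + be10*FS10 + g1110*FS11",
    "S11": "-al11*F*S11 + be11*FS11 + c0111*KS01 + c1011*KS10 + c0011*KS00",
    "KS00": "a00*K*S00 - (b00+c0001+c0010+c0011)*KS00",
    "KS01": "a01*K*S01 - (b01+c0111)*KS01",
    "KS10": "a10*K*S10 - (b10+c1011)*KS10",
    "FS01": "al01*F*S01 - (be01+g0100)*FS01",
    "FS10": "al10*F*S10 - (be10+g1000)*FS10",
    "FS11": "al11*F*S11 - (be11+g1101+g1110+g1100)*FS11",
    "K": "-a00*K*S00 + (b00+c0001+c0010+c0011)*KS00 - a01*K*S01 + (b01+c0111)*KS01 - a10*K*S10 + (b10+c1011)*KS10",
    "F": "-al01*F*S01 + (be01+g0100)*FS01 - al10*F*S10 + (be10+g1000)*FS10 - al11*F*S11 + (be11+g1101+g1110+g1100)*FS11"
  },
  "output_exprs": {
    "y1": "S00",
    "y2": "S01",
    "y3": "S10",
    "y4": "S11"
  }
}
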