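{
 "trait": "p_base",
 "units": "hours",
 "intercept": 4.85,
 "terms": [
  {"marker": "PpdD1.PromDel", "chromosome": "2D", "reference": "1",
   "effects": {"2": -1.5}},
  {"marker": "cfn5828", "chromosome": "2D", "reference": "A",
   "effects": {"G": -0.5}},
  {"marker": "gpw1107", "chromosome": "3B", "reference": "149",
   "effects": {"153": 0.4, "169": 0.5, "171": 0.7, "173": 0.1,
               "175": -0.4, "177": -0.1, "179": -0.5}},
  {"marker": "wPt-7063", "chromosome": "6A", "reference": "0",
   "effects": {"1": 0.3}},
  {"marker": "cfn5539", "chromosome": "2B", "reference": "A",
   "effects": {"G": 0.4}},
  {"marker": "cfn4818", "chromosome": "7A", "reference": "T",
   "effects": {"G": 0.6}},
  {"marker": "cfn4764", "chromosome": "5A", "reference": "A",
   "effects": {"C": -0.5}},
  {"marker": "cfn5634", "chromosome": "6B", "reference": "T",
   "effects": {"C": -0.4}},
  {"marker": "cfn5055", "chromosome": "5B", "reference": "T",
   "effects": {"C": -0.4}},
  {"marker": "wPt-5346", "chromosome": "5B", "reference": "0",
   "effects": {"1": 0.3}},
  {"marker": "gluA1.1.Y.1667", "chromosome": "1A", "reference": "C",
   "effects": {"T": 0.4}},
  {"marker": "wPt-7108", "chromosome": "7B", "reference": "0",
   "effects": {"1": -0.4}}
 ],
 "r2_fit": 0.68
}
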