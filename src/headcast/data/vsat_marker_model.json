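{
 "trait": "v_sat",
 "units": "days",
 "intercept": 53.9,
 "terms": [
  {"marker": "Vrn.A1ex7", "chromosome": "5A", "reference": "11",
   "effects": {"12": -24.7, "22": -28.3}},
  {"marker": "vern.5B.Sins.8761", "chromosome": "5B", "reference": "del",
   "effects": {"ins": 13.3}},
  {"marker": "Vrn.A1pr", "chromosome": "5A", "reference": "11",
   "effects": {"22": 7.0, "25": -29.9, "33": 17.9, "44": 36.6, "55": -1.7}},
  {"marker": "FdGogat.2D.Y.545", "chromosome": "2D", "reference": "C",
   "effects": {"T": -9.4}},
  {"marker": "Vrn.B1int1", "chromosome": "5B", "reference": "11",
   "effects": {"22": -13.1}},
  {"marker": "cfn5274", "chromosome": "2D", "reference": "T",
   "effects": {"G": -6.6}},
  {"marker": "cfn5187", "chromosome": "4A", "reference": "T",
   "effects": {"C": 2.1}},
  {"marker": "cfn5114", "chromosome": "4A", "reference": "T",
   "effects": {"C": 8.0}},
  {"marker": "cfn5680", "chromosome": "7A", "reference": "A",
   "effects": {"G": 7.0}},
  {"marker": "wPt-7062", "chromosome": "4B", "reference": "0",
   "effects": {"1": 10.0}},
  {"marker": "cfn5405", "chromosome": "na", "reference": "T",
   "effects": {"C": -6.7}}
 ],
 "r2_fit": 0.71
}
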