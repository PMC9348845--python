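{
 "scenarios": [
  {
   "family": "7",
   "error_law": "beta"
  },
  {
   "family": "7lessE",
   "error_law": "beta"
  }
 ],
 "estimators": [
  "LRM",
  "HLRM",
  "BRM"
 ],
 "n_datasets": 100
}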