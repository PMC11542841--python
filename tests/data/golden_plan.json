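{
 "n_targets": 60,
 "person_days": 3,
 "travel_km": 40.78663970686283,
 "work_h": 23.157327941372564,
 "travel_share": 0.352256873592
}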