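{
 "biomarker_window_percent": 1.0,
 "clustering": {
  "gel_bin_width": 10.0,
  "linkage": "average"
 },
 "msp": {
  "aggregate": "mean",
  "match_tol_floor_da": 2.0,
  "match_tol_ppm": 600.0,
  "max_ref_peaks": 70,
  "max_replicates": 24,
  "min_peak_frequency": 0.25,
  "min_replicates": 10,
  "min_reproducible_proportion": 0.6
 },
 "preprocess": {
  "max_peaks": 100,
  "noise_method": "mad",
  "peak_width_mz": 5.0,
  "sg_cycles": 1,
  "sg_polyorder": 2,
  "sg_width_mz": 5.0,
  "snr_threshold": 3.0,
  "tophat_width_mz": 150.0
 },
 "schema_version": 1,
 "tolerance": {
  "floor_da": 2.0,
  "ppm": 600.0
 }
}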