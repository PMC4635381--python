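"""Simulate one replicate spectrum of a synthetic strain and pick its peaks.

The strain is a fixed fingerprint of 30 protein peaks in the 2-20 kDa
window; the replicate adds mass jitter, intensity variability, dropout,
spurious peaks, a decaying baseline, and detector noise.  Preprocessing
(smoothing, top-hat baseline, S/N-3 centroid detection) should recover
essentially every planted peak.
"""

import numpy as np

import archaeotype as at

model = at.make_strain(seed=42, n_peaks=30, strain_id="demo-strain")
cfg = at.SimulationConfig(seed=42)
spectrum, truth = at.simulate_replicate(model, cfg, "r1")

peaks = at.preprocess(spectrum)

print(f"planted peaks rendered : {truth.planted.shape[0]}")
print(f"peaks detected         : {len(peaks)}")
hits = sum(
    1 for mz_true in truth.planted[:, 0]
    if np.min(np.abs(peaks.mz - mz_true)) <= 2.0
)
print(f"planted peaks recovered: {hits}")
print("\nfive most intense detections (mz Da, height a.u., S/N):")
for p in sorted(peaks, key=lambda q: -q.intensity)[:5]:
    print(f"  {p.mz:9.2f}  {p.intensity:8.1f}  {p.snr:6.1f}")
print(
    "\nEach detection is a centroid (intensity-weighted mean m/z of the "
    "above-half-height region);\nrecovered == rendered means the peak "
    "picker found every planted protein signal."
)
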