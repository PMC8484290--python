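"""Per-epoch multitaper band-power features of a simulated night.

Each 30-s epoch becomes six log band powers (delta through 30-50 Hz)
estimated with DPSS multitapers after 0.1-50 Hz zero-phase filtering.
The per-stage feature means recover the spectral signatures the simulator
planted: N3 is delta-dominant, N2 carries extra sigma, wake extra alpha.
"""

import numpy as np

import sleepuq as s

config = s.SyntheticStudyConfig(n_epochs=480, seed=2)
hypnogram, signal = s.simulate_night(config)
filtered = s.bandpass_zero_phase(signal, 0.1, 50.0, sample_rate_hz=config.sample_rate_hz)
features = s.multitaper_epoch_features(filtered, config.sample_rate_hz)

bands = [f"{lo:g}-{hi:g}Hz" for lo, hi in features.band_edges]
print("mean log band power (dB) per stage:")
print("stage  " + "  ".join(f"{b:>10}" for b in bands))
for code, label in enumerate(s.STAGE_LABELS):
    rows = features.matrix[hypnogram.stages == code]
    if rows.size:
        print(f"{label:>5}  " + "  ".join(f"{v:10.1f}" for v in rows.mean(axis=0)))

# Read each row against the others: N3 peaks in 0.5-4 Hz, N2 in 12-16 Hz
# relative to its neighbours, W in 8-12 Hz - the classic sleep-EEG picture.
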