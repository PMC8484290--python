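"""Simulate one night of sleep: ground-truth hypnogram + single-channel EEG.

The hypnogram is drawn from a five-stage Markov chain; the EEG carries
stage-specific band power (delta-rich N3, sigma spindles in N2, theta in
REM/N1, alpha/beta in wake).  Raising `fragmentation` mixes the chain toward
a uniform one, emulating the fragmented sleep of obstructive sleep apnea.
"""

import numpy as np

import sleepuq as s

for fragmentation in (0.0, 0.4):
    config = s.SyntheticStudyConfig(n_epochs=480, fragmentation=fragmentation, seed=1)
    hypnogram, signal = s.simulate_night(config)
    counts = np.bincount(hypnogram.stages, minlength=5)
    transitions = int(np.count_nonzero(np.diff(hypnogram.stages)))
    print(f"fragmentation={fragmentation}:")
    print("  epochs per stage (W/REM/N1/N2/N3):", counts.tolist())
    print(f"  stage transitions over the night: {transitions}")
    print(f"  signal: {signal.size} samples at {config.sample_rate_hz:g} Hz")

# More fragmentation -> more stage transitions per night, the hallmark of
# sleep-disordered breathing; stage occupancy stays broadly similar.
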