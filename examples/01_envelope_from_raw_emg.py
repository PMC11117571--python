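"""Envelope extraction: surrogate raw sEMG -> normalized linear envelope.

Builds a one-muscle surrogate EMG burst (band-limited carrier modulated
by a known activation profile, plus 50 Hz mains and baseline noise),
runs the envelope pipeline (notch, zero-phase high-pass, rectification,
zero-phase low-pass) and normalizes by the MVC envelope peak. The
printed correlation says how faithfully the pipeline recovers the
modulating activation profile.
"""

import numpy as np

from synergykit import (
    compute_mvc_peak,
    mvc_normalize,
    preprocess_emg,
    synthesize_raw_recording,
)

fs = 1000.0
t = np.arange(1500) / fs
target = 0.15 + 0.7 * np.exp(-0.5 * ((t - 0.7) / 0.15) ** 2)  # landing burst

raw = synthesize_raw_recording(target[:, None], fs=fs, seed=0, muscle_names=("TA",))
mvc = synthesize_raw_recording(np.ones((1500, 1)), fs=fs, seed=1, muscle_names=("TA",))

envelope = preprocess_emg(raw)
reference = compute_mvc_peak(mvc)
normalized = mvc_normalize(envelope, reference)

r = np.corrcoef(normalized.samples[:, 0], target)[0, 1]
print(f"raw RMS             : {np.sqrt(np.mean(raw.samples**2)):.3f} (arbitrary units)")
print(f"MVC envelope peak   : {reference.peaks[0]:.3f}")
print(f"normalized peak     : {normalized.samples.max():.3f} (fraction of MVC)")
print(f"recovery correlation: {r:.3f}")
print("-> the envelope pipeline reproduces the known activation profile;")
print("   values near 1.0 mean amplitude timing survived filtering intact.")
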