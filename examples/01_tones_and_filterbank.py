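"""Synthesize the probe stimuli and inspect the analysis filterbank.

Builds a pure tone and a harmonic complex tone, shows the calibration
conventions, and designs the 22-channel log-spaced filterbank every
stimulation strategy shares.
"""

import numpy as np

import cisync as cs
from cisync.stimuli import Calibration, harmonic_count

# 30 ms, peak-normalized for implant processing
pure = cs.make_pure_tone(500.0, duration=0.030)
print(f"pure tone: {pure.n_samples} samples at {pure.sample_rate:.0f} Hz, "
      f"peak={np.max(np.abs(pure.samples)):.3f} (electric calibration)")

acoustic = cs.make_pure_tone(
    500.0, 0.030, calibration=Calibration.ACOUSTIC_DBSPL, level_db=65.0
)
rms_pa = np.sqrt(np.mean(acoustic.samples**2))
print(f"same tone at 65 dB SPL: RMS={rms_pa * 1e3:.4f} mPa (re 20 µPa)")

cx = cs.make_complex_tone(220.0)
print(f"complex tone at F0=220 Hz: {harmonic_count(220.0)} harmonics below "
      "10 kHz, amplitudes falling 6 dB/octave")

fb = cs.design_filterbank(22, 125.0, 8000.0, 100_000.0)
print(f"filterbank: {fb.n_channels} channels, centers "
      f"{fb.center_freqs[0]:.0f}-{fb.center_freqs[-1]:.0f} Hz, "
      f"adjacent-center ratio {fb.center_ratio:.3f}")

ch = cs.apply_filterbank(pure, fb)
best = int(np.argmax(np.sqrt(np.mean(ch.data**2, axis=1))))
print(f"strongest response to the 500 Hz tone: channel {best + 1} "
      f"(CF {fb.center_freqs[best]:.0f} Hz) — tonotopy works")
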