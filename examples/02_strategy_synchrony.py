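"""Encode a 500 Hz tone with CIS, HDCIS and PDT and measure synchrony.

The charge-weighted vector strength at the tone frequency, computed on the
channel receiving the greatest charge, quantifies how much temporal fine
structure each strategy writes into its pulse train: ~0 for CIS (envelope
only), ~pi/4 = 0.785 for HDCIS (half-wave-rectified modulation), ~1 for PDT
(one pulse per fine-structure peak).
"""

import numpy as np

import cisync as cs

tone = cs.make_pure_tone(500.0, 0.030)
fb = cs.design_filterbank()
ch = cs.apply_filterbank(tone, fb)

encodings = {
    "cis": cs.schedule_carrier(cs.cis_envelopes(ch), 90_000.0, strategy="cis"),
    "hdcis": cs.schedule_carrier(cs.hdcis_envelopes(ch), 90_000.0, strategy="hdcis"),
    "pdt": cs.pdt_encode(ch),
}

for name, eg in encodings.items():
    vs = cs.vs_electrodogram(eg, 500.0, channel="max_charge")
    print(f"{name:6s} {eg.n_pulses:5d} pulses, max-charge electrode "
          f"{eg.max_charge_channel():2d}, VS(500 Hz) = {vs:.3f}")

print(f"\nanalytic high-rate limit for half-wave weighting: pi/4 = "
      f"{np.pi / 4:.3f}")
print("CIS near zero means its pulse timing carries no pitch cue; HDCIS and "
      "PDT restore cycle-by-cycle synchrony.")
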