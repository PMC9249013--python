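"""Interspike-interval analysis of strategy-driven fiber populations.

Runs a scaled-down version of the interval experiment (a 100 ms 500 Hz
tone, single max-charge electrode, drive calibrated to ~100 spikes/s,
10 presentations instead of 100) and reports the periodicity of the pooled
all-order interval histograms at multiples of the 2 ms tone period.
"""

from cisync.experiments import ExperimentConfig, isi_experiment
from cisync.metrics import isi_comb

cfg = ExperimentConfig(thresholds_ma=(0.1, 0.8, 0.1), master_seed=5)
results = isi_experiment(cfg, n_iterations=10)

for strategy, res in results.items():
    comb = isi_comb(res["all"], period_us=2000.0, smooth_us=500.0)
    mods = ", ".join(f"{m:.2f}" for m in comb["modulation"])
    print(f"{strategy:6s} rate {res['mean_rate_hz']:5.1f}/s, "
          f"{res['all'].n_intervals} intervals, "
          f"comb modulation at 2/4/6 ms: {mods}")

print("\nHDCIS and PDT lock spikes to the 2 ms tone period (large comb "
      "modulation); CIS intervals follow only the carrier and refractoriness.")
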