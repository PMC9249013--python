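"""Follow synchrony through current spread and the point-process fibers.

Current spread mixes phase-delayed neighboring channels at each neural
position, smearing temporal fine structure (vector strength drops). The
stochastic threshold fibers then fire preferentially at the crest of each
cycle's charge accumulation, re-sharpening the synchrony.
"""

import cisync as cs
from cisync.experiments import ExperimentConfig, stage_vs

cfg = ExperimentConfig(thresholds_ma=(0.1, 0.8, 0.1), master_seed=7)
tone = cs.make_pure_tone(500.0, cfg.duration_s, cfg.sample_rate)

for strategy in ("hdcis", "pdt"):
    out = stage_vs(tone, strategy, cfg)
    print(f"{strategy}: stimulation VS={out['stimulation']:.3f} -> "
          f"after spread {out['spread']:.3f} -> "
          f"neural {out['neural']:.3f} "
          f"(population rate {out['neural_rate_hz']:.0f} spikes/s)")

print("\nThe drop-then-recover pattern is the pipeline's central result: "
      "spread degrades timing cues, neural thresholding restores them.")
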