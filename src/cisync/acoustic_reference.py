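"""Simplified acoustic auditory-periphery stand-in.

The acoustic-hearing baseline in the analyses is produced by a deliberately
simple, property-tested cascade rather than a full phenomenological
periphery model (middle ear, control path, hair-cell synapse kinetics are
out of scope). Per fiber, with 256 characteristic frequencies log-spaced
125–8,000 Hz:

band-pass at CF (two cascaded constant-Q biquads; the steeper skirts give
harmonic resolution at low CF) -> static compressive gain normalizing the
fiber's drive toward a reference level (a stand-in for cochlear compressive
amplification; weakly driven fibers are amplified, silence stays silent) ->
half-wave rectification -> expansive cube (IHC-like transduction
sharpening) -> second-order low-pass (the phase-locking roll-off) ->
subtractive short-term adaptation -> saturating drive-to-rate map ->
inhomogeneous Poisson spiking with an absolute refractory period.

The cascade reproduces the qualitative signatures the comparisons rely on:
strong phase locking below ~1–2 kHz, a monotone decline above 2–4 kHz
(governed by the low-pass cutoff), spontaneous firing in silence, and the
fluctuation-profile property for complex tones (fibers tuned between
resolved harmonics beat at the fundamental, fibers on a harmonic lock to
that harmonic instead). The absolute vector-strength maxima of a full
periphery model are not reproduced, and are not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .filterbank import log_spaced_cfs
from .neuron import SpikeRaster
from .stimuli import Calibration, Waveform

__all__ = ["AcousticFiberConfig", "an_response"]


@dataclass(frozen=True)
class AcousticFiberConfig:
    n_fibers: int = 256
    f_lo_hz: float = 125.0
    f_hi_hz: float = 8000.0
    q_factor: float = 4.0
    bp_cascade: int = 2
    compress_ref_pa: float = 0.035   # RMS of an on-CF tone at 65 dB SPL
    compress_floor_pa: float = 0.0035  # caps the gain applied to weak drives
    ihc_lowpass_hz: float = 2500.0
    ihc_lowpass_order: int = 2
    transduction_exponent: float = 3.0
    half_sat_pa: float = 0.02
    spont_rate: float = 5.0
    peak_rate: float = 300.0
    adapt_tau_s: float = 0.05
    adapt_strength: float = 0.6
    refractory_us: float = 700.0

    @property
    def cf_grid(self) -> np.ndarray:
        """CF grid from the same log-spaced designer as the filterbank."""
        return log_spaced_cfs(self.n_fibers, self.f_lo_hz, self.f_hi_hz)


def _rate_waveform(
    x: np.ndarray, cf: float, fs: float, cfg: AcousticFiberConfig
) -> np.ndarray:
    """Deterministic Poisson intensity (spikes/s) for one fiber."""
    s = 1.0 + 1.0 / (2.0 * cfg.q_factor)
    bp = signal.butter(1, [cf / s, cf * s], btype="bandpass", fs=fs, output="sos")
    y = x
    for _ in range(cfg.bp_cascade):
        y = signal.sosfilt(bp, y)
    # compressive gain toward the reference drive; floor caps amplification
    rms = np.sqrt(np.mean(y**2))
    y = y * (cfg.compress_ref_pa / (rms + cfg.compress_floor_pa))
    y = np.maximum(y, 0.0) ** cfg.transduction_exponent
    lp = signal.butter(cfg.ihc_lowpass_order, cfg.ihc_lowpass_hz, fs=fs, output="sos")
    y = np.maximum(signal.sosfilt(lp, y), 0.0)
    # subtractive short-term adaptation against an exponential average
    alpha = 1.0 / (fs * cfg.adapt_tau_s)
    ema = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], y)
    y = np.maximum(y - cfg.adapt_strength * ema, 0.0)
    c = cfg.half_sat_pa ** cfg.transduction_exponent
    v = y / (y + c)
    return cfg.spont_rate + (cfg.peak_rate - cfg.spont_rate) * v


def _draw_spikes(
    rate: np.ndarray, fs: float, refractory_us: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli thinning of the intensity with a dead time (times in s)."""
    p = rate / fs
    cand = np.flatnonzero(rng.random(len(p)) < p)
    if len(cand) == 0:
        return np.array([])
    t_us = cand / fs * 1e6
    keep = [t_us[0]]
    for t in t_us[1:]:
        if t - keep[-1] >= refractory_us:
            keep.append(t)
    return np.array(keep) * 1e-6


def an_response(
    w: Waveform,
    cfg: AcousticFiberConfig = AcousticFiberConfig(),
    n_rep: int = 1,
    seed: int = 0,
) -> SpikeRaster:
    """Population response of the acoustic stand-in to a calibrated tone.

    Returns one fiber entry per (CF, repetition); repetitions reuse the
    deterministic intensity with fresh seeded noise, so spikes may be pooled
    per CF for stable synchrony estimates. Requires acoustic calibration.
    """
    if w.calibration is not Calibration.ACOUSTIC_DBSPL:
        raise ValueError(
            "acoustic model requires a waveform with acoustic (dB SPL) "
            "calibration, not electric peak normalization"
        )
    x = np.asarray(w.samples, float)
    fs = w.sample_rate
    cfs = cfg.cf_grid
    spikes = []
    rows = []
    for i, cf in enumerate(cfs):
        rate = _rate_waveform(x, cf, fs, cfg)
        for rep in range(n_rep):
            rng = np.random.default_rng([seed, i, rep])
            spikes.append(_draw_spikes(rate, fs, cfg.refractory_us, rng))
            rows.append({"cf_hz": cf, "rep": rep})
    return SpikeRaster(
        fiber_table=pd.DataFrame(rows),
        spikes=spikes,
        duration_s=w.duration,
        meta={"seed": seed, "n_rep": n_rep, "level_db": w.level_db},
    )


def pooled_by_cf(raster: SpikeRaster) -> tuple[np.ndarray, list]:
    """Pool repetitions: (cf grid, list of pooled spike arrays per CF)."""
    cfs = raster.fiber_table["cf_hz"].to_numpy()
    uniq = np.unique(cfs)
    pooled = []
    for cf in uniq:
        idx = np.flatnonzero(cfs == cf)
        pooled.append(
            np.sort(np.concatenate([raster.spikes[i] for i in idx]))
            if len(idx)
            else np.array([])
        )
    return uniq, pooled
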