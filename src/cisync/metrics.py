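"""Synchrony and response metrics.

Vector strength measures phase locking of events to an analysis frequency:
the magnitude of the mean unit phasor exp(j 2 pi f t_i), 1 for perfect
locking and 0 for uniform phase. Two variants are used:

* spike vector strength — unweighted mean over action-potential times;
* charge-weighted vector strength — for pulse trains, each pulse's phasor
  is weighted by its charge per phase (a proxy for spiking probability),
  normalized by the total charge.

The charge-weighted form is a normalized discrete-time Fourier transform of
the pulse train, so with short rectangular observation windows spectral
leakage from the carrier line and the DC term can masquerade as synchrony;
an optional Hann taper over the stimulus window suppresses it (the sweep
drivers use it; the plain estimator is the default here).

Interspike-interval histograms (first-order: consecutive differences;
all-order: all ordered pairs within a window) capture periodicity that
vector strength cannot see, such as locking to alternating stimulus cycles.
Excitation profiles summarize the spatial spread of charge or firing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .current_spread import FieldTraceSet
from .neuron import SpikeRaster
from .strategies import Electrodogram

__all__ = [
    "UndefinedSynchronyError",
    "SynchronyTable",
    "ISIHistogram",
    "vs_spikes",
    "vs_pulses",
    "vs_electrodogram",
    "vs_field",
    "vs_raster",
    "isi",
    "excitation_profile",
    "isi_comb",
]


class UndefinedSynchronyError(ValueError):
    """Vector strength is undefined (no events / zero total weight)."""


def _taper_weights(
    t_s: np.ndarray, weights: np.ndarray, taper: str | None, window_s: float | None
) -> np.ndarray:
    if taper is None:
        return weights
    if taper != "hann":
        raise ValueError(f"unknown taper {taper!r}")
    if window_s is None:
        raise ValueError("hann taper needs the observation window duration")
    return weights * np.sin(np.pi * np.clip(t_s / window_s, 0.0, 1.0)) ** 2


def vs_spikes(times_s: np.ndarray, f: float) -> float:
    """Spike vector strength |mean exp(j 2 pi f t_i)|.

    Raises :class:`UndefinedSynchronyError` on an empty train — an absent
    response is not the same as a desynchronized one.
    """
    t = np.asarray(times_s, float)
    if t.size == 0:
        raise UndefinedSynchronyError("vector strength of an empty spike train")
    return float(np.abs(np.mean(np.exp(2j * np.pi * f * t))))


def vs_pulses(
    times_s: np.ndarray,
    charges: np.ndarray,
    f: float,
    taper: str | None = None,
    window_s: float | None = None,
) -> float:
    """Charge-weighted vector strength |sum q_i exp(j 2 pi f t_i)| / sum q_i."""
    t = np.asarray(times_s, float)
    q = np.asarray(charges, float)
    if t.size == 0 or np.sum(q) <= 0:
        raise UndefinedSynchronyError("zero total charge: vector strength undefined")
    w = _taper_weights(t, q, taper, window_s)
    return float(np.abs(np.sum(w * np.exp(2j * np.pi * f * t))) / np.sum(w))


def vs_electrodogram(
    eg: Electrodogram,
    f: float,
    channel: int | str = "max_charge",
    taper: str | None = None,
) -> float:
    """Charge-weighted VS of a stimulation pattern at frequency ``f``.

    ``channel`` is a 1-based electrode, ``"max_charge"`` (the maximally
    excited channel — greatest total delivered charge), or ``"pooled"``.
    """
    if channel == "max_charge":
        sub = eg.on_electrode(eg.max_charge_channel())
    elif channel == "pooled":
        sub = eg
    else:
        sub = eg.on_electrode(int(channel))
    return vs_pulses(
        sub.times_s, sub.charges, f, taper=taper, window_s=eg.duration_us * 1e-6
    )


def vs_field(
    traces: FieldTraceSet,
    f: float,
    mode: str = "max",
    taper: str | None = None,
) -> float | np.ndarray:
    """VS of post-spread effective currents, per neural position.

    Each pulse is an event weighted by the effective current it delivers at
    the position (the continuous analogue of the charge weighting). ``mode``
    "max" returns the maximum over positions, "all" the per-position array.
    """
    t = traces.pulse_times_us * 1e-6
    E = traces.eff_amplitudes_ma
    if E.shape[0] == 0:
        raise UndefinedSynchronyError("empty field: vector strength undefined")
    w = _taper_weights(
        t, np.ones_like(t), taper, traces.duration_us * 1e-6
    )
    phasors = w * np.exp(2j * np.pi * f * t)
    num = np.abs(phasors @ E)
    den = w @ E
    vs = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    if mode == "all":
        return vs
    return float(np.nanmax(vs))


def vs_raster(
    raster: SpikeRaster,
    f: float,
    mode: str = "max",
    min_spikes: int = 1,
) -> float | np.ndarray:
    """Per-fiber spike VS, summarized across the population.

    ``mode`` "max" takes the maximum per-fiber VS over fibers with at least
    ``min_spikes`` spikes (the summary statistic of the sweeps); "pooled"
    concatenates all spikes first; "all" returns the per-fiber array (NaN
    where a fiber has too few spikes).
    """
    if mode == "pooled":
        return vs_spikes(raster.pooled(), f)
    per = np.full(raster.n_fibers, np.nan)
    for i, s in enumerate(raster.spikes):
        if len(s) >= max(min_spikes, 1):
            per[i] = vs_spikes(s, f)
    if mode == "all":
        return per
    if np.all(np.isnan(per)):
        raise UndefinedSynchronyError(
            f"no fiber reached {min_spikes} spikes; population VS undefined"
        )
    return float(np.nanmax(per))


@dataclass(frozen=True)
class SynchronyTable:
    """Tidy vector-strength rows: (unit, analysis_freq_hz, vs)."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def summary(self) -> float:
        """Maximum vector strength across units."""
        return float(self.table["vs"].max())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interspike intervals


@dataclass(frozen=True)
class ISIHistogram:
    order: str  # "first" | "all"
    bin_width_us: float
    counts: np.ndarray
    n_intervals: int
    window_us: float

    @property
    def bin_edges_us(self) -> np.ndarray:
        return np.arange(0.0, self.window_us + self.bin_width_us / 2,
                         self.bin_width_us)

    @property
    def bin_centers_us(self) -> np.ndarray:
        e = self.bin_edges_us
        return (e[:-1] + e[1:]) / 2.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"bin_center_us": self.bin_centers_us, "count": self.counts}
        ).to_csv(path, index=False)


def _train_intervals(t_s: np.ndarray, order: str, window_us: float) -> np.ndarray:
    t = np.sort(np.asarray(t_s, float)) * 1e6
    if len(t) < 2:
        return np.array([])
    if order == "first":
        return np.diff(t)
    # all ordered pairs within the window, forward differences only
    out = []
    for i in range(len(t) - 1):
        d = t[i + 1 :] - t[i]
        d = d[d <= window_us]
        if len(d):
            out.append(d)
    return np.concatenate(out) if out else np.array([])


def isi(
    source: SpikeRaster | np.ndarray,
    order: str = "first",
    bin_width_us: float = 100.0,
    window_us: float = 20_000.0,
) -> ISIHistogram:
    """Interspike-interval histogram of a train or a pooled population.

    For a :class:`SpikeRaster`, intervals are formed within each fiber and
    the histograms pooled (intervals never straddle fibers). First-order
    counts sum to the number of consecutive intervals in the window;
    all-order counts to the number of ordered within-window pairs.
    """
    if order not in ("first", "all"):
        raise ValueError("order must be 'first' or 'all'")
    trains = source.spikes if isinstance(source, SpikeRaster) else [source]
    edges = np.arange(0.0, window_us + bin_width_us / 2, bin_width_us)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    n_total = 0
    for t in trains:
        iv = _train_intervals(np.asarray(t), order, window_us)
        iv = iv[iv <= window_us]
        if len(iv):
            counts += np.histogram(iv, bins=edges)[0]
            n_total += len(iv)
    return ISIHistogram(
        order=order,
        bin_width_us=bin_width_us,
        counts=counts,
        n_intervals=n_total,
        window_us=window_us,
    )


def isi_comb(
    hist: ISIHistogram,
    period_us: float,
    lags: tuple[int, ...] = (1, 2, 3),
    peak_halfwidth_us: float = 250.0,
    smooth_us: float | None = None,
) -> pd.DataFrame:
    """Quantify histogram periodicity at multiples of ``period_us``.

    For each lag k the peak is the largest count within
    ``peak_halfwidth_us`` of k*period; the local baseline is the mean count
    in equally wide windows at the half-period offsets on either side.
    ``modulation`` = (peak - baseline) / baseline. A comb at the period
    yields large positive modulation; a smooth histogram stays near zero.

    ``smooth_us`` applies a boxcar of that width first — set it near the
    pulse-carrier period to measure periodicity at the analysis scale
    without picking up carrier-locked microstructure.
    """
    c = hist.bin_centers_us
    h = hist.counts.astype(float)
    if smooth_us is not None:
        k = max(int(round(smooth_us / hist.bin_width_us)), 1)
        h = np.convolve(h, np.ones(k) / k, mode="same")
    rows = []
    for k in lags:
        lag = k * period_us
        sel = (c >= lag - peak_halfwidth_us) & (c <= lag + peak_halfwidth_us)
        if not np.any(sel):
            continue
        peak = h[sel].max()
        peak_at = c[sel][np.argmax(h[sel])]
        base_sel = (
            (np.abs(c - (lag - period_us / 2)) <= peak_halfwidth_us)
            | (np.abs(c - (lag + period_us / 2)) <= peak_halfwidth_us)
        )
        baseline = h[base_sel].mean() if np.any(base_sel) else np.nan
        rows.append(
            {
                "lag_us": lag,
                "peak_count": peak,
                "peak_at_us": peak_at,
                "baseline_count": baseline,
                "modulation": (peak - baseline) / baseline if baseline else np.inf,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# excitation profiles


def excitation_profile(x: Electrodogram | SpikeRaster) -> np.ndarray:
    """Spatial response summary.

    Electrodogram -> fraction of total charge per electrode (sums to 1;
    zeros if the pattern is empty). SpikeRaster -> mean firing rate per
    fiber over the stimulus duration.
    """
    if isinstance(x, Electrodogram):
        q = x.channel_charges()
        total = q.sum()
        return q / total if total > 0 else q
    if isinstance(x, SpikeRaster):
        return x.fiber_rates()
    raise TypeError(f"cannot profile {type(x).__name__}")
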