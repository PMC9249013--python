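"""Pulse-coding strategies: CIS, HDCIS, PDT and HD-ACE.

All strategies share the filterbank front end and emit trains of
charge-balanced biphasic pulses (cathodic-first, 25 µs phases, 8 µs
interphase gap by default) on a 1 µs time grid. They differ in what the
pulse amplitudes and timings carry:

* CIS modulates a fixed-rate interleaved carrier with the Hilbert-magnitude
  envelope of each channel — the temporal fine structure is discarded and
  pulse times are independent of the input.
* HDCIS modulates the same carrier with the half-wave-rectified channel
  signal, so the within-cycle fine structure survives as cycle-by-cycle
  amplitude modulation.
* PDT emits one pulse per strict local maximum of each channel's filtered
  signal, so pulse *timing* itself carries the fine structure.
* HD-ACE is HDCIS with n-of-m channel selection per stimulation frame, the
  scheme used to study reduced total stimulation rates.

Interleaving is apex-to-base in a fixed rotation; pulses on different
electrodes never share an onset microsecond.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .filterbank import ChannelSignals

__all__ = [
    "PulseParams",
    "Electrodogram",
    "FrameOverrunError",
    "cis_envelopes",
    "hdcis_envelopes",
    "schedule_carrier",
    "pdt_encode",
    "hd_ace_select",
    "write_pulse_table",
    "read_pulse_table",
]


class FrameOverrunError(ValueError):
    """A biphasic pulse does not fit in the per-channel stimulation frame."""


@dataclass(frozen=True)
class PulseParams:
    """Biphasic pulse shape: phase duration, interphase gap (µs)."""

    phase_us: float = 25.0
    gap_us: float = 8.0
    polarity: str = "cathodic_first"

    def __post_init__(self):
        if self.phase_us <= 0:
            raise ValueError("phase duration must be positive")
        if self.gap_us < 0:
            raise ValueError("interphase gap cannot be negative")

    @property
    def footprint_us(self) -> float:
        """Total biphasic footprint: two phases plus the gap."""
        return 2.0 * self.phase_us + self.gap_us


@dataclass(frozen=True)
class Electrodogram:
    """Timed biphasic pulses: onset time (µs), electrode (1..n), amplitude (mA).

    Charge per phase is amplitude x phase duration; it weights each pulse in
    the charge-weighted vector strength. Pulses are onset-sorted and no two
    pulses on different electrodes share an onset microsecond.
    """

    times_us: np.ndarray
    electrodes: np.ndarray  # 1-based
    amplitudes_ma: np.ndarray
    n_channels: int
    params: PulseParams
    duration_us: float
    strategy: str = ""
    total_rate_pps: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = np.asarray(self.times_us, float)
        if len(t) and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise ValueError("pulse times must be non-negative and sorted")
        if np.any(np.asarray(self.amplitudes_ma) < 0):
            raise ValueError("pulse amplitudes must be non-negative")

    @property
    def n_pulses(self) -> int:
        return len(self.times_us)

    @property
    def times_s(self) -> np.ndarray:
        return np.asarray(self.times_us, float) * 1e-6

    @property
    def charges(self) -> np.ndarray:
        """Charge per phase (nC when amplitude is mA and phase µs)."""
        return np.asarray(self.amplitudes_ma, float) * self.params.phase_us

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.charges))

    def channel_charges(self) -> np.ndarray:
        """Total charge per electrode, length ``n_channels``."""
        return np.bincount(
            np.asarray(self.electrodes) - 1,
            weights=self.charges,
            minlength=self.n_channels,
        )

    def max_charge_channel(self) -> int:
        """1-based electrode receiving the greatest total charge."""
        return int(np.argmax(self.channel_charges())) + 1

    def on_electrode(self, electrode: int) -> "Electrodogram":
        m = np.asarray(self.electrodes) == electrode
        return Electrodogram(
            times_us=np.asarray(self.times_us)[m],
            electrodes=np.asarray(self.electrodes)[m],
            amplitudes_ma=np.asarray(self.amplitudes_ma)[m],
            n_channels=self.n_channels,
            params=self.params,
            duration_us=self.duration_us,
            strategy=self.strategy,
            total_rate_pps=self.total_rate_pps,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# envelopes


def cis_envelopes(ch: ChannelSignals) -> ChannelSignals:
    """Hilbert-magnitude envelope per channel (fine structure removed)."""
    env = np.abs(signal.hilbert(ch.data, axis=1))
    return ChannelSignals(
        data=env, spec=ch.spec, sample_rate=ch.sample_rate, kind="envelope_hilbert"
    )


def hdcis_envelopes(ch: ChannelSignals) -> ChannelSignals:
    """Half-wave-rectified channel signal (fine structure retained)."""
    env = np.maximum(ch.data, 0.0)
    return ChannelSignals(
        data=env, spec=ch.spec, sample_rate=ch.sample_rate, kind="envelope_halfwave"
    )


# ---------------------------------------------------------------------------
# carriers

#: apex-to-base rotation: channel 1 (lowest CF, most apical electrode) first
def _interleave_order(n: int) -> np.ndarray:
    return np.arange(n)


def _sample_envelope(env: np.ndarray, sample_rate: float, t_us: np.ndarray,
                     channel: np.ndarray) -> np.ndarray:
    idx = np.minimum(
        np.round(t_us * 1e-6 * sample_rate).astype(int), env.shape[1] - 1
    )
    return env[channel, idx]


def _frame_schedule(
    envelopes: ChannelSignals,
    total_rate_pps: float,
    params: PulseParams,
    active: np.ndarray | None,
    n_per_frame: int,
    strategy: str,
) -> Electrodogram:
    """Shared frame machinery for the interleaved carriers.

    Pulse slots tick at ``total_rate_pps``; frames group ``n_per_frame``
    consecutive slots. With no selection (``active`` = None) every channel
    is visited once per frame in apex-to-base order; with selection,
    ``active(frame_start_idx)`` -> channel indices chosen for that frame.
    """
    env = envelopes.data
    n_ch = env.shape[0]
    fs = envelopes.sample_rate
    duration_us = env.shape[1] / fs * 1e6
    slot_us = 1e6 / total_rate_pps
    frame_us = n_per_frame * slot_us
    # a channel is revisited once per frame: the biphasic footprint must fit
    if frame_us < params.footprint_us:
        raise FrameOverrunError(
            f"frame of {frame_us:.1f} µs cannot fit a "
            f"{params.footprint_us:.0f} µs biphasic pulse"
        )
    n_slots = int(np.ceil(duration_us / slot_us))
    times, chans = [], []
    order = _interleave_order(n_ch)
    j = 0
    while j * slot_us < duration_us:
        frame = j // n_per_frame
        pos = j - frame * n_per_frame
        if active is None:
            chan = order[pos]
        else:
            sel = active(frame)
            if pos >= len(sel):
                j += 1
                continue
            chan = sel[pos]
        times.append(round(j * slot_us))
        chans.append(chan)
        j += 1
    t = np.array(times, float)
    c = np.array(chans, int)
    a = _sample_envelope(env, fs, t, c)
    return Electrodogram(
        times_us=t,
        electrodes=c + 1,
        amplitudes_ma=a,
        n_channels=n_ch,
        params=params,
        duration_us=duration_us,
        strategy=strategy,
        total_rate_pps=total_rate_pps,
    )


def schedule_carrier(
    envelopes: ChannelSignals,
    total_rate_pps: float = 90_000.0,
    params: PulseParams = PulseParams(),
    strategy: str = "cis",
) -> Electrodogram:
    """Modulate the fixed-rate interleaved carrier with channel envelopes.

    Channels are stimulated cyclically; the per-channel rate is
    ``total_rate_pps / n_channels`` (90,000 pps over 22 channels gives
    ~4,091 pps per channel). Each pulse's amplitude is the envelope sampled
    at the pulse onset.
    """
    return _frame_schedule(
        envelopes, total_rate_pps, params, active=None,
        n_per_frame=envelopes.n_channels, strategy=strategy,
    )


def hd_ace_select(
    envelopes: ChannelSignals,
    total_rate_pps: float,
    n_maxima: int,
    params: PulseParams = PulseParams(),
) -> Electrodogram:
    """n-of-m channel selection on half-wave envelopes (HD-ACE).

    Per stimulation frame only the ``n_maxima`` channels with the largest
    envelope value at frame start receive pulses; ties break toward the
    lower channel index. The per-electrode rate is
    ``total_rate_pps / n_maxima``.
    """
    n_ch = envelopes.n_channels
    if not 1 <= n_maxima <= n_ch:
        raise ValueError("n_maxima must be within 1..n_channels")
    env = envelopes.data
    fs = envelopes.sample_rate
    slot_us = 1e6 / total_rate_pps
    order = _interleave_order(n_ch)

    def active(frame: int) -> np.ndarray:
        t_us = frame * n_maxima * slot_us
        idx = min(int(round(t_us * 1e-6 * fs)), env.shape[1] - 1)
        vals = env[:, idx]
        # stable sort on -value keeps lower channel index on ties
        sel = np.argsort(-vals, kind="stable")[:n_maxima]
        in_sel = np.zeros(n_ch, bool)
        in_sel[sel] = True
        return order[in_sel[order]]

    return _frame_schedule(
        envelopes, total_rate_pps, params, active=active,
        n_per_frame=n_maxima, strategy=f"hd_ace_{n_maxima}of{n_ch}",
    )


# ---------------------------------------------------------------------------
# peak-derived timing


def pdt_encode(
    ch: ChannelSignals, params: PulseParams = PulseParams()
) -> Electrodogram:
    """One pulse at each strict positive local maximum of each channel.

    A peak is a strict sign change of the discrete first difference with a
    positive sample value; a plateau contributes its first sample. The pulse
    amplitude equals the signal value at the peak. When peaks from several
    channels land on the same microsecond, later-detected pulses (higher
    channel index in the apex-to-base rotation) are delayed by the minimum
    biphasic footprint so stimulation stays non-simultaneous.
    """
    x = ch.data
    fs = ch.sample_rate
    duration_us = x.shape[1] / fs * 1e6
    cand_t, cand_c, cand_a = [], [], []
    for c in _interleave_order(x.shape[0]):
        row = x[c]
        d = np.diff(row)
        # strict rise into the sample, fall (or plateau-end fall) after it
        rising = d[:-1] > 0
        falling = d[1:] < 0
        flat_then_fall = (d[:-1] == 0) & (d[1:] < 0)
        peaks = np.where((rising & falling) & (row[1:-1] > 0))[0] + 1
        # plateau: first sample of a flat top that eventually falls
        plat = np.where((d[:-1] > 0) & (d[1:] == 0))[0] + 1
        plat = np.array(
            [p for p in plat if _plateau_falls(row, p) and row[p] > 0], int
        )
        del flat_then_fall
        all_p = np.unique(np.concatenate([peaks, plat])) if len(plat) else peaks
        for i in all_p:
            cand_t.append(round(i / fs * 1e6))
            cand_c.append(c)
            cand_a.append(row[i])
    # collision resolution on the 1 µs grid, in detection order
    occupied: set[int] = set()
    step = int(round(params.footprint_us))
    res_t = []
    for t in cand_t:
        tt = int(t)
        while tt in occupied:
            tt += step
        occupied.add(tt)
        res_t.append(tt)
    o = np.argsort(res_t, kind="stable")
    return Electrodogram(
        times_us=np.array(res_t, float)[o],
        electrodes=np.array(cand_c, int)[o] + 1,
        amplitudes_ma=np.array(cand_a, float)[o],
        n_channels=x.shape[0],
        params=params,
        duration_us=duration_us,
        strategy="pdt",
    )


def _plateau_falls(row: np.ndarray, p: int) -> bool:
    """True if the plateau starting at index p ends in a fall, not a rise."""
    q = p
    while q + 1 < len(row) and row[q + 1] == row[q]:
        q += 1
    return q + 1 < len(row) and row[q + 1] < row[q]


# ---------------------------------------------------------------------------
# pulse-table interchange (CSV + JSON sidecar)


def write_pulse_table(eg: Electrodogram, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_us": eg.times_us,
            "electrode": eg.electrodes,
            "amplitude_mA": eg.amplitudes_ma,
            "phase_us": eg.params.phase_us,
            "gap_us": eg.params.gap_us,
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "strategy": eg.strategy,
        "total_rate_pps": eg.total_rate_pps,
        "n_channels": eg.n_channels,
        "duration_us": eg.duration_us,
        "polarity": eg.params.polarity,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_pulse_table(path: str | Path) -> Electrodogram:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    params = PulseParams(
        phase_us=float(df["phase_us"].iloc[0]) if len(df) else 25.0,
        gap_us=float(df["gap_us"].iloc[0]) if len(df) else 8.0,
        polarity=meta.get("polarity", "cathodic_first"),
    )
    return Electrodogram(
        times_us=df["time_us"].to_numpy(float),
        electrodes=df["electrode"].to_numpy(int),
        amplitudes_ma=df["amplitude_mA"].to_numpy(float),
        n_channels=int(meta["n_channels"]),
        params=params,
        duration_us=float(meta["duration_us"]),
        strategy=meta.get("strategy", ""),
        total_rate_pps=meta.get("total_rate_pps"),
    )
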