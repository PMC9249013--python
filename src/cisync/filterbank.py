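"""The analysis filterbank shared by all stimulation strategies.

Twenty-two second-order recursive (IIR) band-pass filters with
logarithmically spaced center frequencies from 125 to 8,000 Hz and -3 dB
crossovers at the geometric means of adjacent centers. Filtering is causal
(forward-only) on purpose: the channel-dependent phase delay mimics the
base-to-apex travel of the cochlear traveling wave, and the temporal
smearing it causes under current spread is one of the effects under study.
Zero-phase filtering would erase it.

The same designer with n = 256 supplies the characteristic-frequency grid
of the acoustic reference model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .stimuli import Waveform

__all__ = [
    "FilterbankSpec",
    "ChannelSignals",
    "FilterDesignError",
    "log_spaced_cfs",
    "design_filterbank",
    "apply_filterbank",
]


class FilterDesignError(ValueError):
    """Filterbank cannot be realized at this sample rate."""


def log_spaced_cfs(n: int, f_lo: float = 125.0, f_hi: float = 8000.0) -> np.ndarray:
    """``n`` log-spaced center frequencies, endpoints included."""
    if n < 2:
        raise ValueError("need at least two channels")
    return f_lo * (f_hi / f_lo) ** (np.arange(n) / (n - 1))


@dataclass(frozen=True)
class FilterbankSpec:
    """Designed filterbank: centers, crossovers and biquad sections.

    ``sos`` holds one second-order section per channel (scipy ``sos``
    layout). Band edges of channel i sit at cf_i / sqrt(r) and
    cf_i * sqrt(r) where r is the constant adjacent-center ratio, so the
    -3 dB points between neighboring channels coincide with the geometric
    means sqrt(cf_i * cf_{i+1}).
    """

    n_channels: int
    center_freqs: np.ndarray
    crossover_freqs: np.ndarray
    sample_rate: float
    order: int = 2
    sos: tuple = field(default=(), repr=False, compare=False)

    @property
    def center_ratio(self) -> float:
        return float(self.center_freqs[1] / self.center_freqs[0])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_channels": self.n_channels,
            "center_freqs": self.center_freqs.tolist(),
            "crossover_freqs": self.crossover_freqs.tolist(),
            "sample_rate": self.sample_rate,
            "order": self.order,
            "sos": [np.asarray(s).tolist() for s in self.sos],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FilterbankSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            n_channels=d["n_channels"],
            center_freqs=np.asarray(d["center_freqs"]),
            crossover_freqs=np.asarray(d["crossover_freqs"]),
            sample_rate=d["sample_rate"],
            order=d["order"],
            sos=tuple(np.asarray(s) for s in d["sos"]),
        )


@dataclass(frozen=True)
class ChannelSignals:
    """Per-channel signals on the input time base (filtered or envelopes)."""

    data: np.ndarray  # (n_channels, n_samples)
    spec: FilterbankSpec
    sample_rate: float
    kind: str = "filtered"  # or "envelope_hilbert" / "envelope_halfwave"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def design_filterbank(
    n_channels: int = 22,
    f_lo: float = 125.0,
    f_hi: float = 8000.0,
    sample_rate: float = 100_000.0,
) -> FilterbankSpec:
    """Design the log-spaced second-order band-pass bank.

    Each channel is a second-order (biquad) Butterworth band-pass realized
    by the bilinear transform, with -3 dB edges at the geometric crossovers.
    """
    if not (0 < f_lo < f_hi < sample_rate / 2):
        raise FilterDesignError(
            f"need 0 < f_lo < f_hi < Nyquist; got {f_lo}, {f_hi} at fs={sample_rate}"
        )
    cfs = log_spaced_cfs(n_channels, f_lo, f_hi)
    r = (f_hi / f_lo) ** (1.0 / (n_channels - 1))
    sqrt_r = np.sqrt(r)
    hi_edge = cfs[-1] * sqrt_r
    if hi_edge >= sample_rate / 2:
        raise FilterDesignError(
            f"top band edge {hi_edge:.0f} Hz reaches Nyquist {sample_rate / 2:.0f} Hz"
        )
    crossovers = np.sqrt(cfs[:-1] * cfs[1:])
    sos = tuple(
        signal.butter(
            1, [cf / sqrt_r, cf * sqrt_r], btype="bandpass", fs=sample_rate,
            output="sos",
        )
        for cf in cfs
    )
    return FilterbankSpec(
        n_channels=n_channels,
        center_freqs=cfs,
        crossover_freqs=crossovers,
        sample_rate=sample_rate,
        order=2,
        sos=sos,
    )


def apply_filterbank(w: Waveform, spec: FilterbankSpec) -> ChannelSignals:
    """Causal forward filtering of a waveform through every channel."""
    if w.sample_rate != spec.sample_rate:
        raise ValueError(
            f"filterbank designed for fs={spec.sample_rate}, waveform has "
            f"fs={w.sample_rate}"
        )
    x = np.asarray(w.samples, dtype=float)
    data = np.stack([signal.sosfilt(s, x) for s in spec.sos])
    return ChannelSignals(data=data, spec=spec, sample_rate=spec.sample_rate)
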