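"""Tone synthesis.

Probe stimuli are short pure tones and harmonic complex tones. Both are
built from sinusoids in sine phase with no onset or offset ramp — the
abrupt onset is a deliberately retained feature, since hyper-synchronized
onset responses of electrically stimulated fibers are part of what the
downstream analyses look at.

Two calibration conventions are supported:

* ``electric_peak1`` — the waveform is scaled so its absolute peak is
  exactly 1; the implant-processing chain is driven with peak-normalized
  input.
* ``acoustic_dbspl`` — samples are in pascals, scaled so the RMS of the
  summed signal corresponds to the stated sound pressure level re 20 µPa
  (the level convention is per-signal, not per-component).

Complex tones contain every integer harmonic of the fundamental strictly
below 10 kHz, with amplitudes falling 6 dB per octave (component amplitude
proportional to 1/k), the typical spectral slope of natural complex sounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Calibration",
    "Waveform",
    "NyquistError",
    "NoHarmonicsError",
    "make_pure_tone",
    "make_complex_tone",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_waveform_wav",
]

#: default audio sample rate (Hz): comfortably above twice the 8 kHz top
#: analysis channel, and an integer number of microseconds per sample so the
#: pulse bookkeeping of the strategies stays on a clean 1 µs grid.
DEFAULT_SAMPLE_RATE = 100_000.0

#: harmonics are included while k*f0 is strictly below this frequency (Hz)
HARMONIC_LIMIT_HZ = 10_000.0

P_REF = 20e-6  # reference pressure, Pa


class NyquistError(ValueError):
    """Requested frequency is at or above the Nyquist frequency."""


class NoHarmonicsError(ValueError):
    """No harmonic of the fundamental lies below the harmonic limit."""


class Calibration(str, Enum):
    ACOUSTIC_DBSPL = "acoustic_dbspl"
    ELECTRIC_PEAK1 = "electric_peak1"


@dataclass(frozen=True)
class Waveform:
    """A sampled, calibrated signal.

    ``level_db`` is meaningful only for acoustic calibration (dB SPL re
    20 µPa RMS of the summed signal); ``freq_or_f0`` records the tone
    frequency or fundamental used to synthesize the signal.
    """

    samples: np.ndarray
    sample_rate: float
    calibration: Calibration
    freq_or_f0: float
    level_db: float | None = None
    label: str = field(default="", compare=False)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def _calibrate(x: np.ndarray, calibration: Calibration, level_db: float) -> np.ndarray:
    if calibration is Calibration.ELECTRIC_PEAK1:
        peak = np.max(np.abs(x))
        if peak == 0:
            raise ValueError("cannot peak-normalize an all-zero signal")
        return x / peak
    rms = np.sqrt(np.mean(x**2))
    target = P_REF * 10.0 ** (level_db / 20.0)
    return x * (target / rms)


def make_pure_tone(
    freq: float,
    duration: float = 0.030,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    calibration: Calibration = Calibration.ELECTRIC_PEAK1,
    level_db: float = 65.0,
) -> Waveform:
    """Sine-phase pure tone, no ramps.

    Raises :class:`NyquistError` if ``freq`` is not inside (0, Nyquist).
    """
    if not 0.0 < freq < sample_rate / 2.0:
        raise NyquistError(
            f"tone frequency {freq} Hz outside (0, {sample_rate / 2} Hz)"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = round(duration * sample_rate)
    t = np.arange(n) / sample_rate
    x = np.sin(2.0 * np.pi * freq * t)
    return Waveform(
        samples=_calibrate(x, calibration, level_db),
        sample_rate=sample_rate,
        calibration=calibration,
        freq_or_f0=freq,
        level_db=level_db if calibration is Calibration.ACOUSTIC_DBSPL else None,
        label=f"pure_{freq:g}Hz",
    )


def harmonic_count(f0: float) -> int:
    """Number of integer harmonics of ``f0`` strictly below 10 kHz."""
    k = int(np.ceil(HARMONIC_LIMIT_HZ / f0)) - 1
    if (k + 1) * f0 < HARMONIC_LIMIT_HZ:  # guard against float edge cases
        k += 1
    while k >= 1 and k * f0 >= HARMONIC_LIMIT_HZ:
        k -= 1
    return max(k, 0)


def make_complex_tone(
    f0: float,
    duration: float = 0.030,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    calibration: Calibration = Calibration.ELECTRIC_PEAK1,
    level_db: float = 65.0,
) -> Waveform:
    """Harmonic complex: sine-phase components k*f0 < 10 kHz, amplitude 1/k.

    The 1/k amplitude law is the -6 dB/octave spectral slope (amplitude
    halves per frequency doubling). Calibration is applied to the summed
    signal. Raises :class:`NoHarmonicsError` when even the fundamental would
    lie at or above 10 kHz.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_harm = harmonic_count(f0)
    if n_harm < 1:
        raise NoHarmonicsError(f"f0={f0} Hz leaves no component below 10 kHz")
    n = round(duration * sample_rate)
    t = np.arange(n) / sample_rate
    k = np.arange(1, n_harm + 1)
    # (n_harm, n) outer product kept modest: n_harm <= 181 for f0 >= 55 Hz
    x = np.sum(np.sin(2.0 * np.pi * np.outer(k * f0, t)) / k[:, None], axis=0)
    return Waveform(
        samples=_calibrate(x, calibration, level_db),
        sample_rate=sample_rate,
        calibration=calibration,
        freq_or_f0=f0,
        level_db=level_db if calibration is Calibration.ACOUSTIC_DBSPL else None,
        label=f"complex_f0_{f0:g}Hz",
    )


# ---------------------------------------------------------------------------
# convenience I/O: single-column CSV + JSON sidecar, and float WAV


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, w.samples, fmt="%.10g", header="sample", comments="")
    sidecar = {
        "sample_rate": w.sample_rate,
        "calibration": w.calibration.value,
        "freq_or_f0": w.freq_or_f0,
        "level_db": w.level_db,
        "label": w.label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_waveform_csv(path: str | Path) -> Waveform:
    path = Path(path)
    samples = np.loadtxt(path, skiprows=1, ndmin=1)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Waveform(
        samples=samples,
        sample_rate=float(meta["sample_rate"]),
        calibration=Calibration(meta["calibration"]),
        freq_or_f0=float(meta["freq_or_f0"]),
        level_db=meta.get("level_db"),
        label=meta.get("label", ""),
    )


def write_waveform_wav(w: Waveform, path: str | Path) -> None:
    from scipy.io import wavfile

    wavfile.write(str(path), int(round(w.sample_rate)), w.samples.astype(np.float32))


def rescale(w: Waveform, calibration: Calibration, level_db: float = 65.0) -> Waveform:
    """Re-express a waveform under the other calibration convention."""
    return replace(
        w,
        samples=_calibrate(np.asarray(w.samples, float), calibration, level_db),
        calibration=calibration,
        level_db=level_db if calibration is Calibration.ACOUSTIC_DBSPL else None,
    )
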