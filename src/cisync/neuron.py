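"""Stochastic point-process model of electrically stimulated nerve fibers.

Each fiber is described by a handful of single-fiber statistics from the
electrical-stimulation literature: a threshold current theta, a relative
spread RS (the coefficient of variation of the stochastic threshold, which
sets the slope of the firing-probability curve), spike-time jitter, a
chronaxie that sets the membrane's temporal-integration scale, and absolute
plus relative refractory periods.

Candidate events are pulse arrivals. The cascade per candidate pulse:

1. leaky integration of effective current with time constant
   tau = chronaxie / ln 2, so closely spaced pulses summate;
2. firing probability Phi((I - theta_eff) / (RS * theta)) with Phi the
   standard normal integral — a pulse exactly at threshold fires with
   probability one half;
3. theta_eff is theta times a refractory factor: infinite within the
   absolute refractory period of the last spike, then an elevation decaying
   as 1 + exp(-dt / tau_rel);
4. an emitted spike is the event time plus Gaussian jitter; after sorting,
   jittered times are forward-clipped so consecutive spikes always remain
   at least the absolute refractory period apart. The integrator resets on
   a spike.

Every fiber owns an independent RNG stream derived from the master seed and
its (position, threshold) grid indices, so growing the population never
reshuffles existing fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .current_spread import FieldTrace, FieldTraceSet

__all__ = [
    "FiberParams",
    "SpikeRaster",
    "CalibrationError",
    "default_threshold_grid",
    "simulate_fiber",
    "simulate_population",
    "calibrate_level",
]


class CalibrationError(RuntimeError):
    """Target firing rate unreachable within the amplitude bounds."""


@dataclass(frozen=True)
class FiberParams:
    """Single-fiber statistics (cat-fiber literature values by default)."""

    threshold_ma: float = 0.3
    relative_spread: float = 0.06
    jitter_sd_us: float = 85.0
    chronaxie_us: float = 276.0
    abs_refractory_us: float = 332.0
    rel_refractory_tau_us: float = 411.0

    def __post_init__(self):
        if self.threshold_ma <= 0 or self.relative_spread <= 0:
            raise ValueError("threshold and relative spread must be positive")
        for name in ("chronaxie_us", "abs_refractory_us", "rel_refractory_tau_us"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.jitter_sd_us < 0:
            raise ValueError("jitter_sd_us cannot be negative")

    @property
    def tau_integration_us(self) -> float:
        """Leaky-integrator time constant derived from the chronaxie."""
        return self.chronaxie_us / np.log(2.0)


def default_threshold_grid() -> np.ndarray:
    """Thresholds 0.1 to 0.8 mA in 0.05 mA increments (15 values)."""
    return np.round(np.arange(0.1, 0.8 + 1e-9, 0.05), 3)


@dataclass(frozen=True)
class SpikeRaster:
    """Population spike trains with a per-fiber attribute table.

    ``fiber_table`` carries one row per fiber (columns such as
    ``position_mm`` and ``threshold_mA``, or ``cf_hz`` and ``rep`` for the
    acoustic reference); ``spikes[i]`` holds fiber i's spike times in
    seconds.
    """

    fiber_table: pd.DataFrame
    spikes: list
    duration_s: float
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def n_fibers(self) -> int:
        return len(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))

    def mean_rate(self) -> float:
        """Population mean firing rate (spikes/s per fiber)."""
        return self.n_spikes / self.n_fibers / self.duration_s

    def fiber_rates(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes]) / self.duration_s

    def pooled(self) -> np.ndarray:
        """All spike times pooled across fibers, sorted (seconds)."""
        if not self.spikes:
            return np.array([])
        return np.sort(np.concatenate([np.asarray(s) for s in self.spikes]))

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for i, s in enumerate(self.spikes):
            rec = self.fiber_table.iloc[i].to_dict()
            for t in s:
                rows.append({"fiber_id": i, **rec, "spike_time_s": t})
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# vectorized core: loops over pulses, vectorizes over fibers


def _run_population(
    times_us: np.ndarray,
    eff_amp_ma: np.ndarray,  # (n_pulses, n_fibers)
    thresholds_ma: np.ndarray,  # (n_fibers,)
    params: FiberParams,
    uniforms: np.ndarray,  # (n_pulses, n_fibers)
    normals: np.ndarray,  # (n_pulses, n_fibers)
    scale: float = 1.0,
) -> list:
    n_p, n_f = eff_amp_ma.shape
    theta = np.asarray(thresholds_ma, float)
    tau = params.tau_integration_us
    t_abs = params.abs_refractory_us
    t_rel = params.rel_refractory_tau_us
    rs_theta = params.relative_spread * theta
    integ = np.zeros(n_f)
    last_spike = np.full(n_f, -np.inf)
    raw: list = [[] for _ in range(n_f)]
    t_prev = times_us[0] if n_p else 0.0
    for j in range(n_p):
        t = times_us[j]
        integ *= np.exp(-(t - t_prev) / tau)
        t_prev = t
        integ += scale * eff_amp_ma[j]
        dt = t - last_spike
        refractory = dt < t_abs
        factor = 1.0 + np.exp(-dt / t_rel)
        p = ndtr((integ - theta * factor) / rs_theta)
        p[refractory] = 0.0
        fired = uniforms[j] < p
        if fired.any():
            idx = np.flatnonzero(fired)
            jit = params.jitter_sd_us * normals[j, idx]
            for i, g in zip(idx, jit):
                raw[i].append(t + g)
            last_spike[idx] = t
            integ[idx] = 0.0
    out = []
    for train in raw:
        s = np.maximum(np.sort(np.array(train, float)), 0.0)
        # enforce the hard refractory floor on emitted (jittered) times
        for i in range(1, len(s)):
            if s[i] - s[i - 1] < t_abs:
                s[i] = s[i - 1] + t_abs
        out.append(s * 1e-6)  # -> seconds
    return out


def _fiber_streams(
    master_seed: int, keys: list, n_pulses: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fiber uniform and normal draws from independent seeded streams."""
    n_f = len(keys)
    U = np.empty((n_pulses, n_f))
    G = np.empty((n_pulses, n_f))
    for i, key in enumerate(keys):
        rng = np.random.default_rng([int(master_seed)] + [int(k) for k in key])
        U[:, i] = rng.random(n_pulses)
        G[:, i] = rng.standard_normal(n_pulses)
    return U, G


def simulate_fiber(
    trace: FieldTrace,
    params: FiberParams,
    seed: int = 0,
    scale: float = 1.0,
) -> np.ndarray:
    """Spike times (s) of a single fiber driven by a field trace."""
    t = np.asarray(trace.pulse_times_us, float)
    amp = np.asarray(trace.pulse_amplitudes_ma, float)[:, None]
    U, G = _fiber_streams(seed, [(0, 0)], len(t))
    out = _run_population(
        t, amp, np.array([params.threshold_ma]), params, U, G, scale=scale
    )
    return out[0]


def simulate_population(
    traces: FieldTraceSet,
    thresholds_ma: np.ndarray | None = None,
    master_seed: int = 0,
    params: FiberParams = FiberParams(),
    scale: float = 1.0,
    stream_offset: int = 0,
) -> SpikeRaster:
    """One fiber per (neural position, threshold) pair.

    ``stream_offset`` shifts every fiber's RNG stream id; it is how repeated
    iterations of the same stimulus obtain fresh, reproducible noise.
    """
    if thresholds_ma is None:
        thresholds_ma = default_threshold_grid()
    thresholds_ma = np.asarray(thresholds_ma, float)
    if thresholds_ma.size == 0:
        raise ValueError("threshold grid must be non-empty")
    n_x = traces.n_positions
    n_t = len(thresholds_ma)
    # fiber order: position-major within each threshold
    pos_idx = np.tile(np.arange(n_x), n_t)
    thr_idx = np.repeat(np.arange(n_t), n_x)
    theta = thresholds_ma[thr_idx]
    eff = traces.eff_amplitudes_ma[:, pos_idx]
    keys = [(int(p), int(q), int(stream_offset)) for p, q in zip(pos_idx, thr_idx)]
    U, G = _fiber_streams(master_seed, keys, traces.n_pulses)
    spikes = _run_population(
        traces.pulse_times_us, eff, theta, params, U, G, scale=scale
    )
    table = pd.DataFrame(
        {
            "position_mm": traces.positions_mm[pos_idx],
            "threshold_mA": theta,
        }
    )
    return SpikeRaster(
        fiber_table=table,
        spikes=spikes,
        duration_s=traces.duration_us * 1e-6,
        meta={
            "master_seed": master_seed,
            "stream_offset": stream_offset,
            "scale": scale,
            **traces.meta,
        },
    )


def calibrate_level(
    traces: FieldTraceSet,
    target_rate: float = 100.0,
    thresholds_ma: np.ndarray | None = None,
    master_seed: int = 0,
    params: FiberParams = FiberParams(),
    rel_tol: float = 0.10,
    bounds: tuple[float, float] = (1e-3, 1e3),
    max_iter: int = 60,
) -> float:
    """Bisect a global amplitude scale to a mean population firing rate.

    Returns the scale at which the population mean rate is within
    ``rel_tol`` of ``target_rate`` (spikes/s per fiber). Deterministic for
    a given master seed: every evaluation reuses the same noise streams.
    Raises :class:`CalibrationError` when the target cannot be bracketed.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")

    def rate_at(s: float) -> float:
        r = simulate_population(
            traces, thresholds_ma, master_seed, params, scale=s
        )
        return r.mean_rate()

    lo, hi = bounds
    if rate_at(hi) < target_rate:
        raise CalibrationError(
            f"target {target_rate}/s unreachable below scale {hi}"
        )
    if rate_at(lo) > target_rate:
        raise CalibrationError(
            f"rate already above target {target_rate}/s at scale {lo}"
        )
    mid = np.sqrt(lo * hi)
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        r = rate_at(mid)
        if abs(r - target_rate) <= rel_tol * target_rate:
            return mid
        if r > target_rate:
            hi = mid
        else:
            lo = mid
    raise CalibrationError(
        f"bisection did not converge to {target_rate}/s (last scale {mid})"
    )
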