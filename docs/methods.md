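# Methods

This note records the models implemented in `cisync`, the parameters that
matter, the numerical choices that were genuinely open, and what the
synthetic stimuli and simplified stages do and do not establish.

## Stimuli

Pure tones are sine-phase sinusoids; complex tones sum sine-phase integer
harmonics `k·f0 < 10 kHz` with amplitudes `1/k` (−6 dB/octave, the typical
slope of natural complex sounds). Tones are 30 ms by default and carry **no
onset/offset ramp**: abrupt onsets are part of what the downstream analyses
probe (onset hyper-synchronization, alternating-cycle locking), so ramping
them away would remove the phenomenon. Two calibrations: peak = 1 for
implant processing, and dB SPL re 20 µPa applied to the RMS of the summed
signal (not per component) for the acoustic model. Default sample rate
100 kHz — above twice the top 8 kHz channel and an integer number of
microseconds per sample, so pulse bookkeeping stays on a clean 1 µs grid.

## Filterbank

Twenty-two second-order recursive band-pass filters (one biquad each),
centers log-spaced 125–8,000 Hz (adjacent ratio 64^(1/21) ≈ 1.219), −3 dB
edges at the geometric means of adjacent centers. The digital design is a
bilinear-transform Butterworth band-pass — the flat-passband family with
the standard −3 dB edge definition; the design method was an open choice
and bilinear was preferred over matched-z for its exact edge placement.
Filtering is **causal only**. The resulting group delay decreases with
center frequency, a traveling-wave-like dispersion; this phase delay is
deliberately retained because the loss of synchrony under current spread
is driven by neighboring channels being mixed *out of phase*. Zero-phase
filtering would erase the effect being studied.

## Strategies

All pulses are charge-balanced biphasic, cathodic-first, 25 µs phases with
an 8 µs gap (58 µs footprint), on a 1 µs time grid.

* **CIS / HDCIS** share an interleaved carrier: slots tick at the total
  rate (90,000 pps default), frames visit all 22 channels in a fixed
  apex-to-base rotation, so each channel sees total/22 ≈ 4,090.9 pps. The
  pulse amplitude is the channel envelope sampled at pulse onset. CIS uses
  the Hilbert magnitude (fine structure removed); HDCIS uses the half-wave
  rectified channel signal. The carrier raises an error if a frame cannot
  fit one biphasic footprint. CIS envelopes are the raw Hilbert magnitude —
  whether a further envelope low-pass was used upstream is unknowable from
  the description emulated here, and the raw magnitude is the more
  conservative (least fine-structure-destroying) choice.
* **PDT** emits one pulse per strict positive local maximum of the
  filtered signal (plateaus contribute their first sample), amplitude
  equal to the peak value — the alternative (a separately derived envelope
  value) was rejected as adding a free parameter with no observable
  consequence at these stimuli. Cross-channel collisions on the same
  microsecond delay the later-detected pulse by one 58 µs footprint;
  at 500 Hz this shifts phase by <0.011 cycles and is negligible for VS.
* **HD-ACE** selects, per frame, the n channels with the largest envelope
  value at frame start (ties to the lower channel index); each selected
  electrode fires once per frame, so per-electrode rate = total/n. With
  n = 22 the pulse set is identical to the plain carrier.

## Current spread

Point electrodes on a straight line parallel to the fiber axis, 0.75 mm
pitch, 1 mm from the nerve; the most basal (highest-CF) electrode sits
perpendicular to the 0 mm neural position and the array spans 15.75 mm.
Electrode e contributes to position x with inverse-law weight
`z/√(z² + (x−x_e)²)` (unit weight directly opposite), and contributions
superpose linearly. The summed per-pulse effective currents are rescaled
once per stimulus so the global peak is 1 mA. The normalization is defined
on the per-pulse effective-current matrix rather than on a densely
rendered waveform: the neural stage consumes pulse events, and this keeps
drive and normalization consistent (a dense biphasic rendering is
available for export). Voltage-vs-current units are deliberately collapsed
into one effective-current unit (mA); the distinction has no observable
consequence in a linear spread model with a global normalization.

## Point-process fibers

Each fiber: threshold θ (grid 0.1–0.8 mA, 0.05 mA steps by default; the
figure-style experiments override to 0.1 mA steps), relative spread
RS = 0.06, jitter SD 85 µs, chronaxie 276 µs, absolute refractory period
332 µs, relative-refractory time constant 411 µs — standard cat-fiber
statistics from the electrical-stimulation literature, all overridable.

Candidate events are pulse arrivals (no spontaneous activity: these are
electrically driven deafened-ear fibers). Per pulse: (1) a leaky
integrator with τ = chronaxie/ln 2 ≈ 398 µs accumulates effective current,
capturing summation across closely spaced pulses; (2) firing probability
is Φ((I − θ_eff)/(RS·θ)) — a pulse at threshold fires with probability
one half, and θ(1+2RS) gives Φ(2); (3) θ_eff multiplies θ by ∞ inside the
absolute refractory period and by 1 + exp(−Δt/τ_rel) afterwards; (4) the
integrator resets after a spike (renewal assumption). Emitted spikes are
event times plus Gaussian jitter; after sorting, jittered times are
forward-clipped so consecutive spikes never violate the absolute
refractory period — jitter alone would otherwise produce sub-refractory
intervals, and the clip (sub-µs-scale shifts at these rates) preserves
both spike counts and the hard invariant that interval analyses rely on.

Each fiber draws from an independent RNG stream keyed by (master seed,
position index, threshold index, iteration), so enlarging the population
or adding iterations never reshuffles existing fibers.

Level calibration bisects a global amplitude scale (log-spaced, bounds
10⁻³–10³) until the population mean rate is within 10% of the target
(100 spikes/s for the interval experiment); every evaluation reuses the
same noise streams, so the result is deterministic given the seed.

## Acoustic reference (simplified stand-in)

The normal-hearing baseline is a deliberately simple cascade, not a
re-implementation of a full phenomenological periphery model; its printed
maxima (e.g. 0.88 at 500 Hz) are not reproduced and not claimed. Per fiber
(256 CFs log-spaced 125–8,000 Hz, the same grid designer as the
filterbank): two cascaded constant-Q biquads (Q = 4; the steeper composite
skirts are what lets a fiber centered on harmonic k reject its
double-amplitude neighbor k−1); a static compressive gain
`ref/(rms + floor)` with ref = 0.035 Pa (the RMS of a 65 dB SPL tone) and
floor = 0.0035 Pa, standing in for cochlear compressive amplification —
weakly driven fibers between resolved harmonics are amplified into their
operating range while silence stays silent; half-wave rectification
followed by a cubic expansion (the transduction sharpening that makes
locked spikes bunch near the cycle crest, VS ≈ 9π/32 ≈ 0.88 in the linear
regime); a second-order low-pass at 2.5 kHz producing the phase-locking
roll-off across the 2–4 kHz band and VS < 0.2 above 6 kHz (2.5 kHz rather
than a 3 kHz first guess: with the cutoff at 3 kHz the deterministic
rate-modulation analysis puts VS at 6.3 kHz just above 0.2); subtractive
short-term adaptation (60% of a 50 ms exponential average); a Hill-type
saturating map to Poisson intensity (spont 5/s, peak 300/s, half
saturation 0.02 Pa-equivalent); Bernoulli thinning at the sample rate with
a 700 µs dead time.

What this stand-in shows: the *qualitative* acoustic signatures the
electric comparison needs — strong low-frequency phase locking, high-
frequency desynchronization, spontaneous firing in silence, and the
fluctuation-profile contrast for complex tones. What it does not show:
absolute rates and synchrony maxima of real fibers, level dependence of
tuning, two-tone suppression, or synaptic adaptation dynamics; passing
tests here say nothing about those.

## Metrics and estimator choices

`vs_spikes` and `vs_pulses` implement the plain and charge-weighted vector
strength; an empty train or zero total charge raises a distinct error
rather than returning 0 (an absent response is not a desynchronized one).
The charge-weighted VS is a normalized DTFT of the pulse train, so finite
rectangular observation windows leak the carrier line and the DC term into
nearby analysis frequencies — with a 30 ms window and a 4,090.9 pps
per-channel carrier the leakage reaches ~0.09 near 4 kHz, which would
masquerade as synchrony where there is none. The **sweep drivers**
therefore apply a Hann taper over the stimulus window to pulse-pattern and
field-stage estimates; single-frequency reported values and spike-train VS
are untapered. VS is computed over the full stimulus (no onset exclusion)
by default, with an optional onset-skip for sensitivity analyses.

The population summary is the maximum per-fiber VS ("max across fibers"),
with a pooled-phasor mode available; per-fiber-then-max is the primary
reading of the summary statistic used throughout. Because the max over
many noisy estimates is biased upward at small spike counts, population
summaries in the tests gate fibers on a minimum pooled spike count.

ISI histograms: first order = consecutive differences, all order = all
ordered pairs within a 20 ms window, 100 µs bins. The comb metric compares
the peak near each multiple of the analysis period with the mean count at
the adjacent half-period offsets; a 500 µs boxcar smoothing is applied
first when the question is tone-scale periodicity, because the raw
histograms of carrier-driven strategies carry a 244 µs carrier-locked
microstructure that is real but irrelevant at the 2 ms scale.

Excitation profiles: fraction of total charge per electrode (sums to 1)
or mean firing rate per fiber. "Maximally excited channel" means greatest
total delivered charge (pulse domain) or highest mean rate (spike domain).

## Experiments and problem sizes

* **Sweeps**: 73 semitone frequencies 125–8,000 Hz (pure), 61 fundamentals
  55–1,760 Hz, A1–A6 (complex); per frequency and strategy the three-stage
  VS chain. Default neural population for stage analyses: positions −2 to
  18 mm in 0.1 mm steps, eight thresholds (0.1 mA steps).
* **Interval experiment**: 100 ms 500 Hz tone, strategy output restricted
  to its max-charge electrode (the single-electrode configuration of the
  neural-response analyses), 201 positions within ±10 mm, thresholds
  0.1–0.8 by 0.1, drive calibrated to 100 spikes/s, 100 presentations
  pooled (interval counts far exceed the 10⁴ floor).
* **Rate study**: HD-ACE at (90,000 pps, 8), (14,400, 6), (3,500, 4);
  five cycles of a 500 Hz pure and a 220 Hz complex tone; fibers 0–30 mm
  in 0.1 mm steps. Complex-tone population VS at F0 falls monotonically
  across the three conditions. For the pure tone the middle condition
  consistently edges out the highest rate by ~0.03 (sparser per-electrode
  sampling concentrates charge nearer envelope peaks); the clear contrast
  is between the high-rate and legacy conditions, and that is what the
  tests assert.

All experiment outputs carry the configuration hash and master seed.
Simulation sizes in the shipped tests and examples (iteration counts,
grid steps, repetition counts) are chosen so the full suite runs on a
single CPU in a couple of minutes while keeping every estimate far from
its decision boundary.

## Known limitations

Loudness mapping/compression to clinical current units is not modeled
(charge is used directly as the spiking-probability proxy); zero-crossing
triggered strategies are out of scope; the spread model has no tissue
anisotropy or longitudinal current paths; the point process has no
spontaneous or electrophonic activity and its relative-refractory form is
a two-parameter phenomenological elevation; the acoustic stand-in is
qualitative as described above.
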