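# Methods

This document records the scientific conventions and numerical choices
behind `b63osc`, and the measured performance of each estimator on
synthetic recordings with exact ground truth.

## 1. Signal model

A synthetic cell is a sum of five components, sampled at 100 Hz by default:

**Slow oscillation.** Cycle `k` of period `P` contributes
`v_osc(t) = A_k (1 − cos 2πt/P)` starting from the resting potential, so
troughs sit at rest and crests at `rest + 2 A_k`; the peak-to-peak swing of
a cycle is twice its amplitude parameter. Cycle amplitudes `A_k` are drawn
i.i.d. from a gamma distribution (mean `slow_amp_mean`, coefficient of
variation `slow_amp_cv`), which reproduces the irregular, occasionally
near-flat cycles of real recordings. The amplitude scales with the
electrochemical driving force: holding the cell at `V_hold` multiplies all
amplitudes by `(E_rev − V_hold)/(E_rev − V_rest)` while leaving the period
untouched, because the oscillatory mechanism itself is voltage-insensitive.
A cell held at or above the spike threshold is in depolarization block and
fires nothing.

**Plateau potentials.** When a cycle crest would cross the plateau
threshold (−48 mV by default), a logistic gate (width
`plateau_gate_softness_mv`) decides whether the cycle regenerates. A firing
cycle triggers on its rising phase, at the exact moment the carrier crosses
threshold (`φ = arccos(1 − (θ_p − b)/A_k)`), and produces a square
depolarization of `plateau_extra_depol` (30 mV) with 5 s cosine ramps, a
lognormal duration (mean 30 s, CV 0.3, floored at 18 s), a crown of ~15 mV
spikelets at 10 Hz, and a 30 s refractory period. During a plateau the
underlying oscillation is suppressed (the trajectory is clamped to the
plateau, not superimposed on the cycle).

**Isolated spikes.** Cycles that cross the spike threshold (−52 mV) but do
not regenerate emit 1–3 large (60 mV, 20 ms) biphasic action potentials
near the crest.

**Noise.** Ornstein–Uhlenbeck membrane noise (sd 1.5 mV, correlation time
2 s), initialized from its stationary distribution.

**Pharmacology.** A suppression schedule multiplies the oscillation
amplitude by an envelope and can shift the baseline: TTX is a step to zero
after a 60 s perfusion dead time; calcium-free saline decays exponentially
(τ = 240 s); CPA and FCCP decline sigmoidally (width 60 s), CPA with a
reversible +2 mV depolarization and FCCP with an irreversible +15 mV one;
intracellular heparin silences the injected B63 but not the homologue B31.
The *longevity* of the oscillation is the time from perfusion onset until
the envelope first falls below 5%; it is analytic for every schedule, so
the ordering "calcium-free outlives TTX" holds for every seed by
construction and is also verified empirically on post-application windows.

All randomness derives from `numpy` `SeedSequence` streams spawned per
cell and per component (amplitudes, gating, durations, spikes, noise), so
traces are bit-reproducible, cohorts are order-independent, and a coupled
partner can share the leader's amplitude sequence (attenuated by the
coupling coefficient, delayed by the propagation latency) while keeping
independent noise.

## 2. Conditioning

Spectral and wavelet analysis operate on a conditioned copy: a centered
boxcar of half-width 0.5 s (edges handled by window truncation, which
preserves constants exactly), then integer decimation to 1 Hz. Event
detection operates on the raw 100 Hz trace. Spike removal for phase-plane
work uses a 1 s running median followed by a zero-phase 4th-order
Butterworth low-pass.

## 3. Spectral analysis

The periodogram of a 1 Hz excerpt is the one-sided PSD of the mean-removed
signal, zero-padded eightfold to localize peaks beyond the native Rayleigh
resolution, restricted to the 8–512 s period band. The integral of the
full spectrum must equal the signal variance to within 1% (checked at
construction; Parseval's theorem).

Dominant periods are local maxima ranked by density, subject to: a noise
floor of 16× the band median density, a dominance floor of 4.5% of the
strongest candidate, and harmonic exclusion — a candidate within 10% of
`P/k` (k = 2..4) of an already retained, stronger peak is flagged as its
harmonic *only if* it carries less than half the parent's density, so a
genuine second component of comparable power is never discarded. The "peak
density" of the strongest retained peak is the oscillation-amplitude
metric; when nothing clears the floor the result is `None` (absence is a
decidable outcome, used for non-coupled control cells and post-drug
traces), never zero.

When measuring the oscillation period of a trace containing plateaus, the
detected plateau intervals are first replaced by linear bridges
(`mask_plateaus`, 3 s padding). The plateau train is itself quasi-periodic
(it fires on a subset of oscillation crests), and in short records its
square-wave power and harmonics otherwise shadow the oscillation line; on
600 s synthetic cohorts masking removes a bias of several seconds and
leaves the period estimate accurate to ~0.1 s on average.

## 4. Wavelet analysis

The continuous wavelet transform uses the analytic Morlet wavelet
(ω₀ = 6, Fourier factor 4π/(ω₀+√(2+ω₀²)) ≈ 1.033), computed in the FFT
domain on a 32-voice logarithmic period grid spanning 8–512 s, with a
cone of influence at √2·scale from each record edge. Band-limited
waveforms are recovered by the standard delta-function reconstruction
(C_δ = 0.776) summed over periods within ±25% of the center period;
reconstruction of a pure sinusoid correlates with the original at
r > 0.999, and the 61 s and 144 s components of a two-period mixture are
recovered essentially independently. The implementation is cross-checked
in the test suite against PyWavelets' complex Morlet phases.

The phase latency between two cells at a reference period is the circular
mean of the cross-wavelet phase angle `arg(W_a · conj(W_b))` over samples
inside both cones, converted to seconds and wrapped to ±half a period;
positive latency means the partner lags. The estimator is antisymmetric
under exchanging the two traces by construction. On coupled synthetic
pairs whose partner signal-to-noise ratio is ≥ 10, recovered latencies of
0–5 s are accurate to better than 0.5 s (worst case 0.42 s over 200
runs); at low partner SNR (strong attenuation, full noise) errors grow to
the order of 1 s.

## 5. Event detection

**Spikes** are peaks of the residual after a 1 s running median, at least
20 mV high (above the ~15 mV plateau spikelets) and 50 ms apart.

**Plateaus** are runs where a despiked copy exceeds a slow baseline — a
5-minute centered rolling median — by more than 15 mV for at least 10 s
(sub-2 s gaps bridged). Each event's extra depolarization is the median
elevation over its core; boundaries are then refined outward to the
half-height crossings, with the walk capped at 6 s so an abutting
depolarized cycle cannot drag a boundary. Records shorter than the
baseline window are flagged and analyzed against their global median.
Because the oscillation itself lifts the running median a few millivolts
above rest, a generator plateau of 30 mV above rest reads as roughly
23 mV above the *running baseline*; the detector's median extra
depolarization over default recordings is ~23 mV, inside the
physiological 20–30 mV range. Matched against ground truth onsets within
±2 s over 50 default recordings, the detector achieves precision 0.96 and
recall 0.98; the residual false positives are giant subthreshold cycles
during the post-plateau refractory period, and the missed events are
plateaus clipped by record edges.

**Cycle classification** delimits cycles at the troughs of the
band-reconstructed oscillation and labels each as `plateau` (contains a
plateau onset), `spiking` (contains an isolated spike), or
`subthreshold`. A plateau onset on the falling phase of its cycle is
reported as an anomaly rather than silently accepted.

## 6. Phase-plane analysis and the plateau threshold

Phase-plane trajectories (V vs dV/dt) are computed on a despiked 10 Hz
copy, cut at cycle boundaries. Two kinds of non-plateau cycles are
excluded: cycles overlapped by a plateau that began earlier (their
elevated voltages belong to the plateau's trajectory), and cycles starting
within 30 s of a plateau offset (the cell is refractory, so even large
crests fail to regenerate and would misrepresent resting excitability).

The bifurcation threshold separates the maximal voltages of cycles that
spiral back without regenerating (subthreshold and isolated-spike cycles)
from the voltage at which plateau trajectories leave the slow manifold —
the "foot" of the regenerative upstroke, found by walking back from the
steepest point of dV/dt to where the slope falls below 40% of its peak
(walk capped at 4 s). The estimate is the midpoint of the two brackets.
On 1200 s synthetic recordings with a true threshold of −48 mV the
median estimate over 50 seeds is −48.3 mV, with 94% of per-recording
estimates inside [−51, −45] mV; the rare outliers trace to the ~2% of
plateaus the detector misses.

## 7. Exact statistics

The sample sizes in this kind of experiment (6–12 cells) make asymptotic
p-values unreliable, so both tests are exact enumerations of their null
distributions. The Wilcoxon signed-rank distribution is built by dynamic
programming over doubled ranks (mid-ranks of tied magnitudes stay
integral), covering all `2^n` sign assignments; zero differences are
dropped and counted, and an all-zero sample returns `None` rather than a
meaningless p. The Mann–Whitney null distribution is the Gaussian-binomial
partition count for tie-free data, and a direct enumeration of group
assignments when ties are present. Both report two-tailed p-values as
`min(1, 2·min(P≤, P≥))`. The implementations are verified in the test
suite against full brute-force enumeration for every n ≤ 12 and against
scipy's exact modes. With all n differences of one sign the signed-rank
p is `2/2^n` — e.g. 0.031 at n = 6, 0.0039 at n = 9, 0.0005 at n = 12 —
and seven-of-eight concordant values with the discordant one smallest give
V = 35, p = 0.016; two groups of six with U = 3 give p = 14/924 ≈ 0.015.

## 8. Presets and calibration

The named presets are study conditions, not tuning knobs. Two generator
constants were calibrated once, before any test was written, so that
*emergent* statistics land in the intended regimes: the control
oscillation amplitude (`slow_amp_mean = 6.35`) sets the plateau recurrence
of the default cell near 148 s, and the low-calcium/cobalt amplitude
(5.6) sets its slower carrier's recurrence near 270 s. The `DUAL_PERIOD`
exemplar is fully deterministic (no noise, no amplitude or duration
dispersion, plateaus locked to the crests of its 144 s amplitude
modulation): its spectrum is identical for every seed, with retained
dominant periods 61.0 s and 143.3 s and the 106 s intermodulation tone
(1/(1/61 − 1/144)) correctly ranked below both.

## 9. Validation summary

All quantitative claims above are enforced by the test suite
(`tests/test_acceptance.py` end-to-end, the other files per module) and
regenerated by `scripts/acceptance.py`: dominant-period recovery within
2% on the exemplar; cohort mean period within 5 s over 26 cells; the five
exact p-values; plateau precision/recall ≥ 0.95 with median extra
depolarization in 20–30 mV over 50 seeds; Parseval within 1%; harmonic
exclusion on sawtooth input; latency antisymmetry and ±0.5 s recovery at
SNR ≥ 10; driving-force amplitude scaling with unchanged period;
calcium-free longevity exceeding TTX longevity on every seed; and exact
tests matching brute-force enumeration for all n ≤ 12.
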