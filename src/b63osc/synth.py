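"""Synthetic intracellular voltage traces with a known ground truth.

The generator is deliberately phenomenological.  The target dynamics -- a
pacemaker interneuron whose membrane potential rides a strictly periodic
slow depolarizing oscillation (period on the order of a minute) of randomly
varying cycle amplitude, from which all-or-none plateau potentials and spike
bursts sporadically arise -- are reproduced with few parameters rather than
with a conductance-based membrane model:

* carrier: a fixed-period raised cosine, ``A_k (1 - cos(2 pi t / P))``
  above the resting potential -- a sinusoid of amplitude ``A_k`` whose
  troughs sit at rest, so every cycle is a depolarizing hump of
  peak-to-peak range ``2 A_k``;
* cycle amplitudes ``A_k``: i.i.d. gamma draws with configurable mean and
  coefficient of variation.  The mean scales with the driving force
  ``(E_rev - V_rest)``, which is what makes experimental holding-potential
  changes alter oscillation amplitude without touching its period;
* plateaus: on each cycle a Bernoulli draw with logistic probability in the
  cycle's peak-voltage overshoot of the plateau threshold decides whether a
  plateau fires; a fired plateau starts where the rising phase crosses
  threshold, adds a sustained extra depolarization with cosine rise/fall
  ramps and a high-frequency crown of low-amplitude spikes, and imposes a
  refractory period.  Because firing is probabilistic per cell, perfectly
  coupled homologous cells share their oscillation but plateau
  independently.  Plateau recurrence is therefore *emergent*: its mean
  period is the carrier period divided by the per-cycle firing probability;
* intermediate cycles that clear the spike threshold but produce no plateau
  emit 1-3 large isolated action potentials;
* additive Ornstein-Uhlenbeck (colored) membrane noise;
* pharmacology: a named schedule multiplies the oscillation by a
  time-dependent envelope and adds a baseline offset (abrupt block,
  slowly damping block, sigmoidal suppression with depolarizing drift, ...).

Every random element derives from a single seed through counter-based
``numpy`` SeedSequence spawning, so traces are bit-reproducible and cohort
members are independent of generation order.  All ground truth (cycle
onsets and amplitudes, spike times, plateau intervals, true period and
coupling latency) is returned alongside the trace.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.stats import truncnorm

from .trace import VoltageTrace

PHARMACOLOGY_PRESETS = ("TTX", "CA_FREE", "CPA", "FCCP", "HEPARIN_B63", "HEPARIN_B31")


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class PharmacologySchedule:
    """Time course of an oscillation-suppressing bath or injection.

    ``envelope(t)`` multiplies the oscillation amplitude (1 = intact,
    0 = fully suppressed); ``baseline_offset(t)`` is added to the resting
    potential (drugs that release stored calcium depolarize the cell).
    ``t_block_s`` is the perfusion dead time before any observable effect.
    """

    preset: str
    t_on_s: float
    t_block_s: float = 60.0
    tau_damp_s: float = 240.0      # slow exponential run-down (calcium-free)
    tau_sigmoid_s: float = 60.0    # width of the sigmoidal suppression (CPA/FCCP)
    baseline_shift_mv: float = 0.0
    washout_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.preset not in PHARMACOLOGY_PRESETS:
            raise ConfigError(f"unknown pharmacology preset {self.preset!r}; "
                              f"choose one of {PHARMACOLOGY_PRESETS}")

    def _decline(self, t: np.ndarray) -> np.ndarray:
        """Suppression time course ignoring washout (1 -> 0)."""
        t = np.asarray(t, dtype=float)
        t0 = self.t_on_s + self.t_block_s
        if self.preset == "TTX":
            return np.where(t < t0, 1.0, 0.0)
        if self.preset == "CA_FREE":
            return np.where(t < t0, 1.0, np.exp(-np.maximum(t - t0, 0.0) / self.tau_damp_s))
        if self.preset in ("CPA", "FCCP"):
            tc = t0 + 2.0 * self.tau_sigmoid_s
            return 1.0 / (1.0 + np.exp((t - tc) / self.tau_sigmoid_s))
        if self.preset == "HEPARIN_B63":
            # intracellular injection: suppression once the compound fills
            # the cell, cell-specific (the homologue B31 is unaffected)
            return np.where(t < t0, 1.0, 0.0)
        return np.ones_like(t)  # HEPARIN_B31: no effect

    def envelope(self, t) -> np.ndarray:
        env = self._decline(t)
        if self.washout_s is not None and self.preset != "FCCP":
            # FCCP suppression is irreversible; others recover after washout
            # with the same kinetics they declined with.
            rec = 1.0 - self._decline(np.asarray(t, float) - (self.washout_s - self.t_on_s))
            env = np.maximum(env, np.where(np.asarray(t, float) >= self.washout_s, rec, 0.0))
        return env

    def baseline_offset(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        off = self.baseline_shift_mv * (1.0 - self._decline(t))
        if (self.washout_s is not None and self.preset == "CPA"):
            off = np.where(t >= self.washout_s,
                           self.baseline_shift_mv * self._decline(t - (self.washout_s - self.t_on_s)),
                           off)
        return off

    def longevity_s(self, threshold: float = 0.05) -> float:
        """Time from perfusion onset until the envelope first drops below
        ``threshold`` of its initial value (the oscillation's longevity)."""
        if self.preset == "TTX":
            return self.t_block_s
        if self.preset == "CA_FREE":
            return self.t_block_s + self.tau_damp_s * math.log(1.0 / threshold)
        if self.preset in ("CPA", "FCCP"):
            return (self.t_block_s + 2.0 * self.tau_sigmoid_s
                    + self.tau_sigmoid_s * math.log((1.0 - threshold) / threshold))
        if self.preset == "HEPARIN_B63":
            return self.t_block_s
        return math.inf


def apply_pharmacology(config: "GeneratorConfig", preset: str,
                       t_on: float, **overrides) -> "GeneratorConfig":
    """Install a named pharmacology schedule on a generator configuration.

    Preset-specific defaults: FCCP adds a sustained +15 mV depolarization
    (irreversible), CPA a gradual +2 mV drift (reversible on washout); TTX
    suppression is a step, calcium-free saline damps slowly.
    """
    defaults = {"CPA": {"baseline_shift_mv": 2.0},
                "FCCP": {"baseline_shift_mv": 15.0}}
    kwargs = dict(defaults.get(preset, {}))
    kwargs.update(overrides)
    schedule = PharmacologySchedule(preset=preset, t_on_s=float(t_on), **kwargs)
    return dataclasses.replace(config, pharmacology=schedule)


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic cell.

    Voltages in mV, times in s, rates in Hz.  ``slow_amp_mean`` sets the mean
    per-cycle oscillation amplitude at a -60 mV resting potential; the actual
    mean scales with the driving force ``(e_rev - v_rest)`` so holding the
    cell away from rest rescales the oscillation without changing its
    period.  ``amp_mod_period_s``/``amp_mod_depth`` replace the i.i.d. gamma
    amplitudes with a deterministic slow cosine modulation (used by exemplar
    presets whose two spectral periods are exact ground truth).
    """

    duration_s: float = 600.0
    sample_rate: float = 100.0
    v_rest: float = -60.0
    fast_period_s: float = 58.0
    slow_amp_mean: float = 6.35
    slow_amp_cv: float = 0.45
    e_rev: float = -20.0
    spike_threshold: float = -52.0
    plateau_threshold: float = -48.0
    plateau_extra_depol: float = 30.0
    plateau_duration_mean_s: float = 30.0
    plateau_duration_cv: float = 0.3
    plateau_duration_min_s: float = 18.0
    plateau_refractory_s: float = 30.0
    spike_amp: float = 60.0
    spike_width_s: float = 0.02
    plateau_spike_amp: float = 15.0
    plateau_spike_rate: float = 10.0
    noise_sd: float = 1.5
    noise_tau_s: float = 2.0
    pharmacology: Optional[PharmacologySchedule] = None
    seed: int = 0
    amp_mod_period_s: Optional[float] = None
    amp_mod_depth: float = 0.0
    plateau_gate_softness_mv: float = 1.0
    plateau_ramp_s: float = 5.0

    def validate(self) -> None:
        numeric = [self.duration_s, self.sample_rate, self.v_rest, self.fast_period_s,
                   self.slow_amp_mean, self.slow_amp_cv, self.e_rev,
                   self.spike_threshold, self.plateau_threshold,
                   self.plateau_extra_depol, self.plateau_duration_mean_s,
                   self.plateau_duration_cv, self.plateau_refractory_s,
                   self.spike_amp, self.spike_width_s, self.plateau_spike_amp,
                   self.plateau_spike_rate, self.noise_sd, self.noise_tau_s]
        if not all(np.isfinite(numeric)):
            raise ConfigError("generator configuration contains non-finite parameters")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.duration_s <= 3.0 * self.fast_period_s:
            raise ConfigError(
                f"duration ({self.duration_s} s) must exceed three oscillation "
                f"cycles ({3 * self.fast_period_s:g} s)")
        if self.fast_period_s <= 0:
            raise ConfigError("fast_period_s must be positive")
        if not (self.plateau_threshold > self.spike_threshold):
            raise ConfigError("plateau_threshold must exceed spike_threshold")
        if self.e_rev <= self.v_rest:
            raise ConfigError("reversal potential must lie above the resting/holding "
                              "potential (non-positive driving force)")
        if not (0.0 < self.plateau_extra_depol < 60.0):
            raise ConfigError("plateau_extra_depol must lie in (0, 60) mV")
        for name in ("plateau_duration_mean_s", "plateau_refractory_s",
                     "spike_width_s", "plateau_ramp_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.slow_amp_cv < 0 or self.plateau_duration_cv < 0 or self.noise_sd < 0:
            raise ConfigError("dispersion parameters must be non-negative")

    @property
    def mean_amplitude_mv(self) -> float:
        """Mean per-cycle sinusoid (half-swing) amplitude after
        driving-force scaling; cycle peaks reach twice this above rest."""
        return self.slow_amp_mean * (self.e_rev - self.v_rest) / (self.e_rev + 60.0)

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class CouplingConfig:
    """How a gap-junction partner inherits the leader's oscillation."""

    coupling_coefficient: float = 0.5
    latency_s: float = 3.0
    partner_has_oscillation: bool = True
    independent_plateaus: bool = True
    label: str = "partner"

    def validate(self) -> None:
        if not (0.0 <= self.coupling_coefficient <= 1.0):
            raise ConfigError("coupling_coefficient must lie in [0, 1]")
        if self.latency_s < 0:
            raise ConfigError("latency_s must be non-negative")


@dataclass
class PlateauEvent:
    """One plateau potential: trigger/end times are ramp start/end; the
    half-height boundaries (mid-rise, mid-fall) are what a detector should
    recover for a ramped event."""

    onset_s: float
    offset_s: float
    extra_depol_mv: float
    ramp_s: float
    n_spikes: int = 0

    @property
    def half_onset_s(self) -> float:
        return self.onset_s + self.ramp_s / 2.0

    @property
    def half_offset_s(self) -> float:
        return self.offset_s - self.ramp_s / 2.0


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests."""

    fast_period_s: float
    cycle_onsets: np.ndarray
    cycle_amplitudes: np.ndarray
    spike_times: np.ndarray
    plateaus: list
    latency_s: Optional[float] = None
    cell: str = "cell"

    def __post_init__(self) -> None:
        ons = [p.onset_s for p in self.plateaus]
        offs = [p.offset_s for p in self.plateaus]
        for i in range(1, len(ons)):
            if ons[i] < offs[i - 1]:
                raise ValueError("plateau intervals must be disjoint and ordered")


def _ou_noise(rng: np.random.Generator, n: int, dt: float,
              sd: float, tau: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    e = rng.standard_normal(n) * (sd * math.sqrt(1.0 - a * a))
    e[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -a], e)


def _spike_template(fs: float, width_s: float, amp: float) -> np.ndarray:
    m = max(2, int(round(width_s * fs)))
    lobe = np.sin(np.pi * np.arange(m + 1) / m)
    return np.concatenate([amp * lobe, -0.3 * amp * lobe[1:]])


def _add_template(values: np.ndarray, template: np.ndarray, i0: int) -> None:
    lo = max(0, i0)
    hi = min(values.size, i0 + template.size)
    if hi > lo:
        values[lo:hi] += template[lo - i0: hi - i0]


def _plateau_profile(t: np.ndarray, onset: float, offset: float, ramp: float) -> np.ndarray:
    """0 -> 1 -> 0 with cosine rise/fall ramps of length ``ramp`` inside
    [onset, offset]; half-height exactly at onset + ramp/2 and offset - ramp/2."""
    dur = offset - onset
    ramp = min(ramp, dur / 2.0)
    tau = t - onset
    r = np.zeros_like(t)
    rising = (tau >= 0) & (tau < ramp)
    high = (tau >= ramp) & (tau <= dur - ramp)
    falling = (tau > dur - ramp) & (tau <= dur)
    r[rising] = 0.5 * (1.0 - np.cos(np.pi * tau[rising] / ramp))
    r[high] = 1.0
    r[falling] = 0.5 * (1.0 - np.cos(np.pi * (dur - tau[falling]) / ramp))
    return r


def _draw_cycle_amplitudes(config: GeneratorConfig, n_cycles: int,
                           delay: float, rng: np.random.Generator) -> np.ndarray:
    mean = config.mean_amplitude_mv
    if config.amp_mod_period_s is not None:
        mids = (np.arange(n_cycles) + 0.5) * config.fast_period_s + delay
        amps = mean * (1.0 + config.amp_mod_depth
                       * np.cos(2.0 * np.pi * mids / config.amp_mod_period_s))
        return np.clip(amps, 0.0, None)
    if config.slow_amp_cv == 0.0 or mean == 0.0:
        _ = rng.standard_normal(n_cycles)  # keep the stream position stable
        return np.full(n_cycles, mean)
    shape = 1.0 / config.slow_amp_cv ** 2
    scale = mean / shape
    return rng.gamma(shape, scale, size=n_cycles)


def _lognormal_durations(rng: np.random.Generator, n: int, mean: float,
                         cv: float) -> np.ndarray:
    if cv == 0.0:
        _ = rng.standard_normal(n)
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _simulate(config: GeneratorConfig, seed_seq: np.random.SeedSequence,
              coeff: float = 1.0, delay: float = 0.0,
              cycle_amps: Optional[np.ndarray] = None,
              plateau_schedule: Optional[list] = None,
              cell: str = "cell") -> tuple:
    """Render one cell.  Returns (trace, ground_truth, raw_cycle_amplitudes).

    ``coeff``/``delay`` implement gap-junction attenuation and propagation
    delay of the oscillatory component; ``cycle_amps`` (unscaled) lets a
    partner share the leader's amplitude sequence; ``plateau_schedule``
    forces the leader's plateau times instead of independent firing.
    """
    config.validate()
    fs = config.sample_rate
    n = int(round(config.duration_s * fs))
    dt = 1.0 / fs
    t = np.arange(n) * dt
    P = config.fast_period_s

    streams = seed_seq.spawn(5)
    amp_rng, gate_rng, dur_rng, spike_rng, noise_rng = (
        np.random.Generator(np.random.PCG64(s)) for s in streams)

    n_cycles = int(math.ceil((config.duration_s + abs(delay)) / P)) + 1
    if cycle_amps is None:
        cycle_amps = _draw_cycle_amplitudes(config, n_cycles, delay, amp_rng)
    amps_eff = coeff * cycle_amps

    pharm = config.pharmacology
    if pharm is not None:
        env = pharm.envelope(t)
        base = config.v_rest + pharm.baseline_offset(t)
    else:
        env = np.ones(n)
        base = np.full(n, config.v_rest)

    teff = t - delay
    k_of_t = np.clip(np.floor(teff / P).astype(int), 0, n_cycles - 1)
    # carrier: v_rest + A_k (1 - cos wt) -- a sinusoid of amplitude A_k
    # centered A_k above rest, so every cycle is a depolarizing hump of
    # peak-to-peak range 2 A_k
    osc = amps_eff[k_of_t] * env * (1.0 - np.cos(2.0 * np.pi * teff / P))

    # --- per-cycle event process -------------------------------------------
    gate_u = gate_rng.uniform(size=n_cycles)
    durations = _lognormal_durations(dur_rng, n_cycles, config.plateau_duration_mean_s,
                                     config.plateau_duration_cv)
    spike_counts = spike_rng.integers(1, 4, size=n_cycles)

    theta_p = config.plateau_threshold
    theta_s = config.spike_threshold
    soft = max(config.plateau_gate_softness_mv, 1e-9)
    ramp = config.plateau_ramp_s

    def env_at(time: float) -> float:
        i = min(max(int(round(time * fs)), 0), n - 1)
        return float(env[i])

    def base_at(time: float) -> float:
        i = min(max(int(round(time * fs)), 0), n - 1)
        return float(base[i])

    plateaus: list[PlateauEvent] = []
    spike_times: list[float] = []
    forced = list(plateau_schedule) if plateau_schedule is not None else None
    last_offset = -math.inf

    for k in range(n_cycles):
        t0 = k * P + delay
        t_peak = t0 + P / 2.0
        if t_peak < 0 or t_peak >= config.duration_s:
            continue
        a_eff = amps_eff[k] * env_at(t_peak)
        b = base_at(t_peak)
        if b >= theta_s:
            continue  # depolarization block: no regenerative events
        peak_v = b + 2.0 * a_eff

        fired = False
        if forced is None:
            if config.amp_mod_period_s is not None:
                # deterministic exemplar mode: one plateau per modulation
                # crest, on the cycle whose peak lies closest to the crest,
                # so the plateau train is strictly periodic at the
                # modulation period
                mod = config.amp_mod_period_s
                fired = (abs(t_peak - mod * round(t_peak / mod)) <= P / 2.0
                         and peak_v > theta_p and b < theta_p)
            else:
                overshoot = peak_v - theta_p
                p_gate = 1.0 / (1.0 + math.exp(-overshoot / soft))
                fired = gate_u[k] < p_gate and b < theta_p
        if fired:
            need = theta_p - b
            if 2.0 * a_eff > need > 0:
                phi = math.acos(1.0 - need / a_eff)
                t_on = t0 + phi * P / (2.0 * math.pi)
            else:
                t_on = t_peak
            if t_on - last_offset < config.plateau_refractory_s:
                fired = False
            else:
                dur = max(durations[k], config.plateau_duration_min_s)
                t_off = min(t_on + dur, config.duration_s - 2.0 * dt)
                if t_off - t_on > ramp:
                    plateaus.append(PlateauEvent(t_on, t_off, config.plateau_extra_depol,
                                                 min(ramp, (t_off - t_on) / 2.0)))
                    last_offset = t_off
                else:
                    fired = False
        if not fired and peak_v >= theta_s and forced is None:
            # isolated large spikes near the crest of the cycle
            need = theta_s - b
            if 2.0 * a_eff > need > 0:
                phi_s = math.acos(1.0 - need / a_eff)
            else:
                phi_s = math.pi * 0.8
            lo_t = t0 + phi_s * P / (2.0 * math.pi)
            hi_t = t0 + (2.0 * math.pi - phi_s) * P / (2.0 * math.pi)
            times = np.sort(spike_rng.uniform(lo_t, hi_t, size=int(spike_counts[k])))
            for ts in times:
                if 0 < ts < config.duration_s and not any(
                        p.onset_s - 1.0 <= ts <= p.offset_s + 1.0 for p in plateaus):
                    spike_times.append(float(ts))

    if forced is not None:
        plateaus = [PlateauEvent(p.onset_s, p.offset_s, config.plateau_extra_depol,
                                 p.ramp_s) for p in forced
                    if p.offset_s < config.duration_s]

    # --- render -------------------------------------------------------------
    gate_sig = np.zeros(n)
    plate_sig = np.zeros(n)
    for p in plateaus:
        prof = _plateau_profile(t, p.onset_s, p.offset_s, p.ramp_s)
        gate_sig = np.maximum(gate_sig, prof)
        plate_sig = np.maximum(plate_sig, p.extra_depol_mv * prof)

    v = base + osc * (1.0 - gate_sig) + plate_sig

    spike_tmpl = _spike_template(fs, config.spike_width_s, config.spike_amp)
    half = int(round(0.5 * config.spike_width_s * fs))
    for ts in spike_times:
        _add_template(v, spike_tmpl, int(round(ts * fs)) - half)

    plat_tmpl = _spike_template(fs, config.spike_width_s, config.plateau_spike_amp)
    for p in plateaus:
        lo_t = p.onset_s + p.ramp_s
        hi_t = p.offset_s - p.ramp_s
        if hi_t <= lo_t or config.plateau_spike_rate <= 0:
            continue
        step = 1.0 / config.plateau_spike_rate
        base_times = np.arange(lo_t, hi_t, step)
        jitter = spike_rng.uniform(-0.2 * step, 0.2 * step, size=base_times.size)
        count = 0
        for ts in base_times + jitter:
            if lo_t <= ts <= hi_t:
                _add_template(v, plat_tmpl, int(round(ts * fs)) - half)
                count += 1
        p.n_spikes = count

    v = v + _ou_noise(noise_rng, n, dt, config.noise_sd, config.noise_tau_s)

    onsets = np.arange(n_cycles) * P + delay
    keep = (onsets >= 0) & (onsets < config.duration_s)
    gt = GroundTruth(fast_period_s=P, cycle_onsets=onsets[keep],
                     cycle_amplitudes=amps_eff[keep],
                     spike_times=np.array(spike_times), plateaus=plateaus,
                     latency_s=delay if delay != 0 else None, cell=cell)
    trace = VoltageTrace(0.0, fs, v, metadata={"cell": cell,
                                               "fast_period_s": P,
                                               "seed_entropy": str(seed_seq.entropy)})
    return trace, gt, cycle_amps


def generate_cell_trace(config: GeneratorConfig) -> tuple:
    """Generate one cell.  Returns ``(VoltageTrace, GroundTruth)``."""
    trace, gt, _ = _simulate(config, np.random.SeedSequence(config.seed), cell="B63")
    return trace, gt


def set_holding_potential(config: GeneratorConfig, v_hold: float) -> GeneratorConfig:
    """Configuration for the same cell held at ``v_hold`` by current injection.

    The oscillation amplitude rescales with the driving force,
    ``(e_rev - v_hold) / (e_rev - v_rest)``, and the period is untouched
    (the oscillatory mechanism is voltage-insensitive).  Spike and plateau
    thresholds stay absolute, so hyperpolarization silences plateaus and a
    strong depolarization blocks regenerative events altogether.
    """
    if v_hold >= config.e_rev:
        raise ConfigError(
            f"holding potential {v_hold} mV at or above the reversal potential "
            f"{config.e_rev} mV leaves no driving force")
    return config.replace(v_rest=float(v_hold))


def generate_coupled_set(config: GeneratorConfig,
                         couplings: Sequence[CouplingConfig]) -> tuple:
    """Leader plus gap-junction partners.  Returns ``(traces, truths)``.

    Partners share the leader's per-cycle amplitude sequence, attenuated by
    the coupling coefficient and delayed by the propagation latency; their
    plateau and noise processes run on independent seed streams.  A partner
    with ``partner_has_oscillation=False`` (a non-coupled control cell)
    carries only membrane noise.
    """
    if not couplings:
        raise ConfigError("need at least one partner specification")
    for c in couplings:
        c.validate()
    leader_trace, leader_gt, raw_amps = _simulate(
        config, np.random.SeedSequence(config.seed), cell="B63")
    traces = [leader_trace]
    truths = [leader_gt]
    for i, cpl in enumerate(couplings):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1000 + i,))
        coeff = cpl.coupling_coefficient if cpl.partner_has_oscillation else 0.0
        schedule = None if cpl.independent_plateaus else leader_gt.plateaus
        tr, gt, _ = _simulate(config, ss, coeff=coeff, delay=cpl.latency_s,
                              cycle_amps=raw_amps, plateau_schedule=schedule,
                              cell=cpl.label)
        gt.latency_s = cpl.latency_s
        traces.append(tr)
        truths.append(gt)
    return traces, truths


def cohort_periods(n_cells: int, period_mean: float, period_sd: float,
                   master_seed: int, bounds: tuple = (30.0, 120.0)) -> np.ndarray:
    """Per-cell fast periods: truncated normal, one independent counter-based
    stream per cell so the draw is reproducible and order-independent."""
    lo, hi = bounds
    if period_sd < 0:
        raise ConfigError("period_sd must be non-negative")
    if not (8.0 <= lo < hi <= 512.0):
        raise ConfigError("truncation bounds must lie inside the 8-512 s analysis band")
    out = np.empty(n_cells)
    for i in range(n_cells):
        if period_sd == 0.0:
            out[i] = period_mean
            continue
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(entropy=master_seed, spawn_key=(i, 0))))
        a = (lo - period_mean) / period_sd
        b = (hi - period_mean) / period_sd
        out[i] = truncnorm.rvs(a, b, loc=period_mean, scale=period_sd, random_state=rng)
    return out


def generate_cohort(n_cells: int, period_mean: float, period_sd: float,
                    base: GeneratorConfig,
                    bounds: tuple = (30.0, 120.0)) -> tuple:
    """A cohort of independent cells with dispersed fast periods.

    Returns ``(traces, truths)``.  Each cell's period comes from a truncated
    normal and each cell simulates on its own seed stream split from the
    master seed, so regenerating any subset gives identical results.
    """
    if n_cells < 2:
        raise ConfigError("a cohort needs at least two cells")
    periods = cohort_periods(n_cells, period_mean, period_sd, base.seed, bounds)
    traces, truths = [], []
    for i, p in enumerate(periods):
        cfg = base.replace(fast_period_s=float(p))
        ss = np.random.SeedSequence(entropy=base.seed, spawn_key=(i, 1))
        tr, gt, _ = _simulate(cfg, ss, cell=f"cell{i:02d}")
        traces.append(tr)
        truths.append(gt)
    return traces, truths
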