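"""Event extraction: spikes, plateau potentials, cycle classification,
phase-plane trajectories and the bifurcation (plateau-triggering) threshold.

All detectors operate on the raw high-rate trace (spikes ride on top of the
slow waveform and would be destroyed by the 1 Hz conditioning).  Plateau
boundaries follow the half-height convention: for a ramped depolarization
the reported onset/offset are the times the membrane potential crosses
halfway between the local baseline and the sustained plateau level, which is
well defined regardless of ramp shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .trace import VoltageTrace
from .wavelet import ReconstructedWaveform


@dataclass
class SpikeSet:
    times: np.ndarray           # s, isolated large action potentials
    amplitudes: np.ndarray      # mV above the running median

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class Plateau:
    """Detected plateau: half-height boundaries, sustained extra
    depolarization above the local baseline, and the count of low-amplitude
    spikes riding on its top."""

    onset_s: float
    offset_s: float
    extra_depol_mv: float
    spike_count: int = 0

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventSet:
    spikes: SpikeSet
    plateaus: list
    baseline_short_record: bool = False


@dataclass
class CycleLabels:
    """Per-cycle classification of the slow oscillation.

    ``boundaries``: trough times delimiting the cycles (len = n_cycles + 1).
    ``labels``: 'plateau', 'spiking' or 'subthreshold' per cycle.
    ``anomalies``: descriptions of events that defy the expected geometry
    (e.g. a plateau onset on a falling phase).
    """

    boundaries: np.ndarray
    labels: list
    anomalies: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != self.boundaries.size - 1:
            raise ValueError("need exactly one label per inter-trough interval")


@dataclass
class PhasePlane:
    """(V, dV/dt) trajectory of a despiked trace, segmented by cycle."""

    v: np.ndarray
    dvdt: np.ndarray
    times: np.ndarray
    cycle_slices: list          # slice objects, one per classified cycle
    labels: list


def _rolling_median_baseline(trace: VoltageTrace, window_s: float = 300.0):
    """Slow baseline estimate; flags records shorter than the window."""
    n = trace.n_samples
    w = int(round(window_s * trace.sample_rate)) | 1
    short = w >= n
    if short:
        base = np.full(n, float(np.median(trace.values)))
    else:
        base = (pd.Series(trace.values)
                .rolling(w, center=True, min_periods=w // 4)
                .median()
                .to_numpy())
        base = pd.Series(base).bfill().ffill().to_numpy()
    return base, short


def detect_spikes(trace: VoltageTrace, min_amp: float = 20.0,
                  min_separation_s: float = 0.05,
                  median_window_s: float = 1.0) -> SpikeSet:
    """Isolated large action potentials.

    The slow waveform is removed with a short running median; peaks of the
    residual above ``min_amp`` (default 20 mV, above the ~15 mV spikelets
    that crown plateaus) separated by at least ``min_separation_s`` are
    reported at their sample times.
    """
    fs = trace.sample_rate
    w = max(3, int(round(median_window_s * fs)) | 1)
    med = (pd.Series(trace.values)
           .rolling(w, center=True, min_periods=1)
           .median()
           .to_numpy())
    resid = trace.values - med
    idx, props = signal.find_peaks(resid, height=min_amp,
                                   distance=max(1, int(round(min_separation_s * fs))))
    return SpikeSet(times=trace.start_time + idx / fs,
                    amplitudes=props["peak_heights"])


def detect_plateaus(trace: VoltageTrace, min_extra_mv: float = 15.0,
                    min_duration_s: float = 10.0, merge_gap_s: float = 2.0,
                    baseline_window_s: float = 300.0) -> tuple:
    """Sustained depolarized states.  Returns ``(plateaus, short_record)``.

    Candidate intervals are runs where a despiked copy of the trace exceeds
    the slow rolling-median baseline by ``min_extra_mv`` for at least
    ``min_duration_s`` (gaps shorter than ``merge_gap_s`` are bridged).  Each
    interval's extra depolarization is the median elevation over its core;
    boundaries are then refined outward to the half-height crossings
    (baseline + extra/2).
    """
    fs = trace.sample_rate
    base, short = _rolling_median_baseline(trace, baseline_window_s)
    w = max(3, int(round(1.0 * fs)) | 1)
    despiked = (pd.Series(trace.values)
                .rolling(w, center=True, min_periods=1)
                .median()
                .to_numpy())
    above = despiked - base > min_extra_mv

    # run-length encode, then bridge short gaps
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    merged = []
    for s, e in zip(starts, stops):
        if merged and (s - merged[-1][1]) / fs < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    plateaus = []
    n = trace.n_samples
    for s, e in merged:
        if (e - s) / fs < min_duration_s:
            continue
        core = despiked[s:e] - base[s:e]
        extra = float(np.median(core))
        level = extra / 2.0
        elev = despiked - base
        # refine outward to the half-height crossings; cap the walk so a
        # depolarized oscillation cycle abutting the plateau cannot drag a
        # boundary along its own hump
        max_walk = int(round(6.0 * fs))
        i0 = s
        while i0 > 0 and s - i0 < max_walk and elev[i0 - 1] >= level:
            i0 -= 1
        i1 = e - 1
        while i1 < n - 1 and i1 - e < max_walk and elev[i1 + 1] >= level:
            i1 += 1
        plateaus.append(Plateau(onset_s=trace.start_time + i0 / fs,
                                offset_s=trace.start_time + i1 / fs,
                                extra_depol_mv=extra))
    return plateaus, short


def extract_events(trace: VoltageTrace, spike_min_amp: float = 20.0,
                   plateau_min_extra_mv: float = 15.0) -> EventSet:
    """Full event inventory of a raw trace.

    Spikes inside detected plateaus are removed from the isolated-spike list;
    instead, residual peaks of 5 mV or more within each plateau are counted
    as its crown of low-amplitude spikes.
    """
    spikes = detect_spikes(trace, min_amp=spike_min_amp)
    plateaus, short = detect_plateaus(trace, min_extra_mv=plateau_min_extra_mv)

    fs = trace.sample_rate
    w = max(3, int(round(1.0 * fs)) | 1)
    med = (pd.Series(trace.values)
           .rolling(w, center=True, min_periods=1)
           .median()
           .to_numpy())
    resid = trace.values - med
    small_idx, _ = signal.find_peaks(resid, height=5.0,
                                     distance=max(1, int(round(0.05 * fs))))
    small_t = trace.start_time + small_idx / fs

    keep = np.ones(spikes.times.size, dtype=bool)
    for p in plateaus:
        keep &= ~((spikes.times >= p.onset_s - 1.0) & (spikes.times <= p.offset_s + 1.0))
        p.spike_count = int(np.count_nonzero(
            (small_t >= p.onset_s) & (small_t <= p.offset_s)))
    spikes = SpikeSet(times=spikes.times[keep], amplitudes=spikes.amplitudes[keep])
    return EventSet(spikes=spikes, plateaus=plateaus, baseline_short_record=short)


def mask_plateaus(trace: VoltageTrace, plateaus: Sequence[Plateau],
                  pad_s: float = 3.0) -> VoltageTrace:
    """Replace plateau intervals (padded by ``pad_s``) with linear bridges.

    The subthreshold oscillation is suppressed while a plateau is in
    progress, and the plateau's own large square-wave power otherwise swamps
    the oscillation peak in short records; masking the plateaus isolates the
    oscillatory component so its period can be measured cleanly.
    """
    v = trace.values.copy()
    t = trace.times
    n = v.size
    for p in plateaus:
        lo = int(np.searchsorted(t, p.onset_s - pad_s))
        hi = int(np.searchsorted(t, p.offset_s + pad_s))
        lo, hi = max(lo, 0), min(hi, n)
        if hi <= lo + 1:
            continue
        a = v[max(lo - 1, 0)]
        c = v[min(hi, n - 1)]
        v[lo:hi] = np.linspace(a, c, hi - lo)
    return trace.with_values(v, plateaus_masked=len(list(plateaus)))


def classify_cycles(recon: ReconstructedWaveform, events: EventSet) -> CycleLabels:
    """Label each oscillation cycle by its regenerative outcome.

    Cycles are the intervals between successive troughs of the reconstructed
    fast waveform.  A cycle containing a plateau onset is 'plateau'
    (an onset on the falling half, after the cycle's reconstructed peak, is
    reported as an anomaly instead); a plateau-free cycle containing at
    least one isolated spike is 'spiking'; otherwise 'subthreshold'.
    """
    x = recon.values
    trough_idx, _ = signal.find_peaks(-x, distance=max(2, int(0.5 * recon.source_period)))
    if trough_idx.size < 2:
        raise ValueError("fewer than two troughs: cannot delimit cycles")
    boundaries = recon.times[trough_idx]
    n_cycles = boundaries.size - 1
    labels = ["subthreshold"] * n_cycles
    anomalies: list[str] = []

    for p in events.plateaus:
        k = int(np.searchsorted(boundaries, p.onset_s) - 1)
        if k < 0 or k >= n_cycles:
            anomalies.append(f"plateau at {p.onset_s:.1f} s outside classified cycles")
            continue
        seg = slice(trough_idx[k], trough_idx[k + 1] + 1)
        peak_rel = int(np.argmax(x[seg]))
        peak_time = recon.times[trough_idx[k] + peak_rel]
        if p.onset_s > peak_time + 0.05 * recon.source_period:
            anomalies.append(
                f"plateau onset {p.onset_s:.1f} s on falling phase of cycle {k}")
        labels[k] = "plateau"

    for t in events.spikes.times:
        k = int(np.searchsorted(boundaries, t) - 1)
        if 0 <= k < n_cycles and labels[k] == "subthreshold":
            labels[k] = "spiking"

    return CycleLabels(boundaries=boundaries, labels=labels, anomalies=anomalies)


def phase_plane(trace_10hz: VoltageTrace, cycles: CycleLabels,
                events: Optional[EventSet] = None,
                refractory_shadow_s: float = 30.0) -> PhasePlane:
    """(V, dV/dt) trajectory of a despiked 10 Hz trace, cut at cycle
    boundaries so plateau and subthreshold orbits can be compared.

    When ``events`` is given, two kinds of non-plateau cycles are dropped:
    cycles that overlap a detected plateau without being its onset cycle
    (the plateau spills over from the previous cycle, so the elevated
    voltages belong to the plateau's trajectory, not the cycle's own orbit),
    and cycles starting within ``refractory_shadow_s`` after a plateau ends
    (the cell is refractory there, so even large depolarizations fail to
    regenerate and would misrepresent the resting excitability).
    """
    if abs(trace_10hz.sample_rate - 10.0) > 1e-6:
        raise ValueError("phase-plane analysis expects a 10 Hz trace")
    v = trace_10hz.values
    dvdt = np.gradient(v, trace_10hz.dt)
    t = trace_10hz.times
    slices, labels = [], []
    for k in range(len(cycles.labels)):
        lo_t, hi_t = cycles.boundaries[k], cycles.boundaries[k + 1]
        if events is not None and cycles.labels[k] != "plateau":
            if any(p.onset_s < hi_t and p.offset_s > lo_t for p in events.plateaus):
                continue
            if any(0.0 <= lo_t - p.offset_s < refractory_shadow_s
                   for p in events.plateaus):
                continue
        lo = int(np.searchsorted(t, lo_t))
        hi = int(np.searchsorted(t, hi_t))
        if hi - lo > 3:
            slices.append(slice(lo, hi))
            labels.append(cycles.labels[k])
    return PhasePlane(v=v, dvdt=dvdt, times=t, cycle_slices=slices, labels=labels)


def _divergence_voltage(pp: PhasePlane, sl: slice, frac: float = 0.4,
                        max_back_s: float = 4.0) -> Optional[float]:
    """Voltage at the 'foot' of a plateau cycle's regenerative upstroke.

    From the sample of steepest depolarization, walk back to the last sample
    whose slope is at most ``frac`` of that peak slope; the voltage there is
    where the trajectory leaves the slow manifold.  The walk is capped at
    ``max_back_s`` so filter smear of the upstroke cannot drag the foot down
    the preceding oscillation limb.
    """
    d = pp.dvdt[sl]
    v = pp.v[sl]
    i_max = int(np.argmax(d))
    peak = d[i_max]
    if peak <= 0:
        return None
    dt = float(pp.times[1] - pp.times[0])
    i_lo = max(0, i_max - int(round(max_back_s / dt)))
    i = i_max
    while i > i_lo and d[i] > frac * peak:
        i -= 1
    return float(v[i])


def bifurcation_threshold(pp: PhasePlane) -> Optional[float]:
    """Estimate of the all-or-none plateau-triggering voltage.

    The threshold separates the maximal voltage reached by cycles whose
    trajectories spiral back without a plateau (subthreshold and
    isolated-spike cycles, on the despiked trace) from the voltage at which
    plateau cycles' trajectories diverge into the regenerative upstroke; the
    midpoint of the two is returned.  Needs at least two cycles of each
    class, otherwise None.
    """
    sub_max, div_v = [], []
    for sl, lab in zip(pp.cycle_slices, pp.labels):
        if lab in ("subthreshold", "spiking"):
            sub_max.append(float(pp.v[sl].max()))
        elif lab == "plateau":
            dv = _divergence_voltage(pp, sl)
            if dv is not None:
                div_v.append(dv)
    if len(sub_max) < 2 or len(div_v) < 2:
        return None
    return 0.5 * (max(sub_max) + min(div_v))
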