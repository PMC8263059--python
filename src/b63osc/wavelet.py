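"""Morlet continuous wavelet transform, band reconstruction, pair phase lag.

The periodogram answers "which periods dominate"; the wavelet field answers
"when".  The transform is the standard analytic Morlet (central frequency
omega0 = 6) evaluated in the Fourier domain on a log2 period grid with 32
voices per octave, following the usual geophysical-time-series formulation:

    psi_hat(s w) = pi^(-1/4) * sqrt(2 pi s / dt) * exp(-(s w - w0)^2 / 2),  w > 0
    period      = s * 4 pi / (w0 + sqrt(2 + w0^2))          (~ 1.033 s)
    x_rec(t)    = dj sqrt(dt) / (Cdelta pi^(-1/4)) * sum_j Re W(s_j, t)/sqrt(s_j)

with the reconstruction constant Cdelta = 0.776 for omega0 = 6.  The cone of
influence (e-folding time sqrt(2) s from either record edge) marks
coefficients contaminated by the edges; phase statistics exclude them.

Pair phase latency converts the circular mean of the cross-wavelet phase at
a reference period into seconds; positive latency means the second trace
lags the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .trace import VoltageTrace

OMEGA0 = 6.0
#: period = FOURIER_FACTOR * scale for the omega0 = 6 Morlet.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0 ** 2))
C_DELTA = 0.776
PSI0 = np.pi ** -0.25
DEFAULT_VOICES = 32
PERIOD_RANGE = (8.0, 512.0)


@dataclass
class WaveletField:
    periods: np.ndarray        # s, ascending
    times: np.ndarray          # s
    coef: np.ndarray           # complex, shape (n_periods, n_times)
    coi_valid: np.ndarray      # bool mask, True where outside edge influence
    dt: float
    dj: float                  # log2 grid spacing

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("wavelet coefficients contain non-finite values")


@dataclass
class ReconstructedWaveform:
    """Sinusoid-like component of a trace within one period band (mV)."""

    times: np.ndarray
    values: np.ndarray
    band: tuple               # (lo_s, hi_s)
    source_period: float

    def __post_init__(self) -> None:
        if abs(float(np.mean(self.values))) > 0.1:
            raise ValueError("reconstructed waveform must be zero-mean (within 0.1 mV)")


@dataclass
class PhaseLatency:
    latency_s: float          # positive: second trace delayed
    reference_period: float
    circular_sd_s: float

    def __post_init__(self) -> None:
        if abs(self.latency_s) > self.reference_period / 2 + 1e-9:
            raise ValueError("latency must lie within +-period/2")


def default_period_grid(lo: float = PERIOD_RANGE[0], hi: float = PERIOD_RANGE[1],
                        voices: int = DEFAULT_VOICES) -> np.ndarray:
    n = int(round(np.log2(hi / lo) * voices))
    return lo * 2.0 ** (np.arange(n + 1) / voices)


def cwt(trace_1hz: VoltageTrace,
        period_grid: Optional[np.ndarray] = None) -> WaveletField:
    """Morlet transform of a 1 Hz trace at each grid period.

    The signal is mean-removed and zero-padded to the next power of two; the
    cone-of-influence mask marks where the wavelet's e-folding time reaches
    past a record edge.
    """
    if abs(trace_1hz.sample_rate - 1.0) > 1e-9:
        raise ValueError("cwt expects a 1 Hz trace")
    if period_grid is None:
        period_grid = default_period_grid()
    periods = np.asarray(period_grid, dtype=float)
    if np.any(periods < PERIOD_RANGE[0] - 1e-9) or np.any(periods > PERIOD_RANGE[1] + 1e-9):
        raise ValueError(f"period grid must lie within {PERIOD_RANGE} s")
    dt = trace_1hz.dt
    x = trace_1hz.values - trace_1hz.values.mean()
    n = x.size
    npad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(x, npad)
    w = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    scales = periods / FOURIER_FACTOR
    coef = np.empty((periods.size, n), dtype=complex)
    pos = w > 0
    for j, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        psi_hat[pos] = (PSI0 * np.sqrt(2.0 * np.pi * s / dt)
                        * np.exp(-0.5 * (s * w[pos] - OMEGA0) ** 2))
        coef[j] = np.fft.ifft(xhat * psi_hat)[:n]
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi_valid = (np.sqrt(2.0) * scales)[:, None] <= edge[None, :]
    if periods.size > 1:
        dj = float(np.mean(np.diff(np.log2(periods))))
    else:
        dj = 1.0 / DEFAULT_VOICES
    return WaveletField(periods=periods, times=trace_1hz.times, coef=coef,
                        coi_valid=coi_valid, dt=dt, dj=dj)


def reconstruct_band(field: WaveletField, center_period: float,
                     rel_bandwidth: float = 0.25) -> ReconstructedWaveform:
    """Inverse-wavelet sum over periods within ``center * (1 +- rel_bandwidth)``.

    Standard delta-function reconstruction normalization; the result is
    forced to zero mean (the transform drops DC by construction, the
    correction is numerical).
    """
    lo = center_period * (1.0 - rel_bandwidth)
    hi = center_period * (1.0 + rel_bandwidth)
    if lo < field.periods[0] - 1e-9 or hi > field.periods[-1] + 1e-9:
        raise ValueError(
            f"band [{lo:.1f}, {hi:.1f}] s exits the wavelet grid "
            f"[{field.periods[0]:.1f}, {field.periods[-1]:.1f}] s")
    sel = (field.periods >= lo) & (field.periods <= hi)
    if not np.any(sel):
        raise ValueError("no grid periods inside the requested band")
    scales = field.periods[sel] / FOURIER_FACTOR
    terms = np.real(field.coef[sel]) / np.sqrt(scales)[:, None]
    x = field.dj * np.sqrt(field.dt) / (C_DELTA * PSI0) * terms.sum(axis=0)
    x = x - x.mean()
    return ReconstructedWaveform(times=field.times, values=x,
                                 band=(lo, hi), source_period=center_period)


def equivalence_scale(recon: ReconstructedWaveform) -> ReconstructedWaveform:
    """Divide a reconstruction by its RMS (display-only superposition aid)."""
    rms = float(np.sqrt(np.mean(recon.values ** 2)))
    if rms == 0:
        return recon
    return ReconstructedWaveform(recon.times, recon.values / rms,
                                 recon.band, recon.source_period)


def pair_phase_latency(a: VoltageTrace, b: VoltageTrace,
                       period: float) -> PhaseLatency:
    """Cross-wavelet phase lag between two cells at a reference period.

    The phase angle of ``W_a conj(W_b)`` is averaged circularly over the
    samples inside both cones of influence and converted to seconds; the
    result is wrapped into (-period/2, period/2].  Positive latency: ``b``
    lags ``a``.
    """
    if a.n_samples != b.n_samples or abs(a.sample_rate - b.sample_rate) > 1e-9:
        raise ValueError("traces must share length and sampling rate")
    if abs(a.start_time - b.start_time) > 1e-6:
        raise ValueError("traces are misaligned in time")
    grid = np.array([period])
    fa = cwt(a, grid)
    fb = cwt(b, grid)
    cross = fa.coef[0] * np.conj(fb.coef[0])
    valid = fa.coi_valid[0] & fb.coi_valid[0] & (np.abs(cross) > 0)
    if not np.any(valid):
        raise ValueError("no samples inside both cones of influence at this period")
    phasors = cross[valid] / np.abs(cross[valid])
    mean_ph = phasors.mean()
    resultant = float(np.abs(mean_ph))
    ang = float(np.angle(mean_ph))
    latency = ang / (2.0 * np.pi) * period
    half = period / 2.0
    latency = (latency + half) % period - half
    if resultant >= 1.0:
        circ_sd = 0.0
    else:
        circ_sd = float(np.sqrt(-2.0 * np.log(resultant)) * period / (2.0 * np.pi))
    return PhaseLatency(latency_s=latency, reference_period=period,
                        circular_sd_s=circ_sd)
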