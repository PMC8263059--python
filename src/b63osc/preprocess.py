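"""Trace conditioning: boxcar smoothing, integer decimation, spike removal.

The spectral and wavelet analyses operate on the 8-512 s period band, far
below the bandwidth of the raw acquisition, so traces are smoothed with a
centered boxcar (time constant 0.5 s by default) and decimated to 1 Hz.
Phase-plane analysis uses the same smoothing but 10 Hz.  All steps are
zero-phase: latency estimates between cell pairs would be biased by any
causal (phase-lagging) filter.

Edge handling is by window truncation -- near the record ends the boxcar
average runs over the available samples only.  The first and last ``tau``
seconds are flagged in the trace metadata so downstream consumers can mask
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .trace import VoltageTrace


def smooth(trace: VoltageTrace, tau: float = 0.5) -> VoltageTrace:
    """Centered moving average over the window [t - tau, t + tau].

    The kernel is a boxcar of half-width ``round(tau * fs)`` samples; edges
    are handled by truncating the window (normalized convolution), which
    preserves constants exactly everywhere including the first and last
    samples.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    h = int(round(tau * trace.sample_rate))
    if h < 1:
        raise ValueError(
            f"tau = {tau} s is shorter than one sample period at {trace.sample_rate} Hz")
    kernel = np.ones(2 * h + 1)
    num = np.convolve(trace.values, kernel, mode="same")
    den = np.convolve(np.ones(trace.n_samples), kernel, mode="same")
    return trace.with_values(num / den, smoothed_tau_s=tau, edge_flagged_s=tau)


def resample(trace: VoltageTrace, target_rate: float) -> VoltageTrace:
    """Decimate to ``target_rate`` by keeping every k-th sample.

    The decimation factor ``k = sample_rate / target_rate`` must be an
    integer; anti-aliasing is the caller's job (apply :func:`smooth` first).
    The start time and first sample are preserved.
    """
    if target_rate > trace.sample_rate:
        raise ValueError("target_rate must not exceed the trace sample rate")
    k = trace.sample_rate / target_rate
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"decimation factor {k:g} from {trace.sample_rate} Hz to "
            f"{target_rate} Hz is not an integer")
    k = int(round(k))
    if k == 1:
        return trace.copy()
    out = trace.with_values(trace.values[::k])
    out.sample_rate = target_rate
    return out


def despike(trace: VoltageTrace, cutoff: float = 0.2,
            median_window_s: float = 1.0, order: int = 4) -> VoltageTrace:
    """Remove action potentials: running median then zero-phase low-pass.

    A 1 s running median knocks out the narrow spike templates without
    displacing the slow envelope; the subsequent zero-phase Butterworth
    low-pass (4th order, 0.2 Hz, applied forward and backward) removes the
    residual staircase.  The cutoff sits above the analysis band's 0.125 Hz
    upper edge, so oscillation components pass essentially untouched and the
    DC level is preserved.
    """
    fs = trace.sample_rate
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist rate {fs / 2} Hz")
    w = max(3, int(round(median_window_s * fs)) | 1)
    med = (pd.Series(trace.values)
           .rolling(w, center=True, min_periods=1)
           .median()
           .to_numpy())
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(med.size - 1, 3 * (2 * order + 1) * 10)
    out = signal.sosfiltfilt(sos, med, padlen=padlen)
    return trace.with_values(out, despiked=True, despike_cutoff_hz=cutoff)


def standard_pipeline(trace: VoltageTrace, tau: float = 0.5,
                      target_rate: float = 1.0) -> VoltageTrace:
    """Smooth then decimate -- the conditioning applied before all spectral
    and wavelet analysis (0.5 s boxcar, 1 Hz by default)."""
    return resample(smooth(trace, tau=tau), target_rate)
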