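"""Band-limited period-domain spectral density and dominant-period selection.

The oscillations of interest live between 8 s and 512 s (0.125 Hz down to
0.00195 Hz).  A trace conditioned to 1 Hz is mean-removed, zero-padded 8x and
Fourier transformed; the one-sided power spectral density (mV^2 s) is then
restricted to the band and re-indexed by period (the reciprocal frequency),
which is the natural axis for signals this slow.  Oscillation "amplitude"
throughout the package means the peak spectral density of the dominant
period, matching how slow-oscillation magnitude is quantified from
intracellular recordings.

Dominant periods are local maxima ranked by density, with three guards:

* a noise floor (default 16x the band median) so that an oscillation-free
  cell is a decidable outcome -- see docs/methods.md for the calibration;
* harmonic exclusion: a candidate within 10% of P/k (k = 2..4) of a larger
  retained peak, with less than half its density, is flagged as a harmonic;
* a dominance floor (4.5% of the strongest peak) that drops residual
  high-order harmonics of strongly non-sinusoidal waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len
from scipy import stats as sps

from .trace import VoltageTrace

#: Analysis band in Hz (periods 512 s down to 8 s).
BAND_HZ = (1.0 / 512.0, 0.125)


@dataclass
class Periodogram:
    """Band-limited one-sided spectral density on a descending period axis."""

    periods: np.ndarray          # s, descending
    density: np.ndarray          # mV^2 s
    band: tuple = BAND_HZ
    n_samples: int = 0
    metadata: dict = field(default_factory=dict)
    variance: float = 0.0        # variance of the (mean-removed) input
    parseval_ratio: float = 1.0  # full-spectrum integral / variance

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("spectral density must be non-negative")
        lo, hi = self.band
        if np.any(self.periods < 1.0 / hi - 1e-9) or np.any(self.periods > 1.0 / lo + 1e-9):
            raise ValueError("periods outside the analysis band")


@dataclass
class PeakEntry:
    period_s: float
    density: float
    harmonic_of: Optional[float] = None   # parent period when flagged


@dataclass
class DominantPeriods:
    """Retained dominant peaks (density-ranked) and the harmonics they shed."""

    entries: list            # PeakEntry, harmonic_of is None for all
    excluded_harmonics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        dens = [e.density for e in self.entries]
        if dens != sorted(dens, reverse=True):
            raise ValueError("entries must be sorted by decreasing density")
        if any(e.harmonic_of is not None for e in self.entries):
            raise ValueError("retained entries must not be flagged harmonics")

    @property
    def periods(self) -> list:
        return [e.period_s for e in self.entries]


@dataclass
class AveragedPeriodogram:
    periods: np.ndarray
    mean_density: np.ndarray
    ci95_halfwidth: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("averaging requires at least two periodograms")
        if np.any(self.ci95_halfwidth < 0):
            raise ValueError("CI95 half-widths must be non-negative")


def periodogram(trace_1hz: VoltageTrace, pad_factor: int = 8) -> Periodogram:
    """One-sided PSD of a 1 Hz trace, restricted to the 8-512 s band.

    The mean-removed signal is zero-padded to at least ``pad_factor`` times
    its length (rounded up to an FFT-friendly size) to localize peaks beyond
    the native Rayleigh resolution.  Density scaling follows the convention
    that the integral of the full (unrestricted) one-sided PSD over frequency
    equals the signal variance; the achieved ratio is stored as
    ``parseval_ratio`` and asserted to 1% at construction time.
    """
    if abs(trace_1hz.sample_rate - 1.0) > 1e-9:
        raise ValueError(f"periodogram expects a 1 Hz trace, got {trace_1hz.sample_rate} Hz")
    n = trace_1hz.n_samples
    if n < 64:
        raise ValueError(f"trace too short for spectral analysis ({n} < 64 samples)")
    nfft = next_fast_len(pad_factor * n)
    f, pxx = signal.periodogram(trace_1hz.values, fs=1.0, window="boxcar",
                                nfft=nfft, detrend="constant", scaling="density")
    var = float(np.var(trace_1hz.values))
    df = f[1] - f[0]
    total = float(pxx.sum() * df)
    ratio = total / var if var > 0 else 1.0
    if var > 0 and abs(ratio - 1.0) > 0.01:
        raise AssertionError(f"Parseval check failed: spectral integral / variance = {ratio:.4f}")
    lo, hi = BAND_HZ
    mask = (f >= lo) & (f <= hi)
    periods = 1.0 / f[mask]
    return Periodogram(periods=periods, density=pxx[mask], band=BAND_HZ,
                       n_samples=n, metadata=dict(trace_1hz.metadata),
                       variance=var, parseval_ratio=ratio)


def dominant_periods(pgram: Periodogram, max_n: int = 2,
                     noise_floor_factor: float = 16.0,
                     harmonic_tol: float = 0.10,
                     harmonic_ks: Sequence[int] = (2, 3, 4),
                     harmonic_max_ratio: float = 0.5,
                     dominance_min_ratio: float = 0.045) -> DominantPeriods:
    """Rank local spectral maxima and retain up to ``max_n`` non-harmonics.

    A candidate is flagged as a harmonic of an already retained, larger peak
    of period P when it lies within ``harmonic_tol`` of P/k for some k in
    ``harmonic_ks`` *and* carries less than ``harmonic_max_ratio`` of the
    parent's density (genuinely independent components of comparable power
    are never removed, whatever their period ratio).  Candidates below
    ``noise_floor_factor`` times the band median, or below
    ``dominance_min_ratio`` of the strongest candidate, are not dominant.
    """
    dens = pgram.density
    if dens.size < 3:
        raise ValueError("periodogram band is empty or too sparse for peak finding")
    idx, _ = signal.find_peaks(dens)
    if idx.size == 0:
        return DominantPeriods(entries=[])
    floor = noise_floor_factor * float(np.median(dens))
    order = idx[np.argsort(dens[idx])[::-1]]
    top = float(dens[order[0]])
    retained: list[PeakEntry] = []
    excluded: list[PeakEntry] = []
    for i in order:
        d = float(dens[i])
        if d < floor or d < dominance_min_ratio * top:
            continue
        p = float(pgram.periods[i])
        parent = None
        for r in retained:
            if r.period_s <= p or d >= harmonic_max_ratio * r.density:
                continue
            for k in harmonic_ks:
                target = r.period_s / k
                if abs(p - target) <= harmonic_tol * target:
                    parent = r.period_s
                    break
            if parent is not None:
                break
        if parent is not None:
            excluded.append(PeakEntry(p, d, harmonic_of=parent))
        elif len(retained) < max_n:
            retained.append(PeakEntry(p, d))
    return DominantPeriods(entries=retained, excluded_harmonics=excluded)


def oscillation_amplitude(pgram: Periodogram, **kwargs) -> Optional[float]:
    """Peak spectral density (mV^2 s) of the top dominant period.

    Returns None -- an absence indicator, deliberately not zero -- when no
    peak clears the noise floor, which is how "the oscillation is absent"
    (non-coupled cells, post-drug traces) becomes a decidable outcome.
    """
    dom = dominant_periods(pgram, max_n=1, **kwargs)
    if not dom.entries:
        return None
    return dom.entries[0].density


def fast_dominant_period(pgram: Periodogram, max_n: int = 2, **kwargs) -> Optional[float]:
    """Shortest retained dominant period (the 'fast' rhythm), or None."""
    dom = dominant_periods(pgram, max_n=max_n, **kwargs)
    if not dom.entries:
        return None
    return min(e.period_s for e in dom.entries)


def average_periodograms(pgrams: Sequence[Periodogram],
                         n_grid: int = 257) -> AveragedPeriodogram:
    """Per-point mean and t-based CI95 on a common log-period grid."""
    if len(pgrams) < 2:
        raise ValueError("need at least two periodograms to average")
    band = pgrams[0].band
    for p in pgrams[1:]:
        if p.band != band:
            raise ValueError("periodograms have mismatched analysis bands")
    lo, hi = band
    grid = np.logspace(np.log10(1.0 / hi), np.log10(1.0 / lo), n_grid)
    rows = []
    for p in pgrams:
        # periods are stored descending; np.interp needs ascending x
        x = np.log(p.periods[::-1])
        y = p.density[::-1]
        rows.append(np.interp(np.log(grid), x, y))
    mat = np.vstack(rows)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return AveragedPeriodogram(periods=grid, mean_density=mean,
                               ci95_halfwidth=half, n_cells=n)
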