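"""Simulate a control recording, detect its events, measure its rhythm.

Run from the repository root::

    python examples/simulate_and_spectrum.py
"""

import numpy as np

import b63osc as b

# a 600 s control recording at 100 Hz with the default study parameters
config = b.GeneratorConfig(seed=0)
trace, truth = b.generate_cell_trace(config)
print(f"simulated {trace.duration_s:.0f} s at {trace.sample_rate:g} Hz, "
      f"resting potential {config.v_rest:g} mV")
print(f"ground truth: fast period {truth.fast_period_s:g} s, "
      f"{len(truth.plateaus)} plateaus, {truth.spike_times.size} isolated spikes")

# event inventory from the raw trace alone
events = b.extract_events(trace)
print(f"\ndetected {len(events.plateaus)} plateaus:")
for p in events.plateaus:
    print(f"  onset {p.onset_s:7.1f} s  duration {p.duration_s:5.1f} s  "
          f"extra depolarization {p.extra_depol_mv:5.1f} mV  "
          f"{p.spike_count} crown spikes")

# spectral analysis of the conditioned (0.5 s boxcar, 1 Hz) trace, with the
# plateaus masked out so their square-wave power cannot shadow the rhythm
masked = b.mask_plateaus(trace, events.plateaus)
pg = b.periodogram(b.standard_pipeline(masked))
dom = b.dominant_periods(pg)
print("\ndominant periods (plateaus masked):")
for e in dom.entries:
    print(f"  {e.period_s:6.1f} s   density {e.density:9.1f} mV^2 s")
print(f"excluded harmonics: {[round(e.period_s, 1) for e in dom.excluded_harmonics]}")
print(f"Parseval ratio of the underlying spectrum: {pg.parseval_ratio:.4f}")
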