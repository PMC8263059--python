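"""Phase-plane analysis: estimate the plateau-triggering voltage.

Run from the repository root::

    python examples/phase_plane_threshold.py
"""

import numpy as np

import b63osc as b

estimates = []
for seed in range(6):
    config = b.GeneratorConfig(seed=seed, duration_s=1200.0)
    trace, _ = b.generate_cell_trace(config)

    conditioned = b.standard_pipeline(trace)
    recon = b.reconstruct_band(b.cwt(conditioned), config.fast_period_s)
    events = b.extract_events(trace)
    cycles = b.classify_cycles(recon, events)

    # despiked 10 Hz copy for the (V, dV/dt) trajectory
    t10 = b.resample(b.smooth(b.despike(trace, cutoff=0.5), tau=0.5), 10.0)
    pp = b.phase_plane(t10, cycles, events=events)
    est = b.bifurcation_threshold(pp)
    counts = {lab: pp.labels.count(lab) for lab in set(pp.labels)}
    print(f"seed {seed}: cycles {counts}, threshold estimate "
          f"{'n/a' if est is None else f'{est:.1f} mV'}")
    if est is not None:
        estimates.append(est)

print(f"\nmedian estimate: {np.median(estimates):.1f} mV "
      f"(generator threshold {b.GeneratorConfig().plateau_threshold:g} mV)")
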