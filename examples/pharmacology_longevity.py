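"""Oscillation suppression by different manipulations, and its longevity.

Run from the repository root::

    python examples/pharmacology_longevity.py
"""

import math

import b63osc as b

T_ON = 300.0

print(f"{'condition':>12}  {'longevity (s)':>13}   oscillation in 400-700 s window?")
for name in ("TTX", "CA_FREE", "CPA", "FCCP", "HEPARIN_B63", "HEPARIN_B31"):
    config = b.apply_pharmacology(
        b.GeneratorConfig(seed=0, duration_s=1500.0), name, t_on=T_ON)
    trace, _ = b.generate_cell_trace(config)

    # analytic longevity of the suppression envelope
    longevity = config.pharmacology.longevity_s()
    text = "never suppressed" if math.isinf(longevity) else f"{longevity:13.0f}"

    # empirical check on a post-application window
    i0 = int(400.0 * trace.sample_rate)
    i1 = int(700.0 * trace.sample_rate)
    window = b.VoltageTrace(400.0, trace.sample_rate, trace.values[i0:i1])
    amp = b.oscillation_amplitude(b.periodogram(b.standard_pipeline(window)))
    verdict = "yes" if amp is not None else "no"
    print(f"{name:>12}  {text:>13}   {verdict}")
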