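"""Synthetic-recording generator: determinism, amplitude conventions,
holding-potential scaling, plateau statistics, coupling, pharmacology."""

import numpy as np
import pytest

import b63osc as b
from b63osc import (ConfigError, CouplingConfig, GeneratorConfig,
                    PharmacologySchedule, apply_pharmacology, cohort_periods,
                    generate_cell_trace, generate_cohort, generate_coupled_set,
                    set_holding_potential)


def test_bit_identical_determinism():
    cfg = GeneratorConfig(seed=17)
    tr1, gt1 = generate_cell_trace(cfg)
    tr2, gt2 = generate_cell_trace(cfg)
    np.testing.assert_array_equal(tr1.values, tr2.values)
    assert [p.onset_s for p in gt1.plateaus] == [p.onset_s for p in gt2.plateaus]
    np.testing.assert_array_equal(gt1.spike_times, gt2.spike_times)


def test_seeds_decorrelate_traces():
    tr1, _ = generate_cell_trace(GeneratorConfig(seed=0))
    tr2, _ = generate_cell_trace(GeneratorConfig(seed=1))
    assert not np.array_equal(tr1.values, tr2.values)


def test_peak_to_peak_is_twice_cycle_amplitude():
    # Noiseless, dispersion-free, event-free configuration: troughs at rest,
    # crests at rest + 2 * amplitude.
    cfg = GeneratorConfig(seed=0, noise_sd=0.0, slow_amp_cv=0.0, slow_amp_mean=4.0,
                          spike_threshold=-20.5, plateau_threshold=-20.2)
    tr, gt = generate_cell_trace(cfg)
    assert len(gt.plateaus) == 0
    assert tr.values.min() == pytest.approx(cfg.v_rest, abs=0.01)
    assert tr.values.max() - tr.values.min() == pytest.approx(
        2.0 * cfg.mean_amplitude_mv, abs=0.02)


def test_holding_potential_scales_amplitude_not_period():
    # subthreshold regime: thresholds out of reach so the pure oscillation
    # swing can be compared across holding potentials
    base = GeneratorConfig(seed=3, noise_sd=0.0, slow_amp_cv=0.0, slow_amp_mean=8.0,
                           spike_threshold=-20.5, plateau_threshold=-20.2)
    tr0, _ = generate_cell_trace(base)
    held = set_holding_potential(base, -80.0)
    tr80, gt80 = generate_cell_trace(held)
    swing0 = tr0.values.max() - tr0.values.min()
    swing80 = tr80.values.max() - tr80.values.min()
    # driving-force ratio (E_rev - V_hold)/(E_rev - V_rest) = 60/40
    assert swing80 / swing0 == pytest.approx(1.5, abs=0.02)
    assert len(gt80.plateaus) == 0  # hyperpolarization silences plateaus
    # period untouched
    p0 = b.dominant_periods(b.periodogram(b.standard_pipeline(tr0))).entries[0]
    p80 = b.dominant_periods(b.periodogram(b.standard_pipeline(tr80))).entries[0]
    assert p80.period_s == pytest.approx(p0.period_s, rel=0.01)


def test_depolarized_holding_blocks_regenerative_events():
    base = GeneratorConfig(seed=5, noise_sd=0.0)
    held = set_holding_potential(base, -30.0)
    tr, gt = generate_cell_trace(held)
    assert len(gt.plateaus) == 0
    assert gt.spike_times.size == 0
    swing = tr.values.max() - tr.values.min()
    ref, _ = generate_cell_trace(base)
    assert swing < 0.5 * (ref.values.max() - ref.values.min())


def test_holding_at_or_above_reversal_rejected():
    with pytest.raises(ConfigError):
        set_holding_potential(GeneratorConfig(), -20.0)


def test_plateau_onsets_on_rising_phase():
    cfg = GeneratorConfig(seed=2, duration_s=1200.0)
    _, gt = generate_cell_trace(cfg)
    assert len(gt.plateaus) >= 3
    P = cfg.fast_period_s
    for p in gt.plateaus:
        phase = (p.onset_s % P) / P
        assert 0.0 < phase <= 0.5 + 1e-9


def test_plateau_durations_respect_floor_and_refractory():
    cfg = GeneratorConfig(seed=4, duration_s=1800.0)
    _, gt = generate_cell_trace(cfg)
    for p in gt.plateaus:
        assert p.offset_s - p.onset_s >= cfg.plateau_duration_min_s - 1e-9
    for p1, p2 in zip(gt.plateaus, gt.plateaus[1:]):
        assert p2.onset_s - p1.offset_s >= cfg.plateau_refractory_s - 1e-9


def test_plateau_count_increases_with_oscillation_amplitude():
    counts = []
    for amp in (5.0, 6.35, 8.0):
        n = 0
        for s in range(20):
            _, gt = generate_cell_trace(GeneratorConfig(seed=s, slow_amp_mean=amp))
            n += len(gt.plateaus)
        counts.append(n)
    assert counts[0] < counts[1] < counts[2]


def test_coupled_partner_shares_rhythm_with_delay_and_attenuation():
    cfg = GeneratorConfig(seed=6, duration_s=1200.0, noise_sd=0.5,
                          slow_amp_mean=8.0, slow_amp_cv=0.3,
                          spike_threshold=-20.5, plateau_threshold=-20.2)
    traces, truths = generate_coupled_set(cfg, [CouplingConfig(0.5, 3.0, label="B31")])
    assert truths[1].latency_s == 3.0
    lead = b.standard_pipeline(traces[0])
    part = b.standard_pipeline(traces[1])
    lat = b.pair_phase_latency(lead, part, cfg.fast_period_s)
    assert lat.latency_s == pytest.approx(3.0, abs=0.5)
    a_lead = b.oscillation_amplitude(b.periodogram(lead))
    a_part = b.oscillation_amplitude(b.periodogram(part))
    # spectral density scales with amplitude squared: 0.5^2 = 0.25
    assert a_part / a_lead == pytest.approx(0.25, rel=0.2)


def test_non_coupled_control_cell_has_no_oscillation():
    cfg = GeneratorConfig(seed=7, duration_s=1200.0)
    traces, _ = generate_coupled_set(
        cfg, [CouplingConfig(0.0, 0.0, partner_has_oscillation=False, label="B8")])
    amp = b.oscillation_amplitude(b.periodogram(b.standard_pipeline(traces[1])))
    assert amp is None


def test_cohort_reproducible_and_order_independent():
    p10 = cohort_periods(10, 58.0, 13.0, master_seed=42)
    p10b = cohort_periods(10, 58.0, 13.0, master_seed=42)
    np.testing.assert_array_equal(p10, p10b)
    p5 = cohort_periods(5, 58.0, 13.0, master_seed=42)
    np.testing.assert_array_equal(p10[:5], p5)
    assert np.all((p10 >= 30.0) & (p10 <= 120.0))


def test_cohort_traces_use_drawn_periods():
    traces, truths = generate_cohort(3, 58.0, 13.0, GeneratorConfig(seed=9))
    periods = cohort_periods(3, 58.0, 13.0, master_seed=9)
    for gt, p in zip(truths, periods):
        assert gt.fast_period_s == pytest.approx(p)
    assert len({tr.metadata["cell"] for tr in traces}) == 3


def test_ca_free_outlives_ttx_for_any_seed_and_empirically():
    for s in range(10):
        base = GeneratorConfig(seed=s, duration_s=1500.0)
        ttx = apply_pharmacology(base, "TTX", t_on=300.0)
        cafree = apply_pharmacology(base, "CA_FREE", t_on=300.0)
        assert cafree.pharmacology.longevity_s() > ttx.pharmacology.longevity_s()
    # empirical: 400-700 s window is silent under TTX, still rhythmic in
    # calcium-free saline (slow run-down)
    tr_ttx, _ = generate_cell_trace(apply_pharmacology(
        GeneratorConfig(seed=0, duration_s=1500.0), "TTX", t_on=300.0))
    tr_ca, _ = generate_cell_trace(apply_pharmacology(
        GeneratorConfig(seed=0, duration_s=1500.0), "CA_FREE", t_on=300.0))

    def window_amp(tr):
        i0, i1 = int(400 * tr.sample_rate), int(700 * tr.sample_rate)
        cut = b.VoltageTrace(400.0, tr.sample_rate, tr.values[i0:i1])
        return b.oscillation_amplitude(b.periodogram(b.standard_pipeline(cut)))

    assert window_amp(tr_ttx) is None
    assert window_amp(tr_ca) is not None


def test_pharmacology_baseline_shifts_and_reversibility():
    cpa = PharmacologySchedule("CPA", t_on_s=300.0, baseline_shift_mv=2.0,
                               washout_s=900.0)
    fccp = PharmacologySchedule("FCCP", t_on_s=300.0, baseline_shift_mv=15.0,
                                washout_s=900.0)
    t_late = np.array([1400.0])
    # CPA: depolarization reverses on washout; FCCP: irreversible
    assert cpa.baseline_offset(t_late)[0] < 0.5
    assert fccp.baseline_offset(t_late)[0] == pytest.approx(15.0, abs=0.5)
    assert fccp.envelope(t_late)[0] < 0.05
    assert cpa.envelope(t_late)[0] > 0.95


def test_heparin_is_cell_specific():
    b63 = PharmacologySchedule("HEPARIN_B63", t_on_s=300.0)
    b31 = PharmacologySchedule("HEPARIN_B31", t_on_s=300.0)
    assert np.isinf(b31.longevity_s())
    assert b63.longevity_s() == pytest.approx(b63.t_block_s)
    t = np.array([1000.0])
    assert b63.envelope(t)[0] == 0.0
    assert b31.envelope(t)[0] == 1.0


def test_configuration_validation():
    with pytest.raises(ConfigError):
        GeneratorConfig(duration_s=100.0).validate()  # < 3 cycles
    with pytest.raises(ConfigError):
        GeneratorConfig(e_rev=-70.0).validate()  # no driving force
    with pytest.raises(ConfigError):
        GeneratorConfig(plateau_threshold=-55.0).validate()  # below spike th
    with pytest.raises(ConfigError):
        GeneratorConfig(slow_amp_cv=-0.1).validate()
    with pytest.raises(ConfigError):
        PharmacologySchedule("UNKNOWN", t_on_s=0.0)
    with pytest.raises(ConfigError):
        generate_coupled_set(GeneratorConfig(), [])
    with pytest.raises(ConfigError):
        CouplingConfig(coupling_coefficient=1.5).validate()


def test_ground_truth_spikes_appear_in_trace(asw_trace):
    tr, gt = asw_trace
    # at every isolated-spike time the raw trace exceeds the despiked trace
    iso = [t for t in gt.spike_times
           if not any(p.onset_s - 1 < t < p.offset_s + 1 for p in gt.plateaus)]
    assert iso, "expected isolated spikes in the default recording"
    des = b.despike(tr)
    for t in iso:
        i = int(round((t - tr.start_time) * tr.sample_rate))
        lo, hi = max(0, i - 5), i + 6
        assert (tr.values[lo:hi] - des.values[lo:hi]).max() > 20.0
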