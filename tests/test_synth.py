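"""Synthetic-generator contracts: Hill curves, pulse shape, drug effects,
trace/plate simulation, and the cell-line calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catrisk.phenotyping import phenotype
from catrisk.registry import DMSO, CellLine, Phase
from catrisk.synth import (
    CellLineProfile,
    DrugEffectModel,
    EventFlags,
    TraceConfig,
    WaveformParams,
    apply_drug_effect,
    default_profile,
    hill_effect,
    make_pulse,
    recovery_width,
    simulate_plate,
    simulate_trace,
)

from conftest import make_quiet


class TestHillEffect:
    def test_zero_dose(self):
        assert hill_effect(0.0, ec50=10.0, emax=1.0, h=2.0) == 0.0

    def test_midpoint(self):
        assert hill_effect(10.0, ec50=10.0, emax=0.8, h=1.7) == pytest.approx(0.4)

    def test_ten_times_ec50(self):
        # closed form: emax * 10 / 11 at dose = 10*ec50, h=1
        assert hill_effect(10.0, ec50=1.0, emax=1.0, h=1.0) == pytest.approx(10 / 11)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            hill_effect(-1.0, ec50=1.0, emax=1.0, h=1.0)

    @given(
        doses=st.lists(
            st.floats(min_value=0.0, max_value=1e6), min_size=2, max_size=10
        ),
        ec50=st.floats(min_value=1e-3, max_value=1e5),
        h=st.floats(min_value=0.2, max_value=4.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_dose(self, doses, ec50, h):
        doses = sorted(doses)
        values = [hill_effect(d, ec50, 1.0, h) for d in doses]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


_PARAMS = WaveformParams(
    cycle_length_mean=2.0,
    cycle_length_cv=0.0,
    amplitude=1.0,
    upstroke_time=0.2,
    plateau_time=0.3,
    decay_tau=0.25,
    baseline_level=0.5,
)


class TestMakePulse:
    def test_peak_at_upstroke_end(self):
        assert make_pulse(_PARAMS.upstroke_time, _PARAMS) == pytest.approx(1.5)

    def test_baseline_before_onset(self):
        assert make_pulse(-0.5, _PARAMS) == pytest.approx(0.5)

    def test_decay_asymptote(self):
        assert make_pulse(50.0, _PARAMS) == pytest.approx(0.5, abs=1e-9)

    def test_plateau_flat(self):
        mid = _PARAMS.upstroke_time + 0.5 * _PARAMS.plateau_time
        assert make_pulse(mid, _PARAMS) == pytest.approx(1.5)

    @pytest.mark.parametrize("frac", [0.2, 0.5, 0.8])
    def test_analytic_width_matches_dense_scan(self, frac):
        # independent oracle: scan a dense grid for the level crossings
        t = np.linspace(0.0, 6.0, 600_001)
        v = np.asarray(make_pulse(t, _PARAMS))
        level = _PARAMS.baseline_level + (1 - frac) * _PARAMS.amplitude
        above = v >= level
        idx = np.nonzero(above)[0]
        scanned = t[idx[-1]] - t[idx[0]]
        assert scanned == pytest.approx(recovery_width(_PARAMS, frac), abs=2e-5)

    def test_width80_closed_form(self):
        # f*upstroke + plateau + tau*ln(5) for the 80%-recovery width
        expected = 0.8 * 0.2 + 0.3 + 0.25 * math.log(5)
        assert recovery_width(_PARAMS, 0.8) == pytest.approx(expected)


def _drug(**overrides) -> DrugEffectModel:
    base = dict(
        compound="X",
        doses=(1.0, 10.0, 100.0, 1000.0),
        ec50_p80=10.0,
        emax_p80=0.4,
        hill_p80=1.0,
    )
    base.update(overrides)
    return DrugEffectModel(**base)


class TestApplyDrugEffect:
    def test_zero_dose_is_identity(self, control_profile):
        rng = np.random.default_rng(0)
        params, flags = apply_drug_effect(control_profile, _drug(), 0.0, rng)
        assert params == control_profile.baseline
        assert flags == EventFlags(ead=False, ceased=False)

    def test_cessation_threshold(self, control_profile):
        rng = np.random.default_rng(0)
        drug = _drug(cessation_dose=100.0)
        _, flags = apply_drug_effect(control_profile, drug, 100.0, rng)
        assert flags.ceased
        _, flags = apply_drug_effect(control_profile, drug, 99.0, rng)
        assert not flags.ceased

    def test_prolongation_at_ec50(self, control_profile):
        # emax 0.4 at the midpoint scales plateau+decay by exactly 1.2
        rng = np.random.default_rng(0)
        params, _ = apply_drug_effect(control_profile, _drug(), 10.0, rng)
        base = control_profile.baseline
        got = params.plateau_time + params.decay_tau
        assert got == pytest.approx(1.2 * (base.plateau_time + base.decay_tau))
        assert params.cycle_length_mean == pytest.approx(
            1.2 * base.cycle_length_mean
        )

    def test_amplitude_suppression(self, control_profile):
        rng = np.random.default_rng(0)
        drug = _drug(ec50_amp=10.0, emax_amp=0.5, hill_amp=1.0)
        params, _ = apply_drug_effect(control_profile, drug, 10.0, rng)
        assert params.amplitude == pytest.approx(
            0.75 * control_profile.baseline.amplitude
        )

    def test_irregularity_gain(self, control_profile):
        rng = np.random.default_rng(0)
        drug = _drug(irregularity_gain=0.4)
        params, _ = apply_drug_effect(control_profile, drug, 1000.0, rng)
        assert params.cycle_length_cv == pytest.approx(
            control_profile.baseline.cycle_length_cv + 0.4
        )

    def test_ead_probability_ramp(self, control_profile):
        drug = _drug(ead_onset_dose=100.0, ead_probability_at_top=1.0)
        rng = np.random.default_rng(0)
        _, below = apply_drug_effect(control_profile, drug, 50.0, rng)
        assert not below.ead
        # at top dose the ramp reaches probability 1 -> always flagged
        _, top = apply_drug_effect(control_profile, drug, 1000.0, rng)
        assert top.ead

    def test_negative_dose_rejected(self, control_profile):
        with pytest.raises(ValueError):
            apply_drug_effect(
                control_profile, _drug(), -1.0, np.random.default_rng(0)
            )


class TestSimulateTrace:
    def test_pulse_count_oracle(self, control_profile):
        quiet = make_quiet(control_profile, cycle_length_mean=1.2)
        trace, _ = simulate_trace(quiet, duration=60.0, seed=0)
        assert phenotype(trace).pn == 50  # floor(60 / 1.2)

    def test_same_seed_identical(self, control_profile):
        a, _ = simulate_trace(control_profile, seed=7)
        b, _ = simulate_trace(control_profile, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self, control_profile):
        a, _ = simulate_trace(control_profile, seed=7)
        b, _ = simulate_trace(control_profile, seed=8)
        assert not np.array_equal(a.values, b.values)

    def test_ceased_trace_has_no_cycles(self, control_profile):
        drug = _drug(cessation_dose=1000.0)
        trace, flags = simulate_trace(control_profile, drug, 3, seed=0)
        assert flags.ceased
        assert phenotype(trace).pn == 0

    def test_low_sampling_rate_rejected(self, control_profile):
        with pytest.raises(ValueError, match="upstroke"):
            simulate_trace(control_profile, fs=20.0, seed=0)

    def test_drift_applied(self, control_profile):
        drifting = make_quiet(control_profile, drift_per_s=0.1)
        trace, _ = simulate_trace(drifting, seed=0)
        flat, _ = simulate_trace(make_quiet(control_profile), seed=0)
        ramp = trace.values - flat.values
        np.testing.assert_allclose(ramp, 0.1 * trace.times, atol=1e-9)


class TestSimulatePlate:
    def test_counting_oracle(self, registry):
        traces, platemap, _ = simulate_plate(
            registry, lines=[CellLine.CONTROL], replicates=6,
            duration=12.0, seed=0,
        )
        # 11 compounds x 4 doses x 6 wells + 6 DMSO wells, pre+post each
        assert len(traces) == 2 * (11 * 4 * 6 + 6)
        assert len(platemap) == len(traces)

    def test_single_well_case(self, registry):
        traces, platemap, _ = simulate_plate(
            registry[:1], lines=[CellLine.CONTROL], replicates=1,
            duration=12.0, seed=0,
        )
        non_dmso = [t for t in traces if t.meta.compound != DMSO]
        assert len(non_dmso) == 2 * 4  # one well per dose, pre + post

    def test_master_seed_determinism(self, registry):
        kwargs = dict(lines=[CellLine.CONTROL], replicates=2, duration=12.0)
        a, pm_a, fl_a = simulate_plate(registry[:2], seed=5, **kwargs)
        b, pm_b, fl_b = simulate_plate(registry[:2], seed=5, **kwargs)
        assert pm_a.entries == pm_b.entries
        assert fl_a == fl_b
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.values, tb.values)

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            simulate_plate([], seed=0)


class TestCalibration:
    """The shipped baselines must reproduce the target mean P80 values."""

    @pytest.mark.parametrize(
        "line,target,tol",
        [(CellLine.CONTROL, 0.70, 0.04), (CellLine.PROGERIA, 0.98, 0.05)],
    )
    def test_mean_p80(self, line, target, tol):
        profile = default_profile(line)
        p80s = []
        for child in np.random.SeedSequence(123).spawn(100):
            trace, _ = simulate_trace(profile, seed=np.random.default_rng(child))
            p80s.append(phenotype(trace).p80)
        assert np.nanmean(p80s) == pytest.approx(target, abs=tol)

    def test_dose_monotonicity_noiseless(self, control_profile):
        # EAD disabled: monotone prolongation must give monotone mean P80
        drug = _drug(emax_p80=0.8)
        quiet = make_quiet(control_profile)
        means = []
        for dose_index in range(4):
            trace, _ = simulate_trace(quiet, drug, dose_index, seed=0)
            means.append(phenotype(trace).p80)
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_dmso_conservation_noiseless(self, quiet_control):
        pre, _ = simulate_trace(quiet_control, seed=11)
        post, _ = simulate_trace(quiet_control, seed=99)
        from catrisk.phenotyping import percent_change

        change = percent_change(phenotype(post), phenotype(pre))
        np.testing.assert_array_equal(change.as_array(), np.zeros(6))

    def test_dmso_conservation_noisy(self, control_profile):
        from catrisk.phenotyping import percent_change

        changes = []
        for child in np.random.SeedSequence(3).spawn(30):
            rng = np.random.default_rng(child)
            pre, _ = simulate_trace(control_profile, seed=rng)
            post, _ = simulate_trace(control_profile, seed=rng)
            changes.append(
                percent_change(phenotype(post), phenotype(pre)).as_array()
            )
        mean_change = np.mean(changes, axis=0)
        # p80, r82, cl, amp, pn stay within tight noise bounds; csd is a
        # ratio of noisy small std estimates (Jensen-biased upward), so
        # its bound is wider
        assert np.all(np.abs(mean_change[:5]) < 5.0)
        assert abs(mean_change[5]) < 30.0


class TestWaveformParamsValidation:
    def test_cycle_shorter_than_pulse_rejected(self):
        with pytest.raises(ValueError):
            WaveformParams(
                cycle_length_mean=0.3,
                cycle_length_cv=0.0,
                amplitude=1.0,
                upstroke_time=0.2,
                plateau_time=0.2,
                decay_tau=0.1,
            )

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            WaveformParams(
                cycle_length_mean=1.0,
                cycle_length_cv=0.0,
                amplitude=1.0,
                upstroke_time=0.1,
                plateau_time=0.1,
                decay_tau=0.1,
                noise_sd=-0.1,
            )
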