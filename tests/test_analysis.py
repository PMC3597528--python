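import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgcds import analysis
from rgcds.engine import Trace
from rgcds.synthetic_data import SyntheticEPSPSpec, SyntheticProtocolSpec, biexp_waveform, make_epsp


def _trace(values, dt=0.1, onsets=(0.0,), vrest=None):
    values = np.asarray(values, dtype=float)
    return Trace(
        np.arange(len(values)) * dt,
        values,
        annotations={"stimulus_onsets": list(onsets)},
        vrest=vrest,
    )


def _biexp_trace(amplitude=2.0, tau_rise=20.0, tau_fall=109.0, vrest=-65.0,
                 pre=100.0, post=700.0, dt=0.1):
    t = np.arange(0.0, pre + post, dt)
    v = vrest + biexp_waveform(t - pre, amplitude, tau_rise, tau_fall)
    return Trace(t, v, annotations={"stimulus_onsets": [pre]}, vrest=vrest)


class TestSummationRatio:
    def test_triple_charge_is_linear(self):
        single = _biexp_trace(amplitude=2.0)
        summed = _biexp_trace(amplitude=6.0)
        # same waveform scaled x3: charge exactly 3x, ratio 1
        r = analysis.summation_ratio(summed, single, 3, "charge")
        assert r == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("delay", [10.0, 50.0, 125.0])
    def test_superposition_of_three_singles_has_unit_charge_ratio(self, delay):
        dt, pre = 0.1, 100.0
        t = np.arange(0.0, pre + 700.0 + 2 * delay, dt)
        single_wave = biexp_waveform(t - pre, 2.0, 20.0, 109.0)
        summed_wave = sum(
            biexp_waveform(t - (pre + k * delay), 2.0, 20.0, 109.0) for k in range(3)
        )
        onsets = [pre + k * delay for k in range(3)]
        single = Trace(t, -65 + single_wave, annotations={"stimulus_onsets": [pre]})
        summed = Trace(t, -65 + summed_wave, annotations={"stimulus_onsets": onsets})
        r = analysis.summation_ratio(summed, single, 3, "charge")
        assert r == pytest.approx(1.0, abs=0.01)

    def test_charge_ratio_of_4_17x_is_1_39(self):
        single = _biexp_trace()
        summed = _biexp_trace(amplitude=2.0 * 4.17)
        r = analysis.summation_ratio(summed, single, 3, "charge")
        assert r == pytest.approx(4.17 / 3.0, rel=1e-9)
        assert r == pytest.approx(1.39, abs=0.01)

    def test_baseline_offset_invariance(self):
        single = _biexp_trace(vrest=-65.0)
        summed = _biexp_trace(amplitude=4.0, vrest=-65.0)
        r0 = analysis.summation_ratio(summed, single, 3, "charge")
        single_up = _biexp_trace(vrest=-55.0)
        summed_up = _biexp_trace(amplitude=4.0, vrest=-55.0)
        r1 = analysis.summation_ratio(summed_up, single_up, 3, "charge")
        assert r1 == pytest.approx(r0, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        amp=st.floats(0.5, 5.0),
        offset=st.floats(-30.0, 30.0),
    )
    def test_ratio_invariant_to_common_baseline_offset(self, amp, offset):
        single = _biexp_trace(amplitude=amp, vrest=-65.0)
        summed = _biexp_trace(amplitude=2.4 * amp, vrest=-65.0)
        single_s = _biexp_trace(amplitude=amp, vrest=-65.0 + offset)
        summed_s = _biexp_trace(amplitude=2.4 * amp, vrest=-65.0 + offset)
        r0 = analysis.summation_ratio(summed, single, 3, "charge")
        r1 = analysis.summation_ratio(summed_s, single_s, 3, "charge")
        assert r1 == pytest.approx(r0, rel=1e-9)

    def test_zero_single_is_undefined(self):
        flat = _trace(np.full(2000, -65.0), vrest=-65.0)
        summed = _biexp_trace()
        with pytest.raises(ValueError, match="undefined"):
            analysis.summation_ratio(summed, flat, 3, "charge")


class TestDirectionalSelectivity:
    def test_identical_traces_give_zero(self):
        a = _biexp_trace()
        b = _biexp_trace()
        assert analysis.directional_selectivity(a, b, "amplitude") == pytest.approx(0.0)
        assert analysis.directional_selectivity(a, b, "charge") == pytest.approx(0.0)

    def test_amplitude_formula_arithmetic(self):
        # Vpeak_away -60, Vpeak_toward -61, Vrest -66 -> (1/5)*100 = 20%
        away = _biexp_trace(amplitude=6.0, vrest=-66.0)
        toward = _biexp_trace(amplitude=5.0, vrest=-66.0)
        ds = analysis.directional_selectivity(away, toward, "amplitude", vrest=-66.0)
        assert ds == pytest.approx(20.0, rel=1e-6)

    def test_charge_formula_arithmetic(self):
        away = _biexp_trace(amplitude=1.2)
        toward = _biexp_trace(amplitude=1.0)
        ds = analysis.directional_selectivity(away, toward, "charge", vrest=-65.0)
        assert ds == pytest.approx(20.0, rel=1e-6)

    def test_charge_antisymmetry_relation(self):
        """Swapping the inputs obeys the exact algebraic relation
        ds(a,b) = -ds(b,a) * (Q_a / Q_b), not a naive sign flip."""
        away = _biexp_trace(amplitude=1.7)
        toward = _biexp_trace(amplitude=1.1)
        q_a = analysis.charge(away, baseline=-65.0)
        q_b = analysis.charge(toward, baseline=-65.0)
        ds_ab = analysis.directional_selectivity(away, toward, "charge", vrest=-65.0)
        ds_ba = analysis.directional_selectivity(toward, away, "charge", vrest=-65.0)
        assert ds_ab != pytest.approx(-ds_ba)  # not naively antisymmetric
        assert ds_ab == pytest.approx(-ds_ba * (q_a / q_b), rel=1e-9)


class TestKinetics:
    def test_biexponential_oracle(self):
        """Rise and decay of an ideal bi-exponential match values computed
        from a dense evaluation of the closed form."""
        tau_rise, tau_fall = 5.0, 109.0
        tr = _biexp_trace(tau_rise=tau_rise, tau_fall=tau_fall, dt=0.05)
        k = analysis.epsp_kinetics(tr)
        # oracle: dense closed-form crossing times
        tt = np.linspace(0, 800, 400001)
        w = biexp_waveform(tt, 1.0, tau_rise, tau_fall)
        peak = w.max()
        i_peak = w.argmax()
        t10 = tt[:i_peak][np.argmax(w[:i_peak] >= 0.1 * peak)]
        t90 = tt[:i_peak][np.argmax(w[:i_peak] >= 0.9 * peak)]
        assert k.rise_10_90 == pytest.approx(t90 - t10, rel=0.01, abs=0.1)
        assert k.decay_time == pytest.approx(tau_fall, rel=0.01)

    def test_step_trace_rise_time_is_subsample(self):
        v = np.full(3000, -65.0)
        v[1000:] = -60.0
        tr = _trace(v, onsets=(100.0,), vrest=-65.0)
        k = analysis.epsp_kinetics(tr)
        assert k.rise_10_90 <= tr.dt
        assert np.isnan(k.decay_time)  # a sustained step has no decay

    def test_amplitude_rescaling_invariance(self):
        k1 = analysis.epsp_kinetics(_biexp_trace(amplitude=1.0))
        k2 = analysis.epsp_kinetics(_biexp_trace(amplitude=3.5))
        assert k1.rise_10_90 == pytest.approx(k2.rise_10_90, rel=1e-6)
        assert k1.decay_time == pytest.approx(k2.decay_time, rel=1e-6)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            analysis.epsp_kinetics(_trace(np.full(2000, -65.0), vrest=-65.0))


class TestSpikeProbability:
    def test_fraction_of_suprathreshold_trials(self):
        supra = _trace(np.concatenate([np.full(100, -65.0), np.full(5, -10.0),
                                       np.full(100, -65.0)]))
        sub = _trace(np.full(205, -65.0))
        trials = [supra, supra] + [sub] * 6
        p = analysis.spike_probability(trials, dvdt_threshold=None)
        assert p == pytest.approx(0.25)

    def test_all_subthreshold_is_zero(self):
        sub = _trace(np.full(200, -65.0))
        assert analysis.spike_probability([sub] * 5, dvdt_threshold=None) == 0.0

    def test_dvdt_rule_detects_fast_event(self):
        v = np.full(200, -65.0)
        v[100] = -55.0  # 10 mV in one 0.1 ms sample = 100 mV/ms
        p = analysis.spike_probability([_trace(v)], v_threshold=-20.0,
                                       dvdt_threshold=20.0)
        assert p == 1.0


class TestGaussianResolution:
    def test_fwhm_identity(self):
        sigma = 2.42
        x = np.linspace(-8, 8, 17)
        y = 30.0 * np.exp(-(x**2) / (2 * sigma**2))
        w = analysis.gaussian_resolution_fit(x, y)
        assert w == pytest.approx(2.3548 * sigma, rel=1e-4)
        assert w == pytest.approx(5.7, abs=0.05)

    def test_translation_invariance(self):
        sigma = 3.0
        x = np.linspace(0, 30, 25)
        y = 10.0 * np.exp(-((x - 11.0) ** 2) / (2 * sigma**2))
        w1 = analysis.gaussian_resolution_fit(x, y)
        w2 = analysis.gaussian_resolution_fit(x + 100.0, y)
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_constant_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            analysis.gaussian_resolution_fit(np.arange(6.0), np.ones(6))


class TestTailCurrentIV:
    def _step_trace(self, level, step):
        t = np.arange(0.0, 20.0, 0.05)
        tr = Trace(t, np.full_like(t, level), units="pA")
        tr.annotations.update(step_mV=step, step_off_ms=0.0, holding_current=0.0)
        return tr

    def test_identical_conditions_give_zeros(self):
        steps = [-100, -80, -60]
        ctl = [self._step_trace(5.0, s) for s in steps]
        iv = analysis.tail_current_iv(ctl, [self._step_trace(5.0, s) for s in steps], steps)
        np.testing.assert_allclose(iv["tail_pA"], 0.0, atol=1e-12)

    def test_normalization_maps_largest_step_to_one(self):
        steps = [-100, -80, -60]
        ctl = [self._step_trace(a, s) for a, s in zip((-10.0, -5.0, -1.0), steps)]
        blk = [self._step_trace(0.0, s) for s in steps]
        iv = analysis.tail_current_iv(ctl, blk, steps)
        assert iv["normalized"].max() == pytest.approx(1.0)
        assert iv.loc[iv.step_mV == -100, "normalized"].iloc[0] == pytest.approx(1.0)

    def test_mismatched_steps_rejected(self):
        with pytest.raises(ValueError):
            analysis.tail_current_iv([self._step_trace(1, -80)], [], [-80])
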