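"""Spike detection and feature definitions: closed-form waveforms, hand-
computed statistics, and simulator oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ephysdecomp import Protocol, Trace, simulate_neuron
from ephysdecomp.protocol import Epoch
from ephysdecomp.spikes import (
    SweepFeatures,
    adaptation_index,
    ap_features,
    detect_spikes,
    fi_curve,
    passive_props,
    rheobase,
    sweep_features,
)


def triangle_trace(onset_ms=10.0, rise_ms=1.0, fall_ms=1.0, peak=100.0,
                   base=0.0, dt=0.02, total_ms=40.0):
    """Isosceles-triangle 'spike' on a flat baseline."""
    t = np.arange(0.0, total_ms, dt)
    v = np.full(t.size, base)
    up = (t >= onset_ms) & (t < onset_ms + rise_ms)
    v[up] = base + (t[up] - onset_ms) / rise_ms * (peak - base)
    dn = (t >= onset_ms + rise_ms) & (t <= onset_ms + rise_ms + fall_ms)
    v[dn] = peak - (t[dn] - onset_ms - rise_ms) / fall_ms * (peak - base)
    return Trace(dt_ms=dt, signal=v, command=np.zeros_like(v),
                 mode="current_clamp")


def make_sweep(count, current):
    return SweepFeatures(spike_count=count, latency_ms=math.nan, isis_ms=[],
                         adaptation_index=math.nan,
                         firing_rate_hz=float(count), step_current=current)


class TestTriangleGeometry:
    def test_fwhm_of_unit_triangle_is_half_its_base(self):
        """A 2 ms isosceles triangle from 0 to 100 mV has FWHM 1.0 ms."""
        tr = triangle_trace()
        f = ap_features(tr, onset_index=int(10.0 / 0.02), baseline_v=0.0)
        assert f.fwhm_ms == pytest.approx(1.0, abs=1e-9)

    def test_rise_time_20_80_of_linear_ramp(self):
        """20%-80% of a linear 1 ms rise is 0.6 ms."""
        tr = triangle_trace()
        f = ap_features(tr, onset_index=int(10.0 / 0.02), baseline_v=0.0)
        assert f.rise_time_20_80_ms == pytest.approx(0.6, abs=1e-9)

    def test_decay_time_to_37_percent_remaining(self):
        """On a linear 1 ms fall to the post-spike minimum, the 37%-remaining
        level is reached after 63% of the fall: 0.63 ms."""
        tr = triangle_trace()
        f = ap_features(tr, onset_index=int(10.0 / 0.02), baseline_v=0.0)
        assert f.decay_time_37_ms == pytest.approx(0.63, abs=0.005)

    def test_amplitude_references_the_baseline(self):
        tr = triangle_trace(base=0.0, peak=100.0)
        f = ap_features(tr, onset_index=int(10.0 / 0.02), baseline_v=-5.0)
        assert f.amplitude == pytest.approx(105.0, abs=1e-9)


class TestAdaptationIndex:
    def test_hand_computed_example(self):
        """ISIs [10,10,10,20,40]: skip two, pairs (10,20) and (20,40) give
        (10/30 + 20/60)/2 = 1/3."""
        assert adaptation_index([10.0, 10.0, 10.0, 20.0, 40.0]) == pytest.approx(1.0 / 3.0)

    def test_constant_train_has_zero_adaptation(self):
        assert adaptation_index([7.0] * 8) == 0.0

    def test_undefined_below_four_isis(self):
        assert math.isnan(adaptation_index([10.0, 12.0, 14.0]))

    @given(st.lists(st.floats(min_value=1.0, max_value=100.0), min_size=2,
                    max_size=12))
    def test_pairwise_statistic_is_antisymmetric_under_reversal(self, isis):
        """Reversing an ISI sequence negates the pairwise-normalized mean
        (checked on the raw statistic, i.e. without the initial skip)."""
        fwd = adaptation_index(isis, skip=0)
        rev = adaptation_index(isis[::-1], skip=0)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestDetection:
    def test_flat_trace_has_no_spikes(self):
        tr = Trace(dt_ms=0.02, signal=np.full(5000, -65.0),
                   command=np.zeros(5000), mode="current_clamp")
        assert detect_spikes(tr) == []

    def test_voltage_clamp_trace_rejected(self):
        tr = Trace(dt_ms=0.02, signal=np.zeros(100), command=np.zeros(100),
                   mode="voltage_clamp")
        with pytest.raises(ValueError, match="current-clamp"):
            detect_spikes(tr)

    def test_subvalidation_excursion_rejected(self):
        """A spike-shaped transient peaking at -40 mV is not an AP under the
        default -20 mV validation level."""
        tr = triangle_trace(base=-65.0, peak=-40.0)
        assert detect_spikes(tr) == []
        tall = triangle_trace(base=-65.0, peak=0.0)
        assert len(detect_spikes(tall)) == 1

    def test_count_matches_zero_crossing_oracle(self, step_family,
                                                step_family_clean,
                                                step_protocol):
        """Detected spike count on the 250 pA sweep equals the number of
        upward 0 mV crossings of the noise-free ground-truth voltage."""
        traces, _ = step_family
        _, gt = step_family_clean
        idx = list(step_protocol.sweep_levels).index(250.0)
        ep = step_protocol.step_epoch()
        dt = step_protocol.dt_ms
        sl = slice(int(ep.start_ms / dt), int(ep.end_ms / dt))
        v = gt.sweeps[idx].v[sl]
        crossings = int(np.sum((v[:-1] < 0.0) & (v[1:] >= 0.0)))
        onsets = np.array(detect_spikes(traces[idx])) * dt
        inside = np.sum((onsets >= ep.start_ms) & (onsets < ep.end_ms))
        assert inside == crossings


class TestFeatureRobustness:
    def test_noisy_and_clean_features_agree(self, step_family,
                                            step_family_clean, step_protocol):
        """FWHM and amplitude from the noisy recording (0.2 mV SD) are
        within 5% of the values from the noise-free voltage."""
        idx = list(step_protocol.sweep_levels).index(250.0)
        ep = step_protocol.step_epoch()
        out = []
        for traces, _ in (step_family, step_family_clean):
            tr = traces[idx]
            base_sl = tr.slice_ms(ep.start_ms - 50.0, ep.start_ms)
            base = float(np.mean(tr.signal[base_sl]))
            onsets = detect_spikes(tr)
            f = ap_features(tr, onsets[0], base, next_onset_index=onsets[1])
            out.append(f)
        noisy, clean = out
        assert noisy.fwhm_ms == pytest.approx(clean.fwhm_ms, rel=0.05)
        assert noisy.amplitude == pytest.approx(clean.amplitude, rel=0.05)

    def test_refining_dt_barely_moves_features(self, model):
        """Doubling the sampling rate changes FWHM/rise/decay by less than
        two samples of the coarse (50 kHz) grid."""
        feats = {}
        for rate in (50_000.0, 100_000.0):
            proto = Protocol(
                mode="current_clamp", holding=0.0, duration_ms=300.0,
                epochs=[Epoch(50.0, 250.0)], sweep_levels=[250.0],
                sample_rate_hz=rate,
            )
            traces, _ = simulate_neuron(model, proto, noise_sd=0.0, seed=0)
            tr = traces[0]
            onsets = detect_spikes(tr)
            nxt = onsets[1] if len(onsets) > 1 else None
            feats[rate] = ap_features(tr, onsets[0], -65.0, next_onset_index=nxt)
        coarse_2dt = 2 * (1000.0 / 50_000.0)
        for attr in ("fwhm_ms", "rise_time_20_80_ms", "decay_time_37_ms"):
            a = getattr(feats[50_000.0], attr)
            b = getattr(feats[100_000.0], attr)
            assert abs(a - b) < coarse_2dt


class TestSweepFeaturesAndRheobase:
    def test_latency_is_step_onset_to_first_ap_onset(self, step_family,
                                                     step_protocol):
        traces, _ = step_family
        idx = list(step_protocol.sweep_levels).index(250.0)
        sf = sweep_features(traces[idx], step_protocol)
        onsets = np.array(detect_spikes(traces[idx])) * step_protocol.dt_ms
        first = onsets[onsets >= step_protocol.step_epoch().start_ms][0]
        assert sf.latency_ms == pytest.approx(
            first - step_protocol.step_epoch().start_ms
        )
        assert sf.spike_count == len(sf.isis_ms) + 1
        assert sf.firing_rate_hz == pytest.approx(sf.spike_count / 1.0)

    def test_empty_sweep_is_flagged_not_an_error(self, step_family,
                                                 step_protocol):
        traces, _ = step_family
        sf = sweep_features(traces[0], step_protocol)  # -200 pA
        assert sf.spike_count == 0
        assert math.isnan(sf.latency_ms)
        assert math.isnan(sf.adaptation_index)

    def test_rheobase_definition_and_absence(self):
        sweeps = [(c, make_sweep(n, c)) for c, n in
                  [(-50.0, 0), (0.0, 0), (50.0, 0), (100.0, 2), (150.0, 5)]]
        assert rheobase(sweeps) == 100.0
        silent = [(c, make_sweep(0, c)) for c in (0.0, 50.0)]
        assert math.isnan(rheobase(silent))
        with pytest.raises(ValueError):
            rheobase([])

    def test_rheobase_order_invariant(self, rng):
        sweeps = [(c, make_sweep(int(c > 120), c))
                  for c in np.arange(-200.0, 401.0, 50.0)]
        expected = rheobase(sweeps)
        for _ in range(5):
            rng.shuffle(sweeps)
            assert rheobase(sweeps) == expected

    def test_rheobase_matches_ground_truth_on_simulated_grid(
            self, step_family, step_protocol, step_family_clean):
        traces, _ = step_family
        _, gt = step_family_clean
        sweeps = [sweep_features(tr, step_protocol) for tr in traces]
        assert rheobase(sweeps) == gt.true_rheobase_pa


class TestPassiveProps:
    @staticmethod
    def _pulse_trace(g_l, C, pulse_pa=-50.0, pulse_ms=10.0):
        from ephysdecomp import NeuronModel

        m = NeuronModel(C=C, g_Na=0.0, g_DR=0.0, g_A=0.0, g_L=g_l, E_L=-70.0)
        proto = Protocol(
            mode="current_clamp", holding=0.0, duration_ms=120.0,
            epochs=[Epoch(100.0, 100.0 + pulse_ms, level=pulse_pa)],
        )
        traces, _ = simulate_neuron(m, proto, noise_sd=0.0, seed=0)
        return traces[0]

    def test_leak_only_input_resistance_is_ohms_law(self):
        tr = self._pulse_trace(g_l=10.0, C=100.0)
        pp = passive_props(tr, pulse_start_ms=100.0)
        assert pp.r_in_mohm == pytest.approx(100.0, rel=0.01)

    def test_leak_only_time_constant_is_c_over_g(self):
        tr = self._pulse_trace(g_l=10.0, C=100.0)
        pp = passive_props(tr, pulse_start_ms=100.0)
        assert pp.tau_m_ms == pytest.approx(10.0, rel=0.01)
        assert pp.rmp_mv == pytest.approx(-70.0, abs=0.05)

    def test_asymptote_agrees_with_long_pulse(self, model):
        """R_in from the 10 ms pulse (fitted asymptote) is within 10% of the
        value from a 10x longer pulse on the full model."""
        r = {}
        for dur in (10.0, 100.0):
            proto = Protocol(
                mode="current_clamp", holding=0.0, duration_ms=150.0 + dur,
                epochs=[Epoch(100.0, 100.0 + dur, level=-50.0)],
            )
            traces, _ = simulate_neuron(model, proto, noise_sd=0.0, seed=0)
            r[dur] = passive_props(traces[0], pulse_start_ms=100.0,
                                   pulse_dur_ms=dur).r_in_mohm
        assert r[10.0] == pytest.approx(r[100.0], rel=0.10)

    def test_spikes_in_pulse_window_rejected(self, step_family, step_protocol):
        traces, _ = step_family
        idx = list(step_protocol.sweep_levels).index(300.0)
        tr = traces[idx]
        onset_ms = detect_spikes(tr)[3] * tr.dt_ms
        with pytest.raises(ValueError, match="spike"):
            passive_props(tr, pulse_start_ms=onset_ms - 1.0)


class TestFICurve:
    def test_rates_from_simulated_family_are_sane(self, step_family,
                                                  step_protocol):
        traces, _ = step_family
        sweeps = [sweep_features(tr, step_protocol) for tr in traces]
        fic = fi_curve(sweeps)
        assert np.all(np.diff(fic.currents_pa) > 0)
        assert np.all(fic.rates_hz >= 0)
        sub = fic.rates_hz[fic.currents_pa < fic.rheobase_pa]
        assert np.all(sub == 0)
        supra = fic.rates_hz[fic.currents_pa >= fic.rheobase_pa][:3]
        assert np.all(np.diff(supra) >= 0)

    def test_halved_step_duration_doubles_rate_at_fixed_count(self):
        a = SweepFeatures(3, 1.0, [1.0, 1.0], 0.0, 3 / 1.0, 100.0)
        b = SweepFeatures(3, 1.0, [1.0, 1.0], 0.0, 3 / 0.5, 100.0)
        assert b.firing_rate_hz == 2 * a.firing_rate_hz

    def test_duplicate_currents_rejected(self):
        with pytest.raises(ValueError):
            fi_curve([make_sweep(0, 50.0), make_sweep(1, 50.0)])
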