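"""Simulator: closed-form limits, determinism, charge balance, ground truth."""

import numpy as np
import pytest

from ephysdecomp import (
    NeuronModel,
    Protocol,
    current_step_protocol,
    simulate_event_trace,
    simulate_neuron,
    synth_ais_profile,
)
from ephysdecomp.model import apply_pharmacology
from ephysdecomp.protocol import Epoch
from ephysdecomp.signal_utils import smoothed_derivative
from ephysdecomp.simulate import analytic_edge_crossings, resting_potential


def leak_only(g_l=10.0, C=100.0, e_l=-70.0):
    return NeuronModel(C=C, g_Na=0.0, g_DR=0.0, g_A=0.0, g_L=g_l, E_L=e_l)


class TestPassiveLimits:
    def test_leak_only_step_is_single_exponential(self):
        """With only the leak conductance, a current step charges the
        membrane exponentially with tau = C/g_L and dV_ss = I/g_L."""
        m = leak_only(g_l=10.0, C=100.0)  # tau 10 ms, R_in 100 MOhm
        proto = Protocol(
            mode="current_clamp", holding=0.0, duration_ms=300.0,
            epochs=[Epoch(50.0, 250.0)], sweep_levels=[100.0],
        )
        traces, _ = simulate_neuron(m, proto, noise_sd=0.0, seed=0)
        v = traces[0].signal
        dt = traces[0].dt_ms
        t = traces[0].time_ms
        sel = (t >= 50.0) & (t < 250.0)
        trel = t[sel] - 50.0
        pred = -70.0 + 10.0 * (1.0 - np.exp(-trel / 10.0))  # 100 pA * 100 MOhm
        assert np.max(np.abs(v[sel] - pred)) < 0.02
        assert abs(v[int(49.0 / dt)] - (-70.0)) < 1e-6

    def test_default_model_rests_in_physiological_band(self, model):
        v_rest = resting_potential(model)
        assert -75.0 <= v_rest <= -60.0

    def test_hyperpolarizing_step_has_no_spikes(self, model):
        proto = Protocol(
            mode="current_clamp", holding=0.0, duration_ms=1200.0,
            epochs=[Epoch(100.0, 1100.0)], sweep_levels=[-200.0],
        )
        traces, gt = simulate_neuron(model, proto, noise_sd=0.0, seed=0)
        assert traces[0].signal.max() < -60.0
        assert gt.spiking_levels == []


class TestDeterminismAndNoise:
    def test_same_seed_bit_identical(self, model):
        proto = current_step_protocol(
            start_pa=100.0, stop_pa=150.0, step_dur_ms=300.0,
            passive_pulse=False, tail_ms=50.0,
        )
        a, _ = simulate_neuron(model, proto, noise_sd=0.3, seed=9)
        b, _ = simulate_neuron(model, proto, noise_sd=0.3, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.signal, tb.signal)
            assert np.array_equal(ta.command, tb.command)

    def test_ground_truth_is_noise_free(self, model):
        proto = current_step_protocol(
            start_pa=0.0, stop_pa=0.0, step_dur_ms=200.0,
            passive_pulse=False, tail_ms=50.0,
        )
        t1, g1 = simulate_neuron(model, proto, noise_sd=0.5, seed=1)
        t2, g2 = simulate_neuron(model, proto, noise_sd=0.5, seed=2)
        assert not np.array_equal(t1[0].signal, t2[0].signal)
        assert np.array_equal(g1.sweeps[0].v, g2.sweeps[0].v)

    def test_negative_noise_rejected(self, model, step_protocol):
        with pytest.raises(ValueError):
            simulate_neuron(model, step_protocol, noise_sd=-1.0, seed=0)


class TestChargeBalance:
    def test_recorded_currents_balance_capacitive_current(self, model,
                                                          step_family_clean):
        """C dV/dt + sum(I_ion) - I_inj vanishes at every sample (away from
        the command-step discontinuities, where the derivative stencil
        straddles the jump)."""
        traces, gt = step_family_clean
        proto = traces[0].meta["protocol"]
        dt = traces[0].dt_ms
        guard = int(round(0.5 / dt))
        edges = []
        for ep in proto.epochs:
            edges += [int(ep.start_ms / dt), int(ep.end_ms / dt)]
        for sweep in (gt.sweeps[3], gt.sweeps[9], gt.sweeps[-1]):
            dvdt = smoothed_derivative(sweep.v, dt, window=7, polyorder=5)
            resid = model.C * dvdt + sweep.i_total - sweep.i_inj
            mask = np.ones(resid.size, bool)
            for e in edges:
                mask[max(0, e - guard):e + guard] = False
            scale = max(np.max(np.abs(sweep.i_total)), 100.0)
            assert np.max(np.abs(resid[mask])) < 0.01 * scale


class TestRheobaseGroundTruth:
    def test_true_rheobase_matches_per_level_resimulation(self, model,
                                                          step_family_clean):
        """Ground-truth rheobase equals the smallest level that spikes when
        each grid level is re-simulated independently (brute force)."""
        _, gt = step_family_clean
        assert gt.true_rheobase_pa is not None
        levels = np.arange(-200.0, 401.0, 50.0)
        brute = None
        for lev in levels:
            proto = Protocol(
                mode="current_clamp", holding=0.0, duration_ms=1300.0,
                epochs=[Epoch(100.0, 1100.0)], sweep_levels=[lev],
            )
            traces, _ = simulate_neuron(model, proto, noise_sd=0.0, seed=0)
            sl = traces[0].slice_ms(100.0, 1100.0)
            v = traces[0].signal[sl]
            if np.any((v[:-1] < 0.0) & (v[1:] >= 0.0)):
                brute = lev
                break
        assert brute == gt.true_rheobase_pa


class TestPharmacology:
    def test_ttx_blocks_sodium_and_abolishes_spiking(self, model):
        blocked = apply_pharmacology(model, "TTx", 1.0)
        assert blocked.g_Na == 0.0
        assert model.g_Na > 0  # input untouched
        proto = current_step_protocol(
            start_pa=400.0, stop_pa=400.0, step_dur_ms=500.0,
            passive_pulse=False, tail_ms=50.0,
        )
        _, gt = simulate_neuron(blocked, proto, noise_sd=0.0, seed=0)
        assert gt.spiking_levels == []

    def test_4ap_zero_block_is_identity(self, model):
        assert apply_pharmacology(model, "4AP", 0.0) == model

    def test_partial_block_scales_conductance(self, model):
        assert apply_pharmacology(model, "4AP", 0.25).g_A == pytest.approx(
            0.75 * model.g_A
        )

    def test_unknown_drug_lists_supported(self, model):
        with pytest.raises(ValueError, match="TTx"):
            apply_pharmacology(model, "apamin", 1.0)


class TestFwhmMonotoneInGA:
    def test_more_a_current_narrows_the_spike(self, model):
        """AP full width at half maximum decreases strictly as the A-type
        conductance grows from its default to twice its default."""
        from ephysdecomp.spikes import ap_features, detect_spikes

        proto = Protocol(
            mode="current_clamp", holding=0.0, duration_ms=400.0,
            epochs=[Epoch(100.0, 350.0)], sweep_levels=[300.0],
        )
        widths = []
        for scale in (1.0, 1.5, 2.0):
            m = model.with_(g_A=model.g_A * scale)
            traces, _ = simulate_neuron(m, proto, noise_sd=0.0, seed=0)
            tr = traces[0]
            onsets = detect_spikes(tr)
            assert onsets, f"no spikes at g_A scale {scale}"
            nxt = onsets[1] if len(onsets) > 1 else None
            f = ap_features(tr, onsets[0], baseline_v=-65.0, next_onset_index=nxt)
            widths.append(f.fwhm_ms)
        assert widths[0] > widths[1] > widths[2]


class TestEventGenerator:
    def test_zero_rate_gives_flat_baseline(self):
        tr, gt = simulate_event_trace(0.0, -30.0, 0.2, 0.5, 5.0, 5.0,
                                      noise_sd=0.0, seed=0)
        assert gt.event_times_s.size == 0
        assert np.allclose(tr.signal, 0.0)

    def test_poisson_count_statistics(self):
        """2 Hz for 120 s: the generated count is within 3 sigma of 240."""
        _, gt = simulate_event_trace(2.0, -30.0, 0.2, 0.5, 5.0, 120.0,
                                     noise_sd=0.0, seed=7)
        n = gt.event_times_s.size
        assert abs(n - 240) <= 3 * np.sqrt(240)

    def test_zero_cv_makes_all_amplitudes_equal(self):
        _, gt = simulate_event_trace(5.0, -30.0, 0.0, 0.5, 5.0, 10.0,
                                     noise_sd=0.0, seed=3)
        assert gt.event_times_s.size > 0
        assert np.allclose(gt.event_amplitudes, -30.0)

    def test_bad_kinetics_rejected(self):
        with pytest.raises(ValueError):
            simulate_event_trace(1.0, -30.0, 0.2, 5.0, 0.5, 10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_event_trace(1.0, -30.0, 0.2, 0.5, 5.0, -1.0, seed=0)


class TestAisProfileGenerator:
    def test_boxcar_limit(self):
        prof = synth_ais_profile(5.0, 25.0, edge_sd_um=0.0, noise_sd=0.0,
                                 step_um=0.1)
        x, y = prof.distance_um, prof.intensity
        inside = (x >= 5.0) & (x <= 25.0)
        assert np.all(y[inside] == y.max())
        assert np.all(y[~inside] == y.min())

    def test_analytic_crossings_match_erf_profile(self):
        """Closed-form threshold crossings of a Gaussian-edged plateau."""
        prof = synth_ais_profile(5.0, 25.0, edge_sd_um=1.0, noise_sd=0.0,
                                 step_um=0.01)
        x1, x2 = analytic_edge_crossings(5.0, 25.0, 1.0, 0.33)
        norm = (prof.intensity - prof.intensity.min()) / (
            prof.intensity.max() - prof.intensity.min()
        )
        above = norm >= 0.33
        first = prof.distance_um[np.argmax(above)]
        last = prof.distance_um[len(above) - 1 - np.argmax(above[::-1])]
        assert first == pytest.approx(x1, abs=0.02)
        assert last == pytest.approx(x2, abs=0.02)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            synth_ais_profile(25.0, 5.0)
        with pytest.raises(ValueError):
            synth_ais_profile(5.0, 25.0, step_um=0.0)
        with pytest.raises(ValueError):
            synth_ais_profile(5.0, 25.0, plateau=50.0, baseline=100.0)
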