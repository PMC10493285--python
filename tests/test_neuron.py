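"""Unit tests for the two-compartment neuron and the PWAM strength code."""

import math

import numpy as np
import pytest

from ifatsim.neuron import (
    CompartmentParams,
    NeuronParams,
    NeuronState,
    SynapseParams,
    apply_synaptic_event,
    conductance_step,
    decay_conductances,
    decode_strength,
    fire_and_reset,
    integrate_step,
)


class TestStrengthCode:
    @pytest.mark.parametrize(
        "byte,W,A",
        [(0, 0, 0), (255, 15, 15), (80, 0, 5), (17, 1, 1), (31, 15, 1)],
    )
    def test_decode_splits_mantissa_and_exponent(self, byte, W, A):
        code = decode_strength(byte)
        assert (code.W, code.A) == (W, A)
        assert code.byte == byte

    @pytest.mark.parametrize("byte", [-1, 256, 1000])
    def test_out_of_range_byte_rejected(self, byte):
        with pytest.raises(ValueError):
            decode_strength(byte)

    @pytest.mark.parametrize(
        "byte,expected",
        [(0, 1.0), (15, 1.9375), (240, 32768.0), (80, 32.0)],
    )
    def test_conductance_step_code_law(self, byte, expected):
        assert conductance_step(decode_strength(byte), 1.0) == expected

    def test_step_strictly_increasing_over_all_codes(self):
        # at mantissa rollover 1.9375 * 2**A < 2 * 2**A, so the full
        # 256-code law is strictly monotone
        steps = [conductance_step(decode_strength(b), 1.0) for b in range(256)]
        assert all(b > a for a, b in zip(steps, steps[1:]))
        assert all(s > 0 for s in steps)

    def test_log_slope_matches_ideal_pwam_law(self):
        # average least-squares slope of log10(dG) vs code over 16..255
        codes = np.arange(16, 256)
        logg = np.log10([conductance_step(decode_strength(int(b)), 1.0) for b in codes])
        slope = np.polyfit(codes, logg, 1)[0]
        assert abs(slope - math.log10(2) / 16) < 5e-4


class TestConductanceDecay:
    def test_zero_dt_is_identity(self, params):
        s = NeuronState(G_syn=(1e-9, 2e-9, 3e-9, 4e-9))
        assert decay_conductances(s, 0.0, params) == s

    def test_decay_over_one_time_constant(self, params):
        tau = params.synapses[0].tau_syn
        s = NeuronState(G_syn=(1e-9, 0, 0, 0))
        out = decay_conductances(s, tau, params)
        assert out.G_syn[0] == pytest.approx(1e-9 / math.e, rel=1e-12)

    def test_semigroup_property(self, params, rng):
        s = NeuronState(G_syn=tuple(rng.uniform(0, 1e-9, 4)))
        for _ in range(20):
            d1, d2 = rng.uniform(0, 10e-3, 2)
            a = decay_conductances(decay_conductances(s, d1, params), d2, params)
            b = decay_conductances(s, d1 + d2, params)
            assert a.G_syn == pytest.approx(b.G_syn, rel=1e-12)

    def test_negative_dt_rejected(self, params):
        with pytest.raises(ValueError):
            decay_conductances(NeuronState(), -1e-6, params)


class TestSynapticEvent:
    def test_min_code_adds_one_quantum(self, params):
        g0 = params.synapses[2].g0
        out = apply_synaptic_event(NeuronState(), 2, 0, params)
        assert out.G_syn[2] == pytest.approx(g0)
        assert out.G_syn[0] == out.G_syn[1] == out.G_syn[3] == 0.0

    def test_back_to_back_events_add(self, params):
        g0 = params.synapses[2].g0
        s = apply_synaptic_event(NeuronState(), 2, 0, params)
        s = apply_synaptic_event(s, 2, 0, params)
        assert s.G_syn[2] == pytest.approx(2 * g0)

    def test_max_code_step(self):
        p = NeuronParams(synapses=tuple(
            SynapseParams(i, 1.0, 5e-3, 1e-15) for i in range(4)
        ))
        out = apply_synaptic_event(NeuronState(), 0, 255, p)
        assert out.G_syn[0] == pytest.approx(63488e-15)

    def test_bad_index_rejected(self, params):
        with pytest.raises(ValueError):
            apply_synaptic_event(NeuronState(), 4, 0, params)


class TestIntegration:
    def test_relaxes_to_common_leak_potential(self):
        p = NeuronParams(
            distal=CompartmentParams(1e-12, 50e-12, 0.2),
            proximal=CompartmentParams(1e-12, 50e-12, 0.2),
            V_thresh=0.5, G_comp=1e-9,
        )
        s = NeuronState(V_mem0=0.05, V_mem1=0.4)
        for _ in range(40000):
            s = integrate_step(s, p, 1e-5)
        assert s.V_mem0 == pytest.approx(0.2, abs=1e-6)
        assert s.V_mem1 == pytest.approx(0.2, abs=1e-6)

    def test_two_compartment_fixed_point(self):
        # G_leak0 = G_leak1 = G_comp = 1 nS, E_leak0 = 0, E_leak1 = 0.1 V:
        # solving the 2x2 steady state gives V0 = 1/30 V, V1 = 2/30 V
        p = NeuronParams(
            distal=CompartmentParams(1e-12, 1e-9, 0.0),
            proximal=CompartmentParams(1e-12, 1e-9, 0.1),
            G_comp=1e-9, V_thresh=0.5,
        )
        s = NeuronState()
        for _ in range(20000):
            s = integrate_step(s, p, 1e-5)
        assert s.V_mem0 == pytest.approx(1 / 30, abs=1e-8)
        assert s.V_mem1 == pytest.approx(2 / 30, abs=1e-8)

    def test_voltage_bounded_by_reversal(self, params):
        # huge constant excitatory conductance can push V only toward E_rev
        s = NeuronState(G_syn=(0, 0, 1e-6, 0))
        e_rev = params.synapses[2].E_rev
        p = NeuronParams(V_thresh=2.0)  # disable firing for this check
        for _ in range(5000):
            s = integrate_step(s, p, 1e-5)
            assert s.V_mem1 <= e_rev + 1e-12
        assert s.V_mem1 == pytest.approx(e_rev, abs=1e-3)

    def test_convex_hull_invariant_under_random_events(self, params, rng):
        # voltages never leave the hull of reversal/leak potentials and the
        # initial values, for arbitrary event sequences; with the defaults
        # that hull is [0 V, 1 V]
        lo, hi = 0.0, 1.0
        s = NeuronState()
        for _ in range(300):
            s = apply_synaptic_event(s, int(rng.integers(0, 4)),
                                     int(rng.integers(0, 256)), params)
            s = integrate_step(s, params, float(rng.uniform(1e-6, 1e-4)))
            s = decay_conductances(s, float(rng.uniform(0, 1e-4)), params)
            assert lo - 1e-12 <= s.V_mem0 <= hi + 1e-12
            assert lo - 1e-12 <= s.V_mem1 <= hi + 1e-12
            assert all(g >= 0 for g in s.G_syn)

    def test_nonpositive_dt_rejected(self, params):
        with pytest.raises(ValueError):
            integrate_step(NeuronState(), params, 0.0)


class TestFireAndReset:
    def test_below_threshold_no_spike(self, params):
        s = NeuronState(V_mem1=params.V_thresh - 1e-9)
        out, spike = fire_and_reset(s, params, 0.01)
        assert spike is None and out == s

    def test_at_threshold_spikes_and_resets(self, params):
        s = NeuronState(V_mem0=0.3, V_mem1=params.V_thresh, G_syn=(1e-9, 0, 0, 0))
        out, spike = fire_and_reset(s, params, 0.01)
        assert spike == 0.01
        assert out.V_mem1 == params.V_reset
        assert out.V_mem0 == 0.3 and out.G_syn == s.G_syn  # untouched
        assert out.t_refr_until == pytest.approx(0.01 + params.t_refr)

    def test_refractory_lockout_blocks_second_crossing(self):
        p = NeuronParams(t_refr=1e-3)
        s = NeuronState(V_mem1=p.V_thresh)
        s, first = fire_and_reset(s, p, 0.0)
        assert first == 0.0
        # forced second crossing inside the lockout
        s = NeuronState(s.V_mem0, p.V_thresh, s.G_syn, s.t_last, s.t_refr_until)
        s, second = fire_and_reset(s, p, 0.5e-3)
        assert second is None
        _, third = fire_and_reset(s, p, 1.1e-3)
        assert third == 1.1e-3

    def test_exponential_euler_matches_dense_integrator(self, params, rng):
        # one neuron driven by random events: engine-step trace at dt agrees
        # with a dense dt/16 trace to <= 1% relative voltage error
        dt = 1e-5
        # event times on the coarse grid so both traces apply them at the
        # same instants and only the integration error differs
        events = sorted(
            (int(rng.integers(0, 10_000)) * dt, int(rng.integers(0, 4)),
             int(rng.integers(0, 256)))
            for _ in range(100)
        )

        def run(h):
            s = NeuronState()
            p = NeuronParams(V_thresh=2.0)  # follow subthreshold dynamics only
            ev = list(events)
            t = 0.0
            vs = []
            while t < 0.1 - 1e-12:
                while ev and ev[0][0] <= t + 0.5 * h:
                    _, syn, byte = ev.pop(0)
                    s = apply_synaptic_event(s, syn, byte, p)
                s = integrate_step(s, p, h)
                s = decay_conductances(s, h, p)
                t += h
                vs.append((t, s.V_mem0, s.V_mem1))
            return vs

        coarse = run(dt)
        fine = run(dt / 16)
        fine_at = {round(t / dt): (v0, v1) for t, v0, v1 in fine
                   if abs(t / dt - round(t / dt)) < 1e-6}
        scale = max(abs(v1) for _, _, v1 in fine) or 1.0
        for t, v0, v1 in coarse:
            f = fine_at.get(round(t / dt))
            if f is None:
                continue
            assert abs(v1 - f[1]) <= 0.01 * scale
            assert abs(v0 - f[0]) <= 0.01 * scale


class TestParamValidation:
    def test_reset_must_be_below_threshold(self):
        with pytest.raises(ValueError):
            NeuronParams(V_thresh=0.1, V_reset=0.1)

    def test_four_ordered_synapses_required(self, params):
        with pytest.raises(ValueError):
            NeuronParams(synapses=params.synapses[:3])

    def test_negative_conductances_rejected(self):
        with pytest.raises(ValueError):
            NeuronState(G_syn=(-1e-12, 0, 0, 0))
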