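import numpy as np
import pytest

from colrhythm.column import ConfigurationError
from colrhythm.constants import nmda_voltage_factor
from colrhythm.dynamics import (
    IntegrationFault,
    NetworkState,
    run_simulation,
    simulate_reference,
    step_membrane,
    total_synaptic_current,
    update_gating,
)
from colrhythm.groups import GroupId
from colrhythm.inputs import make_background
from colrhythm.network import NetworkAssembly
from colrhythm.synapses import AMPA, GABA, build_synapse_table

from conftest import conn_with, micro_spec


class TestNmdaVoltageFactor:
    def test_closed_form_values(self):
        assert nmda_voltage_factor(0.0, 1.0) == pytest.approx(1 / (1 + 1 / 3.57))
        expected = 1 / (1 + np.exp(0.062 * 65) / 3.57)
        assert nmda_voltage_factor(-65.0, 1.0) == pytest.approx(expected)

    def test_magnesium_free_limit(self):
        for v in (-90.0, -60.0, 0.0, 20.0):
            assert nmda_voltage_factor(v, 0.0) == 1.0

    def test_strictly_increasing_in_voltage(self):
        v = np.linspace(-100, 20, 500)
        b = nmda_voltage_factor(v, 1.0)
        assert (np.diff(b) > 0).all()
        assert ((b > 0) & (b < 1)).all()


def _pair_assembly(receptor: int, w: float):
    """Two-neuron assembly with one synapse pre -> post.

    Returns (assembly, pre_id, post_id); for a GABA synapse the
    presynaptic cell is a PV interneuron, otherwise both cells are
    excitatory. Canonical ordering puts E4 before PV4, so ids depend on
    the receptor.
    """
    from colrhythm.synapses import SynapseTable

    if receptor == GABA:
        spec = micro_spec(PV4=1, E4=1)
        pre, post = 1, 0  # E4 occupies id 0, PV4 id 1
    else:
        spec = micro_spec(E4=2)
        pre, post = 0, 1
    tab = SynapseTable(
        pre=np.array([pre], np.int32), post=np.array([post], np.int32),
        receptor=np.array([receptor], np.int8), weight=np.array([w]),
        plastic=np.array([receptor != GABA]), n_neurons=2,
    )
    return NetworkAssembly(spec, tab), pre, post


class TestGating:
    def test_exponential_decay(self):
        """With tau_AMPA = 2 ms a gating value decays by e^-1 over 2 ms."""
        asm, pre, _ = _pair_assembly(AMPA, 0.5)
        state = NetworkState.initial(asm)
        state.s_ampa[pre] = 1.0
        c = asm.const
        for _ in range(40):  # 40 steps of 0.05 ms = 2 ms
            state = update_gating(state, np.empty(0, np.int32), 0.05, c, asm.is_exc)
        assert state.s_ampa[pre] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_all_gating_decays_to_zero_without_spikes(self):
        asm, _, _ = _pair_assembly(AMPA, 0.5)
        state = NetworkState.initial(asm)
        state.s_ampa[:] = 1.0
        state.s_gaba[:] = 1.0
        state.x_nmda[:] = 1.0
        state.s_nmda[:] = 0.5
        state.s_ext[:] = 2.0
        for _ in range(40000):  # 2 s, >= 25 NMDA decay constants
            state = update_gating(state, np.empty(0, np.int32), 0.05, asm.const, asm.is_exc)
        for arr in (state.s_ampa, state.s_gaba, state.s_nmda, state.x_nmda, state.s_ext):
            assert np.all(arr < 1e-10)

    def test_spike_increments_respect_cell_class(self):
        asm, pv, e = _pair_assembly(GABA, 0.5)
        state = NetworkState.initial(asm)
        state = update_gating(state, np.array([pv, e]), 0.05, asm.const, asm.is_exc)
        assert state.s_gaba[pv] > 0 and state.s_ampa[pv] == 0
        assert state.s_ampa[e] > 0 and state.x_nmda[e] > 0 and state.s_gaba[e] == 0

    def test_nmda_gating_saturates_below_one(self):
        """Sustained presynaptic firing drives s_NMDA toward but never
        past its fixed point below 1."""
        asm, pre, _ = _pair_assembly(AMPA, 0.5)
        state = NetworkState.initial(asm)
        for k in range(8000):  # 400 ms, presynaptic spike every 2 ms
            spikes = np.array([pre], np.int32) if k % 40 == 0 else np.empty(0, np.int32)
            state = update_gating(state, spikes, 0.05, asm.const, asm.is_exc)
            assert 0.0 <= state.s_nmda[pre] <= 1.0
        assert state.s_nmda[pre] > 0.5  # well into the saturating regime


class TestSynapticCurrent:
    def test_zero_state_zero_current(self):
        asm, _, _ = _pair_assembly(AMPA, 0.5)
        state = NetworkState.initial(asm)
        I = total_synaptic_current(state, asm)
        np.testing.assert_allclose(I, 0.0)

    def test_single_ampa_synapse_current(self):
        """w=0.5, s=1, V=-70 mV, g=1 nS gives 35 pA of depolarizing drive."""
        asm, pre, post = _pair_assembly(AMPA, 0.5)
        state = NetworkState.initial(asm)
        state.V[post] = -70.0
        state.s_ampa[pre] = 1.0
        I = total_synaptic_current(state, asm)
        assert I[post] == pytest.approx(35.0)
        assert I[pre] == 0.0

    def test_gaba_current_vanishes_at_reversal(self):
        asm, pv, e = _pair_assembly(GABA, 0.7)
        state = NetworkState.initial(asm)
        state.s_gaba[pv] = 1.0
        state.V[e] = asm.v_rest[e]  # postsynaptic rest = GABA reversal
        I = total_synaptic_current(state, asm)
        assert I[e] == pytest.approx(0.0)
        # away from reversal the current is hyperpolarizing
        state.V[e] = asm.v_rest[e] + 10.0
        I = total_synaptic_current(state, asm)
        assert I[e] < 0

    def test_presynaptic_reversal_convention(self):
        from dataclasses import replace

        asm_pre, pv, e = _pair_assembly(GABA, 0.7)
        asm_pre.const = replace(asm_pre.const, gaba_reversal="pre")
        state = NetworkState.initial(asm_pre)
        state.s_gaba[pv] = 1.0
        state.V[e] = asm_pre.v_rest[pv]  # at the presynaptic group's rest
        I = total_synaptic_current(state, asm_pre)
        assert I[e] == pytest.approx(0.0, abs=1e-9)


class TestMembraneStep:
    def test_rest_is_a_fixed_point(self):
        asm, _, _ = _pair_assembly(AMPA, 0.0)
        state = NetworkState.initial(asm)
        for _ in range(1000):
            state, spiked = step_membrane(state, np.zeros(2), asm, 0.05)
            assert len(spiked) == 0
        np.testing.assert_allclose(state.V, asm.v_rest)

    def test_subrheobase_current_never_spikes(self):
        asm, _, _ = _pair_assembly(AMPA, 0.0)
        rheo = asm.g_l[0] * (asm.v_th[0] - asm.v_rest[0])
        state = NetworkState.initial(asm)
        I = np.array([0.95 * rheo, 0.0])
        for _ in range(40000):  # 2 s
            state, spiked = step_membrane(state, I, asm, 0.05)
            assert len(spiked) == 0

    @pytest.mark.parametrize("factor", [1.3, 2.0])
    def test_constant_current_rate_matches_closed_form(self, factor):
        """Suprathreshold constant drive: the firing period is
        tau_m*ln(I/(I-rheobase)) + tau_ref; simulated rate agrees within
        2% at dt = 0.05 ms."""
        spec = micro_spec(E5=1)
        conn = conn_with({})
        tab = build_synapse_table(spec, conn, 0)
        asm = NetworkAssembly(spec, tab)
        g_l, c_m = asm.g_l[0], asm.c_m[0]
        tau_m = c_m / g_l
        rheo = g_l * (asm.v_th[0] - asm.v_rest[0])
        I = factor * rheo
        period = tau_m * np.log(I / (I - rheo)) + asm.tau_ref[0]
        res = run_simulation(
            spec, tab, duration=5000.0, dt=0.05, seed=0, background=False,
            stimulus_segments=[(0.0, 5000.0, np.array([I]))],
        )
        simulated = len(res.spikes) / 5.0  # Hz
        assert simulated == pytest.approx(1000.0 / period, rel=0.02)

    def test_refractory_contract(self, small_spec, small_table):
        """No neuron's inter-spike interval is ever below its group's
        refractory period."""
        res = run_simulation(small_spec, small_table, duration=2000.0, dt=0.05, seed=3)
        asm_tau = NetworkAssembly(small_spec, small_table).tau_ref
        for nid, train in res.spikes.spike_trains().items():
            if len(train) > 1:
                assert np.diff(train).min() >= asm_tau[nid] - 1e-9

    def test_dt_guard(self, small_spec, small_table):
        with pytest.raises(ConfigurationError):
            run_simulation(small_spec, small_table, duration=10.0, dt=0.2, seed=0)

    def test_nonfinite_current_raises_integration_fault(self):
        asm, _, _ = _pair_assembly(AMPA, 0.0)
        state = NetworkState.initial(asm)
        with pytest.raises(IntegrationFault):
            step_membrane(state, np.array([np.inf, 0.0]), asm, 0.05)


class TestSimulation:
    def test_silent_without_input(self, small_spec, small_table):
        res = run_simulation(small_spec, small_table, duration=500.0, dt=0.05,
                             seed=0, background=False)
        assert len(res.spikes) == 0

    def test_deterministic_for_fixed_seed(self, small_spec, small_table):
        a = run_simulation(small_spec, small_table, duration=400.0, dt=0.05, seed=9)
        b = run_simulation(small_spec, small_table, duration=400.0, dt=0.05, seed=9)
        np.testing.assert_array_equal(a.spikes.ids, b.spikes.ids)
        np.testing.assert_array_equal(a.spikes.times, b.spikes.times)
        c = run_simulation(small_spec, small_table, duration=400.0, dt=0.05, seed=10)
        assert len(c.spikes) != len(a.spikes) or not np.array_equal(
            a.spikes.times, c.spikes.times)

    def test_kernel_matches_reference_path(self):
        """The compiled integrator and the dense NumPy reference produce
        identical spike trains on a small column with shared background
        events."""
        spec = micro_spec(E4=40, PV4=10, SST4=8, VIP4=6, bkgnd=900.0)
        conn4 = conn_with({
            ("E4", "E4"): (0.3, 1.0), ("E4", "PV4"): (0.4, 1.2),
            ("E4", "SST4"): (0.4, 0.8), ("E4", "VIP4"): (0.3, 0.6),
            ("PV4", "E4"): (0.5, 3.0), ("PV4", "PV4"): (0.4, 2.0),
            ("SST4", "E4"): (0.4, 1.5), ("SST4", "VIP4"): (0.4, 1.0),
            ("VIP4", "SST4"): (0.5, 1.5),
        })
        tab = build_synapse_table(spec, conn4, 5)
        bg = make_background(spec, 123).events(250.0, 0.05)
        asm = NetworkAssembly(spec, tab)
        ref, ref_state, _ = simulate_reference(asm, 250.0, 0.05, bg_events=bg)
        res = run_simulation(spec, tab, duration=250.0, dt=0.05, seed=0,
                             bg_events=bg, x_eps=0.0)
        assert len(ref) == len(res.spikes) and len(ref) > 10
        np.testing.assert_array_equal(ref.ids, res.spikes.ids)
        np.testing.assert_allclose(ref.times, res.spikes.times, atol=1e-9)

    def test_decoupled_rates_increase_with_background(self):
        """With G=0 each group is an isolated population driven only by
        its background stream; rates grow monotonically with the
        background rate."""
        rates = []
        for scale in (0.6, 1.0, 1.4):
            spec = micro_spec(E4=60, PV4=40, SST5=40, G=0.0)
            for g in spec.bkgnd_rate:
                spec.bkgnd_rate[g] = 0.0
            spec.bkgnd_rate[GroupId("L4", "E")] = 890.0 * scale
            spec.bkgnd_rate[GroupId("L4", "PV")] = 1980.0 * scale
            spec.bkgnd_rate[GroupId("L5", "SST")] = 530.0 * scale
            tab = build_synapse_table(spec, conn_with({}), 2)
            res = run_simulation(spec, tab, duration=3000.0, dt=0.05, seed=4)
            rates.append({
                lbl: res.spikes.mean_rate(GroupId.from_label(lbl))
                for lbl in ("E4", "PV4", "SST5")
            })
        for lbl in ("E4", "PV4", "SST5"):
            assert rates[0][lbl] < rates[1][lbl] < rates[2][lbl], lbl

    def test_decoupled_group_matches_single_neuron_oracle(self):
        """G=0 group rates equal an independently coded fine-step
        single-neuron integrator under the same Poisson AMPA drive
        (within 3 SE)."""
        rate_bg = 2105.0
        spec = micro_spec(SST4=60, G=0.0)
        for g in spec.bkgnd_rate:
            spec.bkgnd_rate[g] = 0.0
        spec.bkgnd_rate[GroupId("L4", "SST")] = rate_bg
        tab = build_synapse_table(spec, conn_with({}), 0)
        res = run_simulation(spec, tab, duration=5000.0, dt=0.05, seed=8)
        t, _ = res.spikes.for_group(GroupId("L4", "SST"))
        net_rate = np.sum(t >= 500) / 60 / 4.5

        # independent oracle: fine-dt scalar LIF + exponential AMPA trace
        m = spec.membrane[GroupId("L4", "SST")]
        rng = np.random.default_rng(77)
        dt = 0.01
        n_rep, dur = 25, 5000.0
        counts = []
        for _ in range(n_rep):
            v, s = m.V_rest, 0.0
            refr, n_sp = -1.0, 0
            n_steps = int(dur / dt)
            events = rng.random(n_steps) < rate_bg * dt * 1e-3
            for k in range(n_steps):
                t_now = k * dt
                if t_now >= refr:
                    I = -1.0 * (v - 0.0) * s  # g_AMPA * (V - V_E) * w_ext*s, inward
                    vinf = m.V_rest + I / m.g_L
                    v = vinf + (v - vinf) * np.exp(-dt / m.tau_m)
                    if v >= m.V_th:
                        v = m.V_rest
                        refr = t_now + dt + m.tau_ref
                        if t_now >= 500:
                            n_sp += 1
                else:
                    v = m.V_rest
                s = s * np.exp(-dt / 2.0) + events[k]
            counts.append(n_sp / 4.5)
        counts = np.array(counts)
        se = counts.std(ddof=1) / np.sqrt(n_rep)
        se_net = np.sqrt(max(net_rate, 1e-9) / (60 * 4.5))  # Poisson-ish
        assert abs(net_rate - counts.mean()) < 3 * np.hypot(se, se_net)

    def test_membrane_recording(self, small_spec, small_table):
        ids = np.array([0, 5, 10], np.int32)
        res = run_simulation(small_spec, small_table, duration=300.0, dt=0.05,
                             seed=1, record_v_ids=ids, record_v_dt=1.0)
        assert res.v_traces.shape[1] == 3
        assert len(res.v_times) == res.v_traces.shape[0]
        assert res.v_traces.shape[0] == pytest.approx(300, abs=2)
        assert np.isfinite(res.v_traces).all()
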