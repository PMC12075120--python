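import warnings

import numpy as np
import pytest

from colrhythm.column import ConfigurationError
from colrhythm.config import load_config
from colrhythm.experiments import (
    build_tables,
    inactivate_groups,
    input_sweep,
    isolate_table,
    make_column,
    run_conditioning,
    run_evoked,
    run_spontaneous,
    shuffle_weights,
    uniform_increase,
)
from colrhythm.groups import GROUPS, GroupId
from colrhythm.synapses import SynapseTable


def _cfg(**data):
    base = {
        "network": {"n_total": 300},
        "dynamics": {"duration": 1500.0},
    }
    for k, v in data.items():
        if isinstance(v, dict) and k in base:
            base[k].update(v)
        else:
            base[k] = v
    return load_config(data=base)


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(11)
    n = 400
    return SynapseTable(
        pre=rng.integers(0, 50, n).astype(np.int32),
        post=rng.integers(0, 50, n).astype(np.int32),
        receptor=rng.integers(0, 3, n).astype(np.int8),
        weight=rng.uniform(0.0, 0.2, n),
        plastic=rng.random(n) < 0.6,
        n_neurons=50,
    )


class TestShuffleControl:
    def test_weight_multiset_preserved_exactly(self, random_table):
        out = shuffle_weights(random_table, seed=3)
        np.testing.assert_array_equal(
            np.sort(out.weight[out.plastic]),
            np.sort(random_table.weight[random_table.plastic]),
        )
        # out-of-scope weights untouched
        np.testing.assert_array_equal(
            out.weight[~out.plastic], random_table.weight[~random_table.plastic])

    def test_topology_and_receptors_untouched(self, random_table):
        out = shuffle_weights(random_table, seed=3)
        for f in ("pre", "post", "receptor", "plastic"):
            np.testing.assert_array_equal(getattr(out, f), getattr(random_table, f))

    def test_mean_and_histogram_invariant(self, random_table):
        out = shuffle_weights(random_table, seed=5)
        m = random_table.plastic
        assert out.weight[m].mean() == pytest.approx(
            random_table.weight[m].mean(), abs=1e-15)
        h0, edges = np.histogram(random_table.weight[m], bins=20)
        h1, _ = np.histogram(out.weight[m], bins=edges)
        np.testing.assert_array_equal(h0, h1)

    def test_equal_weights_shuffle_to_themselves(self, random_table):
        t = random_table.copy()
        t.weight[t.plastic] = 0.07
        out = shuffle_weights(t, seed=9)
        np.testing.assert_array_equal(out.weight, t.weight)

    def test_seeded_determinism(self, random_table):
        a = shuffle_weights(random_table, seed=1)
        b = shuffle_weights(random_table, seed=1)
        np.testing.assert_array_equal(a.weight, b.weight)


class TestUniformIncreaseControl:
    def test_identity_when_means_match(self, random_table):
        out = uniform_increase(random_table, random_table.copy())
        np.testing.assert_allclose(out.weight, random_table.weight)

    def test_doubled_mean_doubles_everything(self, random_table):
        cond = random_table.copy()
        cond.weight[cond.plastic] *= 2.0
        out = uniform_increase(random_table, cond)
        m = random_table.plastic
        np.testing.assert_allclose(out.weight[m], 2.0 * random_table.weight[m])

    def test_means_match_to_machine_precision(self, random_table):
        rng = np.random.default_rng(2)
        cond = random_table.copy()
        m = cond.plastic
        cond.weight[m] = np.clip(cond.weight[m] + rng.normal(0.02, 0.01, m.sum()),
                                 0.0, 0.2)
        out = uniform_increase(random_table, cond)
        assert out.weight[m].mean() == pytest.approx(cond.weight[m].mean(),
                                                     rel=1e-12)

    def test_zero_naive_mean_rejected(self, random_table):
        t = random_table.copy()
        t.weight[t.plastic] = 0.0
        with pytest.raises(ValueError):
            uniform_increase(t, random_table)


class TestIsolation:
    def test_isolated_table_keeps_only_l4_synapses(self):
        cfg = _cfg(network={"n_total": 1000})
        spec, table = build_tables(cfg)
        iso = isolate_table(table, spec)
        gidx = spec.group_of_neuron()
        layers = np.array([GROUPS[i].layer for i in gidx])
        assert (layers[iso.pre] == "L4").all()
        assert (layers[iso.post] == "L4").all()
        assert 0 < len(iso) < len(table)
        # the original table is untouched, so reconnection is exact
        assert len(table) > len(iso)
        iso2 = isolate_table(iso, spec)
        assert len(iso2) == len(iso)

    def test_isolation_preserves_l4_weights(self):
        cfg = _cfg(network={"n_total": 1000})
        spec, table = build_tables(cfg)
        iso = isolate_table(table, spec)
        gidx = spec.group_of_neuron()
        in_l4 = np.array([GROUPS[i].layer == "L4" for i in gidx])
        mask = in_l4[table.pre] & in_l4[table.post]
        np.testing.assert_array_equal(iso.weight, table.weight[mask])


class TestInactivation:
    def test_silencing_is_absorbing(self):
        """Silenced neurons emit no spikes at or after the clamp onset."""
        cfg = _cfg(dynamics={"duration": 1200.0})
        res = inactivate_groups(cfg, {GroupId("L4", "PV")}, t_off=600.0)
        spec = make_column(cfg)
        sl = spec.group_slices()[GroupId("L4", "PV")]
        silenced = (res.spikes.ids >= sl.start) & (res.spikes.ids < sl.stop)
        assert res.spikes.times[silenced].max(initial=0.0) <= 600.0
        # before the clamp the group was active
        assert (res.spikes.times[silenced] < 600.0).sum() > 0

    def test_inactivating_everything_silences_the_column(self):
        cfg = _cfg(dynamics={"duration": 800.0})
        res = inactivate_groups(cfg, set(GROUPS), t_off=400.0)
        assert res.spikes.times.max(initial=0.0) <= 400.0

    def test_subset_counts_limit_the_clamp(self):
        cfg = _cfg(dynamics={"duration": 600.0})
        res = inactivate_groups(
            cfg, {GroupId("L4", "PV")}, t_off=300.0,
            subset_counts={GroupId("L4", "PV"): 2},
        )
        assert res.summaries["n_silenced"] == 2

    def test_empty_set_warns_and_runs(self):
        cfg = _cfg(dynamics={"duration": 600.0})
        with warnings.catch_warnings(record=True) as captured:
            warnings.simplefilter("always")
            res = inactivate_groups(cfg, set(), t_off=300.0)
        assert any("no groups" in str(w.message) for w in captured)
        assert res.summaries["n_silenced"] == 0


class TestNamedExperiments:
    def test_spontaneous_without_background_is_silent(self):
        cfg = _cfg(background={"enabled": False})
        res = run_spontaneous(cfg)
        assert len(res.spikes) == 0

    def test_spontaneous_summaries_cover_all_groups(self):
        cfg = _cfg()
        res = run_spontaneous(cfg)
        assert set(res.summaries["mean_rates"]) == {g.label for g in GROUPS}
        assert len(res.spikes) > 0
        assert res.provenance["config_hash"] == cfg.hash()

    def test_spontaneous_requires_display_window(self):
        with pytest.raises(ConfigurationError):
            run_spontaneous(_cfg(dynamics={"duration": 800.0}))

    def test_rerun_from_provenance_is_bit_identical(self):
        a = run_spontaneous(_cfg())
        b = run_spontaneous(_cfg())
        np.testing.assert_array_equal(a.spikes.ids, b.spikes.ids)
        np.testing.assert_array_equal(a.spikes.times, b.spikes.times)

    def test_zero_amplitude_evoked_equals_spontaneous(self):
        """An amplitude-0 stimulus injects nothing: spike-for-spike equal
        to the spontaneous run of the same seeds."""
        from colrhythm.experiments import _segments, _simulate

        cfg_stim = _cfg(stimulus=[{"group": "E4", "fraction": 0.5,
                                   "amplitude": 0.0, "t_on": 700.0}])
        cfg_plain = _cfg()
        res_plain = run_spontaneous(cfg_plain)
        spec, table = build_tables(cfg_stim)
        res_stim = _simulate(cfg_stim, spec, table,
                             segments=_segments(cfg_stim, spec))
        np.testing.assert_array_equal(res_stim.spikes.ids, res_plain.spikes.ids)
        np.testing.assert_array_equal(res_stim.spikes.times, res_plain.spikes.times)

    def test_evoked_reports_latencies(self):
        cfg = _cfg(network={"n_total": 1000},
                   dynamics={"duration": 2500.0},
                   stimulus=[{"group": "E4", "fraction": 1.0,
                              "amplitude": 60.0, "t_on": 1000.0}])
        res = run_evoked(cfg)
        lat = res.summaries["latency_ms"]
        assert np.isfinite(lat["E4"])
        assert lat["E4"] >= 0.0

    def test_conditioning_requires_plasticity(self):
        with pytest.raises(ConfigurationError):
            run_conditioning(_cfg())

    def test_conditioning_returns_snapshots_and_naive(self):
        cfg = _cfg(network={"n_total": 300},
                   dynamics={"duration": 1000.0},
                   plasticity={"enabled": True},
                   stimulus=[{"group": "E4", "fraction": 0.5,
                              "amplitude": 30.0, "t_on": 200.0}],
                   output={"snapshot_times": [500.0, 1000.0]})
        res = run_conditioning(cfg)
        assert [t for t, _ in res.weight_snapshots] == [500.0, 1000.0]
        assert res.naive_table is not None and res.final_table is not None
        assert len(res.naive_table) == len(res.final_table)

    def test_plastic_scope_restriction(self):
        cfg = _cfg(network={"n_total": 1000},
                   plasticity={"enabled": True, "scope_pre_layers": ["L4"]})
        spec, table = build_tables(cfg)
        gidx = spec.group_of_neuron()
        pre_layers = np.array([GROUPS[i].layer for i in gidx[table.pre]])
        assert (pre_layers[table.plastic] == "L4").all()
        cfg_ex = _cfg(network={"n_total": 1000},
                      plasticity={"enabled": True, "scope_pre_layers": ["L4"],
                                  "scope_exclude": True})
        _, table_ex = build_tables(cfg_ex)
        assert not (np.array([GROUPS[i].layer for i in gidx[table_ex.pre]])
                    [table_ex.plastic] == "L4").any()

    def test_input_sweep_structure(self):
        cfg = _cfg(network={"n_total": 300}, dynamics={"duration": 2000.0})
        spec, table = build_tables(cfg)
        df = input_sweep(cfg, table, axis="FF_L4", amplitudes=(0.0, 30.0))
        assert set(df["amplitude"]) == {0.0, 30.0}
        assert set(df["group"]) == {"E2/3", "E4", "E5", "E6"}
        assert {"peak_frequency", "peak_power", "mean_rate"} <= set(df.columns)
        with pytest.raises(ConfigurationError):
            input_sweep(cfg, table, axis="sideways")
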