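"""The named experiments: spontaneous and evoked activity, STDP
conditioning, interneuron inactivations, layer-4 isolation, the
shuffle / uniformly-increased control pair, and feedforward/feedback
input sweeps.

Every experiment is a pure function of a :class:`~colrhythm.config.RunConfig`
(plus explicit extra arguments); its result carries the full provenance
(config dictionary, resolved seeds, package version) needed to re-run it
bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    AnalysisError,
    RateTrace,
    activation_latency,
    isi_cv,
    population_rate,
    power_spectrum,
    synchrony_chi,
)
from .column import ColumnSpec, ConfigurationError, load_connectivity
from .config import RunConfig
from .constants import SynapseConstants
from .dynamics import SimulationResult, SpikeRecord, run_simulation
from .groups import GROUPS, GroupId
from .inputs import StimulusEpoch, StimulusProtocol, make_stimulus
from .seeding import seed_table
from .synapses import SynapseTable, build_synapse_table


@dataclass
class ExperimentResult:
    name: str
    spikes: SpikeRecord
    rate_traces: dict[str, RateTrace]
    summaries: dict
    provenance: dict
    weight_snapshots: list[tuple[float, SynapseTable]] = field(default_factory=list)
    final_table: SynapseTable | None = None
    naive_table: SynapseTable | None = None
    v_traces: np.ndarray | None = None
    v_ids: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Assembly of the run ingredients from a config
# ---------------------------------------------------------------------------


def make_column(cfg: RunConfig) -> ColumnSpec:
    spec = ColumnSpec.default(cfg.network.n_total, G=cfg.network.G)
    for label, rate in cfg.background.rate_overrides.items():
        spec.bkgnd_rate[GroupId.from_label(label)] = float(rate)
    return spec


def make_connectivity(cfg: RunConfig):
    if cfg.network.matrix_source == "files":
        return load_connectivity(cfg.network.path_P, cfg.network.path_S)
    from .column import generate_synthetic_connectivity

    return generate_synthetic_connectivity(
        cfg.seeds["wiring"], style=cfg.network.matrix_style
    )


def make_constants(cfg: RunConfig) -> SynapseConstants:
    d = cfg.dynamics
    return SynapseConstants(
        g_AMPA=d.g_AMPA, g_NMDA=d.g_NMDA, g_GABA=d.g_GABA,
        gaba_reversal=d.gaba_reversal,
    )


def apply_plastic_scope(table: SynapseTable, spec: ColumnSpec, cfg: RunConfig) -> None:
    """Restrict the plastic flags to the configured presynaptic layers."""
    layers = cfg.plasticity.scope_pre_layers
    if layers is None:
        return
    gidx = spec.group_of_neuron()
    in_layers = np.array([GROUPS[i].layer in layers for i in gidx[table.pre]])
    if cfg.plasticity.scope_exclude:
        in_layers = ~in_layers
    table.plastic &= in_layers


def build_tables(cfg: RunConfig) -> tuple[ColumnSpec, SynapseTable]:
    spec = make_column(cfg)
    conn = make_connectivity(cfg)
    table = build_synapse_table(spec, conn, cfg.seeds["wiring"])
    apply_plastic_scope(table, spec, cfg)
    return spec, table


def _segments(cfg: RunConfig, spec: ColumnSpec, protocol: StimulusProtocol | None = None):
    protocol = protocol if protocol is not None else cfg.protocol()
    segs = make_stimulus(protocol, spec)
    dur = cfg.dynamics.duration
    return [(a, min(b, dur), c) for (a, b, c) in segs if a < dur]


def _provenance(cfg: RunConfig, name: str, **extra) -> dict:
    return {
        "experiment": name,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seeds": dict(cfg.seeds),
        "version": __version__,
        **extra,
    }


def _simulate(cfg: RunConfig, spec: ColumnSpec, table: SynapseTable, *,
              plastic: bool = False, segments=None, record_v_ids=None,
              clamp_ids=None, clamp_from=0.0, snapshot_times=None) -> SimulationResult:
    return run_simulation(
        spec, table,
        duration=cfg.dynamics.duration,
        dt=cfg.dynamics.dt,
        seed=cfg.seed,
        stimulus_segments=segments or [],
        background=cfg.background.enabled,
        plasticity=cfg.stdp_config() if plastic and cfg.plasticity.enabled else None,
        inh_plasticity=(cfg.inh_stdp_config()
                        if plastic and cfg.plasticity.inh_enabled else None),
        clamp_ids=clamp_ids, clamp_from=clamp_from,
        record_v_ids=record_v_ids,
        snapshot_times=snapshot_times,
        x_eps=cfg.dynamics.x_eps,
        force_dt=cfg.dynamics.force_dt,
        const=make_constants(cfg),
        return_final_table=True,
    )


def _rate_traces(cfg: RunConfig, spikes: SpikeRecord) -> dict[str, RateTrace]:
    return {
        g.label: population_rate(
            spikes, g, window=cfg.analysis.rate_window, step=cfg.analysis.rate_step
        )
        for g in GROUPS
    }


def _mean_rates(spikes: SpikeRecord, t_start: float = 0.0) -> dict[str, float]:
    out = {}
    for g in GROUPS:
        t, _ = spikes.for_group(g)
        n = len(spikes.neurons_of_group(g))
        dur_s = (spikes.duration - t_start) * 1e-3
        out[g.label] = float(np.sum(t >= t_start) / n / dur_s) if n and dur_s > 0 else 0.0
    return out


def _spectra(cfg: RunConfig, traces: dict[str, RateTrace], t_start: float,
             t_end: float | None = None) -> dict[str, dict]:
    a = cfg.analysis
    out = {}
    for label, tr in traces.items():
        try:
            ps = power_spectrum(
                tr, t_start=t_start, t_end=t_end,
                band=(a.band_lo, a.band_hi),
                segment_s=a.psd_segment_s, overlap=a.psd_overlap,
            )
            out[label] = {"peak_frequency": ps.peak_frequency,
                          "peak_power": ps.peak_power}
        except AnalysisError:
            out[label] = {"peak_frequency": np.nan, "peak_power": np.nan}
    return out


def _v_sample_ids(spec: ColumnSpec, per_group: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    ids = []
    for g, sl in spec.group_slices().items():
        pool = np.arange(sl.start, sl.stop)
        k = min(per_group, len(pool))
        if k:
            ids.append(np.sort(rng.permutation(pool)[:k]))
    return np.concatenate(ids).astype(np.int32)


# ---------------------------------------------------------------------------
# Named experiments
# ---------------------------------------------------------------------------


def run_spontaneous(cfg: RunConfig, warmup: float = 500.0) -> ExperimentResult:
    """Spontaneous activity: background drive only.

    Simulates at least 1,500 ms (the standard display window) and reports
    per-group mean rates, inter-spike-interval CVs and the membrane-trace
    synchrony measure.
    """
    if cfg.dynamics.duration < 1500.0:
        raise ConfigurationError("spontaneous runs use at least 1,500 ms")
    spec, table = build_tables(cfg)
    per_group = cfg.output.record_v_count or 8
    v_ids = _v_sample_ids(spec, per_group, cfg.seeds["stimulus"])
    res = _simulate(cfg, spec, table, record_v_ids=v_ids)
    traces = _rate_traces(cfg, res.spikes)
    gidx = spec.group_of_neuron()
    chi = {}
    mask_t = res.v_times >= warmup
    for g in GROUPS:
        cols = np.nonzero(gidx[v_ids] == GROUPS.index(g))[0]
        if len(cols) >= 2:
            try:
                chi[g.label] = synchrony_chi(res.v_traces[np.ix_(mask_t, cols)])
            except AnalysisError:
                chi[g.label] = np.nan
    cvs = {}
    for g in GROUPS:
        vals, n_excluded = isi_cv(res.spikes, g)
        cvs[g.label] = {
            "mean_cv": float(np.nanmean(vals)) if len(vals) else np.nan,
            "n_units": int(len(vals)),
            "n_excluded": int(n_excluded),
        }
    summaries = {
        "mean_rates": _mean_rates(res.spikes, warmup),
        "isi_cv": cvs,
        "synchrony_chi": chi,
    }
    return ExperimentResult(
        name="spontaneous", spikes=res.spikes, rate_traces=traces,
        summaries=summaries, provenance=_provenance(cfg, "spontaneous"),
        v_traces=res.v_traces, v_ids=v_ids,
    )


def run_evoked(cfg: RunConfig, n_seeds: int = 1) -> ExperimentResult:
    """Feedforward stimulation of layer-4 pyramidal cells.

    Reports per-group activation latencies (time to half of the maximum
    evoked rate), averaged over ``n_seeds`` repeats, alongside evoked
    mean rates and spectra of the excitatory rate traces.
    """
    if not cfg.stimulus:
        raise ConfigurationError("evoked runs need a stimulus protocol")
    onset = min(e.t_on for e in cfg.stimulus)
    spec, table = build_tables(cfg)
    latencies: dict[str, list[float]] = {g.label: [] for g in GROUPS}
    base_seed = cfg.seed
    first = None
    for k in range(n_seeds):
        cfg.seed = base_seed + k
        cfg.seeds = seed_table(cfg.seed)
        spec_k, table_k = (spec, table) if k == 0 else build_tables(cfg)
        res = _simulate(cfg, spec_k, table_k, segments=_segments(cfg, spec_k))
        traces = _rate_traces(cfg, res.spikes)
        if first is None:
            first = (res, traces)
        for g in GROUPS:
            try:
                latencies[g.label].append(
                    activation_latency(traces[g.label], stim_onset=onset)
                )
            except AnalysisError:
                latencies[g.label].append(np.nan)
    cfg.seed = base_seed
    cfg.seeds = seed_table(cfg.seed)
    res, traces = first
    summaries = {
        "stim_onset": onset,
        "latency_ms": {k: float(np.nanmean(v)) for k, v in latencies.items()},
        "latency_all": {k: [float(x) for x in v] for k, v in latencies.items()},
        "evoked_rates": _mean_rates(res.spikes, onset),
        "spectra": _spectra(cfg, {k: v for k, v in traces.items() if k.startswith("E")},
                            t_start=onset),
    }
    return ExperimentResult(
        name="evoked", spikes=res.spikes, rate_traces=traces,
        summaries=summaries, provenance=_provenance(cfg, "evoked", n_seeds=n_seeds),
    )


def run_conditioning(cfg: RunConfig) -> ExperimentResult:
    """STDP conditioning: sustained feedforward drive with plasticity on.

    The standard protocol is 30 pA to half of the layer-4 pyramidal cells
    from 500 ms onward for 55 s, all E->E weights plastic. Weight
    snapshots are taken at the configured checkpoint times; the naive
    (pre-plasticity) table is kept on the result for the control
    comparisons.
    """
    if not cfg.plasticity.enabled:
        raise ConfigurationError("conditioning requires plasticity.enabled")
    spec, table = build_tables(cfg)
    naive = table.copy()
    snaps = list(cfg.output.snapshot_times) or [cfg.dynamics.duration]
    res = _simulate(cfg, spec, table, plastic=True,
                    segments=_segments(cfg, spec), snapshot_times=snaps)
    traces = _rate_traces(cfg, res.spikes)
    dur = cfg.dynamics.duration
    window = min(5000.0, dur / 2)
    summaries = {
        "mean_rates": _mean_rates(res.spikes, dur - window),
        "spectra_late": _spectra(
            cfg, {k: v for k, v in traces.items() if k.startswith("E")},
            t_start=dur - window),
        "plastic_mean_before": float(naive.weight[naive.plastic].mean()),
        "plastic_mean_after": float(
            res.final_table.weight[res.final_table.plastic].mean()),
    }
    return ExperimentResult(
        name="conditioning", spikes=res.spikes, rate_traces=traces,
        summaries=summaries, provenance=_provenance(cfg, "conditioning"),
        weight_snapshots=res.weight_snapshots, final_table=res.final_table,
        naive_table=naive,
    )


def inactivate_groups(
    cfg: RunConfig,
    groups: set[GroupId] | list[GroupId],
    t_off: float,
    table: SynapseTable | None = None,
    subset_counts: dict[GroupId, int] | None = None,
) -> ExperimentResult:
    """Silence cell groups from ``t_off`` ms onward (voltage clamp at rest).

    ``subset_counts`` silences only the first k cells of a group under a
    seeded permutation (e.g. a PV subset matched in size to the SST
    population). Gating variables of silenced cells decay naturally; a
    silenced cell emits no spikes after ``t_off`` (absorbing).
    """
    groups = set(groups)
    if not groups:
        warnings.warn("inactivate_groups called with no groups; running control")
    if table is None:
        spec, table = build_tables(cfg)
    else:
        spec = make_column(cfg)
    slices = spec.group_slices()
    rng = np.random.default_rng(cfg.seeds["stimulus"] + 17)
    ids = []
    for g in groups:
        pool = np.arange(slices[g].start, slices[g].stop)
        if subset_counts and g in subset_counts:
            pool = np.sort(rng.permutation(pool)[: subset_counts[g]])
        ids.append(pool)
    clamp_ids = np.concatenate(ids).astype(np.int32) if ids else np.empty(0, np.int32)
    res = _simulate(cfg, spec, table, segments=_segments(cfg, spec),
                    clamp_ids=clamp_ids, clamp_from=t_off)
    traces = _rate_traces(cfg, res.spikes)
    e_traces = {k: v for k, v in traces.items() if k.startswith("E")}

    def rates_between(a, b):
        out = {}
        for g in GROUPS:
            t, _ = res.spikes.for_group(g)
            n = len(res.spikes.neurons_of_group(g))
            out[g.label] = float(np.sum((t >= a) & (t < b)) / n / ((b - a) * 1e-3))
        return out

    dur = cfg.dynamics.duration
    summaries = {
        "t_off": t_off,
        "silenced": sorted(g.label for g in groups),
        "n_silenced": int(len(clamp_ids)),
        "rates_before": rates_between(max(0.0, t_off - (dur - t_off)), t_off),
        "rates_after": rates_between(t_off, dur),
        "spectra_before": _spectra(cfg, e_traces, t_start=0.0, t_end=t_off),
        "spectra_after": _spectra(cfg, e_traces, t_start=t_off, t_end=dur),
    }
    return ExperimentResult(
        name="inactivation", spikes=res.spikes, rate_traces=traces,
        summaries=summaries,
        provenance=_provenance(cfg, "inactivation", t_off=t_off,
                               groups=sorted(g.label for g in groups)),
    )


def isolate_table(table: SynapseTable, spec: ColumnSpec) -> SynapseTable:
    """Synapses restricted to the layer-4 subcircuit (L4 -> L4 only)."""
    gidx = spec.group_of_neuron()
    in_l4 = np.array([GROUPS[i].layer == "L4" for i in gidx])
    mask = in_l4[table.pre] & in_l4[table.post]
    return table.select(mask)


def isolate_layer4(cfg: RunConfig, table: SynapseTable) -> ExperimentResult:
    """Run the isolated layer-4 subcircuit: all connections into and out
    of layer 4 removed, background and stimulus unchanged. ``table`` is
    typically a post-conditioning snapshot."""
    spec = make_column(cfg)
    iso = isolate_table(table, spec)
    res = _simulate(cfg, spec, iso, segments=_segments(cfg, spec))
    traces = _rate_traces(cfg, res.spikes)
    onset = min((e.t_on for e in cfg.stimulus), default=0.0)
    summaries = {
        "mean_rates": _mean_rates(res.spikes, onset),
        "spectra": _spectra(cfg, {"E4": traces["E4"]}, t_start=onset + 500.0),
        "n_synapses": int(len(iso)),
    }
    return ExperimentResult(
        name="isolated_l4", spikes=res.spikes, rate_traces=traces,
        summaries=summaries, provenance=_provenance(cfg, "isolated_l4"),
        final_table=iso,
    )


def shuffle_weights(
    table: SynapseTable, seed: int, scope_mask: np.ndarray | None = None
) -> SynapseTable:
    """Permute weight values among the in-scope synapses.

    Graph topology, receptor labels and the weight multiset are preserved
    exactly; only the assignment of values to cell pairs changes. Scope
    defaults to the plastic E->E synapses.
    """
    out = table.copy()
    mask = scope_mask if scope_mask is not None else table.plastic
    idx = np.nonzero(mask)[0]
    rng = np.random.default_rng(seed)
    out.weight[idx] = out.weight[idx][rng.permutation(len(idx))]
    return out


def uniform_increase(
    table_naive: SynapseTable,
    table_conditioned: SynapseTable,
    scope_mask: np.ndarray | None = None,
) -> SynapseTable:
    """The uniformly-increased (UI) control.

    Every in-scope naive weight is multiplied by the ratio of conditioned
    to naive mean weight, so the UI table matches the conditioned mean
    exactly while carrying none of the pairwise structure.
    """
    if len(table_naive) != len(table_conditioned):
        raise ValueError("naive and conditioned tables must share one topology")
    mask = scope_mask if scope_mask is not None else table_naive.plastic
    m_naive = table_naive.weight[mask].mean() if mask.any() else 0.0
    if m_naive == 0.0:
        raise ValueError("naive mean weight is zero; UI scaling undefined")
    factor = table_conditioned.weight[mask].mean() / m_naive
    out = table_naive.copy()
    out.weight[mask] = out.weight[mask] * factor
    return out


def control_triad(
    seed: int,
    n_total: int = 1000,
    conditioning_ms: float = 55000.0,
    eval_ms: float = 4500.0,
    eval_seeds: int = 2,
    band: tuple[float, float] = (15.0, 60.0),
) -> dict:
    """Conditioning plus the full control comparison in one call.

    Runs the STDP conditioning protocol (30 pA to half of the L4
    pyramids, all E->E weights plastic), then evaluates the naive,
    conditioned, shuffled and uniformly-increased weight tables — and the
    conditioned table without feedforward input — with frozen weights.
    Evaluations reuse the conditioned column's wiring and stimulated
    subset; only the background noise stream varies (averaged over
    ``eval_seeds`` repeats).

    Powers are read off the layer-4 excitatory rate spectrum at the
    conditioned network's peak frequency within ``band`` (default
    15-60 Hz, the beta/low-gamma range where the plasticity-induced
    rhythm lives) — the same frequency-matched comparison the shuffle/UI
    controls are designed for. Returns a dict with the peak frequency,
    the per-variant powers, and the weight means.
    """
    from .config import conditioning_preset, load_config

    cfg = conditioning_preset(duration=conditioning_ms + 500.0, n_total=n_total,
                              seed=seed)
    res = run_conditioning(cfg)
    cond, naive = res.final_table, res.naive_table
    shuf = shuffle_weights(cond, seed=cfg.seeds["plasticity"])
    ui = uniform_increase(naive, cond)

    spectra: dict[str, list] = {}
    variants = [("naive", naive, True), ("conditioned", cond, True),
                ("shuffled", shuf, True), ("uniform_increase", ui, True),
                ("no_ff_input", cond, False)]
    for name, tab, stim in variants:
        spectra[name] = []
        for es in range(eval_seeds):
            cfg_eval = load_config(data={
                "seed": 100_000 + 131 * seed + es,
                "network": {"n_total": n_total},
                "dynamics": {"duration": eval_ms},
                "stimulus": [{"group": "E4", "fraction": 0.5,
                              "amplitude": 30.0, "t_on": 500.0}],
            })
            cfg_eval.seeds["wiring"] = cfg.seeds["wiring"]
            cfg_eval.seeds["stimulus"] = cfg.seeds["stimulus"]
            spec = make_column(cfg_eval)
            segs = _segments(cfg_eval, spec) if stim else []
            r = _simulate(cfg_eval, spec, tab, segments=segs)
            tr = population_rate(r.spikes, GroupId("L4", "E"))
            spectra[name].append(power_spectrum(tr, t_start=1000.0, t_end=eval_ms))

    mean_power = np.mean([p.power for p in spectra["conditioned"]], axis=0)
    freqs = spectra["conditioned"][0].frequencies
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    f_star = float(freqs[in_band][np.argmax(mean_power[in_band])])

    def power_at(ps_list, f):
        k = int(np.argmin(np.abs(freqs - f)))
        return float(np.mean([ps.power[k] for ps in ps_list]))

    out = {"peak_frequency": f_star, "seed": seed}
    for name in spectra:
        out[f"power_{name}"] = power_at(spectra[name], f_star)
    m = naive.plastic
    out["plastic_mean_naive"] = float(naive.weight[m].mean())
    out["plastic_mean_conditioned"] = float(cond.weight[m].mean())
    return out


def input_sweep(
    cfg: RunConfig,
    table: SynapseTable,
    axis: str = "FF_L4",
    amplitudes: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    ff_fixed: float = 30.0,
) -> pd.DataFrame:
    """Frequency/power of excitatory rates versus input strength.

    ``FF_L4`` varies the feedforward current into layer-4 pyramids;
    ``FB_L5`` varies a feedback-like current into layer-5 pyramids while
    the layer-4 input stays at ``ff_fixed`` pA. Weights in ``table`` are
    frozen (no plasticity). Returns one row per (amplitude, E group).
    """
    if axis not in ("FF_L4", "FB_L5"):
        raise ConfigurationError(f"unknown sweep axis {axis!r}")
    spec = make_column(cfg)
    dur = cfg.dynamics.duration
    t_on = 500.0
    rows = []
    for amp in amplitudes:
        epochs = []
        if axis == "FF_L4":
            if amp > 0:
                epochs.append(StimulusEpoch(GroupId("L4", "E"), 0.5, amp, t_on, 1e12))
        else:
            if ff_fixed > 0:
                epochs.append(StimulusEpoch(GroupId("L4", "E"), 0.5, ff_fixed, t_on, 1e12))
            if amp > 0:
                epochs.append(StimulusEpoch(GroupId("L5", "E"), 0.5, amp, t_on, 1e12))
        protocol = StimulusProtocol(epochs=epochs, seed=cfg.seeds["stimulus"])
        res = _simulate(cfg, spec, table, segments=_segments(cfg, spec, protocol))
        traces = _rate_traces(cfg, res.spikes)
        for g in GROUPS:
            if not g.is_excitatory:
                continue
            sp = _spectra(cfg, {g.label: traces[g.label]}, t_start=t_on + 500.0)[g.label]
            t, _ = res.spikes.for_group(g)
            n = len(res.spikes.neurons_of_group(g))
            rows.append({
                "axis": axis, "amplitude": amp, "group": g.label,
                "peak_frequency": sp["peak_frequency"],
                "peak_power": sp["peak_power"],
                "mean_rate": float(np.sum(t >= t_on) / n / ((dur - t_on) * 1e-3)),
            })
    return pd.DataFrame(rows)
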