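"""LIF + receptor-gating integration.

Two integration paths share one update ordering:

* a compiled production path (:mod:`colrhythm._kernel`) used by
  :func:`run_simulation`;
* a plain-NumPy reference path built from the step-level operations
  :func:`total_synaptic_current`, :func:`step_membrane` and
  :func:`update_gating`, which is transparent enough to test against
  closed forms and which the kernel is cross-checked against.

Membrane integration is exponential-Euler on the leak term with the
synaptic current held constant over the step; gating decays use their
exact exponential factors; the NMDA saturation cross term is forward
Euler. There are no synaptic transmission delays: a spike stamped at the
end of a step increments its target gating for the following step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .column import ColumnSpec, ConfigurationError
from .constants import SynapseConstants, nmda_voltage_factor
from .groups import GROUPS, GroupId
from .network import NetworkAssembly
from .plasticity import InhStdpConfig, StdpConfig
from .synapses import AMPA, GABA, NMDA, SynapseTable

#: stability guard for the fixed step (ms)
DT_MAX = 0.1


class IntegrationFault(RuntimeError):
    """Non-finite membrane potential encountered during integration."""

    def __init__(self, neuron: int, t: float) -> None:
        super().__init__(f"non-finite membrane potential at neuron {neuron}, t={t:.3f} ms")
        self.neuron = neuron
        self.t = t


@dataclass
class SpikeRecord:
    """Spike times (ms) and neuron ids, plus group membership."""

    times: np.ndarray  # float64, non-decreasing
    ids: np.ndarray  # int32
    n_neurons: int
    group_idx: np.ndarray  # (n_neurons,) group index of every neuron
    duration: float  # ms
    t_start: float = 0.0

    def __len__(self) -> int:
        return len(self.times)

    def neurons_of_group(self, group: GroupId) -> np.ndarray:
        gi = GROUPS.index(group)
        return np.nonzero(self.group_idx == gi)[0]

    def for_group(self, group: GroupId) -> tuple[np.ndarray, np.ndarray]:
        gi = GROUPS.index(group)
        mask = self.group_idx[self.ids] == gi
        return self.times[mask], self.ids[mask]

    def spike_trains(self) -> dict[int, np.ndarray]:
        """Per-neuron sorted spike times, only neurons that fired."""
        order = np.argsort(self.ids, kind="stable")
        ids, times = self.ids[order], self.times[order]
        bounds = np.nonzero(np.diff(ids))[0] + 1
        chunks = np.split(times, bounds)
        first = np.concatenate([[0], bounds]) if len(ids) else []
        return {int(ids[i]): np.sort(c) for i, c in zip(first, chunks)} if len(ids) else {}

    def mean_rate(self, group: GroupId) -> float:
        """Population-mean firing rate of a group, Hz."""
        t, _ = self.for_group(group)
        n = len(self.neurons_of_group(group))
        if n == 0 or self.duration <= 0:
            return 0.0
        return len(t) / n / (self.duration * 1e-3)

    def to_dataframe(self):
        import pandas as pd

        from .groups import GROUP_LABELS
        return pd.DataFrame(
            {
                "neuron_id": self.ids,
                "time_ms": self.times,
                "group_label": [GROUP_LABELS[g] for g in self.group_idx[self.ids]],
            }
        )


# ---------------------------------------------------------------------------
# Reference path: explicit state and step operations
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    """Per-neuron membrane and per-presynaptic-neuron gating state."""

    t: float
    V: np.ndarray
    refr_until: np.ndarray
    s_ampa: np.ndarray
    s_gaba: np.ndarray
    s_nmda: np.ndarray
    x_nmda: np.ndarray
    s_ext: np.ndarray

    @classmethod
    def initial(cls, assembly: NetworkAssembly, t: float = 0.0) -> "NetworkState":
        n = assembly.n
        z = lambda: np.zeros(n)  # noqa: E731
        return cls(
            t=t,
            V=assembly.v_rest.copy(),
            refr_until=np.full(n, -np.inf),
            s_ampa=z(), s_gaba=z(), s_nmda=z(), x_nmda=z(), s_ext=z(),
        )


def total_synaptic_current(
    state: NetworkState,
    assembly: NetworkAssembly,
    I_ext: np.ndarray | float = 0.0,
    dense: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-neuron synaptic current (pA), depolarizing positive.

    The four recurrent/background terms use the conductance form
    g*(V - V_rev)*sum(w s); the value returned enters the membrane
    equation with a plus sign, so each term is negated such that
    excitatory input (V < V_E = 0) depolarizes and GABA input drives V
    toward the inhibitory reversal.
    """
    c = assembly.const
    if dense is None:
        dense = {r: assembly.dense_weight(r) for r in (AMPA, NMDA, GABA)}
    V = state.V
    I = np.broadcast_to(np.asarray(I_ext, dtype=float), V.shape).copy()
    I -= c.g_AMPA * (V - c.V_E) * (c.w_ext * state.s_ext + dense[AMPA] @ state.s_ampa)
    I -= (
        c.g_NMDA
        * (V - c.V_E)
        * nmda_voltage_factor(V, c.Mg)
        * (dense[NMDA] @ state.s_nmda)
    )
    if c.gaba_reversal == "pre":
        csr = assembly.receptors[GABA]
        Wv = np.zeros((assembly.n, assembly.n))
        for j in range(assembly.n):
            lo, hi = csr.indptr[j], csr.indptr[j + 1]
            Wv[csr.post[lo:hi], j] += csr.w[lo:hi] * assembly.gaba_pre_vrest[lo:hi]
        I -= c.g_GABA * (V * (dense[GABA] @ state.s_gaba) - Wv @ state.s_gaba)
    else:
        I -= c.g_GABA * (V - assembly.v_rest) * (dense[GABA] @ state.s_gaba)
    return I


def step_membrane(
    state: NetworkState,
    I_syn: np.ndarray,
    assembly: NetworkAssembly,
    dt: float,
    clamped: np.ndarray | None = None,
) -> tuple[NetworkState, np.ndarray]:
    """Advance membrane potentials one step; returns (state, spiked ids).

    Exponential-Euler: V relaxes toward V_rest + I/g_L with time constant
    tau_m. Threshold crossing resets V to V_rest and arms the refractory
    clock; refractory (and clamped) neurons hold V = V_rest and emit
    nothing. Spikes are stamped at the end of the step, t + dt.
    """
    if dt > DT_MAX:
        raise ConfigurationError(f"dt={dt} ms exceeds the stability guard {DT_MAX} ms")
    V = state.V.copy()
    active = state.t >= state.refr_until
    if clamped is not None:
        active &= ~clamped
    vinf = assembly.v_rest + I_syn / assembly.g_l
    m_decay = np.exp(-dt * assembly.g_l / assembly.c_m)
    V[active] = vinf[active] + (V[active] - vinf[active]) * m_decay[active]
    V[~active] = assembly.v_rest[~active]
    if not np.all(np.isfinite(V)):
        i = int(np.nonzero(~np.isfinite(V))[0][0])
        raise IntegrationFault(i, state.t)
    t_next = state.t + dt
    spiked = np.nonzero(active & (V >= assembly.v_th))[0]
    V[spiked] = assembly.v_rest[spiked]
    refr = state.refr_until.copy()
    refr[spiked] = t_next + assembly.tau_ref[spiked]
    new = NetworkState(
        t=t_next, V=V, refr_until=refr,
        s_ampa=state.s_ampa, s_gaba=state.s_gaba, s_nmda=state.s_nmda,
        x_nmda=state.x_nmda, s_ext=state.s_ext,
    )
    return new, spiked.astype(np.int32)


def update_gating(
    state: NetworkState,
    spikes: np.ndarray,
    dt: float,
    const: SynapseConstants,
    is_exc: np.ndarray,
    bg_events: np.ndarray | None = None,
) -> NetworkState:
    """Advance all gating variables one step.

    Between spikes AMPA/GABA/external gating decay by their exact
    exponential factors; NMDA gating follows first-order decay plus the
    saturating cross term alpha*x*(1-s)*dt (forward Euler), which keeps
    s_NMDA in [0, 1]. A spike of neuron j then increments s_AMPA[j] and
    x_NMDA[j] (excitatory j) or s_GABA[j] (inhibitory j) by one;
    background events increment the per-neuron external gating.
    """
    d_a = np.exp(-dt / const.tau_AMPA)
    d_g = np.exp(-dt / const.tau_GABA)
    d_n = np.exp(-dt / const.tau_NMDA_decay)
    d_x = np.exp(-dt / const.tau_NMDA_rise)
    s_ampa = state.s_ampa * d_a
    s_gaba = state.s_gaba * d_g
    src = const.alpha * state.x_nmda * (1.0 - state.s_nmda) * dt
    s_nmda = state.s_nmda * d_n + src
    x_nmda = state.x_nmda * d_x
    s_ext = state.s_ext * d_a
    if len(spikes):
        exc = spikes[is_exc[spikes]]
        inh = spikes[~is_exc[spikes]]
        s_ampa[exc] += 1.0
        x_nmda[exc] += 1.0
        s_gaba[inh] += 1.0
    if bg_events is not None:
        s_ext += bg_events
    return NetworkState(
        t=state.t, V=state.V, refr_until=state.refr_until,
        s_ampa=s_ampa, s_gaba=s_gaba, s_nmda=s_nmda, x_nmda=x_nmda, s_ext=s_ext,
    )


# ---------------------------------------------------------------------------
# Production path
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    spikes: SpikeRecord
    v_times: np.ndarray | None = None  # ms grid of recorded membrane samples
    v_traces: np.ndarray | None = None  # (n_samples, n_recorded)
    v_ids: np.ndarray | None = None
    weight_snapshots: list[tuple[float, SynapseTable]] = field(default_factory=list)
    final_table: SynapseTable | None = None


def _spike_capacity(assembly: NetworkAssembly, chunk_ms: float, dt: float) -> int:
    # refractoriness caps per-neuron spike counts; +1 slack per neuron
    return int(np.sum(chunk_ms / (assembly.tau_ref + dt) + 1.0)) + 1


def run_simulation(
    spec: ColumnSpec,
    connectivity,
    *,
    duration: float,
    dt: float = 0.05,
    seed: int = 0,
    stimulus_segments: list[tuple[float, float, np.ndarray]] | None = None,
    background: bool = True,
    bg_events: np.ndarray | None = None,
    plasticity: StdpConfig | None = None,
    inh_plasticity: InhStdpConfig | None = None,
    clamp_ids: np.ndarray | None = None,
    clamp_from: float = 0.0,
    record_v_ids: np.ndarray | None = None,
    record_v_dt: float = 1.0,
    snapshot_times: list[float] | None = None,
    return_final_table: bool = False,
    x_eps: float = 1e-4,
    chunk_ms: float = 1000.0,
    force_dt: bool = False,
    assembly: NetworkAssembly | None = None,
    const: SynapseConstants | None = None,
) -> SimulationResult:
    """Simulate the column for ``duration`` ms.

    ``connectivity`` is either a realized :class:`SynapseTable` or a
    :class:`ConnectivityData` (then the wiring is realized with a seed
    derived from ``seed``). Deterministic for fixed (seed, dt, config).
    ``stimulus_segments`` is a list of (t_start, t_end, per-neuron
    current in pA), non-overlapping; outside all segments the external
    current is zero. ``clamp_ids`` are silenced (voltage clamped at rest,
    no spikes) from ``clamp_from`` ms onward.
    """
    from .seeding import derive_seed

    if dt > DT_MAX and not force_dt:
        raise ConfigurationError(
            f"dt={dt} ms exceeds the stability guard {DT_MAX} ms (use force_dt)"
        )
    if assembly is None:
        if isinstance(connectivity, SynapseTable):
            table = connectivity
        else:
            from .synapses import build_synapse_table

            table = build_synapse_table(spec, connectivity, derive_seed(seed, "wiring"))
        assembly = NetworkAssembly(
            spec, table, const=const, inh_plastic_scope=inh_plasticity is not None
        )
    n = assembly.n
    c = assembly.const

    _kernel.seed_rng(derive_seed(seed, "background"))

    # per-step Bernoulli probability of one background event
    p_bg = assembly.bg_rate * dt * 1e-3 if background else np.zeros(n)
    if background and np.any(p_bg >= 0.25):
        worst = float(assembly.bg_rate.max())
        raise ConfigurationError(
            f"background rate {worst} Hz gives per-step event probability "
            f">= 0.25 at dt={dt} ms; reduce dt"
        )

    # state
    v = assembly.v_rest.copy()
    refr_until = np.full(n, -np.inf)
    s_ext = np.zeros(n)
    agg_ampa = np.zeros(n)
    agg_gaba = np.zeros(n)
    agg_gaba_v = np.zeros(n)
    s_nmda = np.zeros(n)
    x_nmda = np.zeros(n)
    agg_nmda = np.zeros(n)
    clamped = np.zeros(n, dtype=bool)

    m_decay = np.exp(-dt * assembly.g_l / assembly.c_m)
    d_ampa = np.exp(-dt / c.tau_AMPA)
    d_gaba = np.exp(-dt / c.tau_GABA)
    d_nmda = np.exp(-dt / c.tau_NMDA_decay)
    d_x = np.exp(-dt / c.tau_NMDA_rise)

    ampa = assembly.receptors[AMPA]
    nmda = assembly.receptors[NMDA]
    gaba = assembly.receptors[GABA]
    gaba_wv = gaba.w * assembly.gaba_pre_vrest

    pl = assembly.plastic
    stdp = plasticity or StdpConfig()
    plas_on = plasticity is not None and pl.n > 0
    pre_tr = np.zeros(n)
    post_tr = np.zeros(n)
    d_trp = np.exp(-dt / stdp.tau_plus)
    d_trm = np.exp(-dt / stdp.tau_minus)

    ipl = assembly.inh_plastic
    istdp = inh_plasticity or InhStdpConfig()
    iplas_on = inh_plasticity is not None and ipl.n > 0
    tr_fast = np.zeros(n)
    tr_slow = np.zeros(n)
    d_trf = np.exp(-dt / istdp.tau_plus)
    d_trs = np.exp(-dt / istdp.tau_minus)

    if record_v_ids is not None:
        record_v_ids = np.asarray(record_v_ids, dtype=np.int32)
        rec_every = max(1, int(round(record_v_dt / dt)))
    else:
        record_v_ids = np.empty(0, dtype=np.int32)
        rec_every = 1

    # timeline: cut at stimulus boundaries, clamp onset and snapshot times
    cuts = {0.0, float(duration)}
    segments = stimulus_segments or []
    for t0, t1, _ in segments:
        cuts.add(float(t0))
        cuts.add(float(t1))
    if clamp_ids is not None and len(clamp_ids):
        cuts.add(float(clamp_from))
    for ts in snapshot_times or []:
        cuts.add(float(ts))
    cuts = sorted(t for t in cuts if 0.0 <= t <= duration)

    all_t: list[np.ndarray] = []
    all_id: list[np.ndarray] = []
    v_rows: list[np.ndarray] = []
    v_times: list[np.ndarray] = []
    snapshots: list[tuple[float, SynapseTable]] = []
    out_info = np.zeros(4, dtype=np.int64)
    global_step = 0

    snap_set = sorted(set(float(t) for t in (snapshot_times or [])))
    if 0.0 in snap_set:
        snapshots.append((0.0, assembly.current_table()))

    for seg_i in range(len(cuts) - 1):
        seg_a, seg_b = cuts[seg_i], cuts[seg_i + 1]
        if seg_b - seg_a <= 0:
            continue
        i_ext = np.zeros(n)
        for t0, t1, cur in segments:
            if t0 <= seg_a and seg_b <= t1:
                i_ext = i_ext + cur
        if clamp_ids is not None and len(clamp_ids) and seg_a >= clamp_from:
            clamped[clamp_ids] = True

        pos = seg_a
        while pos < seg_b - 1e-9:
            chunk_end = min(pos + chunk_ms, seg_b)
            n_steps = int(round((chunk_end - pos) / dt))
            if n_steps == 0:
                break
            cap = _spike_capacity(assembly, n_steps * dt, dt)
            spike_t = np.empty(cap)
            spike_id = np.empty(cap, dtype=np.int32)
            if len(record_v_ids):
                n_samp = n_steps // rec_every + 2
                rec_v = np.empty((n_samp, len(record_v_ids)))
            else:
                rec_v = np.empty((1, 0))
            if bg_events is not None:
                bg_chunk = bg_events[global_step : global_step + n_steps]
                use_bg = True
            else:
                bg_chunk = np.zeros((1, 1), dtype=np.float64)
                use_bg = False

            _kernel.run_chunk(
                pos, dt, n_steps,
                v, assembly.v_rest, assembly.v_th, assembly.g_l, m_decay,
                assembly.tau_ref, refr_until, clamped, assembly.is_exc,
                c.g_AMPA, c.g_NMDA, c.g_GABA, c.Mg, c.V_E, c.w_ext,
                d_ampa, d_gaba, d_nmda, d_x, c.alpha, x_eps,
                c.gaba_reversal == "pre",
                s_ext, agg_ampa, agg_gaba, agg_gaba_v, s_nmda, x_nmda, agg_nmda,
                ampa.indptr, ampa.post, ampa.w,
                nmda.indptr, nmda.post, nmda.w,
                gaba.indptr, gaba.post, gaba.w, gaba_wv, assembly.gaba_pre_vrest,
                i_ext, p_bg, bg_chunk, use_bg,
                plas_on, stdp.A_plus, stdp.A_minus, d_trp, d_trm,
                stdp.w_min, stdp.w_max,
                pre_tr, post_tr,
                pl.out_indptr, pl.out_syn, pl.in_indptr, pl.in_syn,
                pl.pre, pl.post, pl.w, pl.ampa_idx, pl.nmda_idx,
                iplas_on, istdp.B_plus, istdp.B_minus, d_trf, d_trs,
                istdp.w_min, istdp.w_max,
                tr_fast, tr_slow,
                ipl.out_indptr, ipl.out_syn, ipl.in_indptr, ipl.in_syn,
                ipl.pre, ipl.post, ipl.w, ipl.ampa_idx,
                spike_t, spike_id,
                record_v_ids, rec_every, global_step % rec_every, rec_v,
                out_info,
            )
            n_sp, status = int(out_info[0]), int(out_info[1])
            if status == _kernel.STATUS_NONFINITE:
                raise IntegrationFault(int(out_info[2]), pos + out_info[3] * dt)
            if status == _kernel.STATUS_OVERFLOW:  # pragma: no cover - sized out
                raise RuntimeError("spike buffer overflow")
            all_t.append(spike_t[:n_sp].copy())
            all_id.append(spike_id[:n_sp].copy())
            if len(record_v_ids):
                n_rows = int(out_info[3])
                v_rows.append(rec_v[:n_rows].copy())
                first = rec_every - (global_step % rec_every)
                v_times.append(pos + (first + np.arange(n_rows) * rec_every) * dt)
            global_step += n_steps
            pos = chunk_end

        for ts in snap_set:
            if seg_a < ts <= seg_b + 1e-9 and all(abs(ts - s[0]) > 1e-9 for s in snapshots):
                snapshots.append((ts, assembly.current_table()))

    spikes = SpikeRecord(
        times=np.concatenate(all_t) if all_t else np.empty(0),
        ids=np.concatenate(all_id) if all_id else np.empty(0, np.int32),
        n_neurons=n,
        group_idx=assembly.group_idx,
        duration=float(duration),
    )
    result = SimulationResult(spikes=spikes)
    if len(record_v_ids):
        result.v_traces = np.vstack(v_rows) if v_rows else np.empty((0, len(record_v_ids)))
        result.v_times = np.concatenate(v_times) if v_times else np.empty(0)
        result.v_ids = record_v_ids
    result.weight_snapshots = snapshots
    if return_final_table or plasticity is not None or inh_plasticity is not None:
        result.final_table = assembly.current_table()
    return result


def simulate_reference(
    assembly: NetworkAssembly,
    duration: float,
    dt: float,
    bg_events: np.ndarray | None = None,
    i_ext: np.ndarray | float = 0.0,
    plasticity: StdpConfig | None = None,
    clamped: np.ndarray | None = None,
    record_v_ids: np.ndarray | None = None,
    record_v_every: int = 1,
) -> tuple[SpikeRecord, NetworkState, dict]:
    """Plain-NumPy integration of the identical update scheme (small nets).

    Used as the transparent cross-check for the compiled path; dense
    weight matrices, no performance tricks. Background events must be
    supplied precomputed (shape (n_steps, n)) or omitted.
    """
    from .plasticity import OnlineTraces, apply_plasticity_step

    n_steps = int(round(duration / dt))
    state = NetworkState.initial(assembly)
    dense = {r: assembly.dense_weight(r) for r in (AMPA, NMDA, GABA)}
    pl = assembly.plastic
    traces = OnlineTraces.zeros(assembly.n, pl.n)
    stdp = plasticity or StdpConfig()
    times, ids = [], []
    v_rows = []
    for k in range(n_steps):
        I = total_synaptic_current(state, assembly, i_ext, dense=dense)
        state, spiked = step_membrane(state, I, assembly, dt, clamped=clamped)
        if plasticity is not None and pl.n:
            apply_plasticity_step(traces, spiked, pl, stdp, dt)
            # write plastic logical weights through to the dense matrices
            for s in np.nonzero(traces.touched)[0]:
                if pl.ampa_idx[s] >= 0:
                    assembly.receptors[AMPA].w[pl.ampa_idx[s]] = pl.w[s]
                    dense[AMPA][pl.post[s], pl.pre[s]] = pl.w[s]
                if pl.nmda_idx[s] >= 0:
                    assembly.receptors[NMDA].w[pl.nmda_idx[s]] = pl.w[s]
                    dense[NMDA][pl.post[s], pl.pre[s]] = pl.w[s]
            traces.touched[:] = False
        ev = bg_events[k] if bg_events is not None else None
        state = update_gating(state, spiked, dt, assembly.const, assembly.is_exc, ev)
        # pin the clock to the step grid so refractory-release comparisons
        # agree bit-for-bit with the compiled path (t0 + k*dt, not += dt)
        state.t = (k + 1) * dt
        if len(spiked):
            times.append(np.full(len(spiked), state.t))
            ids.append(spiked)
        if record_v_ids is not None and (k + 1) % record_v_every == 0:
            v_rows.append(state.V[record_v_ids].copy())
    rec = SpikeRecord(
        times=np.concatenate(times) if times else np.empty(0),
        ids=np.concatenate(ids) if ids else np.empty(0, np.int32),
        n_neurons=assembly.n,
        group_idx=assembly.group_idx,
        duration=duration,
    )
    aux = {"v_rows": np.array(v_rows) if v_rows else None}
    return rec, state, aux
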