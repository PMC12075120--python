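"""Long-term plasticity rules.

Excitatory-to-excitatory synapses follow pair-based exponential STDP: a
pre-before-post interval x = t_post - t_pre > 0 potentiates by
A+ * exp(-x/tau+), post-before-pre depresses by A- * exp(x/tau-), summed
over *all* spike pairs. Because the kernels are exponentials, the
all-to-all pair sum is implemented exactly online with one presynaptic
and one postsynaptic trace per neuron. Weights are clipped into
[w_min, w_max] immediately after every increment. Slightly
depression-dominant parameters (A- tau- > A+ tau+) make uncorrelated
firing drift weights downward.

PV-to-E GABA synapses can follow a symmetric inhibitory rule
H(x) = B+ exp(-|x|/tau+) - B- exp(-|x|/tau-) with tau+ < tau-: a "sunken
Mexican hat" that strengthens inhibition for near-coincident spiking and
weakens it in the flanks; positive increments mean stronger inhibition.
Realized online with two trace pairs (one per time constant).

Exactly simultaneous spikes contribute nothing under either rule (the
excitatory kernel is defined on x > 0 and x < 0 only; for the inhibitory
rule this is a convention, chosen to match).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StdpConfig:
    """Excitatory STDP parameters (defaults are the model's values)."""

    A_plus: float = 0.02
    A_minus: float = 0.021
    tau_plus: float = 20.0  # ms
    tau_minus: float = 20.0  # ms
    w_min: float = 0.0
    w_max: float = 0.2

    def __post_init__(self) -> None:
        if self.A_plus <= 0 or self.A_minus <= 0:
            raise ValueError("A_plus and A_minus must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")


@dataclass(frozen=True)
class InhStdpConfig:
    """Symmetric PV->E rule parameters."""

    B_plus: float = 0.04
    B_minus: float = 0.02
    tau_plus: float = 10.0  # ms
    tau_minus: float = 20.0  # ms
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.B_plus > self.B_minus:
            raise ValueError("B_plus must exceed B_minus")
        if not self.tau_plus < self.tau_minus:
            raise ValueError("tau_plus must be below tau_minus (sunken-hat shape)")


def stdp_kernel(delta_t, cfg: StdpConfig = StdpConfig()):
    """Weight change for one spike pair, delta_t = t_post - t_pre (ms).

    Positive intervals potentiate, negative depress; exactly zero
    contributes nothing.
    """
    x = np.asarray(delta_t, dtype=float)
    out = np.where(
        x > 0,
        cfg.A_plus * np.exp(-x / cfg.tau_plus),
        np.where(x < 0, -cfg.A_minus * np.exp(x / cfg.tau_minus), 0.0),
    )
    return out if out.ndim else float(out)


def inh_kernel(delta_t, cfg: InhStdpConfig = InhStdpConfig()):
    """Symmetric inhibitory kernel H(delta_t); zero at exactly 0 by convention
    of pair handling, but the closed form is evaluated for any argument."""
    x = np.abs(np.asarray(delta_t, dtype=float))
    out = cfg.B_plus * np.exp(-x / cfg.tau_plus) - cfg.B_minus * np.exp(-x / cfg.tau_minus)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Online (trace) realizations
# ---------------------------------------------------------------------------


@dataclass
class OnlineTraces:
    """Per-neuron exponential trace accumulators."""

    pre: np.ndarray  # tau_plus trace (potentiation, read on post spikes)
    post: np.ndarray  # tau_minus trace (depression, read on pre spikes)
    touched: np.ndarray  # bool per logical synapse, set when weight changed

    @classmethod
    def zeros(cls, n_neurons: int, n_syn: int) -> "OnlineTraces":
        return cls(
            pre=np.zeros(n_neurons),
            post=np.zeros(n_neurons),
            touched=np.zeros(n_syn, dtype=bool),
        )


def apply_plasticity_step(
    traces: OnlineTraces, spikes: np.ndarray, plastic, cfg: StdpConfig, dt: float
) -> None:
    """One time step of the online rule over a plastic connection set.

    Mirrors the compiled path exactly: decay traces, apply weight updates
    for this step's spikes using trace values that exclude those spikes,
    clip into bounds, then increment the traces. ``plastic`` is the
    logical connection set from :class:`~colrhythm.network.NetworkAssembly`.
    """
    traces.pre *= np.exp(-dt / cfg.tau_plus)
    traces.post *= np.exp(-dt / cfg.tau_minus)
    for z in spikes:
        for s in plastic.out_syn[plastic.out_indptr[z] : plastic.out_indptr[z + 1]]:
            plastic.w[s] = np.clip(
                plastic.w[s] - cfg.A_minus * traces.post[plastic.post[s]],
                cfg.w_min, cfg.w_max,
            )
            traces.touched[s] = True
        for s in plastic.in_syn[plastic.in_indptr[z] : plastic.in_indptr[z + 1]]:
            plastic.w[s] = np.clip(
                plastic.w[s] + cfg.A_plus * traces.pre[plastic.pre[s]],
                cfg.w_min, cfg.w_max,
            )
            traces.touched[s] = True
    if len(spikes):
        traces.pre[spikes] += 1.0
        traces.post[spikes] += 1.0


def accumulate_stdp(
    pre_times: np.ndarray, post_times: np.ndarray, cfg: StdpConfig = StdpConfig()
) -> float:
    """Unclipped total weight change of one synapse from its spike trains.

    Event-driven online trace evaluation of the all-pairs sum; exact for
    the exponential kernels. Simultaneous pre/post spikes contribute 0.
    """
    pre_times = np.sort(np.asarray(pre_times, dtype=float))
    post_times = np.sort(np.asarray(post_times, dtype=float))
    events = [(t, 0) for t in pre_times] + [(t, 1) for t in post_times]
    events.sort()
    pre_tr = post_tr = 0.0
    t_last = None  # time the traces are currently valued at
    dw = 0.0
    i = 0
    while i < len(events):
        t = events[i][0]
        batch = []
        while i < len(events) and events[i][0] == t:
            batch.append(events[i][1])
            i += 1
        if t_last is not None:
            pre_tr *= np.exp(-(t - t_last) / cfg.tau_plus)
            post_tr *= np.exp(-(t - t_last) / cfg.tau_minus)
        t_last = t
        # updates use traces that exclude this instant's spikes, so
        # simultaneous pre/post pairs contribute F(0) = 0
        for kind in batch:
            if kind == 0:  # pre spike pairs with all earlier post spikes
                dw -= cfg.A_minus * post_tr
            else:  # post spike pairs with all earlier pre spikes
                dw += cfg.A_plus * pre_tr
        pre_tr += float(sum(1 for k in batch if k == 0))
        post_tr += float(sum(1 for k in batch if k == 1))
    return dw


def accumulate_inh(
    pre_times: np.ndarray, post_times: np.ndarray, cfg: InhStdpConfig = InhStdpConfig()
) -> float:
    """Unclipped total change under the symmetric inhibitory rule."""
    pre_times = np.sort(np.asarray(pre_times, dtype=float))
    post_times = np.sort(np.asarray(post_times, dtype=float))
    events = [(t, 0) for t in pre_times] + [(t, 1) for t in post_times]
    events.sort()
    trf = {0: 0.0, 1: 0.0}  # fast trace per side (0=pre, 1=post)
    trs = {0: 0.0, 1: 0.0}
    t_last = {0: -np.inf, 1: -np.inf}
    dw = 0.0
    i = 0
    while i < len(events):
        t = events[i][0]
        batch = []
        while i < len(events) and events[i][0] == t:
            batch.append(events[i][1])
            i += 1
        now_f, now_s = {}, {}
        for side in (0, 1):
            if np.isfinite(t_last[side]):
                now_f[side] = trf[side] * np.exp(-(t - t_last[side]) / cfg.tau_plus)
                now_s[side] = trs[side] * np.exp(-(t - t_last[side]) / cfg.tau_minus)
            else:
                now_f[side] = now_s[side] = 0.0
        for kind in batch:
            other = 1 - kind
            dw += cfg.B_plus * now_f[other] - cfg.B_minus * now_s[other]
        for side in (0, 1):
            inc = float(sum(1 for k in batch if k == side))
            trf[side] = now_f[side] + inc
            trs[side] = now_s[side] + inc
            t_last[side] = t
    return dw


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


@dataclass
class PlasticitySummary:
    mean_before: float
    mean_after: float
    mean_change: float
    frac_at_lower: float
    frac_at_upper: float
    bin_edges: np.ndarray
    hist_before: np.ndarray
    hist_after: np.ndarray
    per_projection: "object"  # DataFrame (pre_group, post_group, means, change)


def plasticity_summary(
    table_before,
    table_after,
    spec=None,
    bounds: tuple[float, float] = (0.0, 0.2),
    n_bins: int = 30,
    scope_mask: np.ndarray | None = None,
) -> PlasticitySummary:
    """Compare two weight snapshots of the same synapse table.

    Defaults to the plastic scope; reports the weight histograms before
    and after, the mean change, the fraction of weights sitting at the
    clip bounds, and per group-pair projection means when a
    :class:`ColumnSpec` is given.
    """
    import pandas as pd

    if len(table_before) != len(table_after):
        raise ValueError("snapshots must share one synapse topology")
    if not (
        np.array_equal(table_before.pre, table_after.pre)
        and np.array_equal(table_before.post, table_after.post)
    ):
        raise ValueError("snapshots must share one synapse topology")
    mask = scope_mask if scope_mask is not None else table_before.plastic
    w0 = table_before.weight[mask]
    w1 = table_after.weight[mask]
    lo, hi = bounds
    edges = np.linspace(lo, hi, n_bins + 1)
    h0, _ = np.histogram(w0, bins=edges)
    h1, _ = np.histogram(w1, bins=edges)
    per = None
    if spec is not None:
        gidx = spec.group_of_neuron()
        from .groups import GROUP_LABELS

        df = pd.DataFrame(
            {
                "pre_group": [GROUP_LABELS[g] for g in gidx[table_before.pre[mask]]],
                "post_group": [GROUP_LABELS[g] for g in gidx[table_before.post[mask]]],
                "w_before": w0,
                "w_after": w1,
            }
        )
        per = (
            df.groupby(["pre_group", "post_group"], sort=False)
            .agg(mean_before=("w_before", "mean"), mean_after=("w_after", "mean"),
                 n=("w_before", "size"))
            .reset_index()
        )
        per["mean_change"] = per["mean_after"] - per["mean_before"]
    eps = 1e-12
    return PlasticitySummary(
        mean_before=float(w0.mean()) if len(w0) else 0.0,
        mean_after=float(w1.mean()) if len(w1) else 0.0,
        mean_change=float((w1 - w0).mean()) if len(w0) else 0.0,
        frac_at_lower=float(np.mean(w1 <= lo + eps)) if len(w1) else 0.0,
        frac_at_upper=float(np.mean(w1 >= hi - eps)) if len(w1) else 0.0,
        bin_edges=edges,
        hist_before=h0,
        hist_after=h1,
        per_projection=per,
    )
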