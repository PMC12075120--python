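"""Flat array assembly of one column instance for the integrators.

Turns a :class:`ColumnSpec` plus a :class:`SynapseTable` into per-neuron
parameter vectors and presynaptically-indexed CSR connectivity, including
the bookkeeping that lets plastic excitatory-to-excitatory *logical*
connections (one weight shared by the AMPA and NMDA entries of a cell
pair) and plastic PV->E GABA synapses write through to the receptor
weight arrays used by the current sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .column import ColumnSpec
from .constants import SynapseConstants
from .groups import GROUPS
from .synapses import AMPA, GABA, NMDA, SynapseTable


def _csr_by_pre(pre: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(indptr, order) grouping synapse rows by presynaptic neuron."""
    order = np.argsort(pre, kind="stable")
    counts = np.bincount(pre, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, order


@dataclass
class _ReceptorCSR:
    indptr: np.ndarray  # (n+1,) int64, by presynaptic neuron
    post: np.ndarray  # int32 targets
    w: np.ndarray  # float64 weights (mutable under plasticity)
    rows: np.ndarray  # original SynapseTable row of each CSR entry
    pos_of_row: np.ndarray | None = None  # inverse map, row -> CSR position


@dataclass
class _PlasticSet:
    """Logical plastic connections with receptor write-through indices."""

    pre: np.ndarray  # int32
    post: np.ndarray  # int32
    w: np.ndarray  # float64 logical weights
    ampa_idx: np.ndarray  # int64 into ampa.w, -1 if no AMPA entry
    nmda_idx: np.ndarray  # int64 into nmda.w, -1 if no NMDA entry
    out_indptr: np.ndarray  # adjacency by presynaptic neuron
    out_syn: np.ndarray  # logical synapse ids
    in_indptr: np.ndarray  # adjacency by postsynaptic neuron
    in_syn: np.ndarray

    @property
    def n(self) -> int:
        return len(self.w)


def _empty_plastic_set(n_neurons: int) -> _PlasticSet:
    z64 = np.zeros(n_neurons + 1, dtype=np.int64)
    e = np.empty(0, dtype=np.int64)
    return _PlasticSet(
        pre=np.empty(0, np.int32), post=np.empty(0, np.int32),
        w=np.empty(0, np.float64), ampa_idx=e.copy(), nmda_idx=e.copy(),
        out_indptr=z64.copy(), out_syn=e.copy(),
        in_indptr=z64.copy(), in_syn=e.copy(),
    )


class NetworkAssembly:
    """All arrays the integrators need, derived once per run."""

    def __init__(
        self,
        spec: ColumnSpec,
        table: SynapseTable,
        const: SynapseConstants | None = None,
        inh_plastic_scope: bool = False,
    ) -> None:
        self.spec = spec
        self.const = const or SynapseConstants()
        self.table = table
        n = spec.n_neurons
        if table.n_neurons != n:
            raise ValueError("synapse table size does not match the column spec")
        self.n = n

        mem = spec.membrane
        self.group_idx = spec.group_of_neuron()
        slices = spec.group_slices()
        self.v_rest = np.empty(n)
        self.v_th = np.empty(n)
        self.g_l = np.empty(n)
        self.c_m = np.empty(n)
        self.tau_ref = np.empty(n)
        self.is_exc = np.zeros(n, dtype=bool)
        self.bg_rate = np.empty(n)
        for g in GROUPS:
            sl = slices[g]
            m = mem[g]
            self.v_rest[sl] = m.V_rest
            self.v_th[sl] = m.V_th
            self.g_l[sl] = m.g_L
            self.c_m[sl] = m.C_m
            self.tau_ref[sl] = m.tau_ref
            self.is_exc[sl] = g.is_excitatory
            self.bg_rate[sl] = spec.bkgnd_rate[g]
        self.exc_ids = np.nonzero(self.is_exc)[0].astype(np.int32)

        self.receptors: dict[int, _ReceptorCSR] = {}
        for rec in (AMPA, NMDA, GABA):
            rows = np.nonzero(table.receptor == rec)[0]
            indptr, order = _csr_by_pre(table.pre[rows], n)
            ordered = rows[order]
            self.receptors[rec] = _ReceptorCSR(
                indptr=indptr,
                post=table.post[ordered].astype(np.int32),
                w=table.weight[ordered].astype(np.float64).copy(),
                rows=ordered,
            )
            # row -> CSR position map, for plastic write-through
            self.receptors[rec].pos_of_row = np.full(len(table), -1, np.int64)
            self.receptors[rec].pos_of_row[ordered] = np.arange(len(rows))

        # GABA scatter weighted by presynaptic V_rest, for the "pre"
        # reversal convention
        gaba = self.receptors[GABA]
        pre_of_gaba = table.pre[gaba.rows]
        self._gaba_pre_vrest = self.v_rest[pre_of_gaba]

        self.plastic = self._build_excitatory_plastic(table)
        self.inh_plastic = (
            self._build_inhibitory_plastic(table)
            if inh_plastic_scope
            else _empty_plastic_set(n)
        )

    # -- plastic structures -------------------------------------------------

    def _build_excitatory_plastic(self, table: SynapseTable) -> _PlasticSet:
        rows = np.nonzero(table.plastic & np.isin(table.receptor, (AMPA, NMDA)))[0]
        if len(rows) == 0:
            return _empty_plastic_set(self.n)
        key = table.pre[rows].astype(np.int64) * self.n + table.post[rows]
        uniq, inverse = np.unique(key, return_inverse=True)
        n_logical = len(uniq)
        pre = (uniq // self.n).astype(np.int32)
        post = (uniq % self.n).astype(np.int32)
        w = np.zeros(n_logical)
        ampa_idx = np.full(n_logical, -1, np.int64)
        nmda_idx = np.full(n_logical, -1, np.int64)
        for rec, idx_arr in ((AMPA, ampa_idx), (NMDA, nmda_idx)):
            sel = table.receptor[rows] == rec
            idx_arr[inverse[sel]] = self.receptors[rec].pos_of_row[rows[sel]]
            w[inverse[sel]] = table.weight[rows[sel]]
        out_indptr, out_order = _csr_by_pre(pre, self.n)
        in_indptr, in_order = _csr_by_pre(post, self.n)
        return _PlasticSet(
            pre=pre, post=post, w=w, ampa_idx=ampa_idx, nmda_idx=nmda_idx,
            out_indptr=out_indptr, out_syn=out_order.astype(np.int64),
            in_indptr=in_indptr, in_syn=in_order.astype(np.int64),
        )

    def _build_inhibitory_plastic(self, table: SynapseTable) -> _PlasticSet:
        pv_pre = np.array(
            [GROUPS[i].cell_type == "PV" for i in self.group_idx]
        )
        e_post = self.is_exc
        rows = np.nonzero(
            (table.receptor == GABA) & pv_pre[table.pre] & e_post[table.post]
        )[0]
        if len(rows) == 0:
            return _empty_plastic_set(self.n)
        pre = table.pre[rows].astype(np.int32)
        post = table.post[rows].astype(np.int32)
        w = table.weight[rows].astype(np.float64).copy()
        gaba_idx = self.receptors[GABA].pos_of_row[rows]
        out_indptr, out_order = _csr_by_pre(pre, self.n)
        in_indptr, in_order = _csr_by_pre(post, self.n)
        ps = _PlasticSet(
            pre=pre, post=post, w=w, ampa_idx=gaba_idx,
            nmda_idx=np.full(len(rows), -1, np.int64),
            out_indptr=out_indptr, out_syn=out_order.astype(np.int64),
            in_indptr=in_indptr, in_syn=in_order.astype(np.int64),
        )
        return ps

    # -- views and write-back ----------------------------------------------

    def dense_weight(self, receptor: int) -> np.ndarray:
        """Dense (post, pre) weight matrix; reference path only."""
        csr = self.receptors[receptor]
        W = np.zeros((self.n, self.n))
        for j in range(self.n):
            lo, hi = csr.indptr[j], csr.indptr[j + 1]
            W[csr.post[lo:hi], j] += csr.w[lo:hi]
        return W

    @property
    def gaba_pre_vrest(self) -> np.ndarray:
        return self._gaba_pre_vrest

    def current_table(self) -> SynapseTable:
        """A SynapseTable snapshot with the current (possibly plastic) weights."""
        t = self.table.copy()
        for rec, csr in self.receptors.items():
            t.weight[csr.rows] = csr.w
        return t

    def set_weights_from_table(self, table: SynapseTable) -> None:
        """Load weights from a table with identical topology (e.g. a snapshot)."""
        if len(table) != len(self.table):
            raise ValueError("table topology mismatch")
        for rec, csr in self.receptors.items():
            csr.w[:] = table.weight[csr.rows]
        # refresh logical weights from their AMPA (or NMDA) entries
        pl = self.plastic
        has_a = pl.ampa_idx >= 0
        pl.w[has_a] = self.receptors[AMPA].w[pl.ampa_idx[has_a]]
        only_n = (~has_a) & (pl.nmda_idx >= 0)
        pl.w[only_n] = self.receptors[NMDA].w[pl.nmda_idx[only_n]]
        ip = self.inh_plastic
        if ip.n:
            ip.w[:] = self.receptors[GABA].w[ip.ampa_idx]
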