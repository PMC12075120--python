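"""Column architecture: population counts, membrane parameters, connectivity.

Counts follow the anatomical layer fractions (85% excitatory / 15%
inhibitory per full layer, with layer-specific interneuron proportions).
Group-level connectivity is held as a pair of 17x17 matrices: ``P``
(connection probabilities) and ``S`` (group-to-group strengths, arbitrary
units, magnitudes only -- the sign of a projection is carried by the
presynaptic cell class through its receptor type).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .groups import (
    CELL_TYPES,
    FULL_LAYERS,
    GROUP_INDEX,
    GROUP_LABELS,
    GROUPS,
    GroupId,
    N_GROUPS,
)


class ConfigurationError(ValueError):
    """Raised for invalid network configurations."""


class ConnectivityParseError(ValueError):
    """Raised when a connectivity matrix file cannot be parsed."""


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("colrhythm").joinpath("data").joinpath(name)))


@dataclass(frozen=True)
class MembraneParams:
    """Leaky integrate-and-fire parameters of one cell group."""

    C_m: float  # membrane capacitance, pF
    g_L: float  # leak conductance, nS
    tau_ref: float  # refractory period, ms
    V_rest: float  # resting potential, mV
    V_th: float  # spike threshold, mV

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.g_L <= 0:
            raise ConfigurationError("C_m and g_L must be positive")
        if self.tau_ref < 0:
            raise ConfigurationError("tau_ref must be non-negative")
        if self.V_th <= self.V_rest:
            raise ConfigurationError("V_th must exceed V_rest")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m/g_L, ms."""
        return self.C_m / self.g_L


def default_layer_fractions() -> dict[str, float]:
    df = pd.read_csv(_data_path("layer_fractions.csv"))
    return dict(zip(df["layer"], df["fraction"]))


def default_inh_fractions() -> dict[str, dict[str, float]]:
    df = pd.read_csv(_data_path("inh_fractions.csv")).set_index("layer")
    return {layer: {t: float(df.loc[layer, t]) for t in ("PV", "SST", "VIP")}
            for layer in df.index}


def default_membrane_params() -> dict[GroupId, MembraneParams]:
    df = pd.read_csv(_data_path("membrane.csv")).set_index("group")
    out = {}
    for g in GROUPS:
        row = df.loc[g.label]
        out[g] = MembraneParams(
            C_m=float(row["C_m_pF"]),
            g_L=float(row["g_L_nS"]),
            tau_ref=float(row["tau_ref_ms"]),
            V_rest=float(row["V_rest_mV"]),
            V_th=float(row["V_th_mV"]),
        )
    return out


def default_background_rates() -> dict[GroupId, float]:
    df = pd.read_csv(_data_path("background.csv")).set_index("group")
    return {g: float(df.loc[g.label, "rate_hz"]) for g in GROUPS}


INHIBITORY_FRACTION = 0.15  # of each full layer


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def compute_population_counts(
    n_total: int,
    layer_fractions: dict[str, float] | None = None,
    inh_fractions: dict[str, dict[str, float]] | None = None,
) -> dict[GroupId, int]:
    """Per-group neuron counts for a column of ``n_total`` cells.

    Per layer: the layer total is the rounded layer fraction of
    ``n_total``; each interneuron subtype count is the rounded share of
    the (unrounded) 15% inhibitory pool; the excitatory count is the
    layer remainder. Layer 1 holds VIP cells only.
    """
    if n_total < 17:
        raise ConfigurationError("n_total must be at least 17 (one neuron per group)")
    layer_fractions = layer_fractions or default_layer_fractions()
    inh_fractions = inh_fractions or default_inh_fractions()

    counts: dict[GroupId, int] = {}
    positive_expected: set[GroupId] = set()  # groups whose fraction is > 0
    counts[GroupId("L1", "VIP")] = _round_half_up(layer_fractions["L1"] * n_total)
    if layer_fractions["L1"] > 0:
        positive_expected.add(GroupId("L1", "VIP"))
    for layer in FULL_LAYERS:
        layer_n = _round_half_up(layer_fractions[layer] * n_total)
        pool = INHIBITORY_FRACTION * layer_n  # kept unrounded
        inh_total = 0
        for t in ("PV", "SST", "VIP"):
            c = _round_half_up(inh_fractions[layer][t] * pool)
            counts[GroupId(layer, t)] = c
            inh_total += c
            if inh_fractions[layer][t] > 0:
                positive_expected.add(GroupId(layer, t))
        counts[GroupId(layer, "E")] = layer_n - inh_total
        if layer_fractions[layer] > 0:
            positive_expected.add(GroupId(layer, "E"))

    for g in positive_expected:
        if counts[g] <= 0:
            raise ConfigurationError(
                f"n_total={n_total} is too small: group {g.label} would have "
                f"{counts[g]} neurons"
            )
    return counts


@dataclass
class ConnectivityData:
    """Group-level connectivity: probabilities ``P`` and strengths ``S``.

    Both matrices are 17x17 and indexed (presynaptic group, postsynaptic
    group) in canonical group order.
    """

    P: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.P.shape != (N_GROUPS, N_GROUPS) or self.S.shape != (N_GROUPS, N_GROUPS):
            raise ConfigurationError("P and S must both be 17x17")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ConfigurationError("connection probabilities must lie in [0, 1]")
        if np.any(self.S < 0):
            raise ConfigurationError("strengths are magnitudes and must be >= 0")

    def p(self, pre: GroupId, post: GroupId) -> float:
        return float(self.P[GROUP_INDEX[pre], GROUP_INDEX[post]])

    def s(self, pre: GroupId, post: GroupId) -> float:
        return float(self.S[GROUP_INDEX[pre], GROUP_INDEX[post]])


def _read_labeled_matrix(path: str | Path, what: str) -> np.ndarray:
    """Read one comma-separated matrix with group-label header row/column."""
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except Exception as exc:  # malformed file -> parse error, not a crash
        raise ConnectivityParseError(f"cannot parse {what} matrix {path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    for axis, labels in (("row", df.index), ("column", df.columns)):
        unknown = [l for l in labels if l not in GROUP_LABELS]
        if unknown:
            raise ConnectivityParseError(
                f"{what} matrix {path}: unknown {axis} label(s) {unknown}"
            )
        missing = [l for l in GROUP_LABELS if l not in labels]
        if missing:
            raise ConnectivityParseError(
                f"{what} matrix {path}: missing {axis} label(s) {missing}"
            )
    # align to canonical order regardless of file ordering
    df = df.loc[list(GROUP_LABELS), list(GROUP_LABELS)]
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        r, c = GROUP_LABELS[rows[0]], GROUP_LABELS[cols[0]]
        raise ConnectivityParseError(
            f"{what} matrix {path}: missing value at row {r!r}, column {c!r}"
        )
    return df.to_numpy(dtype=float)


def load_connectivity(path_P: str | Path, path_S: str | Path) -> ConnectivityData:
    """Load P and S from labeled CSV files (e.g. empirically fitted matrices).

    Rows are presynaptic groups, columns postsynaptic; any row/column
    ordering is accepted and realigned to canonical order.
    """
    P = _read_labeled_matrix(path_P, "probability")
    S = _read_labeled_matrix(path_S, "strength")
    bad = (P < 0) | (P > 1)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ConnectivityParseError(
            f"probability matrix {path_P}: value {P[i, j]} outside [0, 1] at "
            f"row {GROUP_LABELS[i]!r}, column {GROUP_LABELS[j]!r}"
        )
    return ConnectivityData(P=P, S=S)


def save_connectivity(conn: ConnectivityData, path_P: str | Path, path_S: str | Path) -> None:
    for mat, path in ((conn.P, path_P), (conn.S, path_S)):
        pd.DataFrame(mat, index=GROUP_LABELS, columns=GROUP_LABELS).to_csv(path, float_format="%.17g")


# --------------------------------------------------------------------------
# Synthetic connectivity
# --------------------------------------------------------------------------

#: layer-4-first excitatory feedforward chain through the column
FEEDFORWARD_CHAIN = (("L4", "L2/3"), ("L2/3", "L5"), ("L5", "L6"))

# Base within-layer motif (probability, strength) per (pre type, post type).
# Strengths are in the arbitrary units of the S matrix; the hierarchy
# PV->E > SST->E > VIP->E and the VIP->SST disinhibitory preference are
# built in. The excitatory strengths are small relative to inhibitory
# ones (inhibition-dominated regime), matching the soma-targeting strong
# PV projection versus dendrite-targeting SST and the weak direct VIP->E
# pathway. Probabilities are deliberately dense: with the w = G*s/(N*p)
# normalization, sparse projections from small populations produce
# outsized single-synapse weights whose shot noise breaks the
# size-invariance of the downscaled column, so the generator favors many
# weak synapses over few strong ones.
_WITHIN = {
    ("E", "E"): (0.15, 0.6),
    ("E", "PV"): (0.55, 1.4),
    ("E", "SST"): (0.55, 0.9),
    ("E", "VIP"): (0.45, 0.7),
    ("PV", "E"): (0.85, 7.0),
    ("PV", "PV"): (0.60, 5.0),
    ("PV", "SST"): (0.20, 0.6),
    ("PV", "VIP"): (0.40, 0.25),
    ("SST", "E"): (0.70, 2.5),
    ("SST", "PV"): (0.60, 1.8),
    ("SST", "SST"): (0.20, 0.5),
    ("SST", "VIP"): (0.70, 0.4),
    ("VIP", "E"): (0.25, 0.5),
    ("VIP", "PV"): (0.25, 0.4),
    ("VIP", "SST"): (0.80, 0.8),
    ("VIP", "VIP"): (0.30, 0.3),
}

# Cross-layer motifs as (probability, strength); feedforward E->E links
# along the L4 -> L2/3 -> L5 -> L6 chain are stronger than the remaining
# translaminar projections.
_FF_EE = (0.15, 0.5)
_FB_EE = (0.06, 0.2)
_CROSS_E_I = (0.20, 0.6)
_CROSS_I = (0.25, 0.4)
_CROSS_I_I = (0.35, 0.15)
_L1_VIP_SST = (0.50, 0.8)
_L1_VIP_E = (0.15, 0.5)
_E_TO_L1 = (0.15, 0.6)

# Layer-4 specific overrides. L4 is the feedforward input layer and the
# column's rhythm generator: its recurrent excitation is dense and
# relatively strong, and its inhibitory brake weak enough that the
# standard 30 pA stimulus drives pyramidal cells well above baseline.
# The dense E->E wiring also compensates downscaling: the plasticity cap
# w_max bounds single weights, so the maximum strength of a potentiated
# assembly scales with its in-degree N*p, and a reduced column needs a
# higher p to retain a cap ceiling comparable to the full-size circuit.
_L4_WITHIN = {
    ("E", "E"): (0.80, 1.2),
    ("E", "PV"): (0.55, 1.2),
    ("PV", "E"): (0.85, 5.0),
    ("SST", "E"): (0.70, 0.3),
    ("VIP", "E"): (0.25, 0.2),
}
#: cross-layer inhibition onto L4-E is scaled down by this factor
_L4_CROSS_INH_FACTOR = 0.3


def generate_synthetic_connectivity(
    seed: int, style: str = "inhibition_dominated", jitter: float = 0.15
) -> ConnectivityData:
    """Generate a stand-in connectivity pair (P, S).

    The empirically fitted matrices are not redistributable, so this
    generator emulates their qualitative structure. ``style``:

    ``"inhibition_dominated"``
        Within each full layer PV->E is stronger than SST->E, which is
        stronger than VIP->E; the excitatory feedforward chain
        L4 -> L2/3 -> L5 -> L6 is present; VIP cells preferentially
        target SST cells. All 289 entries are populated. A seeded
        lognormal jitter (sigma=``jitter``) individualizes entries while
        the ordering constraints are enforced as hard guarantees.

    ``"uniform"``
        All probabilities equal, all strengths equal (a structureless
        control).
    """
    rng = np.random.default_rng(seed)
    if style == "uniform":
        P = np.full((N_GROUPS, N_GROUPS), 0.1)
        S = np.full((N_GROUPS, N_GROUPS), 1.0)
        return ConnectivityData(P=P, S=S)
    if style != "inhibition_dominated":
        raise ConfigurationError(f"unknown connectivity style {style!r}")

    P = np.zeros((N_GROUPS, N_GROUPS))
    S = np.zeros((N_GROUPS, N_GROUPS))

    def put(pre: GroupId, post: GroupId, p: float, s: float) -> None:
        i, j = GROUP_INDEX[pre], GROUP_INDEX[post]
        P[i, j] = min(p * rng.lognormal(0.0, jitter), 1.0)
        S[i, j] = s * rng.lognormal(0.0, jitter)

    l1 = GroupId("L1", "VIP")
    for layer in FULL_LAYERS:
        for (tp, tq), (p, s) in _WITHIN.items():
            if layer == "L4" and (tp, tq) in _L4_WITHIN:
                p, s = _L4_WITHIN[(tp, tq)]
            put(GroupId(layer, tp), GroupId(layer, tq), p, s)
        put(l1, GroupId(layer, "SST"), *_L1_VIP_SST)
        put(l1, GroupId(layer, "E"), *_L1_VIP_E)
        put(GroupId(layer, "E"), l1, *_E_TO_L1)
    put(l1, l1, 0.05, 1.0)

    ff_pairs = set(FEEDFORWARD_CHAIN)
    for la in FULL_LAYERS:
        for lb in FULL_LAYERS:
            if la == lb:
                continue
            p_ee, s_ee = _FF_EE if (la, lb) in ff_pairs else _FB_EE
            put(GroupId(la, "E"), GroupId(lb, "E"), p_ee, s_ee)
            for t in ("PV", "SST", "VIP"):
                put(GroupId(la, "E"), GroupId(lb, t), *_CROSS_E_I)
                p_i, s_i = _CROSS_I
                if lb == "L4":
                    s_i *= _L4_CROSS_INH_FACTOR
                put(GroupId(la, t), GroupId(lb, "E"), p_i, s_i)
                for t2 in ("PV", "SST", "VIP"):
                    put(GroupId(la, t), GroupId(lb, t2), *_CROSS_I_I)

    # hard guarantees, independent of jitter draws
    for layer in FULL_LAYERS:
        e = GROUP_INDEX[GroupId(layer, "E")]
        pv = GROUP_INDEX[GroupId(layer, "PV")]
        sst = GROUP_INDEX[GroupId(layer, "SST")]
        vip = GROUP_INDEX[GroupId(layer, "VIP")]
        if not S[pv, e] > S[sst, e]:
            S[pv, e] = S[sst, e] * 1.5
        if not S[sst, e] > S[vip, e]:
            S[vip, e] = S[sst, e] * 0.25
        if not S[vip, sst] > max(S[vip, e], S[vip, pv], S[vip, vip]):
            S[vip, sst] = 2.0 * max(S[vip, e], S[vip, pv], S[vip, vip])
    for la, lb in FEEDFORWARD_CHAIN:
        i, j = GROUP_INDEX[GroupId(la, "E")], GROUP_INDEX[GroupId(lb, "E")]
        if P[i, j] <= 0:
            P[i, j] = _FF_EE[0]
    # every ordered pair populated
    P[P <= 0] = 0.01
    S[S <= 0] = 0.1
    return ConnectivityData(P=P, S=S)


@dataclass
class ColumnSpec:
    """Full architecture of one column instance.

    Holds per-group neuron counts, membrane parameters, background Poisson
    rates, and the global coupling factor G.
    """

    n_total: int
    counts: dict[GroupId, int]
    membrane: dict[GroupId, MembraneParams]
    bkgnd_rate: dict[GroupId, float]
    G: float = 5.0

    @classmethod
    def default(cls, n_total: int = 5000, G: float = 5.0) -> "ColumnSpec":
        return cls(
            n_total=n_total,
            counts=compute_population_counts(n_total),
            membrane=default_membrane_params(),
            bkgnd_rate=default_background_rates(),
            G=G,
        )

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.counts:
                raise ConfigurationError(f"missing count for group {g.label}")
            if g not in self.membrane:
                raise ConfigurationError(f"missing membrane params for {g.label}")
            if g not in self.bkgnd_rate:
                raise ConfigurationError(f"missing background rate for {g.label}")
            if self.bkgnd_rate[g] < 0:
                raise ConfigurationError(f"negative background rate for {g.label}")
        if any(c < 0 for c in self.counts.values()):
            raise ConfigurationError("negative group count")

    @property
    def n_neurons(self) -> int:
        """Realized network size (sum of group counts after rounding)."""
        return int(sum(self.counts.values()))

    def group_slices(self) -> dict[GroupId, slice]:
        """Contiguous neuron-id range of each group, canonical order."""
        out, start = {}, 0
        for g in GROUPS:
            n = self.counts[g]
            out[g] = slice(start, start + n)
            start += n
        return out

    def group_of_neuron(self) -> np.ndarray:
        """Group index (0..16) of every neuron id."""
        idx = np.empty(self.n_neurons, dtype=np.int16)
        for g, sl in self.group_slices().items():
            idx[sl] = GROUP_INDEX[g]
        return idx
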