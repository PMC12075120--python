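"""Realized synapses: Bernoulli wiring draws and weight normalization.

Group-level connectivity (probability p, strength s_hat) is expanded into
individual synapses. A spike from an excitatory neuron can reach AMPA
and/or NMDA receptors of its targets: the two receptor classes are wired
by *independent* Bernoulli draws at probabilities 0.8*p (AMPA) and 0.2*p
(NMDA). Inhibitory presynaptic neurons wire GABA_A synapses at
probability p. Every realized synapse of a group pair carries the weight

    w = G * s_hat / (N_send * p)

which keeps the *expected summed* input weight per postsynaptic neuron
from any presynaptic group equal to G*s_hat, independent of network size
and of p, so that population dynamics and equilibria are preserved when
the column is scaled down. Self-connections are excluded. All weights are
stored as magnitudes; the inhibitory sign enters through the GABA driving
force in the current equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .column import ColumnSpec, ConfigurationError, ConnectivityData
from .groups import GROUPS, GroupId

AMPA, NMDA, GABA = 0, 1, 2
RECEPTOR_NAMES = {AMPA: "AMPA", NMDA: "NMDA", GABA: "GABA"}
RECEPTOR_CODES = {v: k for k, v in RECEPTOR_NAMES.items()}

#: AMPA : NMDA wiring-probability split for excitatory projections
AMPA_FRACTION = 0.8
NMDA_FRACTION = 0.2


@dataclass
class SynapseTable:
    """Columnar store of realized synapses.

    Arrays are index-aligned: synapse k connects neuron ``pre[k]`` to
    ``post[k]`` through receptor ``receptor[k]`` with weight
    ``weight[k]``; ``plastic[k]`` marks synapses in the long-term
    plasticity scope (excitatory-to-excitatory by default).
    """

    pre: np.ndarray  # int32 presynaptic neuron ids
    post: np.ndarray  # int32 postsynaptic neuron ids
    receptor: np.ndarray  # int8 receptor codes (AMPA/NMDA/GABA)
    weight: np.ndarray  # float64 synaptic weights (>= 0)
    plastic: np.ndarray  # bool
    n_neurons: int

    def __post_init__(self) -> None:
        n = len(self.pre)
        for name in ("post", "receptor", "weight", "plastic"):
            if len(getattr(self, name)) != n:
                raise ValueError("synapse table arrays must be index-aligned")
        if n and (self.weight < 0).any():
            raise ValueError("weights are magnitudes and must be >= 0")

    def __len__(self) -> int:
        return len(self.pre)

    def copy(self) -> "SynapseTable":
        return SynapseTable(
            self.pre.copy(), self.post.copy(), self.receptor.copy(),
            self.weight.copy(), self.plastic.copy(), self.n_neurons,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre_id": self.pre,
                "post_id": self.post,
                "receptor": [RECEPTOR_NAMES[int(r)] for r in self.receptor],
                "weight": self.weight,
                "plastic": self.plastic.astype(int),
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_neurons: int) -> "SynapseTable":
        return cls(
            pre=df["pre_id"].to_numpy(np.int32),
            post=df["post_id"].to_numpy(np.int32),
            receptor=np.array([RECEPTOR_CODES[r] for r in df["receptor"]], np.int8),
            weight=df["weight"].to_numpy(np.float64),
            plastic=df["plastic"].to_numpy(bool),
            n_neurons=n_neurons,
        )

    @classmethod
    def load(cls, path: str | Path, n_neurons: int) -> "SynapseTable":
        return cls.from_dataframe(
            pd.read_csv(path, float_precision="round_trip"), n_neurons)

    def select(self, mask: np.ndarray) -> "SynapseTable":
        return SynapseTable(
            self.pre[mask], self.post[mask], self.receptor[mask],
            self.weight[mask], self.plastic[mask], self.n_neurons,
        )


def _bernoulli_pairs(
    rng: np.random.Generator, n_pre: int, n_post: int, p: float, same_group: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of wired (pre, post) pairs; diagonal excluded within a group."""
    draws = rng.random((n_pre, n_post)) < p
    if same_group:
        np.fill_diagonal(draws, False)
    return np.nonzero(draws)


def build_synapse_table(
    spec: ColumnSpec, conn: ConnectivityData, seed: int
) -> SynapseTable:
    """Realize the full synapse table for one column instance.

    Deterministic for a fixed seed. Excitatory-to-excitatory synapses are
    flagged plastic; the AMPA and NMDA entries of one cell pair share a
    single logical weight under plasticity (they are initialized equal
    here and are co-updated by the simulator).
    """
    rng = np.random.default_rng(seed)
    slices = spec.group_slices()
    pres, posts, recs, weights, plast = [], [], [], [], []

    for a in GROUPS:
        n_a = spec.counts[a]
        for b in GROUPS:
            p = conn.p(a, b)
            if p == 0.0:
                continue
            if n_a == 0:
                raise ConfigurationError(
                    f"connection {a.label}->{b.label} has p={p} but the sending "
                    f"group {a.label} is empty"
                )
            n_b = spec.counts[b]
            if n_b == 0:
                continue
            w = spec.G * conn.s(a, b) / (n_a * p)
            same = a == b
            if a.is_excitatory:
                splits = ((AMPA, AMPA_FRACTION * p), (NMDA, NMDA_FRACTION * p))
            else:
                splits = ((GABA, p),)
            for rec, p_eff in splits:
                i, j = _bernoulli_pairs(rng, n_a, n_b, p_eff, same)
                if len(i) == 0:
                    continue
                pres.append((i + slices[a].start).astype(np.int32))
                posts.append((j + slices[b].start).astype(np.int32))
                recs.append(np.full(len(i), rec, np.int8))
                weights.append(np.full(len(i), w, np.float64))
                plast.append(
                    np.full(len(i), a.is_excitatory and b.is_excitatory, bool)
                )

    if not pres:
        empty = lambda dt: np.empty(0, dt)  # noqa: E731
        return SynapseTable(
            empty(np.int32), empty(np.int32), empty(np.int8),
            empty(np.float64), empty(bool), spec.n_neurons,
        )
    return SynapseTable(
        np.concatenate(pres), np.concatenate(posts), np.concatenate(recs),
        np.concatenate(weights), np.concatenate(plast), spec.n_neurons,
    )
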