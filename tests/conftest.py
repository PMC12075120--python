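import numpy as np
import pytest

from colrhythm import ColumnSpec, generate_synthetic_connectivity, build_synapse_table
from colrhythm.column import ConnectivityData, default_membrane_params
from colrhythm.groups import GROUPS, GroupId
from colrhythm.synapses import SynapseTable


@pytest.fixture(scope="session")
def small_spec() -> ColumnSpec:
    """A ~300-neuron column with the packaged parameters."""
    return ColumnSpec.default(300)


@pytest.fixture(scope="session")
def conn() -> ConnectivityData:
    return generate_synthetic_connectivity(1)


@pytest.fixture(scope="session")
def small_table(small_spec, conn) -> SynapseTable:
    return build_synapse_table(small_spec, conn, seed=7)


def micro_spec(G: float = 5.0, bkgnd: float = 0.0, **counts_by_label) -> ColumnSpec:
    """A hand-sized column: zero neurons everywhere except the given groups."""
    counts = {g: 0 for g in GROUPS}
    for label, n in counts_by_label.items():
        counts[GroupId.from_label(label)] = n
    return ColumnSpec(
        n_total=sum(counts.values()),
        counts=counts,
        membrane=default_membrane_params(),
        bkgnd_rate={g: bkgnd for g in GROUPS},
        G=G,
    )


def conn_with(entries: dict[tuple[str, str], tuple[float, float]]) -> ConnectivityData:
    """All-zero connectivity except the listed (pre, post) -> (p, s) pairs."""
    from colrhythm.groups import GROUP_INDEX

    P = np.zeros((17, 17))
    S = np.zeros((17, 17))
    for (pre, post), (p, s) in entries.items():
        i = GROUP_INDEX[GroupId.from_label(pre)]
        j = GROUP_INDEX[GroupId.from_label(post)]
        P[i, j] = p
        S[i, j] = s
    return ConnectivityData(P=P, S=S)


#: reference cell counts of the standard 5,000-neuron column
TABLE_COUNTS_5000 = {
    ("L1", "VIP"): 96,
    ("L2/3", "E"): 1236, ("L2/3", "PV"): 65, ("L2/3", "SST"): 47, ("L2/3", "VIP"): 107,
    ("L4", "E"): 1010, ("L4", "PV"): 98, ("L4", "SST"): 53, ("L4", "VIP"): 27,
    ("L5", "E"): 741, ("L5", "PV"): 63, ("L5", "SST"): 56, ("L5", "VIP"): 11,
    ("L6", "E"): 1263, ("L6", "PV"): 102, ("L6", "SST"): 102, ("L6", "VIP"): 19,
}
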