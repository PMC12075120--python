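"""Receptor kinetics and synaptic constants.

AMPA and GABA_A gating decays first-order (2 ms and 5 ms); NMDA gating has
2 ms rise / 80 ms decay kinetics with a saturating cross term
alpha*x*(1-s) and a magnesium-dependent voltage factor. Receptor
conductances are configuration values (the group-to-group strength matrix
absorbs the overall scale); the external drive uses unit weight w_ext.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SynapseConstants:
    tau_AMPA: float = 2.0  # ms
    tau_GABA: float = 5.0  # ms
    tau_NMDA_decay: float = 80.0  # ms
    tau_NMDA_rise: float = 2.0  # ms
    alpha: float = 0.5  # 1/ms, NMDA saturation rate
    Mg: float = 1.0  # mM, extracellular magnesium
    V_E: float = 0.0  # mV, excitatory reversal
    g_AMPA: float = 1.0  # nS
    g_NMDA: float = 1.0  # nS
    g_GABA: float = 1.0  # nS
    w_ext: float = 1.0  # weight of background synapses
    #: GABA reversal: "post" uses the postsynaptic cell's V_rest (default),
    #: "pre" the presynaptic inhibitory group's V_rest.
    gaba_reversal: str = "post"

    def __post_init__(self) -> None:
        for name in ("tau_AMPA", "tau_GABA", "tau_NMDA_decay", "tau_NMDA_rise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.gaba_reversal not in ("post", "pre"):
            raise ValueError("gaba_reversal must be 'post' or 'pre'")


def nmda_voltage_factor(V, Mg: float = 1.0):
    """Fraction of NMDA conductance unblocked by magnesium at voltage V (mV).

    ``1 / (1 + Mg * exp(-0.062 V) / 3.57)``; strictly increasing in V and
    equal to 1 in the magnesium-free limit.
    """
    return 1.0 / (1.0 + Mg * np.exp(-0.062 * np.asarray(V, dtype=float)) / 3.57)
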