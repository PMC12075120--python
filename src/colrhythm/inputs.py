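"""External drive: background Poisson noise and current-step stimuli.

Every neuron owns an independent background Poisson generator whose rate
is set per group; background events excite the neuron's external AMPA
gating with unit weight. Sensory-like input is a constant current
injected into a seeded random subset of one population (30 pA to 50% of
layer-4 pyramidal cells in the standard protocol); feedback-like input
targets layer-5 pyramidal cells the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .column import ColumnSpec, ConfigurationError
from .groups import GroupId


@dataclass
class BackgroundDrive:
    """Per-neuron independent Poisson event streams.

    Events are binned per integration step: at step size dt (ms) each
    neuron fires a background event with probability rate*dt (kept well
    below 1 by the dt stability guard), which reproduces the nominal
    rate exactly in expectation.
    """

    rates: np.ndarray  # Hz per neuron
    seed: int

    def events(self, duration: float, dt: float) -> np.ndarray:
        """Precomputed event matrix (n_steps, n), entries 0/1 as float."""
        rng = np.random.default_rng(self.seed)
        n_steps = int(round(duration / dt))
        p = self.rates * dt * 1e-3
        if np.any(p >= 1.0):
            raise ConfigurationError("rate*dt too large for binned Poisson events")
        return (rng.random((n_steps, len(self.rates))) < p).astype(np.float64)


def make_background(spec: ColumnSpec, seed: int) -> BackgroundDrive:
    """Background drive with each group's nominal rate (from the spec)."""
    rates = np.empty(spec.n_neurons)
    for g, sl in spec.group_slices().items():
        r = spec.bkgnd_rate[g]
        if r < 0:
            raise ConfigurationError(f"negative background rate for {g.label}")
        rates[sl] = r
    return BackgroundDrive(rates=rates, seed=seed)


@dataclass(frozen=True)
class StimulusEpoch:
    group: GroupId
    fraction: float  # of the population targeted, in (0, 1]
    amplitude: float  # pA
    t_on: float  # ms
    t_off: float  # ms

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ConfigurationError("stimulus fraction must be in (0, 1]")
        if self.t_off <= self.t_on:
            raise ConfigurationError("epoch must satisfy t_on < t_off")


@dataclass
class StimulusProtocol:
    """Time-ordered current-injection epochs with a subset-selection seed."""

    epochs: list[StimulusEpoch] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.epochs = sorted(self.epochs, key=lambda e: e.t_on)


def stimulus_targets(
    spec: ColumnSpec, group: GroupId, fraction: float, seed: int
) -> np.ndarray:
    """The targeted neuron ids: first ceil(fraction*N) of a seeded permutation."""
    sl = spec.group_slices()[group]
    ids = np.arange(sl.start, sl.stop)
    k = math.ceil(fraction * len(ids))
    if k < 1:
        raise ConfigurationError("stimulus must target at least one neuron")
    rng = np.random.default_rng(seed)
    return np.sort(rng.permutation(ids)[:k])


def make_stimulus(
    protocol: StimulusProtocol, spec: ColumnSpec
) -> list[tuple[float, float, np.ndarray]]:
    """Realize a protocol as non-overlapping (t_start, t_end, I_ext) segments.

    The per-neuron current is the sum of all epochs active in a segment;
    outside every epoch the current is identically zero. The target
    subset of each epoch is deterministic for a fixed protocol seed
    (epochs are numbered in time order; each gets a derived sub-seed so
    that simultaneous feedforward and feedback epochs use independent
    subsets).
    """
    n = spec.n_neurons
    if not protocol.epochs:
        return []
    currents = []
    for k, ep in enumerate(protocol.epochs):
        if ep.group not in spec.group_slices():
            raise ConfigurationError(f"unknown stimulus group {ep.group}")
        ids = stimulus_targets(spec, ep.group, ep.fraction, protocol.seed + k)
        cur = np.zeros(n)
        cur[ids] = ep.amplitude
        currents.append(cur)
    bounds = sorted({float(ep.t_on) for ep in protocol.epochs}
                    | {float(ep.t_off) for ep in protocol.epochs})
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        cur = np.zeros(n)
        live = False
        for ep, c in zip(protocol.epochs, currents):
            if ep.t_on <= a and b <= ep.t_off:
                cur = cur + c
                live = True
        if live and np.any(cur != 0.0):
            segments.append((a, b, cur))
    return segments


def feedforward_protocol(
    amplitude: float = 30.0,
    fraction: float = 0.5,
    t_on: float = 700.0,
    t_off: float = 1.0e9,
    seed: int = 0,
) -> StimulusProtocol:
    """The standard evoked-input protocol: current to layer-4 pyramidal cells."""
    return StimulusProtocol(
        epochs=[StimulusEpoch(GroupId("L4", "E"), fraction, amplitude, t_on, t_off)],
        seed=seed,
    )
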