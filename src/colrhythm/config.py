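"""Run configuration: schema, defaults, YAML round-trip, validation.

A run is fully described by one :class:`RunConfig`. All randomness is
controlled by one master seed from which four independent named streams
are derived (wiring, background, stimulus-subset, plasticity/shuffle),
so control experiments can vary exactly one source at a time. Defaults
mirror the standard column: 5,000 neurons, G = 5, 0.05 ms step, 30 pA
feedforward stimulus protocol available as a preset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .column import ConfigurationError
from .groups import GROUP_LABELS, GroupId
from .inputs import StimulusEpoch, StimulusProtocol
from .plasticity import InhStdpConfig, StdpConfig
from .seeding import seed_table

DT_MAX = 0.1  # ms, stability guard


@dataclass
class NetworkConfig:
    n_total: int = 5000
    G: float = 5.0
    matrix_source: str = "synthetic"  # or "files"
    matrix_style: str = "inhibition_dominated"
    path_P: str | None = None
    path_S: str | None = None


@dataclass
class DynamicsConfig:
    dt: float = 0.05  # ms
    duration: float = 1500.0  # ms
    g_AMPA: float = 1.0  # nS
    g_NMDA: float = 1.0
    g_GABA: float = 1.0
    gaba_reversal: str = "post"
    x_eps: float = 1e-4
    force_dt: bool = False


@dataclass
class BackgroundConfig:
    enabled: bool = True
    #: per-group overrides of the packaged background rates, Hz
    rate_overrides: dict = field(default_factory=dict)


@dataclass
class StimulusEpochConfig:
    group: str = "E4"
    fraction: float = 0.5
    amplitude: float = 30.0  # pA
    t_on: float = 700.0  # ms
    t_off: float = 1.0e12


@dataclass
class PlasticityConfig:
    enabled: bool = False
    A_plus: float = 0.02
    A_minus: float = 0.021
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    w_min: float = 0.0
    w_max: float = 0.2
    #: restrict the plastic scope to E->E synapses whose presynaptic cell
    #: lies in these layers (None = all layers); "exclude" inverts.
    scope_pre_layers: list[str] | None = None
    scope_exclude: bool = False
    inh_enabled: bool = False
    B_plus: float = 0.04
    B_minus: float = 0.02
    inh_tau_plus: float = 10.0
    inh_tau_minus: float = 20.0
    inh_w_min: float = 0.0
    inh_w_max: float = 1.0


@dataclass
class AnalysisConfig:
    rate_window: float = 200.0  # ms
    rate_step: float = 1.0  # ms
    psd_segment_s: float = 2.0
    psd_overlap: float = 0.5
    band_lo: float = 5.0  # Hz
    band_hi: float = 100.0


@dataclass
class OutputConfig:
    directory: str = "runs"
    snapshot_times: list[float] = field(default_factory=list)
    record_v_count: int = 0  # membrane traces per group for synchrony


@dataclass
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    stimulus: list[StimulusEpochConfig] = field(default_factory=list)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0
    seeds: dict = field(default_factory=dict)  # resolved stream seeds

    def __post_init__(self) -> None:
        if not self.seeds:
            self.seeds = seed_table(self.seed)

    # -- helpers ------------------------------------------------------------

    def stdp_config(self) -> StdpConfig:
        p = self.plasticity
        return StdpConfig(
            A_plus=p.A_plus, A_minus=p.A_minus, tau_plus=p.tau_plus,
            tau_minus=p.tau_minus, w_min=p.w_min, w_max=p.w_max,
        )

    def inh_stdp_config(self) -> InhStdpConfig:
        p = self.plasticity
        return InhStdpConfig(
            B_plus=p.B_plus, B_minus=p.B_minus, tau_plus=p.inh_tau_plus,
            tau_minus=p.inh_tau_minus, w_min=p.inh_w_min, w_max=p.inh_w_max,
        )

    def protocol(self) -> StimulusProtocol:
        epochs = [
            StimulusEpoch(
                group=GroupId.from_label(e.group), fraction=e.fraction,
                amplitude=e.amplitude, t_on=e.t_on, t_off=e.t_off,
            )
            for e in self.stimulus
        ]
        return StimulusProtocol(epochs=epochs, seed=self.seeds["stimulus"])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()


_SECTIONS = {
    "network": NetworkConfig,
    "dynamics": DynamicsConfig,
    "background": BackgroundConfig,
    "plasticity": PlasticityConfig,
    "analysis": AnalysisConfig,
    "output": OutputConfig,
}


def _build_section(cls, data: dict, path: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigurationError(f"{path}.{key}: unknown field")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def _validate(cfg: RunConfig) -> RunConfig:
    if cfg.network.n_total < 17:
        raise ConfigurationError("network.n_total: must be at least 17")
    if cfg.network.matrix_source not in ("synthetic", "files"):
        raise ConfigurationError("network.matrix_source: 'synthetic' or 'files'")
    if cfg.network.matrix_source == "files" and not (
        cfg.network.path_P and cfg.network.path_S
    ):
        raise ConfigurationError(
            "network.path_P/path_S: required when matrix_source is 'files'"
        )
    if cfg.dynamics.dt > DT_MAX and not cfg.dynamics.force_dt:
        raise ConfigurationError(
            f"dynamics.dt: {cfg.dynamics.dt} ms exceeds the stability guard "
            f"{DT_MAX} ms (set dynamics.force_dt to override)"
        )
    if cfg.dynamics.dt <= 0:
        raise ConfigurationError("dynamics.dt: must be positive")
    if cfg.dynamics.gaba_reversal not in ("post", "pre"):
        raise ConfigurationError("dynamics.gaba_reversal: 'post' or 'pre'")
    for label, rate in cfg.background.rate_overrides.items():
        if label not in GROUP_LABELS:
            raise ConfigurationError(
                f"background.rate_overrides.{label}: unknown group"
            )
        if rate < 0:
            raise ConfigurationError(
                f"background.rate_overrides.{label}: rate must be >= 0"
            )
    for i, e in enumerate(cfg.stimulus):
        if e.group not in GROUP_LABELS:
            raise ConfigurationError(f"stimulus[{i}].group: unknown group {e.group!r}")
        if not 0 < e.fraction <= 1:
            raise ConfigurationError(f"stimulus[{i}].fraction: must be in (0, 1]")
        if e.t_off <= e.t_on:
            raise ConfigurationError(f"stimulus[{i}]: t_on must precede t_off")
    if cfg.plasticity.enabled:
        cfg.stdp_config()  # raises on invalid parameter combinations
    if cfg.plasticity.inh_enabled:
        cfg.inh_stdp_config()
    return cfg


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; omitted fields take model defaults.

    An empty file yields the full default configuration. All seeds are
    resolved and recorded on load.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigurationError(f"{key}: must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key == "stimulus":
            kwargs["stimulus"] = [
                _build_section(StimulusEpochConfig, e, f"stimulus[{i}]")
                for i, e in enumerate(value or [])
            ]
        elif key == "seed":
            kwargs["seed"] = int(value)
        elif key == "seeds":
            kwargs["seeds"] = dict(value)
        else:
            raise ConfigurationError(f"{key}: unknown section")
    return _validate(RunConfig(**kwargs))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# -- presets ----------------------------------------------------------------


def evoked_preset(**overrides) -> RunConfig:
    """Feedforward stimulation: 30 pA to 50% of L4 pyramids at 700 ms."""
    cfg = load_config(data={"stimulus": [{"group": "E4", "fraction": 0.5,
                                          "amplitude": 30.0, "t_on": 700.0}]})
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def conditioning_preset(duration: float = 55000.0, n_total: int = 5000,
                        seed: int = 0) -> RunConfig:
    """The plasticity protocol: 30 pA to half of L4-E from 500 ms onward,
    all E->E synapses plastic, for ``duration`` ms (55 s standard)."""
    return load_config(data={
        "seed": seed,
        "network": {"n_total": n_total},
        "dynamics": {"duration": duration},
        "stimulus": [{"group": "E4", "fraction": 0.5, "amplitude": 30.0,
                      "t_on": 500.0}],
        "plasticity": {"enabled": True},
    })
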