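# colrhythm

A spiking-network model of a mouse primary-visual-cortex (V1) column, for
studying when cortical rhythms emerge. The column contains 17 cell groups —
pyramidal cells (E) plus parvalbumin- (PV), somatostatin- (SST) and
vasoactive-intestinal-peptide-expressing (VIP) interneurons in layers 2/3,
4, 5 and 6, and a VIP-only layer 1 — each with its own leaky
integrate-and-fire parameters and background drive. Synapses carry
conductance-based AMPA, NMDA (magnesium-gated) and GABA_A currents;
excitatory-to-excitatory connections can undergo pair-based
spike-timing-dependent plasticity (STDP), and PV→E synapses optionally
follow a symmetric ("sunken Mexican hat") inhibitory rule. The package
bundles the experiments that probe how oscillations relate to
experience-dependent synaptic reorganization: spontaneous and evoked
activity, long conditioning runs under feedforward drive, interneuron
inactivations, layer-4 isolation, feedforward/feedback input sweeps, and
the control pair for attributing rhythms to weight *structure* — shuffling
conditioned weights between cell pairs, and uniformly scaling naive weights
to the conditioned mean.

It is aimed at computational neuroscientists who want a fast, fully
reproducible columnar model with data-constrained architecture: the
per-group cell counts, membrane parameters and background rates are
packaged; the group-to-group connectivity (a 17×17 probability matrix P and
strength matrix S) is loaded from labeled CSV files when you have empirical
matrices, or synthesized with a documented inhibition-dominated generator
when you do not.

## Model

Each neuron obeys

    C_m dV/dt = -g_L (V - V_rest) + I_syn(t)

with threshold V_th, reset to V_rest, and an absolute refractory period.
The synaptic current is

    I_syn = I_ext + I_ext,AMPA + I_AMPA + I_NMDA + I_GABA

where each receptor term has the form g·(V − V_rev)·Σ_j w_j s_j(t); NMDA
carries the voltage factor 1/(1 + [Mg²⁺] e^(−0.062 V)/3.57). Gating
variables jump on presynaptic spikes and decay with τ_AMPA = 2 ms,
τ_GABA = 5 ms; NMDA has 2 ms rise / 80 ms decay with saturation
α·x·(1 − s). Background noise is an independent per-neuron Poisson AMPA
stream at group-specific rates. Synaptic weights follow

    w = G · ŝ / (N_send · p),   G = 5,

which keeps the expected summed input per target equal to G·ŝ at any
network size. Excitatory axons contact AMPA and NMDA receptors with a
0.8 : 0.2 wiring split. STDP is the classic exponential pair rule
(A₊ = 0.02, A₋ = 0.021, τ± = 20 ms, weights clipped to [0, 0.2]),
implemented online with exact per-neuron traces.

## Worked example

```python
from colrhythm.config import load_config
from colrhythm.experiments import run_spontaneous

cfg = load_config(data={"network": {"n_total": 1000}, "seed": 1})
res = run_spontaneous(cfg)
for label in ("E4", "E5", "E6", "PV2/3", "PV4", "SST4", "VIP4"):
    print(f"{label:6s} {res.summaries['mean_rates'][label]:5.2f} Hz "
          f"CV={res.summaries['isi_cv'][label]['mean_cv']:.2f}")
```

prints (seed 1, 1,000 neurons, 1 s of activity after a 0.5 s warm-up):

```
E4      0.69 Hz CV=0.50
E5      3.22 Hz CV=0.62
E6      0.32 Hz CV=0.63
PV2/3   2.38 Hz CV=0.52
PV4     3.45 Hz CV=0.64
SST4    2.64 Hz CV=0.53
VIP4    0.60 Hz CV=0.73
```

— an asynchronous-irregular, inhibition-dominated spontaneous state:
pyramidal rates from a few hundredths of a Hz (layer 2/3 is nearly
silent) to a few Hz (highest in layer 5), interneurons mostly faster,
single-unit coefficients of variation at or above 0.5. The same configuration object drives every other experiment
(`run_evoked`, `run_conditioning`, `inactivate_groups`, `isolate_layer4`,
`input_sweep`, ...), and each result carries the provenance needed to
re-run it bit-identically.

From the shell the experiments are available as subcommands:

```bash
colrhythm spontaneous --set network.n_total=1000 --out runs/spont
colrhythm condition --set network.n_total=1000 --set dynamics.duration=55500 --out runs/cond
colrhythm sweep --axis FF_L4 --weights runs/cond/weights_final.csv --out runs/sweep.csv
```

Each run directory contains columnar spike/rate/weight files plus a
`manifest.json` with the configuration hash, resolved seeds and per-file
checksums.

## Using empirical connectivity

If you have group-level matrices (for example, fitted to anatomical and
electrophysiological data), save them as labeled CSV (header row and first
column `VIP1, E2/3, PV2/3, ...`) and point the configuration at them:

```yaml
network:
  matrix_source: files
  path_P: matrices/P.csv
  path_S: matrices/S.csv
```

The packaged synthetic generator is a stand-in that reproduces the
qualitative structure — strong within-layer PV→E inhibition, the
PV > SST > VIP hierarchy onto pyramidal cells, VIP→SST disinhibition, and
the L4 → L2/3 → L5 → L6 excitatory feedforward chain — but not any
particular empirical dataset; quantitative results that depend on the real
connectome (absolute oscillation frequencies and powers) require the
empirical matrices. See `docs/methods.md` for the model details, the
generator's design rationale, and known limitations.
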