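# Methods

## Model

The column is a network of leaky integrate-and-fire neurons partitioned
into 17 groups: layer 1 holds only VIP interneurons; layers 2/3, 4, 5 and
6 each hold pyramidal cells (85% of the layer) and PV, SST and VIP
interneurons (15% together, in layer-specific proportions). Group counts
for a column of `n_total` cells follow the packaged layer fractions: the
layer total is the rounded fraction of `n_total`; each interneuron
subtype is the rounded share of the (unrounded) 15% pool; the pyramidal
count is the layer remainder. This rule reproduces the reference census
of the standard 5,000-neuron column in all 17 cells. The packaged
layer-6 fraction is 0.2972, the value implied by that census (the
published per-layer fraction table and the census disagree there by one
neuron; the census is taken as authoritative). Doubling `n_total` tracks
doubled counts within ±1 per interneuron group and ±2 per pyramidal
group (the remainder absorbs up to three subtype roundings).

Membrane dynamics: `C_m dV/dt = -g_L (V - V_rest) + I_syn`, threshold
`V_th`, instantaneous reset to `V_rest`, absolute refractory period
`tau_ref` during which V is clamped at rest. All five parameters are
per-group (packaged tables). Synaptic currents are conductance-based:
AMPA and NMDA reverse at 0 mV, GABA_A at the *postsynaptic* cell's
`V_rest` by default (the convention is ambiguous in the source data; a
`gaba_reversal="pre"` switch uses the presynaptic group's rest instead).
NMDA carries the magnesium factor `1/(1 + [Mg] exp(-0.062 V)/3.57)` with
[Mg] = 1 mM. Gating: AMPA and GABA first-order with τ = 2 and 5 ms; NMDA
rise/decay 2/80 ms with saturation term `alpha x (1 - s)`, α = 0.5/ms,
which keeps s ≤ 1. Background noise is an independent per-neuron Poisson
spike train onto a dedicated external-AMPA gating variable with unit
weight, at the packaged per-group rates.

Weights follow `w = G ŝ /(N_send p)` with G = 5; `ŝ` and `p` come from
the 17×17 strength and probability matrices. The expected *summed* input
weight per target from any group is therefore G·ŝ, independent of
network size and connection density — the property that makes the
reduced columns used throughout the tests dynamically comparable to the
full-size column. Excitatory projections are wired twice, independently:
AMPA synapses at probability 0.8p and NMDA synapses at 0.2p, each
realized synapse carrying the full `w` above. Self-connections are
excluded. All weights are magnitudes; inhibition enters through the GABA
driving force.

Plasticity: excitatory-to-excitatory connections follow pair-based
exponential STDP, Δw summed over *all* spike pairs with
F(x) = A₊ e^(−x/τ₊) for x = t_post − t_pre > 0 and −A₋ e^(x/τ₋) for
x < 0 (A₊ = 0.02, A₋ = 0.021, τ± = 20 ms); F(0) contributes nothing.
Weights are clipped into [0, 0.2] immediately after every increment. The
AMPA and NMDA entries of one cell pair share a single logical weight.
PV→E GABA synapses can additionally follow the symmetric rule
H(x) = B₊ e^(−|x|/τ₊) − B₋ e^(−|x|/τ₋) (B₊ = 0.04, B₋ = 0.02, τ₊ = 10,
τ₋ = 20 ms; positive Δw strengthens inhibition). The source model states
no bounds for the inhibitory rule; weights are clipped into a
configurable range, default [0, 1].

## Numerics

Fixed step dt = 0.05 ms by default, guarded at 0.1 ms (the guard also
keeps the per-step background event probability below 0.25 at the
highest packaged rate). Membrane integration is exponential-Euler on the
leak with the synaptic current held over the step; gating decays use
exact exponential factors; the NMDA saturation cross term is forward
Euler. There are no synaptic transmission delays — a spike stamped at
the end of step k increments its targets' gating for step k+1. This is
worth stating prominently: conduction and synaptic delays shift
oscillation frequencies, and this model has none.

Update order within a step: (1) currents from the state at t, membrane
update, threshold/reset/refractory arming, spikes stamped t+dt;
(2) plasticity — decay traces, apply weight updates for this step's
spikes using trace values that exclude them (so simultaneous pre/post
pairs contribute F(0) = 0, and the all-pairs sum is reproduced exactly
for the exponential kernels), clip, then increment traces; (3) gating —
decay, NMDA source, spike increments, background events.

The production integrator is a compiled (numba) loop that stores
per-postsynaptic *aggregate* drives Σ_j w_ij s_j instead of recomputing
weighted sums: for first-order kinetics the aggregate obeys the same
exponential decay as its terms, so decaying it and scattering presynaptic
weights on spikes is exact. The NMDA aggregate receives the saturation
source scattered over the outgoing synapses of every presynaptic cell
whose rise variable exceeds a cutoff (x > 1e-4; the neglected tail is
~1e-4 of a spike's contribution). Under plasticity the aggregate scheme
applies the weight *at spike-arrival time* where a dense implementation
would apply the current weight to past gating; the difference decays on
the 2–5 ms receptor timescales. A plain-NumPy dense reference path
implements the identical ordering; on a small column with shared
background events the two paths produce identical spike trains (the
suite asserts this; over long horizons chaotic amplification of
last-ulp summation differences eventually desynchronizes any two
floating-point implementations).

Randomness is split into four named streams derived from one master seed
— wiring, background, stimulus-subset, plasticity/shuffle — so control
experiments vary exactly one factor. All runs are bit-reproducible from
their recorded configuration.

## Synthetic connectivity

The empirical group-level matrices are not redistributable, so the
package ships a generator that emulates their qualitative structure:
inhibition-dominated within-layer motifs with the strength hierarchy
PV→E > SST→E > VIP→E (enforced as hard guarantees under the seeded
lognormal entry jitter), VIP preferentially targeting SST, an excitatory
feedforward chain L4 → L2/3 → L5 → L6, weaker feedback and translaminar
projections, and all 289 ordered pairs populated.

Two design rules shaped the default numbers, both consequences of the
`w = G ŝ/(N p)` normalization at reduced scale:

* **Dense, weak wiring.** A sparse projection from a small population
  produces few, large synapses whose shot noise grows as 1/(N p) when
  the column is scaled down, systematically inflating fluctuation-driven
  rates in small networks. The generator therefore favors many weak
  synapses (connection probabilities 0.15–0.85) so that per-group
  spontaneous rates at n = 2,500 and n = 5,000 agree within sampling
  error. One group resists this: VIP in layer 5 has only 11 cells at
  n = 5,000 (6 at 2,500), and its rate retains a genuine ~20% finite-size
  deviation driven by few-cell quenched statistics — disconnected and
  zero-input-weight controls match exactly across sizes, so the effect
  is collective, not an integrator artifact. Tests assert the invariance
  for all groups and this one is a known, documented failure.

* **A layer-4 microcircuit tuned as the rhythm generator.** Layer 4
  receives the feedforward input and is the column's oscillation
  generator, so its recurrent excitation is dense (p = 0.8 within-layer
  E→E) and its inhibitory brake weaker than in other layers, leaving its
  pyramidal cells responsive to the standard 30 pA stimulus. Density
  also compensates downscaling of the plasticity ceiling: the 0.2 weight
  cap bounds a potentiated assembly's total recurrence by its in-degree
  N·p, which a 1,000-neuron column would otherwise lose five-fold
  relative to full size.

What the generator does *not* emulate: the empirical matrices' specific
asymmetries and magnitudes. Absolute oscillation frequencies and powers
(for example the full-column ~26 Hz rhythm and its isolated-L4
counterpart) depend on those data and are only meaningful when the user
supplies the real matrices; with synthetic matrices the package asserts
*directions*, not magnitudes.

## Experiments and measurement

Population rates use a 200 ms sliding window on a 1 ms grid with
truncated edge normalization. Spectra are Welch estimates of the
mean-subtracted rate (2 s Hann segments, 50% overlap), peak taken over
5–100 Hz; the spectral estimator of the source work is unstated, so
absolute powers are comparable only within this package. Irregularity is
the ISI coefficient of variation (units with ≥ 3 spikes). Synchrony is
the membrane-potential measure χ = sqrt(Var_t(mean_i V_i)/mean_i Var_t V_i).
Activation latency is the first crossing of baseline + half the evoked
peak, linearly interpolated; a rise of less than three baseline standard
deviations is reported as undefined.

The conditioning protocol is the source model's: a constant 30 pA into a
seeded half of the layer-4 pyramidal cells from t = 0.5 s for 55 s with
all E→E weights plastic. (A shorter 10 s variant was considered and
rejected: at the rates this stimulus evokes, pair-based STDP moves
weights by less than 0.01 in 10 s — the 55 s duration is integral to the
protocol, not a display choice.) Inactivation clamps the selected
neurons' potentials at rest from the given time on, with their gating
decaying naturally; a size-matched PV subset can be silenced for the
PV-versus-SST comparison. Layer-4 isolation filters the synapse table to
L4→L4. The shuffle control permutes weight values among the plastic
synapses (topology, receptors and the weight multiset preserved
exactly); the uniformly-increased control scales naive weights by the
conditioned/naive mean ratio (means then match to machine precision).

The packaged control-triad experiment (`control_triad`) evaluates the
naive, conditioned, shuffled, uniformly-increased and input-free columns
with frozen weights, reusing the conditioned column's wiring and
stimulated subset and varying only the background stream; powers are
read at the conditioned network's peak frequency inside the 15–60 Hz
band where the plasticity-related rhythm lives. At the reduced scale
(n = 1,000, synthetic matrices) the reproducible outcomes over seeds
are: conditioning raises the layer-4 pyramidal peak power above the
naive column's; the uniformly-increased control shows no comparable
increase; removing the feedforward input abolishes the peak; silencing
all interneurons makes every pyramidal population's rate jump. The
shuffle control does *not* separate from the conditioned column at this
scale: the measured power gain is carried by the weight-distribution
statistics (net potentiation plus a heavy tail), which shuffling
preserves by construction, while the pair-specific resonant-assembly
component that makes shuffling collapse the full-size column's rhythm is
bounded by the capped in-degree of a 1,000-neuron assembly. The
corresponding acceptance test is kept and fails, documenting the limit
rather than hiding it.

## Problem sizes used by the test and acceptance suites

Counts and closed-form oracles run on single neurons or micro-columns in
milliseconds. The kernel/reference equivalence uses a ~60-neuron
microcircuit for 250 ms. The finite-size comparison simulates 2 s
(0.5 s warm-up + 1.5 s measured, the standard display window) at
n = 2,500 and 5,000 over five seeds. The control triad conditions five
reduced columns (n = 1,000) for 55 s each and evaluates each variant for
4.5 s twice. These sizes are the package's standing defaults for its own
validation; all are configurable.

## Known limitations

Point neurons only; no spike-frequency adaptation, short-term
plasticity, or synaptic/conduction delays; plasticity restricted to E→E
(and optionally PV→E); background is AMPA-only and stationary; the
synthetic connectivity is a qualitative stand-in, so quantitative
spectral targets require empirical matrices; receptor conductances
default to 1 nS and are configuration values (the source model never
states them — they are presumed absorbed into the strength-matrix
calibration); the VIP-L5 finite-size deviation and the reduced-scale
shuffle insensitivity described above.
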