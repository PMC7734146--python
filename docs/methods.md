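# Methods

## Model

`aeifnet` simulates random directed networks of adaptive exponential
integrate-and-fire (AEIF) neurons coupled by delayed, conductance-based
chemical synapses, optionally including autapses (self-connections).
Each neuron j obeys

    C_m dV_j/dt = -g_L (V_j - E_L) + g_L Δ_T exp((V_j - V_T)/Δ_T)
                  - w_j + I + I_j^chem(t)
    τ_w dw_j/dt = a_j (V_j - E_L) - w_j
    τ_s ds_j/dt = -s_j

When V_j exceeds the detection cutoff V_thres the state is reset:
V_j → V_r, w_j → w_j + b_j, s_j → s_j + 1.  The synaptic input is

    I_j^chem = (V_REV^exc - V_j) Σ_k M^exc_jk g(k→j) s_k(t - d_exc)
             + (V_REV^inh - V_j) Σ_k M^inh_jk g(k→j) s_k(t - d_inh)

where M^exc / M^inh are the binary adjacency matrices restricted to
excitatory / inhibitory presynaptic neurons, g(k→j) is the conductance
of the edge's class, and the presynaptic trace is evaluated one delay in
the past (d depends on the presynaptic neuron's type).  The model is
deterministic given the network realization and initial conditions; all
randomness enters through seeded generators.

### Trace normalization

The per-neuron synaptic state is a *normalized* trace s_j, incremented
by exactly 1 per spike and decaying with τ_s.  The physical conductance
of a connection is the product of the class conductance with the delayed
trace.  A literal per-neuron conductance incremented by "the" class
value would be ambiguous here, because a spiking neuron projects edges
of several classes (e.g. an autapse at g_e_aut = 20 nS alongside
recurrent edges at g_e = 0.05 nS) whose six conductances are independent
parameters.  Factoring the magnitude into the per-edge weight keeps each
class conductance meaningful on its own; for a neuron with outgoing
edges of a single class the two formulations coincide.

### Parameters and defaults

All defaults are the reference cortical values (units: pF, nS, mV, ms,
pA):

| parameter | default | meaning |
|---|---|---|
| C_m | 200 pF | membrane capacitance |
| g_L | 12 nS | leak conductance |
| E_L | −70 mV | leak reversal |
| Δ_T | 2 mV | spike-initiation slope factor |
| V_T | −50 mV | exponential threshold |
| τ_w | 300 ms | adaptation time constant |
| τ_s | 2.728 ms | synaptic trace decay |
| V_r | −58 mV | reset potential |
| I | 270 pA | constant drive |
| a_j | U[1.9, 2.1] nS (exc), 0 (inh) | subthreshold adaptation |
| b_j | 70 pA (exc), 0 (inh) | spike-triggered adaptation |
| V_REV | 0 mV (exc), −80 mV (inh) | synaptic reversal potentials |
| d | 1.5 ms (exc), 0.8 ms (inh) | presynaptic-type delays |
| V_thres | −40 mV | spike-detection cutoff |

V_thres is a numerical convention rather than a biophysical constant: it
must lie above V_T so the exponential upswing can develop, and we place
it at V_T + 5Δ_T.  Because the upswing traverses the region above V_T in
a few hundredths of a millisecond at dt = 0.01 ms, moving the cutoff by
several mV shifts detected spike times by well under one step.  It is
exposed as a configuration field.  Δ_T → 0 (hard-threshold limit) is not
supported; the exponential argument is clipped at +50 to prevent
overflow between crossing and reset (never active at or below V_thres
with the defaults).

Initial conditions: V_j ~ U[−70, −50] mV; w_j ~ U[0, 300] pA
(excitatory) or U[0, 80] pA (inhibitory); s_j = 0, with empty delay
history (no activity at t ≤ 0).

### Network construction

Populations: the first round(P_exc·N) neurons are excitatory (default
80/20 split).  Six edge classes with independent conductances:
ee (g_e), ei (g_ei), ii (g_i), ie (g_ie) and the autapse classes
e_aut (g_e_aut), i_aut (g_i_aut).  Ordinary synapses are sampled i.i.d.
Bernoulli per ordered pair, self-pairs excluded, with probabilities
p_e = 0.05, p_i = 0.2, p_ei = p_ie = 0.05 by default — the probabilities
are defined as count ratios over eligible pairs, and Bernoulli sampling
is the simplest null model consistent with them.  Autapses are treated
differently: the autapse probability is a count ratio over the
population (p_aut = N_aut/N_pop = 0.25), which reads as a fixed
fraction, so exactly round(p_aut·N_pop) neurons are flagged, chosen
uniformly without replacement, each receiving one self-edge.  Multiple
edges per ordered pair are disallowed.  When a population is absent the
cross-population probabilities are undefined and ignored (with a
warning).

One master seed feeds four named substreams (graph wiring, autapse
placement, initial conditions, per-neuron adaptation draws), so each
source of randomness can be varied in isolation — in particular a sweep
can hold the topology fixed per seed while changing conductances.

## Numerical integration

Classical fixed-step RK4 at dt = 0.01 ms.  Delayed traces live in a
ring buffer sampled on the dt grid (delays must be integer multiples of
dt; 1.5 ms → 150 steps, 0.8 ms → 80).  Within a step's four substages
the delayed trace is frozen at its value for the step-start time — the
delayed value is only available on the grid, and the O(dt) error of
freezing it is negligible against τ_s = 2.728 ms — while the driving
force (V_REV − V) uses the substage voltage.  After each full step all
threshold crossings are detected and reset simultaneously; the spike
time is recorded as the step-end time (no sub-step interpolation, error
bounded by dt), and the post-reset trace enters the history buffer, so
an increment becomes visible to its targets exactly one delay later
(strictly causal).  Halving dt on a coupled 10-neuron fixture moves
spike times by less than 0.1 ms over 2 s (verified in the test suite).

The inner loop is a numba kernel.  Its fastmath flags are restricted to
value-safe transformations (`nsz`, `arcp`, `contract`, `reassoc`):
`nnan`/`ninf` are excluded so that a non-finite state remains
observable, and `afn` is excluded so `exp` keeps full precision.
State validity is checked by a range test (which rejects NaN and ±inf
under these flags, unlike `isfinite`, which LLVM may fold away) swept
every 100 steps; a NaN state persists — NaN never crosses the threshold
comparison, so it is never reset away — hence the sweep misses nothing
and an abort names the neuron and the detection time within 1 ms of
onset.

The mean network current I^chem(t) is recorded every 0.1 ms (100×
coarser than dt, configurable) to bound output size.

## Diagnostics

*Phases and synchronization.*  Between consecutive spikes the phase
grows linearly by 2π: ψ_j(t) = 2πm + 2π(t − t_{j,m})/(t_{j,m+1} −
t_{j,m}).  The Kuramoto order parameter R(t) = |N'⁻¹ Σ exp(iψ_j)| is
sampled every 1 ms (configurable) and time-averaged with the
trapezoidal rule over the analysis window (default [10, 20] s at full
scale, [4, 8] s at desk scale) to give R̄, with subgroup variants over
autaptic / non-autaptic neurons.  The phase is defined only between a
neuron's first and last recorded spike (right-open); neurons without a
defined phase at a grid point are excluded there rather than
extrapolated, and the normalization N' counts only contributors.  An
integer shift of the spike index changes ψ by a multiple of 2π, so the
phase-origin convention cannot affect R.

*Variability.*  CV_j = σ_ISI/mean ISI per neuron, averaged over neurons
with at least two ISIs in the window (others excluded and counted).
The population standard deviation (ddof = 0) is the default — it is
defined already for two ISIs — with ddof switchable.  The collective
pattern is classified as burst firing when CV̄ ≥ 0.5 (inclusive) and
spike firing below.

*Rates.*  Subset firing rate = spike count in the half-open window
(t_ini, t_fin] divided by (subset size × window length), in Hz, for the
subsets all/autaptic/non-autaptic/excitatory/inhibitory.

*Currents.*  Ī_s is the trapezoidal time average of the recorded
I^chem(t) over the analysis window.

## Synthetic spike trains

The generator produces ensembles with known phase structure so every
diagnostic is testable without the simulator: identical periodic trains
(R̄ = 1, CV = 0), anti-phase pairs (R = 0 mid-interval), jittered
periodic trains (independent per-spike Gaussian jitter truncated at
±0.49 period — per-spike rather than cumulative, so the underlying
phase structure the order parameter measures is preserved and ISIs stay
positive), and homogeneous Poisson trains (CV ≈ 1).  These fixtures
emulate idealized limits, not simulator output: they have no adaptation
transients, no rate heterogeneity across neurons, and no delayed-coupling
correlations, so diagnostic tests on them validate the *measures*, not
the network dynamics.

## Experiment drivers and problem sizes

The drivers regenerate the reference studies at desk scale: N = 200
neurons, 8 s runs analysed over [4, 8] s, coarse conductance grids
(≤ 11×11) and ≥ 3 seeds, with one topology per seed reused across a
sweep (resampling per point is a switch).  These sizes were chosen so a
full study runs on a single core in minutes while preserving the
qualitative structure — the firing-rate ordering of autaptic vs
non-autaptic neurons, the burst transitions, and the
synchronization contrasts between the marked conductance points — which
we verified against the full-scale directions.  Conductances are *not*
rescaled with N, so absolute synaptic drive per neuron is smaller than
at N = 1000 (indegree scales with N); quantitative R̄/F̄ values at desk
scale are therefore not comparable pixel-by-pixel with full-scale maps,
only the orderings and transitions are.  The full-scale configuration
(N = 1000, 20 s, fine grids) is supported but not the default.

Marked excitatory-only points ship as presets: circle (g_e = 0.05,
g_e_aut = 10 nS), triangle (0.05, 31), square (0.1, 15), hexagon
(0.1, 22); mixed-network points: circle (g_ei = 0.5, g_ie = 1.5),
square (1.8, 1.5), triangle (4.5, 0.5) nS on top of g_e = 0.5,
g_i = 2 nS.

## Degenerate inputs and edge cases

- Empty graphs are valid (N uncoupled neurons).
- A population of size 0 disables its classes; subgroup metrics over an
  empty subset are NaN (and signalled when requested directly).
- Neurons with < 2 spikes have no phase and no CV; they are excluded
  per grid point / from CV̄ and counted.
- A failed sweep point records missing-value rows with the failure
  reason instead of aborting the sweep.
- Spike-buffer capacity is sized for ~100 Hz mean rate and doubled
  (with a deterministic rerun) on overflow.

## Known limitations

- No sub-step spike-time interpolation; spike times carry O(dt) bias.
- The delayed trace is piecewise-constant across RK4 substages (O(dt)).
- No synaptic plasticity, noise currents, gap junctions, or
  event-driven integration.
- Only Erdős–Rényi-type random topologies; no small-world or
  scale-free generators.
- Desk-scale defaults trade quantitative fidelity for runtime (see
  above); publication-resolution parameter planes are out of scope.
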