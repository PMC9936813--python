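# Methods

`olmcell` models a hippocampal oriens-lacunosum/moleculare (OLM)
interneuron as a single isopotential compartment and layers four analyses
on top of it: in-vivo-like (IVL) background states, spiking resonance,
spike-triggered-average (STA) current decompositions, and unscented-Kalman
conductance estimation. This note documents the model, every tunable that
matters, the numerical choices, and what the reduced-scale checks do and
do not establish.

## The membrane model

The compartment obeys

    C dV/dt = I_inj − Σ_x ḡ_x · (∏_j m_j^{p_j}) · (V − E_x) − I_syn

with five active currents — transient sodium I_Na (m³h), fast
delayed-rectifier I_Kdrf (n⁴), A-type I_Ka (a·b), muscarinic slow
potassium I_M (z), hyperpolarization-activated cation I_h (r) — plus an
ohmic leak. Gates follow dx/dt = (x_∞(V) − x)/τ_x(V) with Boltzmann
steady states and Gaussian- or double-exponential-bell time constants.
Units everywhere: mV, ms, pA, µS, pF.

### Conductances and geometry

The four fitted channel densities are fixed at their published reference
values: g_M = 1.91e-5, g_Kdrf = 4.33e-3, g_Ka = 7.31e-3,
g_Na = 4.85e-3 S/cm². Taken as totals in µS these values cannot sustain
an action potential against any plausible leak, so they are treated as
densities and multiplied by a compartment area of 1.67e-4 cm²
(≈16,700 µm² equivalent surface; C = 150.3 pF at 0.9 µF/cm²), chosen to
give OLM-like input resistance and membrane time constant. The parameter
estimator works directly in density units so the magnitude-based
initializations below apply to the table values verbatim.

### Provisional constants and their calibration

The exact gating equations, leak, and h-current amplitude of the
antecedent model are not part of this package's inputs, so the kinetics
are shipped as *data* (`olmcell/data/olm_single.json`) with constants
that are provisional by construction. They were pinned once, by
calibration against two published excitability facts, and not revisited:

* the constant current for 1-Hz firing (10-s spike count) ≈ 25.5 pA —
  this fixes the leak (ḡ_L = 3.85 nS, E_L = −74 mV) and places the
  spike takeoff near −59 mV (Na m: V½ = −46, k = 6);
* the Set-0 IVL background must reproduce its published statistics
  (firing 3.1–4.6 Hz, subthreshold mean in (−70, −67.5) mV, variance in
  (8, 10) mV², ISI CV > 0.8) — this fixes the OU reversals and time
  constants (below) and cross-checks the subthreshold conductance
  landscape.

Two structural facts fell out of the calibration arithmetic rather than
choice. First, the spike takeoff must sit within ~3σ of the IVL mean
voltage or OU fluctuations can never trigger theta-rate firing; under the
~14 nS synaptic load the effective threshold is where the Na activation
slope reaches the load conductance, which forces the steep, left-shifted
m-curve. Second, with the published OU mean conductances
(g_e0 ≈ 3.2 nS at E_e = 0 mV, g_i0 ≈ 10.9 nS) and any model whose
rheobase is ~25 pA, an inhibitory reversal of −75 mV cannot balance the
cell at −68.5 mV — the mean synaptic current would be ~150 pA inward
against an intrinsic steady-state current capped near 30 pA by the
rheobase. The inhibitory reversal is therefore −86 mV (near the
potassium side of the chloride range), with τ_e = 3 ms and τ_i = 7.5 ms;
the same reversal is used for inhibitory perturbation synapses. These
are package defaults, configurable per `OUBackground`.

After calibration: 1-Hz current ≈ 25.8 pA, Set-0 rates 2.8–5.0 Hz over
20 seeds, mean subthreshold voltage −67.7 mV, variance 9.9 mV²,
ISI CV 0.87.

### Integration

Exponential-Euler for the gates and for V (the membrane equation is
linear in V once gates are frozen over a step), at dt = 0.025 ms by
default. Forward Euler on V is marginally unstable at this dt with these
conductances, which is why the V update is also exponential. The
integrator is a numba-compiled kernel batched over independent membranes,
so parameter scans, seed sweeps and perturbation-frequency batteries run
as single vectorized passes. Charge balance (C·dV/dt + ΣI − I_stim ≈ 0)
is asserted in the tests; away from spikes the residual is below a few
pA.

Degenerate inputs error early: zero-length or non-finite stimuli are
rejected at load time; a non-finite state during integration raises with
the offending time.

### Spikes and protocol conventions

Spike onset = upward crossing of −10 mV; peak = local maximum within
3 ms after onset. Firing rates are spike counts over 10 s (resolution
0.1 Hz), not reciprocal mean ISIs. The model's 4-pA bias current is a
default holding used by protocol helpers; `simulate` applies exactly the
stimulus it is given, and quoted injected currents are totals. The 1-Hz
current is found by bisection for the smallest current whose 10-s count
reaches the target.

## In-vivo-like states

The synaptic background is the point-conductance model: excitatory and
inhibitory conductances are independent Ornstein–Uhlenbeck processes
with means g_e0/g_i0, noise parameters D_e/D_i (stationary sd
D√(τ/2)), and the synaptic current g_e(V−E_e) + g_i(V−E_i). Paths use
the exact OU transition (no dt bias) and start from the stationary
distribution; negative excursions are clipped to zero inside the
integrator only, so recorded paths keep exact moments.

A 10-s trace is IVL when all four criteria hold strictly: V̄m > −70.588
mV, σ_Vm > 2.2 mV, ISI CV > 0.8, 3 Hz < f < 25 Hz, with subthreshold
statistics computed after removing ±7 ms around every spike peak
(overlapping windows merge). The grid search additionally bounds
8 < σ²_Vm < 10 mV² and −70 < V̄m < −67.5 mV, applied once per parameter
set; IVL runs discard a 1-s settle before the scored window so statistics
start from the stochastic steady state.

Representative-set selection measures each valid set's (min, max) firing
rate over the same 50 seeds and picks sets spanning the rate plane by
greedy farthest-point sampling seeded with the lowest- and highest-rate
sets (deterministic; a single representative degenerates to the
centroid-closest set). The ten published representative parameter sets
ship as a JSON fixture. With this package's kinetics the IVL criteria
are marginal for individual seeds exactly as the antecedent work
reports: roughly half the Set-0 seeds score 4/4, and the higher-rate
sets sit below the ISI-CV criterion more often than above it.

## Spiking resonance

Traces become binary spike-onset trains binned at 1 ms (fs = 1 kHz)
before a Welch density estimate with nperseg = min(20000, len). The
1-ms binning is deliberate: at fs = 1/dt with nperseg = 20000 the
frequency resolution (2 Hz) cannot separate perturbation frequencies
spaced 1 Hz apart. The entrainment measure is the baseline ratio
δPSD(f_i) = PSD_perturbed(f_i)/PSD_baseline(f_i) at the grid frequency
nearest f_i, the baseline sharing the OU seed and differing only by the
absent perturbation (so δPSD ≡ 1 at zero perturbation weight, any seed).
The resonant frequency f_r is the argmax over the frequency set
{0.5} ∪ {1..25} ∪ {30} Hz; ties resolve to the lowest frequency and
frequencies with zero baseline density are excluded.

Perturbations are periodic double-exponential conductance events,
peak-normalized to 30× the single-synapse weight (0.006 µS excitatory,
0.0054 µS inhibitory) — one somatic event standing in for 30 synchronous
dendritic synapses. Rise/decay default to 0.5/3 ms (excitatory) and
1/8 ms (inhibitory). The first event lands at the scored window's start
and recurs strictly periodically.

The phase response curve holds a constant current for stable firing
(last-10-ISI CV < 1% required), then delivers one event at each of 20
uniform phases of a late cycle. Δφ = (T0 − T1)/T0 × 100, so positive
values mean a shortened ISI (advance) — the sign convention follows the
stated meaning (advance-positive) rather than the printed formula, which
as written yields positive values for *prolonged* ISIs. The per-current
change ΔI compares each current's maximum absolute amplitude between the
second-last pre-perturbation spike and the perturbation (I0) with the
window from the perturbation to the second following spike (I1).

## Spike-triggered averages

Windows come from perturbed IVL runs whose measured f_r equals the
target frequency; each spike with a preceding ISI ≥ 200 ms contributes
its per-current signed share of total absolute current on [−195, −10] ms
before onset (shares sum to 1 in absolute value per timepoint). Averages
per (f_r, set) are min–max normalized across sets and timepoints to
[0, 1] per current and frequency (a degenerate min = max collapses to
zeros with a warning). Slope analysis fits ordinary least squares to the
across-set mean on [−195, −25] ms (the final 25 ms is excluded because
of the pre-spike curving); combined M+h variants sum the two currents
per set before averaging. Spread(f_r) sums twice the across-set standard
deviation (population denominator, configurable) over the analysis
timepoints. Trends against f_r use linear or parabolic least squares
with R² and the regression F-test; the linear zero-crossing is reported
when inside the fitted range and the parabola vertex always.

The published harvests used 40,000–120,000 seeds per representative set;
this package reproduces the *direction* of the slope trends (M-current
slope increasing toward zero, h-current slope decreasing toward zero
with f_r) as rank correlations at 7 frequencies (3-21 Hz) × 3 sets ×
50 windows.
What passing shows: the mechanism — slow M/h currents integrating
perturbation history — survives reduction by three orders of magnitude
in data volume. What it does not show: the full-scale fit statistics
(the published zero-crossing of the combined slope inside theta, or the
spread parabola vertex), which are cluster-scale quantities.

## Conductance estimation (RAUKF)

The estimation state augments (V, gates) with θ = [g_M, g_Kdrf, g_Ka,
g_Na] in density units; θ follows a random walk and each sigma point is
propagated through the full model carrying its own conductances, with a
scalar unscented update on the observed voltage per sample.

The observation is self-generated: 500 ms of zero mean current, then
steps of 30/60/90/0/−30/−60/−90 pA of 196 ms each, repeated 4 times
(5,988 ms total), plus Gaussian current noise of mean 4 pA (the bias
current) and sd 5 pA; the voltage is recorded at 10 kHz (dt = 0.1 ms)
with 0.03 mV observation noise — a high-quality whole-cell recording
assumption. The protocol's positive steps expose spiking, the negative
ones deinactivate the A-current and engage I_h.

Initializations follow the magnitude rules: P_θ,ii = 10^(2·⌊log10 θ_i⌋)
(prior sd of one order of magnitude), the state block P = 1e-4 and
Q = 1e-8; the poor start is θ_i = 10^⌊log10 θ_i⌋ and the optimal start
the true values. The θ random-walk noise is where a literal reading of
the magnitude rule (10^(4m)) fails — it is ~10 orders of magnitude too
stiff to converge from the poor start in 6 s — so the package uses a
per-step walk sd of 0.7–1% of each parameter's magnitude, annealed as
1/(1 + t/150 ms). Convergence is then gain-driven early and frozen-in
late.

Stability with spiking dynamics required four devices, each of which was
necessary in stress tests across seeds: (i) covariances are projected
back onto the PSD cone (eigenvalue floor) after every unscented
reconstruction — the scaled transform's centre weight is O(1/α²) ≈ 10⁶
at α = 1e-3 and its cancellation fails under spike nonlinearity;
(ii) when the weighted prior mean lands >25 mV from the propagated
central point, the central-point transform (exact for linear dynamics)
replaces it for that step; (iii) θ is held at its initialization during
the zero-current lead-in while the hidden state locks on, which prevents
the small M conductance from absorbing the initial DC mismatch;
(iv) the reported estimate averages the trajectory over the last two
protocol repeats, cancelling the protocol-periodic component of the
estimate wander.

The fault-triggered Q/R adaptation (detector on ν²/R against a
χ²(1) threshold, convex updates with floors λ0 = δ0 = 0.2 and gains
a = 10 ≫ b = 1, R estimated from a short innovation window) is
implemented and tested on miscalibrated-noise scenarios. The default
self-recovery run leaves it off: the protocol's noise statistics are
known exactly, and the only "faults" in that regime are chaotic
spike-timing innovations whose R inflation deafens the filter. θ is
clipped at zero after each update; log-space estimation was evaluated
and rejected (it fixed nothing the devices above fix, and introduced a
Jensen-type downward drift on the A-type conductance).

Desk-scale self-recovery performance, both initializations, across
seeds: per-conductance percent differences of ~0.01–0.5% for g_Kdrf,
g_Na; ~0.3–1.3% for g_Ka; ~0.3–2.5% for g_M, the binding component.
The two initializations converge to nearly identical estimates — the
filter forgets its start, which is the point of the exercise.

## What the synthetic data does and does not emulate

All inputs are self-generated: the OU background stands in for the
irregular, inhibition-dominant synaptic bombardment of the intact
hippocampus, and the estimation observation for a noisy current-clamp
recording. The generator reproduces the target statistics (subthreshold
moments, ISI irregularity, rate ranges) but not dendritic filtering,
synaptic short-term dynamics, or presynaptic rhythmicity; passing tests
therefore show that the analyses behave correctly for a cell whose
background matches the published statistics, not that a real OLM cell
would yield the same numbers. The estimator is likewise validated in the
inverse-crime setting (the filter's model generated the data); observing
a *different* cell — the original multi-compartment model, or a real
recording — is expected to degrade accuracy by an order of magnitude, as
the published comparison against the detailed model shows.

## Problem sizes

Defaults throughout are desk-scale: 10-s simulations, 50-seed rate
envelopes, 15-state resonance checks per polarity over the full
frequency set, 50 windows per STA cell at 7 frequencies × 3 sets, and
single filter passes over the 6-s protocol. The published full-scale counterparts (414-set grid
search, 50,000-state resonance ensemble, 40,000–120,000-seed STA
harvests) are reachable with the same code by raising the seed budgets.
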