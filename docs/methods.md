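# Methods

## Model

A single electrical compartment represents the RGC soma; this is adequate
when dendritic trees are electrotonically compact, and it deliberately
averages away dendritic Ca²⁺ microdomains (see Limitations). The state
vector is (V, m, h, n, a, b, s, s_AMPA, s_NMDA, [Ca²⁺]ᵢ): membrane
potential, six intrinsic gates, two synaptic gates, and one calcium pool.

Currents (µA/cm², positive outward), with conductances in mS/cm² and
potentials in mV:

| current | form | g (default) | E (default) |
|---|---|---|---|
| Na⁺ | g_Na·m³h·(V−E_Na) | 120 | +50 |
| K⁺ delayed rectifier | g_Kdr·n⁴·(V−E_K) | 36 | −77 |
| A-type K⁺ | g_KA·a³b·(V−E_K) | 8 | −77 |
| L-type Ca²⁺ | g_CaL·s²·(V−E_Ca) | 0.3 | +120 |
| Ca²⁺-activated K⁺ | g_KCa·Ca²/(Ca²+K_d²)·(V−E_K), K_d = 0.5 µM | 0.3 | −77 |
| leak | g_L·(V−E_L) | 0.35 | −54.4 |
| AMPA | g_AMPA·s_AMPA·(V−E_exc) | 0.25 | 0 |
| NMDA | g_NMDA·s_NMDA·B(V,Mg)·(V−E_exc) | 1.2 | 0 |

Membrane capacitance C_m = 1.0 µF/cm², resting potential V_rest = −65 mV.

**Mg²⁺ block.** B(V, Mg) = 1/(1 + η·Mg·exp(−γV)) with η = 0.28 mM⁻¹,
γ = 0.062 mV⁻¹ (Jahr–Stevens). At −65 mV this leaves ≈24%, 6% and 3% of the
NMDA conductance unblocked at 0.2, 1.0 and 2.0 mM. The block is the model's
central nonlinearity: depolarisation relieves it, so sustained
depolarisation (high-frequency drive, or a delayed intervention arriving
after depolarisation is established) sharply weakens the protective effect
of raising Mg²⁺.

**Synaptic gating.** ds/dt = [Glu]/([Glu]+EC50)·(1−s)/τ_rise − s/τ_decay.
AMPA: EC50 = 0.5 mM, τ = 0.3/3 ms; NMDA: EC50 = 2 µM (stored internally as
0.002 mM — both EC50s are kept in mM), τ = 5/80 ms. At 1 mM cleft glutamate
the NMDA activation term is 1/1.002: effectively saturated, so NMDA charge
transfer is controlled by the block and the voltage trajectory, not by
glutamate binding.

**Calcium.** d[Ca²⁺]ᵢ/dt = −k_Ca,NMDA·f_Ca·I_NMDA − k_Ca,CaL·I_CaL −
([Ca²⁺]ᵢ−Ca_rest)/τ_Ca with f_Ca = 0.15, k_Ca,NMDA = 0.012,
k_Ca,CaL = 0.003, Ca_rest = 0.05 µM, τ_Ca = 200 ms. The k factors are
treated as absorbing the current-density→concentration conversion for this
geometry; no further volume/Faraday conversion is applied. Inward currents
(negative) yield non-negative influx; with no influx, Ca relaxes to rest
with time constant τ_Ca (the test suite fits this to within 5%).

## Gating kinetics: what is literature and what is identified

The published sources for this cell class fix the *form* of the kinetics
but not every constant, so the kinetics table (`rgc_mg.kinetics`) is
explicit and swappable. Defaults:

* **m, h, n** — the classic squid-axon rate functions expressed at
  V_rest = −65 mV (e.g. α_m = 0.1·(V+40)/(1−exp(−(V+40)/10))).
* **a, b** — the Connor–Stevens transient-K⁺ steady states and time
  constants (Dayan–Abbott parameterisation). The a∞ fit marginally exceeds
  1 at strongly depolarised potentials and is capped at 1.
* **s** — first-order Boltzmann activation for high-threshold (L-type)
  Ca²⁺ channels: s∞ = 1/(1+exp(−(V+7.5)/6)), τ_s = 2.0 ms.

Two constants were *identified* rather than copied, and this is the one
place the package calibrates against target behaviour instead of a printed
constant:

1. **A-current voltage offset, −19.76 mV** (applied to both a and b). With
   the Table-level conductances the unshifted Connor–Stevens curves leave
   ≈3.3 µA/cm² of net outward current at −65 mV, i.e. the cell would rest
   near −67.5 mV. The offset is the root of the resting current balance,
   computed once so that −65 mV is exactly the stable equilibrium.
2. **Delayed-rectifier rate scale, 0.963** (≈4% slower than the squid
   rates), together with the L-type parameters above. These set the cell's
   maximal reliable following frequency and the per-spike Ca²⁺ load. They
   were selected so that the excitotoxic boundary sits at 80 Hz: full
   pulse-following at ≤60 Hz at any Mg²⁺, and at 80 Hz a loss of NMDA
   support under strong block that produces a 4:5 mode-locked plateau
   (160 of 200 pulses, 20% spike loss) across 1.4–2.0 mM before collapsing
   further above 2.0 mM. Because these two constants tune emergent spiking
   rather than a directly measured quantity, downstream quantitative
   results carry meaningful model uncertainty; the test suite asserts the
   structural findings exactly and the derived magnitudes within ±15%.

## Stimulation protocols

Glutamate arrives as ideal rectangular pulses: amplitude 1 mM, width 2 ms,
onset of pulse k at stim_start + k/f; a pulse must end by stim_end to
count. Pulse onsets align with the integration grid. Extracellular Mg²⁺
follows a piecewise-constant schedule; an "intervention" is an
instantaneous concentration switch (no exchange kinetics).

* **Dose–response**: frequencies {10, 30, 60, 80, 90, 100} Hz ×
  Mg²⁺ 0.2–2.5 mM in 0.1 mM steps (144 cells), 3 s per cell. The first
  500 ms are excluded from every metric; spike counts and peak Ca²⁺ use
  t = 500–3000 ms, so the expected pulse count at 80 Hz is 200.
* **Timing**: 80 Hz stress from 0.5 to 4.5 s, total 6 s simulated;
  Mg²⁺ steps from 0.2 to 1.8 mM at delays {pretreat, +0, +0.1, +0.2, +0.3,
  +0.4, +0.5, +0.75, +1, +2, +3 s} relative to stress onset. "Pretreat"
  means 1.8 mM from t = 0. Peak Ca²⁺ is evaluated on the stress window
  (0.5–4.5 s).

Outside the stress interval the cell receives no background drive.

## Analysis definitions

* **Spikes**: upward crossings of −20 mV, detected on the full-resolution
  integration grid; the voltage must fall below threshold before the next
  spike can be counted (de-bounce). Spike probability =
  spikes/expected pulses, capped at 1 (bursting); spike loss =
  100·(1−probability). Loss is reported both absolutely and relative to
  the 0.2 mM baseline at the same frequency; the function criterion uses
  the baseline-relative value (identical whenever the baseline follows
  every pulse).
* **Therapeutic window**: the longest contiguous Mg²⁺ run where peak
  [Ca²⁺]ᵢ < 1.0 µM *and* spike loss ≤ 20% (first run wins ties). Bounds
  are reported at grid resolution, no interpolation. Each concentration is
  classified optimal / fails-protection / fails-function / fails-both.
* **Protection efficacy**: 100·(peak_noMg − peak_interv)/(peak_noMg −
  peak_pre), with the constant-0.2 and constant-1.8 runs as the 0% and
  100% anchors. The pre-treatment row reproduces the 100% anchor by
  construction.
* **Ca²⁺ progress**: (Ca(t)−Ca_rest)/(Ca_peak,noMg−Ca_rest) evaluated on
  the *untreated* trace — a treatment-independent phase variable, 0 at
  rest and 1 at the untreated peak.
* **Mechanistic metrics**: ⟨B⟩ is the time-average of B(V(t), Mg(t)) over
  the analysis window; Q_NMDA = ∫|I_NMDA|dt by trapezoid. Both are
  reconstructed from recorded state (V, s_NMDA, Mg) — the currents are
  memoryless functions of the state, so nothing extra needs recording.

## Numerics

Forward Euler with dt = 0.02 ms is the production integrator (the fastest
gate time constant along simulated trajectories stays well above dt);
classical RK4 is the reference, with the stimulus evaluated at substage
times. Euler vs RK4 at dt = 0.02 ms differ by <0.2% in peak Ca²⁺ on the
80 Hz protocol, and the convergence report (CLI `converge`) shows the
expected first-order error decay against an RK4 reference at dt = 5 µs.

Robustness guards: gates may overshoot [0, 1] by at most 10⁻⁶ per step
(clamped); larger overshoot, non-finite values, |V| > 200 mV or
Ca > 1000 µM abort with an error naming the first offending variable and
time. Batched integration (one array across the Mg²⁺ grid) is verified to
be bit-identical to independent runs, and all simulations are
deterministic — there is no random number generation anywhere in the
package.

Initial conditions: gates at their steady states at V_rest, synaptic gates
closed, Ca at rest. Because −65 mV is an exact equilibrium by calibration,
no settling period is needed; analyses nevertheless discard the first
500 ms, so initialisation cannot affect metrics.

## What the computed results do and do not show

The package's own computations (test suite and `scripts/acceptance.py`)
establish, under default parameters: block percentages 24/6/3% at rest;
peak Ca²⁺ 4.53 µM (80 Hz, 0.2 mM) falling monotonically to 0.86 µM at
2.0 mM; a 20% spike-loss plateau over 1.4–2.0 mM with a therapeutic window
of exactly [1.6, 2.0] mM at 80 Hz; no window at 90–100 Hz; windows of
width 2.1/1.6/1.2 mM at 10/30/60 Hz; timing efficacies 100/100/82/50/12%
for pretreat/+0/+0.1/+0.2/+0.5 s and ≤1% beyond 1 s; a 77% reduction in
integrated NMDA charge and ⟨B⟩ falling 0.35→0.11 between 0.2 and 1.8 mM.

Two quantities are sensitive to the identified kinetics and should be read
with that uncertainty in mind. First, the Ca²⁺ level at the window's lower
edge sits within ~2% of the 1.0 µM criterion at several frequencies, so
the lower window bound can move by one 0.1 mM grid step under small
kinetic changes (at 10 Hz the bound lands at 0.4 mM with Ca(0.4) = 0.98 µM,
i.e. 2% under the criterion). Second, the untreated Ca²⁺ rise reaches ~60%
of its peak 200 ms after stress onset; a model with a slower influx
cascade but the same efficacy curve would report a lower Ca²⁺-progress
value at the 50%-protection boundary, so the progress boundary is the
least transferable number this package computes.

## Limitations

Single compartment: no dendritic Ca²⁺ microdomains, so somatic Ca²⁺ is a
lower bound on local loads and the concentration estimates are
conservative. Periodic, identical glutamate pulses: no stochastic release,
no Poisson trains, no glial clearance, no receptor desensitisation, no
network feedback. The 1.0 µM toxicity threshold and the 20% spike-loss
limit are screening criteria, not mechanistic death models. Mg²⁺ switches
are instantaneous; real pharmacokinetics are much slower, so timing
results describe the relative phase of intervention within the Ca²⁺ rise
rather than literal clinical deadlines.
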