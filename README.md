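# rgc-mg

Conductance-based single-compartment model of a retinal ganglion cell (RGC)
for studying **extracellular Mg²⁺ as a neuroprotectant against glutamate
excitotoxicity**, with the full analysis stack: frequency × [Mg²⁺]
dose–response sweeps with therapeutic-window identification,
intervention-timing experiments with protection-efficacy scoring, and a
state-based Ca²⁺-progress reanalysis.

## Who this is for

Computational neuroscientists and neuroprotection researchers who want a
small, fully deterministic, testable platform for asking: *over what range of
extracellular Mg²⁺, and applied when, does enhanced NMDA-receptor block
prevent excitotoxic Ca²⁺ overload without silencing the cell?*

## The model

Membrane potential follows a Hodgkin–Huxley-type current balance

```
Cm dV/dt = −I_Na − I_Kdr − I_KA − I_CaL − I_KCa − I_L − I_AMPA − I_NMDA
```

with I_Na = g_Na·m³h·(V−E_Na), I_Kdr = g_Kdr·n⁴·(V−E_K), I_KA = g_KA·a³b·(V−E_K),
I_CaL = g_CaL·s²·(V−E_Ca), a Hill-type Ca²⁺-activated K⁺ current
I_KCa = g_KCa·Ca²/(Ca²+K_d²)·(V−E_K), and ohmic leak. Glutamate pulses drive
AMPA and NMDA receptor gates by first-order kinetics

```
ds/dt = [Glu]/([Glu]+EC50) · (1−s)/τ_rise − s/τ_decay
```

and the NMDA current carries the Jahr–Stevens voltage-dependent Mg²⁺ block

```
B(V, [Mg²⁺]) = 1 / (1 + η·[Mg²⁺]·exp(−γV)),   η = 0.28 mM⁻¹, γ = 0.062 mV⁻¹
```

so depolarisation relieves the block (coincidence detection) and raising
[Mg²⁺]ₒ deepens it. Intracellular Ca²⁺ is a single pool fed by the NMDA and
L-type currents and cleared with τ_Ca = 200 ms:

```
d[Ca²⁺]ᵢ/dt = −k_Ca,NMDA·f_Ca·I_NMDA − k_Ca,CaL·I_CaL − ([Ca²⁺]ᵢ − [Ca²⁺]_rest)/τ_Ca
```

Integration is forward Euler at dt = 0.02 ms (RK4 available as an accuracy
reference; they agree to <0.2% on peak Ca²⁺). Everything is deterministic —
repeated runs are bit-identical. See `docs/methods.md` for parameter tables,
the gating-kinetics identification, and known limitations.

## Worked example

```python
import rgc_mg as rm

# dose-response at 80 Hz (excitotoxic drive), Mg 0.2-2.5 mM in 0.1 mM steps
sweep = rm.run_dose_response(rm.SweepGrid(frequencies=(80.0,)))
w = sweep.windows[80.0]
print(f"therapeutic window at 80 Hz: {w.lower}-{w.upper} mM (width {w.width:.1f})")

t = sweep.table.set_index("mg_mM")
for mg in (0.2, 1.6, 2.0):
    print(f"  {mg} mM: peak Ca {t.loc[mg, 'peak_ca_uM']:.2f} uM, "
          f"spike loss {t.loc[mg, 'spike_loss_vs_baseline_pct']:.0f}%")
```

prints

```
therapeutic window at 80 Hz: 1.6-2.0 mM (width 0.4)
  0.2 mM: peak Ca 4.53 uM, spike loss 0%
  1.6 mM: peak Ca 0.99 uM, spike loss 20%
  2.0 mM: peak Ca 0.86 uM, spike loss 20%
```

At 0.2 mM Mg²⁺ the cell follows all 200 pulses but Ca²⁺ climbs to ~4.5 µM —
far above the 1.0 µM toxicity criterion. Between 1.6 and 2.0 mM both
criteria hold simultaneously: peak Ca²⁺ stays below 1.0 µM while spike loss
sits on a 20% plateau (160 of 200 expected spikes, a 4:5 mode-locked
rhythm). Above 2.0 mM spike loss exceeds 20% and the window closes; at 90
and 100 Hz no concentration satisfies both criteria.

The timing experiment (80 Hz stress from 0.5–4.5 s, Mg²⁺ step 0.2→1.8 mM at
varying delays):

```python
timing = rm.run_timing_experiment()
print(timing[["delay", "peak_ca_uM", "efficacy_pct"]].head(6).to_string(index=False))
```

shows protection efficacy of 100% for pre-treatment and intervention at
stress onset, ~82% at +0.1 s, ~50% at +0.2 s and ~12% at +0.5 s — delayed
intervention fails because the membrane is already depolarised (which defeats
the voltage-dependent block) and Ca²⁺ has already accumulated.

## Command line

```bash
rgc-mg simulate --freq 80 --mg 0.2 --out out/           # single trace + summary
rgc-mg dose-response --out out/                          # 144-cell sweep + windows
rgc-mg timing --out out/                                 # intervention-timing table
rgc-mg converge --out out/                               # dt-convergence report
rgc-mg reproduce s1_table --out out/                     # figure/table targets
```

All commands accept `--config config.yaml` (validated; unknown keys
rejected; missing keys default to the reference parameter tables) and write
a `manifest.json` with a hash of the resolved configuration.

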