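# ionhh

Hodgkin–Huxley dynamics with time-dependent ion concentrations, a
Na⁺/K⁺-ATPase pump, and potassium reservoirs (glial buffer or extracellular
bath) — plus the analysis toolkit for the slow–fast structure of such
models: characteristic time scales, fixed-point continuation with
Hopf/limit-point detection, and simulation-based tracking and
classification of tonic firing, seizure-like activity (SLA) and periodic
spreading depression (SD).

The package is for computational neuroscientists studying ion homeostasis,
epileptiform bursting and spreading depolarizations in single-compartment
("local") neuron models, where the interesting dynamics lives on time
scales of seconds to hours rather than milliseconds.

## The model

A single compartment with intracellular (ICS, volume ω_i) and
extracellular (ECS, volume ω_e) spaces separated by an excitable membrane.
Integrated variables: membrane potential V, potassium activation n,
intracellular potassium K_i and chloride Cl_i, plus slow reservoir
variables where applicable. Membrane dynamics:

    C_m dV/dt = −(I_Na + I_K + I_Cl)
    dn/dt     = φ (α_n(V)(1−n) − β_n(V) n)

    I_Na = (g_Na^l + g_Na^g m∞³h)(V − E_Na) + 3 I_p
    I_K  = (g_K^l  + g_K^g  n⁴)(V − E_K)  − 2 I_p
    I_Cl =  g_Cl^l (V − E_Cl)
    I_p  = ρ / [(1 + exp((25 − Na_i)/3))(1 + exp(5.5 − K_e))]

with adiabatic sodium activation m = m∞(V), sodium inactivation slaved to
n via h = 1.1 − 1/(1+exp(−8(n−0.4))), and Nernst potentials computed from
the instantaneous concentrations. Currents convert to concentration
changes through γ = 10·A/F (`dc/dt = γ I/ω`); mass conservation and
electroneutrality of transmembrane fluxes leave only two independent
concentrations, so Na_i, Na_e, K_e, Cl_e follow algebraically.

The central slow variable is ΔN_K, the potassium gained or lost through
reservoirs, expressed per ECS volume:

    K_e = K_e0 − (ω_i/ω_e)(K_i − K_i0) + ΔN_K

Closed model: ΔN_K is a parameter. Glial buffering:
dΔN_K/dt = dB/dt = −λ_k(K_e)·K_e·B + λ_bb(B0 − B), with the forward rate
λ_k sigmoidal in K_e. Bath coupling: dΔN_K/dt = λ_diff (K_bath − K_e).

Treating ΔN_K as a bifurcation parameter of the closed model yields a
folded fixed-point curve whose two stable outer branches — physiological
and free-energy-starved (FES) — organize everything the open models do: SD
is a large excursion to the FES branch and back, with the repolarization
threshold given by a line of Hopf bifurcations.

## Worked example

A spreading-depression episode triggered by interrupting the pump for
10 s in the glia-buffered model:

```python
import ionhh as ih

params = ih.table1()                       # reference parameter set
prot   = ih.Protocol(pump_off_window=(10.0, 20.0))
traj   = ih.simulate(params, variant="buffered", protocol=prot, t_end=300.0)

phases = ih.depolarization_metrics(traj, V_threshold=-50.0)
main   = max(phases, key=lambda ph: ph.duration)
print(f"depolarized for {main.duration:.1f} s, "
      f"peak K_e {main.peak_K_e:.1f} mM, min Na_e {main.min_Na_e:.1f} mM")
```

prints

```
depolarized for 81.0 s, peak K_e 78.3 mM, min Na_e 22.0 mM
```

— the neuron depolarizes during the pump interruption, sits in a
near-Donnan FES state with extracellular potassium risen from 4 mM to
~78 mM and extracellular sodium collapsed from 125 mM to ~22 mM, then
repolarizes abruptly after ~81 s when glial buffering has removed enough
potassium to reach the Hopf (repolarization) line.

The same machinery from the shell:

```sh
ionhh scenario sd_pump_off --out out/sd        # trajectory CSV + summary
ionhh continue --param dNK --range=-80:60 --out out/branch.csv
ionhh timescales                               # time-scale report (JSON)
ionhh sweep --values 8.5,9,9.5,10 --out out/sla.csv
```

The continuation reports the closed model's bifurcations (HB1 at
ΔN_K ≈ 25.8 mM ends the physiological branch; HB4 at ≈ −49.2 mM ends the
FES branch), and the sweep classifies the bath-coupled regimes (SLA
envelope periods of ~20–25 s in this window).

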