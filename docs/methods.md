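# Methods

## Model

The model is a single-compartment Hodgkin–Huxley membrane extended with
ion-concentration dynamics. Two compartments (ICS ω_i = 2160 µm³, ECS
ω_e = 720 µm³) exchange Na⁺, K⁺ and Cl⁻ across a membrane of area
A = 922 µm². The working unit system is ms / mV / mM / µA·cm⁻²;
reservoir rates are stated per second and converted at assembly time.

Integrated variables per variant:

| variant  | integrated                    | reservoir law                      |
|----------|-------------------------------|------------------------------------|
| closed   | V, n, K_i, Cl_i               | ΔN_K fixed parameter               |
| buffered | V, n, K_i, Cl_i, ΔN_K, B      | glial buffer, K_e-dependent uptake |
| bath     | V, n, K_i, Cl_i, ΔN_K         | diffusive, λ_diff (K_bath − K_e)   |

The remaining four concentrations are algebraic: Na_i from the constancy
of the intracellular charge concentration Na_i + K_i − Cl_i (the
electroneutral-flux constraint), Na_e and Cl_e from per-species mass
conservation with the volume ratio ω_i/ω_e = 3, and K_e from potassium
mass conservation plus ΔN_K (per ECS volume). The constraint drops the
capacitive contribution γ·C_m·dV/dt (≈ 4×10⁻³ mM per 100 mV), which is
the usual approximation for this model class; see "Redundant-formulation
check" below.

Gating uses the shifted-HH exponential rate functions
α_m = 0.1(V+30)/(1−e^{−0.1(V+30)}), β_m = 4e^{−(V+55)/18},
α_n = 0.01(V+34)/(1−e^{−0.1(V+34)}), β_n = 0.125e^{−(V+44)/80},
with φ = 3 ms⁻¹, adiabatic m = m∞(V), and sodium inactivation slaved to n
by h(n) = 1.1 − 1/(1+e^{−8(n−0.4)}) (range (0.1, 1.1); h ≈ 1 at rest,
h → 0.1 in depolarization block). The pump current saturates sigmoidally
in Na_i (midpoint 25 mM, slope 3 mM) and K_e (midpoint 5.5 mM), maximal
rate ρ = 6.8 µA·cm⁻²; its 3:2 stoichiometry is carried inside I_Na
(+3 I_p) and I_K (−2 I_p).

The glial buffer is the phenomenological uptake reaction
K_e + B ⇌ KB with forward rate λ_k(K_e)·K_e·B,
λ_k = λ_buf/(1+e^{(15−K_e)/1.09}) — negligible at resting K_e, saturating
at λ_buf = 5×10⁻⁵ (mM·s)⁻¹ for SD-level potassium — and constant backward
rate λ_bb = 5×10⁻⁵ s⁻¹. Free buffer B and ΔN_K are integrated
redundantly; the affine identity ΔN_K + (B0 − B) = const is asserted
post hoc as a built-in solver diagnostic.

Key derived scales (reference parameters): γ = 10·A/F = 9.556×10⁻²,
i.e. 4.42×10⁻⁵ mM/ms per µA·cm⁻²; thermal voltage RTF = 26.71 mV
(T = 310 K). RTF is configurable: the three tabulated "initial Nernst
potentials" of the reference set are mutually inconsistent with any single
temperature applied to the tabulated concentrations (E_Na computes to
≈ +42.8 mV at 310 K, not 39.74 mV), so the concentrations are treated as
authoritative and the potentials as derived; E_K then computes to
−92.8 mV vs the printed −92.94 mV (0.1%).

Every experiment starts from a Newton-polished machine-precision fixed
point near the tabulated state (the table prints two decimals only). The
polished closed rest is V = −67.33 mV, K_e = 4.005 mM; the buffered
variant's conserved bookkeeping (ΔN_K − B = −B0) shifts it to
ΔN_K = −0.083 mM.

## Time scales

τ_V = C_m/g_tot with gating products approximated by 0.1 (0.071 ms),
τ_n = 1/(φ(α_n+β_n)) at rest (1.9 ms), transmembrane ion dynamics
τ_ion = (ω_i/A)/P from the GHK-flux grouping with a typical gated-channel
permeability P = 10⁻⁵ cm/s (23 s; P is configurable — only the order of
magnitude matters and GHK currents are used *only* here, never in the
dynamics), forward buffering 1/(λ_buf·B0) = 40 s, bath exchange
1/λ_diff = 33.3 s, backward buffering 1/λ_bb = 2×10⁴ s. The ordering
τ_V < τ_n < τ_ion < τ_buf < τ_bb is asserted as an invariant and is robust
to ±50% changes of any single reservoir rate.

## Numerics

Integration: explicit adaptive Dormand–Prince 5(4) compiled with numba,
default rtol 10⁻⁸ / atol 10⁻¹⁰, dt capped at 20 ms. An explicit method is
appropriate because the stiffest variable (V) must be resolved during
spikes anyway and costs only ~0.2–0.5 ms steps on depolarized plateaus;
with the RHS compiled, thousands of simulated seconds integrate in
seconds of wall time. Protocol discontinuities (pump gate, stimulus
edges, potassium bolus) are handled by segmenting the integration at
breakpoints; the pump gate itself uses a 1 ms smoothstep ramp so the RHS
stays C¹ inside segments. Spike times are recorded inside the integrator
as linearly interpolated upward 0 mV crossings with a 2 ms refractory
period, independent of the output sampling grid.

Fixed points use damped Newton iteration with central finite-difference
Jacobians (relative step 10⁻⁶); evaluations outside the positive-
concentration domain back the line search off. Continuation is
pseudo-arclength (states scaled by [20 mV, 0.1, 5 mM, 5 mM], parameter by
1 mM) with eigenvalue monitoring: a Hopf is flagged when the count of
unstable eigenvalues changes by two through a complex pair, a limit point
when it changes by one at a fold; both are refined by bisection along the
branch (test functions: real part of the pair nearest the axis, and
det J respectively) to 10⁻⁶ mM. Labels follow traversal order from the
physiological point.

For the clamped-chloride Hopf line the chloride current is removed, Cl_i
becomes a parameter (grid 8…32 mM), and the FES branch of the 3-variable
fast subsystem is continued towards decreasing ΔN_K until it loses
stability; a relaxation run (V = −25 mV, K_i at reference, 150 s) seeds
the FES fixed point at ΔN_K = 20 mM.

### Redundant-formulation check

As a structural diagnostic, all six concentrations are also integrated as
independent ODEs (LSODA, rtol 10⁻¹²) with the model's species fluxes —
sodium's taken from the electroneutral-flux identity J_Na = −(J_K+J_Cl)
in charge terms — and compared pointwise with the constrained run over an
SD episode. Agreement is ≤10⁻⁶ mM before the protocol and across the
entire depolarized plateau, and ≤10⁻⁴ mM through the ignition spike
flurry. Across the near-vertical repolarization front (dK_e/dt ≈
40 mM/s) a pointwise bound only measures front *timing* between two
different solvers, so the repolarization times are compared instead
(they agree to ~0.4 s, i.e. sub-percent on the episode: the front time
inherits the phase of the growing Hopf oscillation that ends the plateau,
which decorrelates between solvers; between rtol 10⁻⁸ and 10⁻¹² the
repolarization time itself moves by ~0.7 s — far inside every tolerance
used here).

## Regime detection and sweeps

Spikes group into bursts wherever an inter-spike gap exceeds 5× the
median ISI; intraburst frequency is the mean reciprocal intraburst ISI.
The slow ionic period is the mean interval between peaks of the 1 s
moving-average K_e signal (peak prominence: a quarter of the smoothed
peak-to-peak amplitude). Classification thresholds (module constants,
overridable): tonic if spiking with K_e amplitude < 0.5 mM, SLA if
burst-modulated with amplitude in [0.5, 10) mM, periodic SD if a slow
oscillation of ≥ 10 mM amplitude visits strongly elevated K_e; quiescent
traces are resting (K_e within 1 mM of its quiescent reference — K_bath
for the bath variant) or FES (mean V > −50 mV). Conflicting evidence
yields "ambiguous", never a silent misclassification. Each analysed
window discards max(20%, 100 s) as transient.

Branch tracking is quasi-static: the bath concentration is stepped (or,
for the SD-branch end, ramped continuously at 5×10⁻⁴ mM/s) with the
attractor handed over between values. The SD-branch end is the bath
concentration at the last ≥10 mM-prominence K_e excursion before collapse
to tonic firing; halving the ramp rate moves it by only ~3×10⁻³ mM, so
the measurement is ramp-rate converged. One SD cycle lasts 350–550 s, so
rates much above ~10⁻³ mM/s would quantize the detected end at the
mM level.

Problem sizes of the canonical experiments: SLA sweep 8.0–11.0 mM in
0.25 mM steps, 600 s analysed per value after 250 s transient; periodic-SD
sweep 14–20 mM in 1 mM steps, 4000 s analysed after 500 s transient
(8–11 cycles per value); SD-branch ramp from 14 mM after 1500 s settling.

## What the synthetic protocols do and do not show

All inputs are generated by the model itself (pump interruptions,
potassium boli, bath ramps); there is no external data. Passing tests
demonstrate internal consistency of the dynamics and reproduction of the
model class's known phenomenology — they say nothing about biological
tissue beyond what this single-compartment, fixed-volume, three-ion
idealization can represent. In particular there is no osmotic volume
dynamics, no spatial propagation, no synaptic input, and the glial buffer
is phenomenological rather than a third compartment.

## Design choices and limitations

* The fast membrane follows the single-compartment Cressman-family
  reduction (adiabatic m, h slaved to n). A variant
  with the Traub/Gutkin-style rate functions was evaluated and discarded:
  it eliminates the slow oscillatory regimes entirely, while the adopted
  forms reproduce the SD episode duration, both oscillation-period bands
  and the bifurcation inventory.
* In the ΔN_K continuation the middle-branch bifurcations HB2, LP2, HB3
  cluster within ~1 mM (the Hopf pair's frequency nearly vanishes there);
  their internal order is numerically delicate and should not be treated
  as a robust model prediction. HB1 (ΔN_K ≈ 25.76 mM, K_e ≈ 6.16 mM),
  LP1 (≈ 26.92 mM) and the restabilizing HB4 (≈ −49.22 mM,
  K_e ≈ 20.4 mM) are robust; detected values are regression baselines.
* The intraburst spike rate in the SLA regime of this reconstruction is
  ~5–7 Hz (minimum ISI ≈ 140 ms): near the firing threshold the membrane
  crawls slowly between spikes given the small leak conductances.
  Fast (100–200 Hz) oscillation appears only as the birth frequency of
  the limit cycle at HB4. Descriptions of ~100 Hz burst-internal rates in
  this model class are not reproduced by this implementation at SLA bath
  concentrations.
* Limit cycles and tori are never continued by boundary-value methods;
  only stable oscillatory attractors are tracked, by direct simulation
  with quasi-static parameter changes. Unstable cycles, period-doubling
  and cycle-fold points are out of scope.
* Stimulation currents enter the voltage equation only (the standard HH
  convention); they carry no ion species.
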