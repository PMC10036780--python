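# Methods

`myofib` simulates one human ventricular cardiomyocyte electrically and
mechanically coupled to `n` identical cardiac fibroblasts, and the in-silico
protocols built on that preparation: steady-state isometric pacing,
calcium-overload triggered activity, vulnerability diagrams over the
(`n`, `g_gap`) plane, mechanosensitive I–V diagrams, and the
cooperativity-clamp mechanism experiment.

## The coupled model

**Myocyte electrophysiology.** The sarcolemmal currents follow the TP06
human ventricular formulation (epicardial variant) in the conventional units
mV / ms / mM / pA·pF⁻¹: i_Na, i_CaL, i_to, i_Kr, i_Ks, i_K1, i_pK, i_pCa,
i_NaK, i_NaCa, i_bNa, i_bCa, with fixed extracellular milieu and dynamic
Na⁺ᵢ, K⁺ᵢ. The L-type conductance scale is 5·10⁻⁵ (F·s)⁻¹ with a
dimensionless multiplier (the calcium-overload dial). Membrane capacitance is
185 pF. The membrane equation carries the junctional drain:

    dV_myo/dt = −( i_myo + Σᵢ g_gap (V_myo − V_cf,i) / C_myo )

**RyR gating and SR calcium.** Release uses a four-state ring
R ⇌ O ⇌ I ⇌ RI with I_rel = k_rel·O·([Ca]_SR − [Ca]_SS). Opening is driven
by subspace Ca²⁺ (∝ Ca_SS²) and modulated by a luminal-load sensor, with
Ca-dependent inactivation and slow recovery (kim = 0.005 ms⁻¹, which gives
the several-hundred-ms post-release refractoriness). The published rate
constants of four-state RyR schemes assume subspace and luminal scales far
below those of the TP06 calcium architecture (mM-scale subspace spikes,
~3.6 mM free SR Ca); the ring rates here are therefore re-anchored so that
the paced cell reproduces the behaviour of the original TP06 release (steady
1-Hz Ca-transient peak ≈ 0.8 µM, diastolic ≈ 0.10 µM, SR between ≈ 2.6 and
3.4 mM), verified against an independently coded original-TP06 reference.

In addition the opening rate carries a store-overload-induced term,

    a_ig = g_ig · S_load(Ca_SR) · S_cyt(Ca_i),

with a steep luminal Hill gate (midpoint 3.85 mM, exponent 20) sensitised by
bulk cytosolic Ca²⁺ (midpoint 1.5 µM, exponent 4). This is the pathway for
spontaneous diastolic release: when the SR is overloaded *and* cytosolic
Ca²⁺ stays elevated through the relaxation phase — which is exactly what the
cooperative Ca-TnC dissociation produces as cross-bridges detach — the ring
re-opens between stimuli. The resulting Ca²⁺ surge drives an inward Na/Ca
exchange current that appears as an early afterdepolarisation, or, when the
resting potential is sufficiently depolarised by coupled fibroblasts, as a
full extra action potential with an extra contraction. Because the
sensitisation reads the relaxation-phase Ca²⁺ excess, freezing the Ca-TnC
off-rate (the cooperativity clamp) abolishes the events.

**Buffering.** The TP06 generalised cytosolic buffer (0.20 mM) is split into
70 µM of dynamic troponin-C sites (owned by the mechanics, kinetics below)
plus a 0.13 mM residual instantaneous buffer, preserving total capacity.

**Mechanics.** The rheological scheme is an external series elastic element
(XSE) in series with a parallel block containing the passive element PE, the
`n` fibroblast elastic elements PEfb, and the contractile chain — the
contractile element CE (parallel viscosity VS1) in series with the internal
elastic element SE (parallel viscosity VS2). All elastic forces are
exponential, F = β(e^{αl} − 1); strains are fractions of L_max (sarcomere
2.23 µm) above slack, and forces are normalised to the peak steady isometric
force of the uncoupled myocyte at 90 % L_max (so that value is 1 by
construction; the normalisation constant ships in the parameter file). The
accepted balance at every step is

    F_myo = F_XSE = F_PE + n·F_PEfb + F_CE + F_VS1 ,

with F_PEfb = β₂fb(e^{α₂fb·l₂} − 1) and (α₂fb, β₂fb) equal to the PE pair by
default. Under whole-preparation isometry the internal compliance of XSE and
SE still lets the sarcomeres shorten; runs started at 90 % L_max keep the
instantaneous sarcomere length above 80 %.

Active force is F_CE = F_max·N_xb·P(v), with a Hill force–velocity factor
(shortening branch zero at v_max = 1.5·10⁻³ L_max/ms, lengthening branch
capped at 1.5 to keep the balance root unique). Cross-bridge kinetics:
attachment ∝ (CaTnC/A_tot)^1.6 × filament overlap (linear ascending limb in
sarcomere length — the length-dependent activation behind mechano-electric
feedback), detachment grows with |v|. Ca-TnC kinetics:

    d[CaTnC]/dt = a_on·Ca_i·(A_tot − CaTnC) − k_off(CaTnC, N_xb)·CaTnC,
    k_off = k_off0 · e^{−k_A·CaTnC} · (π_min + (1−π_min) e^{−k_N·N_xb}),

so the off-rate falls as cross-bridges attach (cooperativity) — during
relaxation, detaching cross-bridges continuously *raise* the off-rate and
sustain the dissociation flux. The clamp experiment freezes `k_off` at the
value reached at the switch time; afterwards the flux decays with the
falling [CaTnC] alone.

**Fibroblasts.** Each fibroblast carries the four MacCannell-style membrane
currents (time-dependent delayed-rectifier K⁺ with activation/inactivation
gates, inward rectifier K⁺, Na/K pump, background Na⁺ leak), capacitance
6.3 pF, fixed intracellular concentrations, and

    dV_cf/dt = −( i_cf + [i_MS] + g_gap (V_cf − V_myo) ) / C_mf ,

where i_MS = g_max·a(Δl)·(V_cf − V_rev(l)) is the non-selective
mechanosensitive current (model-2 mode only; it carries unassigned positive
charge and never touches the ion pools). The deformation factor is affine
with a(0) = 1 (Δl relative to the run's initial length) and the reversal
potential is affine in length across the 80–90 % L_max working range with
endpoints −38 and −30 mV, so the current is depolarising below −38 mV and
repolarising above −30 mV at every working length. The more negative
endpoint sits at the *long* end of the range by default: only with that
orientation does shortening the preparation depolarise the resting
potentials further, as the length protocols require; a configuration switch
(`stretch_rev_negative`) flips it. Fibroblasts deform with the parallel
block (their length tracks l₂), and all of them are homogeneous by default
with per-fibroblast overrides possible through the state vector.

## Parameters

All TP06, MacCannell and stimulus values are the published ones. The
quantities the main sources do not print — RyR ring rates and the
store-overload term, the mechanical coefficients, and (g_max, a_slope) of
i_MS — are calibrated, once, to the qualitative behaviours the study fixes:
force normalisation and the 90 > 85 > 80 % length ordering; the sarcomere
excursion bound; period-1 pacing at norm with period-2 SR alternans at
doubled i_CaL; post-release refractoriness; EADs at doubled i_CaL but not at
×1.4 in the single myocyte; resting-potential depolarisation monotone in `n`
and `g_gap` with only the fully coupled mode showing it; triggered-activity
thresholds below the single-myocyte threshold in coupled configurations; and
the clamp ablation with its dissociation-flux ordering. The calibrated set
is `src/myofib/data/default_params.json`; `g_max` = 8 nS and
`a_slope` = 8 /strain, and results are qualitatively unchanged under ×/÷2
variations of either.

## Numerics

Fixed-step hybrid integrator, dt = 0.02 ms (halving dt moves the final-beat
membrane potential by < 0.5 mV outside the 10-ms upstroke): Rush–Larsen
exponential updates for all Hodgkin–Huxley gates, a backward-Euler solve of
the linear RyR ring (unconditionally stable and exactly occupancy-
conserving), forward Euler for potentials and concentrations. The isometric
force balance is an algebraic constraint solved every step by safeguarded
Newton/bisection on the contractile-element velocity (the chain force is
strictly increasing in velocity, so the root is unique), to a residual of
10⁻¹⁰ normalised force units; the parallel-block velocity then follows
directly from the VS2 branch. Traces are sampled at 1 ms. N_xb and CaTnC are
clipped to their physical ranges after each step (the rates already point
inward at the boundaries). There is no randomness anywhere; identical
configurations give bit-identical traces on a fixed platform.

Initial conditions: pre-paced steady snapshots of the single myocyte at
80/85/90 % L_max are packaged (100 beats at 1 Hz); coupled runs start from
the snapshot, the passive mechanical balance for the actual ensemble, and
the isolated-fibroblast rest, then settle within a few beats. Protocol runs
are 200 s; scans use bisection on the 0.1 multiplier grid (≤ ~6 runs).

## Event classification

Resting potential = mean V over the 10-ms window ending 5 ms before each
stimulus. AP onset = upward crossing of −40 mV with dV/dt above 1 mV/ms —
deliberately permissive, because extra APs launched from a depolarised
resting potential are L-type-driven (i_Na largely inactivated) and rise at
only a few mV/ms. An EAD is an upward deflection ≥ 5 mV after an AP peak
that never meets the onset criteria; an extrasystole is a non-stimulus AP
onset (outside a ±10 ms attribution window) confirmed by an extra force
peak; a preparation whose steady peak force falls below 5 % of the uncoupled
norm is classified as failure. All thresholds live in `EventConfig`,
including an optional phase floor that restricts EADs to the
plateau/repolarisation phase. Synthetic template traces (plain AP train,
AP + sub-threshold hump, AP + ectopic AP with force peak, flat) are
generated programmatically and pin the classifier behaviour without
integrating the ODE system; they emulate event morphology only — piecewise
AP shapes with none of the model's rate structure — so classifier tests on
them validate the detector, not the physiology.

## Design choices where the design was open

- Eq-3 literalism: VS2 sits in parallel with SE inside the contractile
  chain, so the right-hand side of the accepted balance contains F_VS1 only.
- Strain bookkeeping uses L_max units throughout; the fibroblast L_max is
  tied to the myocyte's, and Δl in i_MS is measured from the run's initial
  length (so a = 1 at rest for every starting length).
- The store-overload term reads *bulk* cytosolic Ca²⁺, not subspace Ca²⁺:
  the subspace saturates any sensitiser during every paced release, whereas
  the relaxation-phase excess the cooperativity mechanism produces is a bulk
  signal.
- The "twofold reversal-potential increase" sensitivity knob multiplies both
  V_rev endpoints (0.5 raises them towards zero).

## Known limitations

- With two coupled fibroblasts the myocyte resting potential floors near
  −78 mV however strong the mechanosensitive current is made (the junctional
  drain is capped by the fibroblast's own i_MS reversal), and the
  spontaneous-release NCX surge of ≤ ~10 mV then stays below the inward-
  rectifier barrier that crests near −65 mV: overloaded pairs with n = 2
  show sustained EADs but no extrasystoles. Extra APs with extra
  contractions appear from n = 4 (resting potential ≈ −72 mV). The
  vulnerability diagram therefore places its extrasystole cells at higher
  `n` than its EAD cells.
- Halving the SERCA rate raises the triggered-activity threshold so far that
  no multiplier on the 1.0–3.5 grid ignites the store-overload pathway (the
  half-rate pump cannot fill the SR to the luminal threshold); the scan
  reports an above-grid threshold.
- Isotonic/afterloaded protocols are supported by the rheology but
  unexercised; tissue-level propagation, paracrine signalling and
  Ca-dependent gap-junction conductance are out of scope.
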