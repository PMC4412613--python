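# Methods

This note records the models, parameter choices and numerical decisions
behind `vactrace`, in the spirit of a methods appendix.

## Conventions and units

Voltages in mV, currents in pA, conductances in pS, concentrations in mM,
durations in s, temperatures in K; converters live only at module
boundaries. The membrane voltage is cytosolic minus vacuolar potential
(the convention standard for tonoplast work), and positive current is
cation flux from cytosol to vacuole; an anion-carrying inward current at
negative voltage is therefore negative. The default temperature is
295.15 K (22 °C, the growth temperature of the plant material; recording
temperature is taken to be the same).

## Activities and reversal potentials

Ionic strength is computed from the full recipe, I = ½ Σ cᵢzᵢ². Single-ion
activity coefficients use a Debye–Hückel-family model with the A
coefficient evaluated from the dielectric constant of water at the
solution temperature (A ≈ 0.509 at 22 °C):

* `limiting` (default): log₁₀γ = −A z²√I
* `guntelberg`: log₁₀γ = −A z²√I/(1+√I)
* `davies`: log₁₀γ = −A z²[√I/(1+√I) − 0.3 I]
* `ideal`: γ = 1

The limiting law is nominally outside its textbook validity range at
I ≈ 0.15–0.2 M. It is nevertheless the default because it reproduces the
printed electrochemistry of the study this package re-implements
essentially exactly (E_NO3 = −51.7 mV for the tenfold nitrate gradient
against the printed −51.6 mV; P_NO3/P_Cl = 3.087 against the printed
3.08), indicating it matches the convention under which those numbers
were produced; Güntelberg and Davies remain one keyword away. Under the
same convention BTP (bis-tris propane), added as the counter-cation of a
strong acid, is counted as a fully charged monovalent cation in recipe
ionic strengths. A diprotic speciation (pKa 6.8 and 9.0, literature
values) is available and is the default where chemical accuracy of the
ionic strength matters (chelation, below). The Davies form is also the
only one of the three that is non-monotone in I below 0.5 M (minimum near
0.39 M), which argues against it as a default for these solutions.

GHK sums are restricted to monovalent anions; Ca²⁺ and Mg²⁺ enter ionic
strength only (they are not treated as permeant). With a single permeant
species the GHK expression reduces algebraically to the Nernst potential;
this is enforced by tests to 10⁻⁹ mV. The permeability-ratio inversion is
a Brent root search on log₁₀r over r ∈ (10⁻⁴, 10⁴), verified to reproduce
the measured reversal to < 0.01 mV.

Junction potentials are *estimated* by the Henderson equation (the
experimental practice they replace is a measurement). The shipped
mobility table holds limiting equivalent conductances from standard
electrochemistry tables; BTP's mobility is approximated by TRIS·H⁺
(29.5), overridable per species. The Henderson value is reported as bath
minus pipette and is antisymmetric by construction. The equilibrium
potential of BTP itself is not computed by default: its value depends on
charge/activity assumptions for a partially protonated divalent base that
the convention above deliberately simplifies.

## Ca/Mg–EGTA equilibria

Species: EGTA⁴⁻ (L) with four protonation steps, CaL, CaHL, MgL, MgHL.
pH is clamped (all recipes are heavily buffered), read as H⁺ *activity*
and converted to concentration with the Güntelberg form. The constant set
is the Chelator-lineage, NIST-derived set used by the web chelator
calculators — pKa 9.47/8.85/2.66/2.0, log K: CaL 10.86, CaHL 5.33, MgL
5.21, MgHL 3.37 at I = 0.1 M, 20 °C — corrected to working conditions by

log K(I,T) = log K_ref − Δ(z²)·A(T)·[√I/(1+√I) − √I_ref/(1+√I_ref)]
           + (ΔH/ln10·R)(1/T_ref − 1/T)

with representative reaction enthalpies (−23.4, −19.7 kJ/mol for the
first two protonations; −33.3 for CaL; +21.3 for MgL). Over the 2 °C gap
between the reference and working temperature the enthalpy term is
negligible (<0.05 log units); it is included for completeness. Working
ionic strength defaults to the value computed from the full recipe with
diprotic BTP speciation (I ≈ 0.27 M for the standard 200 mM HNO₃ /
148 mM BTP baths); it can be overridden. With these defaults the five
printed bath designs come back at 97.2 µM, 9.1 µM, 0.90 µM free Ca²⁺ and
10.2 mM, 2.05 mM free Mg²⁺ against nominal 100/10/1 µM and 10/2 mM —
within the few-percent spread expected between constant-set vintages.

Numerics: the three-unknown system (free Ca, free Mg, free L) reduces
exactly to one scalar equation in free L that is strictly increasing, so
it is solved by Brent's method at machine precision instead of the more
fragile multivariate damped Newton; the metal mass balances are then
exact by construction and all residuals are checked against 10⁻⁹ M on
every solve. The inverse design problem rebuilds the full recipe at each
trial total so that the ionic-strength correction stays self-consistent,
making design ∘ solve an identity to well below 0.1%. DTT, HEPES, TRIS,
MES and BTP are treated as non-chelating for Ca/Mg.

## Synthetic recordings

Each channel is an independent two-state Markov chain; dwell times are
exact exponentials (event-driven simulation) and the state is read out
sample-and-hold at the recording rate, which avoids the discretisation
bias of per-sample Bernoulli updates. The chord current model is linear,
i = g(V − E_rev)/1000 pA, matching how unitary conductances are reported
(current/voltage ratios); GHK flux rectification is deliberately not
modelled. Voltage dependence, when wanted, multiplies α/β by a Boltzmann
factor split symmetrically between the rates. Ligand conditions (Ca²⁺,
Mg²⁺, pH) are alternative (α, β) presets, not binding schemes — the data
this emulates constrain only Po, not kinetics. The default closing rate
is 50 s⁻¹ (20 ms mean open time), a mid-range single-channel timescale
chosen once so that dwell times are long against the filter response;
opening rates follow from the target Po. Simulated traces default to
10 kHz sampling, a 2 kHz 4-pole Bessel-type causal filter (DC gain 1,
state initialised to the first sample) and 0.5 pA pre-filter Gaussian
baseline noise. Sweep protocols are 0.5 s holding / 3 s test steps in
20 mV increments / 0.3 s tail by default. Seeds are mandatory; per-sweep
and per-condition generators derive from the run seed by fixed offsets,
so any sweep can be regenerated bit-identically.

What the generator does *not* emulate: capacitive transients, leak/seal
conductance, 1/f and shot noise, sub-conductance levels, modal gating,
correlated channels. Passing recovery tests therefore demonstrates the
correctness of the estimator chain under the stated noise model, not
robustness to every artefact of real recordings.

## Amplitude-histogram analysis

Histograms are all-point, built from the quasi-stationary part of the
test pulse (the first 10 filter time constants after a step are
discarded), with 0.1 pA default bins anchored to an absolute grid so
histograms of different sweeps share edges and add exactly.

The mixture model is a sum of Gaussians (shared width by default —
unconstrained widths are available, but a shared width stabilises
small-area peaks) plus a pedestal confined between the outermost peak
centres. The pedestal absorbs the samples that filtered gating
transitions deposit between levels; without it any information criterion
chases that inter-level "bridge" with spurious components once histograms
contain ~10⁵ samples. For the same reason the component count is *not*
chosen by an information criterion on the raw fit: candidate levels are
detected on a log-count scale (so levels holding a fraction of a percent
of samples survive next to a dominant baseline), filtered for consistency
with an equally spaced level ladder (identical channels produce equally
spaced levels; off-ladder bumps are transition artefacts), and required
to be contiguous from the baseline (binomial occupancy cannot skip a
level). A post-fit unimodality check (occupancy rising >10× outward marks
a halved-spacing artefact) repairs the remaining failure mode. On 30 s
synthetic recordings this selects the true level count in ≥79/80 trials
across the four study-like parameter sets; the residual failure is
Monte-Carlo scatter of Po, not level miscounting.

The baseline peak is the outermost component opposite the conduction
direction when the direction is known (from the applied voltage and the
chord model), and the component nearest the modal current otherwise;
the modal rule alone misidentifies the baseline whenever NPo is large
enough that a one-open level is the mode (e.g. four channels at
Po = 0.21). Peak areas are amplitude·sd·√(2π). Open probability is
NPo/N: Po = Σₖ k·Aₖ / (N ΣAₖ), with N defaulting to the maximum
simultaneous open level observed — for multi-channel patches this
assumes independent identical channels, an assumption the simulator
satisfies and real data may not. Unitary current is the mean adjacent
centre spacing signed away from baseline; chord conductance is i/V at
the most extreme applied voltage (the I/V curves this mirrors are
nonlinear, so a slope conductance would be protocol-dependent). Reversal
potentials are linearly interpolated at the zero crossing nearest 0 mV;
curves that never change sign raise an explicit no-reversal error rather
than extrapolating.

Default analysis parameters: bin width 0.1 pA (halving it moves Po by
<0.02 on default-noise traces, enforced by test), max_channels 4 (6 in
the recovery tests), detection prominence 0.7 log units and ladder
tolerance 0.12·spacing (set for reliable separation of true minor levels
from transition bumps on synthetic data).

## Whole-vacuole analysis

Steady-state current is the mean of the trailing 10% of the 3 s test
pulse (the slow activation has settled well before then; the window is a
parameter). Membrane area comes from the optical diameter (sphere,
A = πd²) or from capacitance with 10 mF m⁻² specific capacitance — both
paths are provided because either sizing practice is common. J/V cohorts
are aggregated pointwise (mean, SEM = sd/√n) and only on exactly matching
voltage grids: junction-shifted grids (e.g. −94…+86 mV) are kept as
recorded and never interpolated onto nominal grids.

## Pipeline and reproducibility

`run_pipeline` validates a YAML config (seed mandatory, all analysis
defaults made explicit in the report), simulates each condition with
seed + 1000·index, writes every intermediate artifact (trace CSV + JSON
sidecar, histogram CSV, mixture JSON) and a `report.json` whose floats
are rounded to fixed precision, so a re-run with the same config is
byte-identical. Timings and stage logs go to `run.log`, never into the
report. Errors are re-raised annotated with the failing stage; artifacts
already written are retained.

## Problem sizes

The recovery tests and examples use single 30 s patches (3·10⁵ samples)
per condition, the scale at which all-point histograms of the study-like
conditions are well resolved; the demo pipeline uses 8 s conditions. The
acceptance computations are equilibrium solves and run in milliseconds.

## Known limitations

* The chelator constant set is one defensible vintage; different NIST
  releases move apparent constants by a few percent, which is the
  dominant uncertainty in the free-ion designs.
* The activity-model and BTP-charge conventions were chosen to match the
  printed electrochemistry (see above); they are conventions, not claims
  about single-ion activities at I ≈ 0.2 M being physically exact.
* No dwell-time/idealisation analysis (threshold crossing, HMM), no burst
  analysis, no capacitance-transient or series-resistance modelling, no
  vendor binary formats.
* Po estimates for nearly silent channels (Po ~ 0.01) carry Monte-Carlo
  scatter of order ±0.005 on a single 30 s patch; pooling patches, as
  experimental histograms do, reduces it as 1/√n.
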