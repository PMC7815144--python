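# Methods

## The model

`glycoevo` simulates a population of yeast-like cells whose energy
metabolism is reduced to a four-reaction core of glycolysis.  Each cell
carries three cytosolic metabolite pools — the lumped intermediate FBP
(fructose-1,6-bisphosphate), ATP and inorganic phosphate P_i — coupled by:

* **Upper glycolysis (UG)**: glucose + 2 ATP → FBP, with irreversible
  two-substrate Michaelis–Menten kinetics and allosteric ATP inhibition,

  v_up = v_max,up [Glc][ATP] / ((K_M,glc+[Glc]) (K_M,atp + [ATP](1+[ATP]/K_i,atp))).

* **Lower glycolysis (LG)**: FBP + 2 ADP + 2 P_i → 4 ATP, irreversible
  three-substrate Michaelis–Menten kinetics; [ADP] = a_tot − [ATP] with the
  adenosine pool a_tot conserved.
* **ATPase**: v_atp = k_atp [ATP], a first-order lumped ATP demand.
* **Phosphate transport**: v_p = k_p ([P_i]_vac − [P_i]); the vacuolar level
  is buffered by the polyphosphate store and declines with the total
  phosphate already imported into the cytosol, P_tot = [P_i] + 2[FBP] + [ATP]:
  [P_i]_vac = [P_i]_vac,max / (1 + (P_tot/K_vac)^m).

Because ATP is invested in UG before it is repaid (with interest) by LG,
this "turbo" pathway is bistable at high glucose: besides the balanced
steady state (v_up = v_lo up to growth dilution, high ATP) there is a
self-sustaining imbalanced regime in which UG outruns LG, FBP accumulates,
and ATP and cytosolic phosphate stay low.  Which basin a cell falls into
depends on its phosphate status when glucose appears.

Metabolite dynamics include dilution by growth, −c·V′/V for each
concentration c.  A useful identity used as a conservation test:
dP_tot/dt = v_p − P_tot·V′/V.

### Growth, health, division

The ATPase flux first pays maintenance: the genotype-dependent expression
cost v_atp,e plus a genotype-independent cost v_atp,m (default 0).  The
remainder, the growth flux v_atp,g, drives volume growth when the cell is at
full health:

    V′/V = u_g v_atp,g   if H = H_max and v_atp,g > 0, else 0.

Negative growth flux drains a reserve variable H (health): H′ = −u_d·v_atp,g
for v_atp,g ≤ 0, recovery at u_g·v_atp,g below H_max, death at H = 0.  The
constants are calibrated so that a reference-genotype cell (10, 10, 10, 0.3)
in the balanced state at 2 mM glucose (ATPase flux 12.7 mM/min) doubles its
volume in τ_g = 90 min, and the same cell trapped in the imbalanced state
(ATPase flux 0.46 mM/min) dies in τ_d = 420 min:

    u_g = ln 2 / (τ_g (12.7 − 5)),    u_d = 1 / (τ_d (0.46 − 5)).

u_d is stored with the literal (negative) sign of its defining relation and
the health equation is implemented verbatim, so no sign juggling is needed
to reproduce the 420 min death time exactly.

A cell divides when V ≥ 2 V_c (V_c = 3.35e-15 L).  One daughter, chosen by a
fair coin, receives a fresh volume U(0.5, 1.5)·V_c; the other receives the
complement, conserving volume.  Daughters copy metabolite concentrations and
genotype, draw individual H_max ~ U(0.9, 1.1) (which desynchronises clonal
lineages) and start at full health.

### Genotype, cost, mutation

The evolvable genotype is (v_max,up, v_max,lo, k_atp, k_p), a proxy for the
expression levels of the pathway's enzymes.  Expression cost (default):

    v_atp,e = k_e [ (w_up v_max,up)^n + (w_lo v_max,lo)^n
                    + (w_atp c_u k_atp)^n + (w_p c_u k_p)^n ],

with unit weights, n = 4, c_u = 1 mM, and k_e normalised so the reference
genotype costs exactly 5 mM/min.  An alternative form raises the weighted
sum to the n-th power; the two coincide at n = 1.  The quartic nonlinearity
prevents unbounded expression: most random genotypes with any parameter a
few-fold above the reference are not viable, which is why evolutionary runs
start from a large founding population.

Mutation multiplies each parameter independently, with probability μ = 0.01
per parameter per division, by e^X with X ~ N(0, σ²), σ = 0.1 — a
multiplicative random walk whose median preserves the parental value.  Both
daughters are mutation-exposed (configurable).

### Environments

* **Chemostat**: the chamber glucose obeys
  [Glc]′ = −Σ_i v_up,i V_i / V_ch + D([Glc]_0 − [Glc]); cells wash out at
  per-capita rate D (binomially sampled per demographic interval with the
  exact survival probability 1 − e^{−D Δt_p}).
* **NCG** ("no competition for glucose"): the limit V_ch → ∞ at fixed D.
  Cells no longer affect the chamber; glucose relaxes to the supply at rate
  D, and crowding removes cells at total rate d·N² (per-capita d·N).

Supply schedules: constant; square wave (equal ON/OFF phases); pulse train
(short ON pulses, long OFF phases whose durations may vary cycle-to-cycle as
truncated normal draws, floor 1 min, cached per cycle for reproducibility).
For pulse trains the chamber is initialised at the OFF supply level — a
1 min, 300 mM pulse raises a D = 4e-3/min chamber by only ~1.2 mM, so
starting the chamber at 300 mM would throw the entire population into the
imbalanced state before the experiment begins.

## Numerics

All cells (FBP, ATP, P_i, V, H each) plus chamber glucose are advanced with
an adaptive Dormand–Prince 5(4) stepper written in-package (numba-compiled),
with per-component error control: atol 1e-5 mM / rtol 1e-5 for
concentrations, atol 1e-17 L for volume, atol 1e-2 for health (rtol 0 for
both).  After each accepted step, a metabolite component c with
−(atol + |c| rtol) < c < 0 is projected to zero; if a more negative
component remains the step is rejected and retried at half the size.  Rates
evaluated at transiently negative concentrations inside a step clamp the
concentration to zero.  Steps never cross supply switch times or sample
times, so the right-hand side is smooth within a step.

Two equivalent execution paths exist:

* **coupled** (chemostat): the whole population plus glucose is one ODE
  system, since every cell's uptake feeds back on [Glc];
* **per-cell** (NCG): cells are mutually independent and the chamber
  glucose has a closed form within each supply segment
  (G(t) = G_0 + (G_k − G_0)e^{−D(t−t_k)}), so each cell integrates its own
  5-dimensional system with an individually adapted step size.  This
  matters in practice: founding populations drawn from U(P/10, 10P) contain
  cells whose Jacobians differ by orders of magnitude, and a shared step
  would force every cell to the stiffest cell's step size.

The test suite cross-checks both paths against each other, against the pure
scalar rate functions, and against an independent scipy integration.

Demography is frozen within each integration interval Δt_p = 5 min; at each
boundary, events apply in a fixed order: death (H ≤ 0, after hard-clipping H
to [0, H_max]) → division (with mutation only inside the mutation-on
segment) → washout → tracked-set maintenance.  Death precedes division so a
dead cell cannot reproduce; washout follows division, matching a
continuous-outflow interpretation.  Division is checked only at boundaries,
so cells may transiently overshoot 2 V_c slightly.

Randomness comes from four named streams spawned from one root seed
(initialization, schedule, demography, mutation), so identical seed +
configuration reproduces a run bit-for-bit.  Mutation draws are consumed in
deterministic cell-index order from a single stream.

## Simulation protocol

A run has three segments: a mutation-free burn-in [t_s, t_ms) that purges
the (mostly non-viable) founding variation, a mutation-on segment
[t_ms, t_me), and a final mutation-free segment to t_e in which only the
fittest genotypes persist.  Before the full run, a mutation-free
pre-simulation of the burn-in duration measures the quasi-steady population
size N_p (mean over its final quarter) and rescales the provisional
population-size control: V_ch = V_ch,0 N*/N_p (chemostat) or d = d_0 N_p/N*
(NCG).  Because the calibration effectively sets the removal parameter to
(reproduction rate)/N*, the realised population size tracks N* up to the
factor by which evolution subsequently raises the reproduction rate.

Tracked cells (N_tr, default 100) are sampled every Δt_s = 1 min; tracking
passes to a uniformly chosen daughter at division and lost members are
replaced by uniform draws from the population.  Recording is windowed
(`track_start`): all statistics in scope are computed over late-run windows,
and recording every minute of a full run would be memory-prohibitive.

## Analysis statistics

* **B_p,cov** — sample covariance (ddof 1) of ([Glc], [ATP]) over the
  largest whole number of supply cycles in a track; positive = balanced.
* **B_p,phs** — mean ATP over ON samples minus mean ATP over OFF samples,
  labelling each sample by the schedule phase (a sample exactly on a switch
  belongs to the new phase); requires at least one sample of each phase.
* **Balanced-state criterion** — a constant-glucose single-cell trajectory
  is balanced when the steady-state identity v_up = v_lo + [FBP]·V′/V holds
  within 0.1 % relative error at more than 10 % of sampled points (samples
  with v_up below the metabolite atol are judged on the absolute residual).
* **B_g** (genotypic balancedness) — scanning glucose 2.00, 1.95, …,
  0.05 mM from the top, the largest concentration at which all 100
  trajectories started from N(mean, 6 % CV) metabolite draws (means
  FBP 2, ATP 1, P_i 10 mM for mode 1; an observed evolved state for mode 2;
  draws truncated at 0 and ATP at a_tot) are balanced after 300 min; 0 if
  none.  Draws depend only on the seed and the grid position, so the result
  is independent of scan order.  Ensemble members use H = H_max = 1 and
  V = V_c.
* **Reproduction rate** — the gated growth law u_g·v_atp,g reconstructed
  from sampled states (so division discontinuities in V never enter),
  averaged over whole cycles.
* **Competition** — two named genotypes (the shipped BC/IC pair), no
  mutation, chemostat; reports the balanced fraction f_b(t) from
  per-interval type counts.
* **Catastrophe summary** — a reporting heuristic only: flags a >50 % drop
  of N within one mean cycle followed by recovery above 80 % of the
  pre-drop size.

## Problem sizes used by the shipped tests and acceptance experiments

The deterministic quantities (expression costs, doubling time, death time,
balanced-state flux, imbalanced plateau) are computed at single-cell scale
and are exact to integrator tolerance.

The population-level replications are run scaled down, as the package's own
choice of desk-scale experiment sizes; at these scales the qualitative
selection pattern is already unambiguous:

* square-wave NCG evolution: N* = 500 with founding population 10 000,
  segments t_ms = 1000, t_me = 16 000, t_e = 26 000 min, three seeds per
  period T ∈ {40, 200} min; survivors' B_p,phs sign summarises the outcome.
* BC/IC chemostat competition: N ≈ 1000 (chamber calibrated by a 2000 min
  mutation-free pre-run), pulse-train supply (mean period 100 min, CV 5 %,
  D = 4e-3/min), 300 supply cycles from balanced fractions 0.2 and 0.8,
  three seeds.  At this population size the rare type occasionally drifts
  to extinction in a single realisation (the balanced fraction jumps to 1),
  so convergence is assessed as a majority over seeds.
* constant-glucose NCG evolution: N* = 300, t_me = 10 000, t_e = 14 000
  min, three seeds at 0.1 mM and at 2 mM.

Because the removal-rate calibration fixes d from the *pre-evolution*
reproduction rate, evolved populations settle above N* by the factor the
reproduction rate improves during the run (typically 2–4 at these scales);
this mirrors the behaviour of the full-scale protocol and is accepted.

## What the scaled experiments do and do not show

The scaled runs retain the full individual-based machinery — bistable
metabolism, health-gated growth, mutation at division, calibrated washout —
and reproduce the direction of selection: fast fluctuations select
imbalanced "hoarder" strategies, slow fluctuations select balanced growers,
scarcer constant glucose shifts expression toward UG at the expense of LG,
and the BC/IC pair under pulsed competition approaches a common interior
balanced fraction from both sides.  They do not resolve phenomena that need
long mutational histories or large populations: precise equilibrium
balanced fractions, the detailed phase structure of the supply cycle, or
recurrent catastrophe statistics.

## Known limitations

* No trehalose cycling, glycerol branch, or hexokinase regulation: the
  pathway is the minimal bistable core.
* Expression costs are instantaneous functions of the genotype; there is no
  expression dynamics or regulation.
* The NCG crowding term d·N² is an abstraction of space competition, not a
  mechanistic biofilm model.
* The balanced-state criterion assumes constant glucose; it is not meant
  for fluctuating-environment tracks (use B_p,cov / B_p,phs there).
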