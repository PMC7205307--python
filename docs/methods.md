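# Methods

## Model structure and assumptions

The circuit is reduced to three dynamical variables: mRNA, a lumped
protein concentration (`[p] = [XapA] = [XapB]`, assuming equal expression
and decay rates for the two operon products), and intracellular
xanthosine.  Two regulatory steps are treated at quasi-equilibrium
because binding is fast compared to expression dynamics: (i) induction of
the XapR dimer by xanthosine, modeled with a two-state MWC scheme (two
binding sites per dimer, active/inactive energy gap `Δε_x`, dissociation
constants `K_χA` to the active and `K_IA·K_χA` to the inactive state), and
(ii) occupancy of the two-site promoter, enumerated as eight Boltzmann-
weighted states with polymerase binding independent of activator binding,
so the partition function factorizes.  Only the fully occupied state
transcribes by default.  XapB import/export and XapA degradation are
Michaelis–Menten; the low-affinity Nup transporters enter linearized, with
efflux asymmetry `ξ`.  XapR copy-number fluctuations, cell division, and
passive diffusion are outside the model's scope.

Nondimensionalization measures time in protein lifetimes (`1/γ_p`) and
concentrations in the XapA Michaelis constant `K_a`; the polymerase
saturation factor `[P]/(K_P+[P])` is folded into the transcription
strength `ρ_m`, so the nondimensional interface never takes `[P]` and
`K_P` separately (the dimensional record carries them explicitly, and the
two forms are verified to commute under the scaling maps).  The canonical
defaults (the `table1()` factory) are the reference estimates built on
`γ_p = 5×10⁻⁴ s⁻¹`, `K_a = 5×10⁻⁵ M`; the lumped expression strength is
`ρ = ρ_m ρ_p / γ_mp = 10⁻²`.

### Cooperativity convention

The doubly occupied promoter state is weighted `r² e^{+Δε_coop}` with
`Δε_coop ≥ 0` the *magnitude* of the favorable XapR–XapR interaction
(default 5 k_BT); `Δε_coop = 0` switches the interaction off.  The
convention was fixed by requiring internal consistency of the model's
published behavior: with an enhancing factor the reference parameter set
yields three fixed points with ~5 / ~250 protein copies, ~2 copies at
zero inducer, and a switch-point mRNA count near one molecule, whereas a
suppressing factor of the same magnitude makes the circuit monostable at
negligible expression everywhere.  Note that the switch is genuinely
sensitive to this energy: at the reference values bistability holds near
`Δε_coop = 5` but not at 0 (weaker activation) or 10 (higher leak), a
fine-tuning the `cooperativity_sweep` helper exposes honestly.  Similarly,
counting singly occupied promoter states as transcribing
(`active_policy="any_xapr_bound"`) triples the leak and shifts the
bistable window from roughly `c_a ∈ [8.7, 23.2]` down to about `[7, 11]`.

## Deterministic analysis

At steady state the mRNA and protein equations are linear, so both are
eliminated (`m_a = (ρ_m/γ_mp)p_active(x_a)`, `p_a = ρ_p m_a`), leaving one
scalar balance `g(x_a) = 0`.  Because the full steady-state condition is
a quintic-like transcendental equation with roots spread over many
decades, `g` is bracketed on a log grid over `x_a ∈ [10⁻⁶, 10⁸]` (2000
points, configurable) and polished by bisection to relative 10⁻¹⁵; every
root is back-substituted into the full 3D right-hand side and must pass a
residual check (10⁻⁹, scaled), with duplicates removed at relative 10⁻⁶.
`g(0) = k_η c_a ≥ 0` and `g → −∞`, so a sign inconsistency at the scan
boundary (the only way to lose a root) raises a warning.  Stability comes
from the eigenvalues of the analytic Jacobian; real parts within ±10⁻⁹ of
zero are flagged `marginal` rather than silently classified, giving fold
detection an explicit dead zone.  The 2D reduction (mRNA at quasi-steady
state) exposes the reduced vector field and both nullclines — the protein
nullcline is exactly `p_a = ρ·p_active(x_a)` — and reproduces the 3D
fixed points and stability classes.

Bifurcation diagrams recompute the fixed points per control value and
refine fold locations by bisection on the branch count; branch linking
uses ranking by protein level, which is sufficient here because the
system shows only 1 or 3 coexisting states.  Trajectories integrate with
LSODA at `rtol 10⁻⁸ / atol 10⁻¹²` (mRNA sits at ~10⁻⁴ in scaled units).

## Stochastic simulation

The master equation lives on integer counts (M, P, X) with nine reaction
channels whose propensities are the macroscopic rates scaled by
`Ω = N_A V K_a` (density scaling: `Sᵀa(Ωy) = Ω·rhs(y)` exactly, which is
asserted in tests).  Transcription evaluates the continuous regulatory
function at the concentration `X/Ω` — the quasi-equilibrium promoter is
not discretized.  The default volume of 1 fL (`Ω ≈ 3.01×10⁴`) puts the
stable states at ~5 and ~250 proteins and up to ~2×10⁷ xanthosine
molecules; it is a configuration knob, not wired into any logic, and the
copy-number checks are convention-dependent on it.

Two solvers share the kernel code (JIT-compiled with numba):

* **direct** — Gillespie's exact algorithm; bit-reproducible given a
  seed; refuses to run past an event budget, which the induced state
  (≈10⁷ propensity per time unit) exceeds by design.
* **hybrid** — per macro-step, channels with propensity ≥ 10³ whose
  consumed species exceed 100 copies advance by Poisson tau-leaps with
  Cao's bounded-relative-change step (ε = 0.03); the remaining channels
  fire as exact events with propensities frozen over the leap; the
  partition is re-evaluated every step, leaps that would drive a count
  negative are halved and redrawn, and the solver falls back to exact
  stepping whenever the leap would be shorter than ~10 exact events.
  The scheme is validated distributionally against the direct method
  (two-sample KS) on networks with and without active leaping, not
  against any particular published partitioning algorithm.

Optional bursts draw geometric burst sizes for transcription and
translation with the initiation rates scaled by 1/mean, so burst mode
preserves the deterministic limit and only widens the noise (mRNA Fano
factor rises above 1).

Ensembles derive per-run seeds from a base seed via `SeedSequence`; runs
that fail are reported, never dropped.  First-passage (adaptation) times
are recorded in-kernel at event resolution when requested, or read off
sampled trajectories otherwise; runs that never cross are returned as
censored.  Bimodal endpoint distributions are split at the histogram
minimum between the two most prominent smoothed peaks; integer data are
binned at unit-aligned widths and the bin count shrinks with sample size,
and a split is accepted only when the valley drops below 60% of the
smaller peak — both guards exist because sub-unit bins on discrete counts
otherwise manufacture comb artifacts that fake a second mode.

## Study conditions and scaling of the test ensembles

The bundled scenarios pin the study conditions: reference parameters with
`c_a = 13` (bistable), 7 and 40 (monostable low/high), 12/18.5/25 for the
endpoint-distribution scan, ablation and reduced-site variants (the
reduced-site scenarios retune `ρ` through `ρ_m`, holding `ρ_p` and
`γ_mp`, since only the lumped product is specified), and the adaptation
protocol at `c_a = 25` over 5×10⁵ s.  Full-scale ensembles are 5000 runs
of 10⁶ s; the test suite and acceptance script use scaled ensembles —
100–200 runs, horizons of 250–500 time units (5×10⁵–10⁶ s) — which pin
mode *positions* and first-passage statistics well but estimate mode
*weights* only coarsely, and the hysteresis scan uses 40 runs per branch
at 100 time units, long after relaxation but short enough that rare
barrier crossings are negligible.

## What the generator does and does not emulate

All inputs are synthetic by construction (the model is the object of
study; there is no external data).  The discrete-molecule simulation
captures intrinsic reaction noise at fixed parameters; it does not
emulate extrinsic noise (XapR copy-number fluctuations, division-driven
dilution discontinuities, parameter drift between cells), so real
populations should show broader distributions and earlier bimodality than
the simulated ensembles.  Timescales inherit this caveat: the ~1.5×10⁵ s
adaptation time is an intrinsic-noise estimate.

## Known limitations

* The fold-continuation machinery only detects saddle-node structure
  (branch-count changes); no Hopf or period-doubling detection — the
  vector field's trapping regions preclude oscillations here.
* The hybrid solver freezes slow propensities over a leap; this is
  accurate when slow channels are genuinely slow (the regime the
  partition thresholds select) but is not an exact method.
* `split_bimodal` targets well-separated modes (the switch's regime); it
  will merge overlapping mixtures by design.
* Copy-number statements depend on the declared cell volume; other
  volumes rescale Ω and with it every count-valued result.
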