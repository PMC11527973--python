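# Methods

## Scientific setting

Surface plasmon resonance (SPR) screens of small-molecule imaging ligands
(luminescent conjugated oligothiophenes such as q-FTAA, h-FTAA, HS-84 and
HS-169, plus drugs like lansoprazole and methylene blue) against amyloid
fibrils (Aβ42, K18-tau, full-length 2N4R-tau, α-synuclein) immobilized on a
sensor chip produce response-vs-time traces (sensorgrams, in resonance
units, RU). Fibrils present multiple chemically distinct binding sites, so a
simple 1:1 Langmuir model rarely fits; the field's standard remedy is a sum
of independent site classes ("heterogeneous ligand" / sum-of-exponentials
models). This package implements that analysis end to end: forward
simulation, global fitting, model-order selection, stability diagnostics,
fast/slow classification, and a synthetic-data generator that stands in for
instrument exports, which are essentially never published for such screens.

## Binding model

Each site class *i* follows pseudo-first-order kinetics with association
rate constant ka_i (M⁻¹s⁻¹), dissociation rate constant kd_i (s⁻¹) and
saturation response Rmax_i (RU):

    dR_i/dt = ka_i · C(t) · (Rmax_i − R_i) − kd_i · R_i

with C(t) the analyte concentration, piecewise constant over the injection
schedule. Within a constant-C segment the solution is a single exponential
relaxation toward Req_i = Rmax_i·ka_i·C/(ka_i·C + kd_i) with observed rate
ka_i·C + kd_i; the total response is the sum over 1–3 classes (model orders
"1+1", sum2exp, sum3exp) plus an optional bulk refractive-index box that is
present only while an injection runs. Segment chaining carries each class's
bound level across boundaries (continuity of bound mass); the bulk box is
the only allowed discontinuity. Time intervals are half-open [start, end):
a sample exactly on a boundary belongs to the later segment. The
three-class ceiling mirrors the validated scope of vendor evaluation
software; SPR's temporal resolution (10–40 points/s) does not support
higher orders anyway.

Equilibrium quantities: KD_i = kd_i/ka_i; the binding isotherm
Req(C) = Σ_i Rmax_i·C/(C + KD_i) is exposed both as the steady-state limit
of the simulation and as a plateau diagnostic (`isotherm_check`).

### Mass-transport limitation

Optionally, a two-compartment quasi-steady-state model replaces the closed
form: the surface-proximal concentration Cs solves

    kt·(C − Cs) = Σ_i [ka_i·Cs·(Rmax_i − R_i) − kd_i·R_i]

algebraically at every instant and drives the same rate equations, which
are then integrated numerically (LSODA). As kt → ∞ the trace converges
monotonically to the unlimited closed form. A physical consequence worth
knowing: at small kt the model exhibits *rebinding* — freed analyte
lingers near the surface, so apparent dissociation is slower than kd. The
trivial statement "C = 0 implies transport-independent decay" holds only
for a surface that was never loaded. Transport-limited *fitting* is out of
the validated scope; the coefficient exists for simulation studies only.

## Global fitting

All curves of a concentration series (duplicates included as separate
curves, never averaged) share the kinetic parameters; an optional bulk-RI
offset is free per curve (bounded |RI| ≤ 50 RU). Curves are assumed
reference-subtracted upstream. Optimization minimizes the plain sum of
squared residuals with `scipy.optimize.least_squares` (trust-region
reflective) in log10 space for ka, kd, Rmax — positivity by construction
and sane conditioning across the seven decades spanned by real fibril
screens. Box bounds: log10 ka ∈ [0, 9], log10 kd ∈ [−7, 1],
log10 Rmax ∈ [−2, 5]. Default tolerances ftol = xtol = gtol = 1e−12;
noise-free round-trip tests need tight tolerances to reach
3-significant-figure recovery.

The Jacobian is analytic: parameter sensitivities of the piecewise
closed form are propagated across segment boundaries together with the
bound level (for each segment, dR/dp = dReq/dp·(1−E) + S₀·E −
(R₀−Req)·τ·(dk/dp)·E with E = exp(−kτ)), then chain-ruled to log10
parameters. This is both ~5× faster than finite differences and more
reliable near convergence.

Multi-exponential least squares is multi-modal, so each fit runs a
deterministic multistart:

1. a data-driven heuristic start (capacity from the peak response, KD near
   the median injected concentration, kd spread log-uniformly);
2. for order k ≥ 2, warm starts grown from a fit of order k−1: (a) the
   lower-order winner plus a near-silent extra class, (b) the winner with
   its largest-Rmax class split in two with kd nudged ×3 and ÷3 — both
   approximately preserve the lower-order SSR, which is what makes nested
   χ² non-increasing under warm-started multistart;
3. `n_starts` Latin-hypercube draws over the log bounds
   (`scipy.stats.qmc.LatinHypercube`, seeded; each marginal stratified).

Winner: lowest SSR, ties broken by start index. Identical inputs and
master seed give bit-identical parameter vectors. Components are reported
in canonical order, ascending kd (slowest-dissociating first); the source
screens list two unlabeled components per interaction, so deterministic
labeling is a package convention that reports state explicitly.

### Fit quality and the χ² normalization

χ² is declared as SSR/N (mean squared residual, RU²); fits with
n_params ≥ n_points are rejected as degenerate. The vendor software's χ²
normalization is undocumented; SSR/N is chosen over SSR/(N−p) because it
makes nested-model dominance (χ² non-increasing with model order under
warm-started multistart) hold by construction. With SSR/(N−p) an extra
component must absorb at least ~3σ² of noise to lower χ², which a
converged fit need not do, so dominance would hold only usually, not
always. With N in the tens of thousands the two normalizations differ in
the fourth decimal place.

Residual randomness is assessed by a Wald–Wolfowitz runs test on residual
signs (zeros dropped): exact runs distribution for n ≤ 30, normal
approximation above, two-sided by default. Under white noise its type-I
error at α = 0.05 calibrates to ~0.055 at n = 100 (the normal
approximation on a discrete statistic; within the accepted 0.03–0.07
band). Systematically patterned residuals (the signature of underfitting
with too few exponentials) give too few runs and p ≈ 0.

### Model-order selection

Stepwise, ascending: accept order k+1 over k iff χ²(k)/χ²(k+1) ≥ 2
(config-exposed) **or** the order-k residuals fail the runs test
(p < 0.05) while order k+1 passes. The thresholds operationalize the
qualitative criteria practitioners use ("good fit", "random residuals").
Order 3 is additionally guarded: if it would be selected, its stability is
probed first (below) and an ill-conditioned order-3 fit is reported with a
`low-confidence` warning but never auto-selected — the over-parameterized
sum3exp regime is precisely where fit results stop being trustworthy.

### Stability probing

`perturb_and_refit` restarts the optimizer from the converged solution
with one parameter multiplied by 10 (default) and declares the fit
reproduced iff every refitted log10 kinetic parameter lies within 0.05 of
the reference. Probing every parameter yields the condition flag: `ill`
if any probe fails. Clean one-site fits reproduce under all probes;
order-3 fits to noisy two-site data typically land in a different local
minimum — the characteristic instability of over-parameterized
multi-exponential fits.

## Synthetic data generator

The generator emulates the acquisition design of fibril–small-molecule
screens:

- dilution series of 5–8 concentrations (default 5), geometric from KD/10
  to 10·KD of component 1, injected in duplicate (default 2) —
  full-kinetics mode: one association + one 600 s dissociation per cycle;
- single-cycle mode (used when component 1's kd < 1e−4 s⁻¹, i.e. when the
  surface cannot be regenerated between cycles): up to 5 consecutive
  injections of ascending concentration and a single 10 min terminal
  dissociation;
- association duration auto-sized so every class reaches ≥ 95% of its Req
  at the median concentration (max_i ln20/(ka_i·C_med + kd_i)), capped at
  600 s with a flag — slow-association scenarios run capped, which is
  faithful to practice: such surfaces never equilibrate within an
  injection;
- sampling 10 Hz (the lower end of the instrument's 10–40 points/s);
- additive white Gaussian noise, default σ = 0.5 RU (a typical
  instrument-class noise floor; not a published value), seeded;
- optional slow downward baseline drift (default exponential, rate
  1e−4 s⁻¹), mimicking slow dissociation of the fibrils themselves;
- optional artifacts: a step jump of stated magnitude (exactly one
  discontinuity; exactly invertible) and a multiplicative signal decay
  during one injection (as seen for methylene-blue-class compounds).

Every dataset is emitted together with its generating model, so recovery
scoring never consults anything but the emitted ground truth. The bundled
bank carries the 12 fibril–analyte interactions of the source screen with
both components' ka, kd, Rmax and the published KD; one bank entry
(α-synuclein/q-FTAA, fast component) is flagged because the published KD
disagrees with kd/ka by a factor of 10 (an apparent exponent typo) — KD is
therefore always recomputed from the rates, never copied.

What the generator does **not** emulate: analyte depletion in the flow
cell, continuous affinity distributions (site heterogeneity beyond 3
discrete classes), temperature effects, regeneration chemistry,
refractive-index dispersion, and correlated (1/f) instrument noise.
Passing recovery tests therefore demonstrate identifiability under the
declared acquisition design and white noise — not robustness to every
pathology of real exports.

## Classification (Type 1 / Type 2)

Interactions are classified by the main component, defined as the class
with the largest Rmax (largest signal share; config-overridable to
smallest KD). Type 1: main component has ka ≥ 1e4 M⁻¹s⁻¹ **and**
kd ≥ 1e−3 s⁻¹ (fast association and dissociation; boundary values count
as fast). Otherwise Type 2 (slow kinetics — slow association pairs with
slow dissociation in these screens; such ligands wash out slowly and are
the better imaging candidates). The ka threshold sits between the
documented fast (≥1e5) and slow (≤1e3) regimes; the kd threshold is a
package convention (dissociation half-life ~12 min) chosen so the
canonical slow interactions classify Type 2.

## Numerical choices and test design

- Closed form vs oracle: the test suite integrates the rate equations with
  an independent stiff integrator (Radau, rtol 1e−9) and requires
  max|ΔR| < 1e−6 RU across orders 1–3 and both schedule types. The oracle
  lives in the test tree and shares no code with the implementation.
- "Effectively infinite" kt: the QSS transport deficit scales as
  Σ ka_i·Rmax_i/kt, so the transport-unlimited equivalence test uses
  kt = 1e12 (for ka·Rmax ~ 1e6, deficits ≪ 1e−3 RU). At kt = 1e9 a
  strong-binding model still differs by ~1e−2 RU — a genuine physical
  effect, not integration error.
- Noise-free round trips run with 2 multistarts: the heuristic + warm-start
  chain always finds the global (zero-residual) basin in these conditions,
  and tight tolerances then recover parameters to ~1e−13 relative.
- Replicated experiments (noisy recovery, selection accuracy) use reduced
  solver effort (2 starts, ftol 1e−8) — enough for problems this
  well-conditioned — and problem sizes of 20 replicates (recovery) and 50
  replicates (selection), chosen as desk-scale defaults.
- Degenerate inputs: all-zero residuals are rejected by the runs test;
  single-concentration series at order ≥ 2 attach an identifiability
  warning rather than failing; fits at the parameter-count limit
  (n_params ≥ n_points) are domain errors.

## Known limitations

- Rmax cannot go below 1e−2 RU, so a superfluous component is silenced via
  a small ka·C/kd ratio rather than a literal zero capacity.
- The fit assumes white noise; drifting or artifact-bearing curves should
  be cleaned first (the jump artifact is exactly removable; drift is not
  modeled in the fit).
- Transport-limited data can be simulated but not fitted.
- Bootstrap/Bayesian uncertainty quantification is deliberately absent;
  the stability probe is a qualitative conditioning diagnostic, not a
  confidence interval.
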