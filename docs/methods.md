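# Methods

## Model family

States (all dimensionless; time in minutes): membrane phosphorylated
receptor `r_p`, internalized phosphorylated receptor `r_pe`, internalized
dephosphorylated receptor `r_e` (the unphosphorylated membrane pool is
`1 − r_p − r_pe − r_e` by conservation), active IRS1 fraction `irs1`, total
IRS2 pool `irs2_tot` (synthesized and degraded), active IRS2 `irs2`, active
Akt `akt`, active aPKC `pkc`.

Minimal model (M4) kinetics, 25 kinetic parameters plus 4 observable
scaling factors:

- receptor cycle (6): `k_ins·I(t)` drives phosphorylation of the free
  membrane pool; `k_dp1` dephosphorylates at the membrane, `k_int`
  internalizes, `k_dp2` dephosphorylates in the endosome, `k_rec` recycles;
  the receptor signal seen downstream is `S = r_p + w_e·r_pe`.
- IRS1 (4): activation `k_a1·S·(1−irs1)·φ` with the aPKC brake
  `φ = 1/(1+(pkc/K_P1)^h1)`; deactivation `k_d1·irs1`.
- IRS2 (6): pool synthesis `k_s2·ψ` with the Akt transcriptional brake
  `ψ = 1/(1+(akt/K_A2)^h2)` and degradation `k_deg`; activation
  `k_a2·S·(irs2_tot−irs2)`, deactivation `(k_d2+k_deg)·irs2`.
- Akt (3): `k_aA·(irs1 + w_2·irs2)·(1−akt) − k_dA·akt`.
- aPKC (4): `(k_aP·irs2 + v_auto·pkc²/(K_auto²+pkc²))·(1−pkc) − k_dP·pkc`.
  The auto-activation Hill exponent is fixed at 2: it keeps the feedback at
  exactly two free parameters while guaranteeing an open parameter region
  with a saddle-node pair.
- input amplitudes (2): `a_feed` and `a_inf` scale the unit-normalized
  feeding and infusion insulin templates (pre-hepatic insulin was never
  measured in the emulated studies, so its amplitude is a fitted quantity).

Optional feedbacks add exactly two parameters each, as multiplicative
Michaelis factors: aPKC on internalization (`k_int·(1+a·pkc/(K+pkc))`), Akt
attenuating membrane dephosphorylation (`k_dp1/(1+a·akt/K)`), Akt
auto-feedback and aPKC inhibition on Akt activation, and Akt inhibition of
IRS1 activation. Disabling a feedback is exactly equivalent to setting its
two parameters to neutral values (0 for gains, ∞ for the IRS-brake
half-saturations); the numeric kernel exploits this so a single jitted
right-hand side serves every variant. The named variants reproduce the
fitted-parameter counts 37/35/33/33/31/29/35/35 for M0–M6/M2a.

With insulin ≡ 0 the model has an exact closed-form fixed point (all
activities zero, `irs2_tot = k_s2/k_deg`) for every variant; `basal_state`
returns it directly instead of relaxing the ODEs, with an optional
relaxation polish for custom kinetics. Observables are scaled states:
`s_IRS1·irs1`, `s_IRS2·irs2`, and `s_Akt_feed/s_Akt_inf · akt` (the two
studies report Akt in different arbitrary units); aPKC was never measured,
so it is reported as the raw state.

## Insulin inputs

All templates are continuous, non-negative, unit-normalized functions.

- *feeding*: log-Gaussian rise-decay over a basal offset (basal 0.1, peak
  1.0 at exactly 30 min, ~2× basal at 120 min).
- *infusion*: offset sinusoid `A(1+sin(2πt/T−π/2))/2` with period T = 5 min
  starting at the trough; the constant mode is the equal-AUC level `A/2`;
  the T2D-mimicking mode is the same sinusoid at amplitude fraction 1/3
  (configurable; the emulated study does not state the value).
- *first phase*: a bump (smoothstep rise for the healthy shape; convex
  cubic ramp for the impaired shapes, which is what a blunted delayed burst
  looks like and keeps their early-window insulin low) plus a second-phase
  plateau ramping in between 45 and 75 min. The plateau level is solved so
  all three shapes match the healthy curve's AUC exactly; because the
  plateau is exactly zero at each bump's peak time, peak heights compare
  exactly (healthy and impaired-slope share peak 1.0; the T2D shape's peak
  is 0.55 with a compensating elevated second phase).
- *composite pulses*: a (1−cos)/2 carrier at T = 5 min modulates any base
  profile with relative amplitude `a`; the result is renormalized
  **multiplicatively** to the base AUC. An additive baseline (the obvious
  alternative) can go negative where the base vanishes; the multiplicative
  correction (a factor within ~10⁻³ of 1) preserves non-negativity and
  leaves the relative pulse amplitude untouched.

## Numerics

Two integration paths: `solve_ivp` LSODA at rtol 1e-8 / atol 1e-10 with
output on a 0.1-min grid (default), and a numba-jitted fixed-step RK4
(dt 0.01–0.02 min, insulin pre-sampled at half-steps) used inside the
optimization loops; the two agree to ~1e-7 on the feeding trajectory and are
cross-checked by a test. AUC bookkeeping uses trapezoidal quadrature on a
0.005-min grid, which is effectively exact for these smooth/periodic
curves.

Equilibria of the aPKC subsystem are bracketed by sign changes on a 1e-3
grid and refined by Brent's method; folds are polished by a damped 2-D
Newton on {f = 0, ∂f/∂pkc = 0} with analytic derivatives, seeded from
equilibrium-count change points, with count-bisection as fallback.
Stability is the sign of ∂f/∂pkc. The subsystem is exactly one scalar ODE
in every variant, because no optional feedback enters the aPKC equation.

Event detection: aPKC switch-on/off are sustained (≥5 min) crossings of 50%
of the trajectory's aPKC maximum; IRS1/Akt rebound is the global minimum
between the first activity peak and the end, confirmed by a ≥5%-of-range
subsequent rise, with a 2.5-min moving average (reflect-padded) so 5-min
input ripple does not spawn spurious peaks. These thresholds are
configuration, not biology.

## Fitting and selection

The objective is the plain (unweighted) root-mean-square difference between
scaled model observables and measured means, pooled over every datum of
both emulated studies; solver failures return a 1e6 penalty. Optimization
is differential evolution (rand/1/bin, F = 0.7, CR = 0.9, seeded,
`updating="immediate"`) in log10 parameter space over physiologically
plausible per-parameter ranges, optionally followed by L-BFGS-B polish
started from the k best mutually distinct population members (DE roughs out
the basin; the polish finishes it — in practice the combination reaches the
noise floor at a fraction of the cost of DE alone). The four scaling
factors are solved in closed form inside the objective (least squares
through the origin per scaling id) rather than searched; they still count
toward k.

AICc = `n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1)`. mAICc is reconstructed as the
mean AICc over insulin-input rescalings {0.85, 1.0, 1.15} with parameters
held fixed — a robustness criterion against errors in the estimated
pre-hepatic insulin level. Variants are ranked ascending by mAICc (ties:
AICc, then RMS).

## Identifiability pipeline

Five steps, in order: (1) diverse solutions from region-constrained refits
(one global fit per parameter × log-range bin, for parameters the data do
not directly inform); (2) a receptor-recycling screen — the steady-state
relative oscillation of `r_p` under the 5-min sinusoidal input must reach
20% (the mean is floored at 1% of receptor capacity so a degenerate cycle
that traps receptors internally cannot pass on relative terms); (3) greedy
minimum-distance pruning in log10 space (ε = 0.5) visiting solutions in
ascending-RMS order; (4) an mAICc cutoff above the best solution; (5) a
prediction battery reported as consistent only when identical across all
survivors. A parameter is "well confined" when its across-solution log10
range is below one decade. All thresholds are exposed configuration.

Two refinements in the shipped recovery study: the solution set pools the
region-constrained fits with every fit's polished local optima
(`FitResult.alternates`), which sample the objective's flat directions at no
extra cost; and the confinement threshold is tightened to 0.4 decades there,
because a verdict meant to certify a point estimate to within a factor of
1.5 (≈0.35 decades) is incoherent at the 1-decade default — a parameter on a
compensation ridge can span 0.9 decades, be "confined" by the loose
definition, and still sit several-fold from its generating value.

## Synthetic data

`synthesize` emulates the structure of the two in vivo studies: a refeeding
time course (IRS1, IRS2, Akt over 0–120 min; sampling restricted to the
first 2 h because later times are confounded by systemic effects) and a
portal-vein infusion study (Akt under pulsatile/constant/T2D-mimicking
insulin, sampled at ≥10 min because earlier points are flow-transient).
Default grids — 12 feeding times × 3 observables plus 5 infusion times × 3
modes, n = 51 — are chosen dense enough that AICc is defined even for the
largest variant (k = 41). Noise is mean-preserving multiplicative
log-normal with CV 5% and 5 replicates per point (means and s.e.m. are
reported); the true designs of the emulated studies are not published.

`default_truth` is a curated M4 parameter set calibrated once against the
study phenotype and frozen: bistable aPKC subsystem (LP1 = 0.338, LP2 =
0.283 in model units; 44.0 and 36.8 a.u. through the IRS2 scaling), feeding
switch-on at ~15 min and switch-off at ~90 min with IRS1/Akt rebounds,
constant-infusion scaled IRS2 steady state ≈ 43 a.u. (staying on) versus
pulsatile deactivation by 30 min, healthy-first-phase switch-off at ~71 min
with impaired/T2D shapes progressively later, and pulse-amplitude ordering
of switch-off times. `truth_self_test()` verifies this battery.

## What the synthetic study does and does not show

Passing tests demonstrate that the implementation reproduces the intended
mechanism and that the workflow (fit → select → filter) behaves correctly
on data whose generating process is known and matches the model class. They
do not validate the biology: real measurements have inter-animal variance,
non-log-normal noise, unknown sampling bias, and a generating process
outside the model family. Two deliberate simplifications: pre-hepatic
pulsatile insulin is a clean sinusoid (real pulses are irregular), and the
synthetic truth follows pulses more deeply than the published trajectories
(its pulsatile IRS2 troughs reach ~13 a.u.). Exact reproduction of the
published RMS/AICc table is out of scope — it requires the original
unpublished datasets.

## Known limitations

- In the synthetic recovery study, the fit reaches the noise floor and the
  minimal model wins the variant ranking, but only a small core of
  parameters (deactivation and turnover rates: k_d1, k_dA, k_deg, with h1
  borderline) is pinned tightly enough that the point estimate lands within
  x1.5 of the generating value. Parameters on compensation ridges (e.g.
  K_P1 with h1, K_A2 with h2, k_a2 with the receptor gains) show small
  across-solution spread yet collectively offset estimates — a "confined"
  verdict does not certify unbiasedness at this sample size and noise
  level. The corresponding acceptance assertion fails and is left failing.

- The first-hour IRS1/Akt windowed AUC is not flat across the first-phase
  input shapes in this reconstruction (~35%/~20% spread): the delayed
  T2D-shape aPKC switch-on leaves IRS1 free-running longer, and compressing
  the switch-on spread enough to flatten it destroys the pulse-amplitude
  timing effects. The corresponding acceptance assertion fails and is left
  failing by design.
- aPKC activity is reported on the model's internal scale; no aPKC
  measurement exists to set its units.
- DE budgets in the shipped analyses are scaled down (popsize multipliers
  5–10, 35–180 generations, multi-start polish) so a full study runs in
  minutes; the budget is a problem-size choice exposed in `DEConfig`.
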