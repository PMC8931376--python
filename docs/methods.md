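# Methods

`cbcflux` analyses ¹³CO₂-labeling kinetics of photosynthetic carbon
metabolism.  This note records the models, the numerical choices, and what
the synthetic study conditions do and do not establish.

## The scientific question

When a leaf at steady-state photosynthesis is switched from ¹²CO₂ to
¹³CO₂, Calvin–Benson cycle (CBC) intermediates label within minutes — but
the last 10–20 % of ¹²C washes out far more slowly, and fully unlabeled
(M0) molecules remain anomalously abundant long after singly labeled (M1)
molecules have vanished.  The package implements the two complementary
analyses that resolve this into a mechanism: (i) polyexponential modelling
of the %¹²C washout curve, whose number of resolvable exponential terms
equals the number of first-order pools feeding the cycle, and (ii)
isotopically nonstationary metabolic flux analysis (INST-MFA) over a
compartmentalized atom-mapped network, comparing hypotheses for where
unlabeled carbon enters.  The supported mechanism is reimport of unlabeled
carbon from cytosolic/vacuolar sugars through a cytosolic
glucose-6-phosphate (G6P) shunt: G6P.c → Ru5P.c + CO₂, with the pentose
phosphate re-entering the chloroplast.

## Network model

The canonical network (in `cbcflux.network`, expressed in a one-line-per-
reaction DSL with per-carbon atom maps) has 34 base reactions over four
compartments — chloroplast stroma (`.p`), cytosol (`.c`), mitochondrion
(`.m`), vacuole (`.v`) — covering the CBC, a lumped photorespiratory
salvage path (2PG → glycine; 2 glycine → serine + CO₂, map
`ab + cd -> cdb + a`; serine → glycerate → PGA), starch and sucrose
synthesis, the cytosolic G6P shunt with pentose return through the
xylulose-5-phosphate translocator, a lumped triose-phosphate efflux
standing for TCA/amino-acid demand, and a single well-mixed intracellular
CO₂ pool fed from the atmosphere and receiving photorespired and shunt
CO₂.  Lumping choices (PGA reduction as one step, the shunt as one
decarboxylating step losing C1, photorespiration condensed to three
steps) preserve every carbon fate the analyses depend on while keeping
the ODE system small.  Reversibility defaults follow standard
thermodynamics: rubisco, the phosphatases, PRK, and kinase/decarboxylase
steps irreversible; isomerases, aldolases and transketolases reversible.

Hypothesis variants add unlabeled-carbon entry routes to the base
network: V1, unlabeled glucose into cytosolic G6P; V2, unlabeled glucose
into plastidic G6P (starch-turnover surrogate); V3, unlabeled CO₂ into
the internal CO₂ pool; V4, unlabeled triose phosphate into the plastid;
V5 (the final model) activates sucrose recycling (cytosolic invertase,
hexokinase, fructokinase) and tonoplast sugar transport.  Two explicit
starch-turnover topologies (whole-pool and oligosaccharide-intermediate)
are also available.

**V5's "glucose entry".**  In the final model the unlabeled carbon is not
an external source: it is the leaf's own (initially unlabeled, slowly
labeling) sugar pools.  V5's glucose entry flux is therefore the
hexokinase flux, fed by cytosolic invertase (default 1.6 µmol gFW⁻¹ h⁻¹)
plus vacuolar sugar efflux (0.3), summing to the 1.9 µmol gFW⁻¹ h⁻¹
entry rate of the headline flux map.  Modelling it as a never-labeling
external source instead would add a spurious constant term to the washout
curve — precisely the inactive-pool artifact the analysis rejects.

**Steady state by construction.**  Flux maps are built from physiological
free fluxes (carboxylation v_c, oxygenation v_o, shunt rate, starch and
sucrose synthesis, recycling rates, entry fluxes, CO₂ efflux); all
dependent fluxes follow from metabolite balances and the cytosolic triose
efflux closes the overall carbon balance.  Every candidate flux state
during fitting is exactly balanced, so no steady-state penalty is needed.
Defaults reproduce the headline map: v_c = 172, v_o = 50 (v_o/v_c ≈ 0.29),
photorespired CO₂ 25, shunt CO₂ 7, net assimilation 140 µmol gFW⁻¹ h⁻¹.

**Carbon accounting.**  From a balanced map: returned carbons are
3 × glycerate return and 5 × pentose import; net assimilation is
carboxylation minus the two CO₂ releases; the ATP cost of fixation is
3 + 3 × (shunt glucose flux)/(net assimilation), three ATP per glucose
cycled through the shunt.  The photorespiratory return fraction is
computed by balancing the salvage subnetwork at unit 2PG production and
counting atoms delivered to PGA (3/4 for the canonical path); the
computation errors out if the branch fluxes are not fixed by
stoichiometry.

## Labeling simulation

Mass isotopologue distributions (MIDs) are simulated by EMU (elementary
metabolite unit) decomposition: the minimal closure of carbon-atom
subsets needed to reproduce the observed MIDs, solved in size order.
Each EMU's MID obeys `c · dX/dt = Σ_r v_r Y_r − (Σ_r v_r) X` with pool
size `c`; condensations contribute convolutions of smaller-EMU MIDs.  The
full cascaded system is integrated at once with BDF: the only
nonlinearity is bilinear, so the sparse Jacobian is assembled
analytically and is exact.  Convolutions with constant source MIDs are
folded into the linear operator as Toeplitz blocks.  Reversible reactions
carry forward/backward rates `v_f = max(v,0)+e`, `v_b = e−min(v,0)` with
exchange flux `e ≥ 0`; default exchanges are modest fractions of the net
rates (e.g. triose-phosphate isomerase 50, phosphoglucoisomerase 10
µmol gFW⁻¹ h⁻¹), fixed at their defaults during fitting unless freed.

Defaults: initial condition fully unlabeled (option: natural abundance,
1.1 % ¹³C per carbon); feed switches to 99 % ¹³C at t = 0; solver
tolerances rtol 1e-8 / atol 1e-10 for simulation (loosened to 1e-6/1e-8
inside fitting loops, where the weighted objective is insensitive below
measurement noise).  Two independent oracles check the simulator: the
Bateman closed form for linear chains (repeated rates are rejected — a
measure-zero case; fitting code perturbs instead), and a brute-force
2ⁿ-state positional-isotopomer integrator feasible on toy networks.
Agreement is ~1e-9 on both.

## Polyexponential washout modelling

The %¹²C series of the pooled CBC intermediates (DHAP, E4P, FBP, GAP,
PGA, RuBP, S7P; pool-size × carbon-count weighted mean, an unweighted
option exists) is fitted in the linear domain with
`u(t) = Σ A_i e^(−k_i t) (+ C)`, K = 1..4, amplitudes and rates
non-negative, C ≥ 0 representing a metabolically inactive pool.
Multistart bound-constrained least squares (default 100 starts: random
log-uniform rates 1e-2–1e2 h⁻¹ and Dirichlet amplitudes, plus a
deterministic semilog curve-stripping start and a log-spaced "spread"
start that guarantees each K-term model can reach the (K−1)+constant
boundary fit); analytic Jacobians; rates reported in descending order
(ties broken by amplitude) to resolve label switching.

Model selection over the nested roster {1exp, 1exp+C, 2exp, 2exp+C,
3exp, 3exp+C, 4exp} uses four criteria: extra-sum-of-squares F tests on
consecutive pairs with Bonferroni–Holm correction; AIC and BIC in their
Gaussian forms `n ln(SSR/n) + 2q` and `n ln(SSR/n) + q ln n` with
q = parameter count + 1; and cross-validation with folds grouped by
sampling time (identical to leave-one-out for unreplicated series;
replicates of one sample are never split across train and test).  The
consensus rule: a model is selected when its Holm-adjusted step-up
p-value is < 0.05 and at least two of {AIC, BIC, CV} prefer it;
otherwise the extra-SS ladder winner stands.  Confidence bands come from
residual-resampling bootstrap (residuals inflated by √(n/(n−p)) to
correct the fitted-residual variance bias; the time grid is fixed by
design, so cases are not resampled).  The F test is exactly calibrated
for unconstrained nested pairs and conservative at the C ≥ 0 boundary —
the usual half-mixture null.

## Flux fitting

`LabelingFluxModel` fits a hypothesis variant to a `MeasurementSet`:
MID time courses with per-channel SDs plus scalar pseudo-measurements
(net assimilation, sucrose and triose export, and the v_o/v_c ratio
constraint, default 0.31 ± 0.02 — constrained, not fixed).  Observed
species are pool-size-weighted mixtures over compartments (e.g. F6P =
F6P.p + F6P.c; sucrose is observed as glucosyl and fructosyl moieties),
so mixing weights move with fitted pool sizes.  Free parameters are any
subset of the physiological flux knobs, log₁₀ pool sizes, and inactive
fractions (`fin:<observable>`, intended for glycine/serine/alanine-like
species; a diagnostic mode may free them for any observable).  Default
multistart is 20 (the flux objective is far costlier than the decay
fits).  Weighted SSR = Σ((sim−meas)/SD)².

Variant comparison fits each variant with its entry flux free and ranks
by SSR restricted to the channels measurable in *every* variant, so
rankings are not artifacts of V5 observing free sugars that smaller
networks lack.  Confidence intervals come from two routes: profile
likelihood (parameter continuation with adaptive step growth and Brent
refinement at the SSR_min + χ²₁(0.95) crossing; box-limited directions
flagged one-sided) and parametric Monte Carlo (resimulate at the stated
SDs, warm-start refits, percentile intervals).  The profile engine is
validated against the analytic ±1.96·SE interval of a linear model to
<1 %.

## Synthetic study conditions

Scenarios (`base_no_reentry`, `glucose_reentry`, `starch_turnover`,
`inactive_pools`, `final_v5`) pin ground truth: balanced fluxes, pool
sizes, the 14-point sampling grid (0, 0.5, 1, 2, 2.5, 3, 5, 7, 10, 15,
30, 60, 90, 120 min), and the noise model — additive truncated Gaussian
per MID channel, SD 0.01 absolute, renormalized to the simplex.  Pool
sizes realise three washout timescales: CBC intermediates turn over in
seconds (RuBP 0.4, PGA 1.2 µmol gFW⁻¹ at v_c = 172), cytosolic hexose
phosphates and sucrose in tens of minutes (G6P.c 3.5, SUC.c 8), and
vacuolar sugars in many hours (SUC.v 20, GLC.v 3, FRC.v 2.5 at 0.3
µmol gFW⁻¹ h⁻¹ cycling).  Under `final_v5`, cytosolic glucose and
fructose are ~12 % and ~23 % labeled at 60 min and the washout of the
CBC aggregate is triphasic with fitted components ≈ (30 %, 34 h⁻¹),
(56 %, 3.4 h⁻¹), (13 %, 0.5 h⁻¹).

The washout dataset emulates the pooled replicate-level design: six
replicate aggregate series (84 points), each the pool-weighted mean of
the seven metabolites' noisy %¹²C values.  Noise for the %¹²C series is
applied without channel clipping — %¹²C is a linear functional and
corrected MS intensities can dip below zero; clipping would bias the
late tail upward by ~0.3 points, which the F test (correctly) flags as
spurious structure.  Fourteen per-time means alone leave the F test
without error degrees of freedom; the replicate-level design is what
gives the selection analysis its power.

**What the synthetic conditions do not show.**  They contain no natural-
abundance contamination, spectral overlap, missing channels, day-drift,
or inter-leaf biological variance; channel noise is homoscedastic, which
real MS error is not.  Passing tests therefore demonstrate correctness
and statistical calibration of the machinery under the stated generative
model, not performance on raw instrument data.  Two empirical behaviors
of the original measured dataset do not reproduce under these
conditions: (i) the network-generated aggregate is not an exact
triexponential, so at replicate-level power the selector occasionally
resolves a fourth component or the small enrichment-floor constant —
3exp-without-constant is the modal consensus, and the ≥80 % selection
rate holds for exactly triphasic washout at the same grid and noise;
(ii) fitted to synthetic reentry data, the unlabeled-CO₂ variant (V3)
absorbs part of the dilution signal (entry ≈ 2.7–4.3 µmol gFW⁻¹ h⁻¹,
SSR reduced ~20–40 % relative to the base model) rather than fitting
exactly zero, although it remains 3–10× worse than the intact-glucose
models — the qualitative conclusion (intact carbon, not CO₂) is
unchanged, but the exact zero appears to be a feature of the real
measured dataset.  Also, the base (no-reentry) scenario still has
sub-hour kinetic structure from photorespiratory and shunt return, so
its washout resolves up to three fast components; what distinguishes it
from the final model is the absence of any sub-1 h⁻¹ component, which is
what the tests assert.

## Numerical conventions and limitations

Fluxes in µmol gFW⁻¹ h⁻¹, pools in µmol gFW⁻¹, file times in minutes
(converted to hours internally); rates in h⁻¹.  MIDs are validated to the
unit simplex within 1e-9 during computation; CSV input off by ≤1e-3 is
renormalized with a warning, beyond that rejected.  Degenerate inputs:
zero-throughput pools simply retain their initial labeling; empty
networks, atom-unbalanced reactions, and underdetermined salvage branches
are errors.  Known limitations: no positional-isotopomer (NMR)
observables; no ²H/¹⁸O tracers; metabolic steady state is assumed
throughout the labeling window; exchange fluxes are weakly identified
(only freed deliberately); absolute weighted SSR values are
dataset-dependent — only differences and rankings on a common channel
set are interpreted.
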