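# Methods

## Scope

One 5 h anaerobic–aerobic operating cycle (2.5 h per phase) of an
*Accumulibacter*-type PAO culture fed a mixture of acetate (HAc) and
propionate (HPr). Anoxic metabolism, GAO competitors, PAO clade
differentiation, multi-cycle SRT/HRT dynamics and duress behaviours
(PO₄-starved glycogen accumulation, TCA-supplemented reducing power) are
out of scope.

## The metabolic model

**State.** Ten reported components: dissolved O₂, HAc, HPr and PO₄ in the
bulk liquid; PAO biomass X_PAO; intracellular PHB, PHV, PH₂MV (the PHA
constituents), glycogen and poly-phosphate. Concentrations are C-mmol/l
(P-mmol/l for phosphorus pools, mmol/l for O₂). An eleventh integrated
pool books CO₂-carbon so that carbon closure is checkable on every
trajectory; an ATP bookkeeping row in the stoichiometric matrix closes the
energy balance per process.

**Processes.** Ten kinetic processes:

1–2. *Anaerobic VFA uptake* (HAc, HPr): Monod in the dissolved acid,
saturating in the intracellular glycogen and poly-P fractions, proportional
to biomass. Per C-mol VFA the cell invests a pH-dependent ATP transport and
activation cost α(pH) = 0.75 + 0.36·(pH−7), met by poly-P hydrolysis (1 ATP
per P-mol, released as PO₄) plus substrate-level ATP from glycolysis
(0.5 ATP per C-mol glycogen). Glycogen demand is 0.50 C-mol/C-mol for HAc
(pH-independent) and 0.33 + 0.05·(pH−7) for HPr; the carbon balance closes
into PHA (1.33 C-mol per C-mol HAc; PHB:PHV:PH₂MV split 0.90/0.10/0 for
HAc, 0.05/0.55/0.40 for HPr, following the carbon-source dependence of PHA
composition) and a small CO₂ evolution. A kinetic pH factor
1 − 0.40·(pH−7) additionally slows uptake at high pH (transport against a
steeper gradient), so pH acts on both yields and rates in opposite
directions.

3. *Anaerobic maintenance*: an ATP demand m_ATP,an·X_PAO met sequentially —
poly-P hydrolysis first, then glycogen glycolysis (producing PHB plus CO₂)
— with smooth reserve-availability switches R/(R+K_sw), K_sw = 10⁻⁴
C-mmol/l, so the right-hand side stays Lipschitz for the solver.

4–5. *Aerobic VFA uptake* (gated): same laws times an O₂ Monod term, active
only when the anaerobic phase ended with no residual VFA. Whenever
S_HAc+S_HPr > 10⁻⁶ at t = 2.5 h the gate closes and residual substrate is
not consumed aerobically, so aerobic process comparisons are not confounded
by carbon uptake.

6. *PHA degradation / growth*: a mobilization cap q_PHA·θ^(T−20)·
f_PHA/(K_fPHA+f_PHA)·Monod(O₂)·X_PAO. Glycogen formation, poly-P formation
and maintenance draw their PHA carbon and ATP first; biomass growth is the
surplus of the cap over those demands, with yield
Y_X = 1/(1 + K_w/(2.25δ)), where K_w interpolates the ATP cost of anabolism
from acetyl-CoA (K₁) and propionyl-CoA (K₂) by the current PHB share, and
2.25δ is the ATP return per C-mol PHA fully oxidized (2.25 NADH₂ × δ ATP
each, 1.125 mol O₂ per C-mol). PHA consumption is split across PHB/PHV/PH₂MV
proportionally to their current shares.

7. *Glycogen formation*: 1 C-mol PHA skeleton plus 0.5 ATP (from PHA
oxidation) per C-mol glycogen, inhibited as f_Gly approaches f_Gly,max.

8. *Poly-P formation*: Monod in PO₄, saturating in the PHA fraction,
inhibited as f_PP approaches f_PP,max; ATP cost (1 + ε) per P-mol, where ε
is the phosphate transport coefficient.

9. *Aerobic maintenance*: sequential on PHA, then glycogen (full oxidation,
0.5 + 2δ ATP per C-mol), then poly-P.

10. *Aeration*: S_O₂ follows a saturating supply k_La·(O₂sat − S_O₂)
(k_La = 10 h⁻¹, O₂sat = 0.25 mmol/l) during the aerobic phase and is held
at zero anaerobically. With biomass absent only this abiotic term acts, so
the zero-biomass trajectory is the identity on every biological pool while
O₂ rises to saturation.

Temperature enters every rate as θ^(T−20 °C) with a per-process Arrhenius
coefficient θ (reference 20 °C, the convention of the cited temperature
studies).

**Balance properties.** Every stoichiometric column conserves carbon and
phosphorus to 10⁻⁹ by construction, and both closures are *linear*
invariants of the state, which Runge–Kutta methods preserve exactly —
observed drift over a full cycle is at machine precision. X_PAO is
untouched by every anaerobic column, so anaerobic biomass constancy is
exact, not a tolerance. With the gate closed no aerobic process produces
PHA, so total PHA is non-increasing over the aerobic phase.

**Numerics.** The production path is a hand-inlined right-hand side with an
adaptive Cash–Karp RK(4,5) integrator (rtol 10⁻⁶, atol 10⁻⁹) compiled with
numba, stepping exactly onto a uniform 301-point grid (1-min resolution,
which resolves the fast anaerobic uptake transient; the phase switch falls
on a grid point). A plain-NumPy reference formulation of the same model
(`ebpr_gsa.model.reference_rhs` + SciPy LSODA) is kept as an independent
oracle; the test suite checks the two right-hand sides agree to 10⁻¹² on
random states and full trajectories agree to solver tolerance. Rate laws
use max(C, 0) internally so quasi-random corners of parameter space that
graze depletion cannot drive components meaningfully negative; reported
trajectories are clamped at zero. A row whose integration exceeds the step
budget or goes non-finite is recorded as failed (never silent NaN); more
than 1 % failures aborts the batch as a mis-specified design. Across the
acceptance-scale runs the observed failure rate is 0.

## The uncertainty database

39 inputs: 12 metabolic (K₁, K₂, δ, ε and eight half-saturations including
K_O₂), 9 kinetic (uptake/conversion maxima, two maintenance coefficients,
f_Gly,max, f_PP,max), 6 Arrhenius coefficients, 10 initial conditions
(influent S_VFA, HAc:HPr ratio, P:C ratio, biomass, total PHA fraction and
its three Dirichlet-coupled constituent weights, glycogen and poly-P
fractions) and 2 environmental (T, pH). The total PHA fraction is itself a
sampled input; its constituent weights consume three unit-hypercube columns
(inverse-gamma transform, normalized, scaled by the total), so the
parameter matrix stays a pure column-wise transform and per-weight index
attribution is well defined — at the cost of one exact linear dependency
among the four PHA columns, which is why the pipeline regression uses the
minimum-norm OLS solution (R² is invariant to that choice).

The shipped measurement collections
(`data/literature_synthetic.yaml`) are *synthetic*, literature-style sets:
they emulate the relative data abundance of a survey of the EBPR modelling
literature (anaerobic acetate uptake and aerobic poly-P formation rates
data-rich with 33 and 90 entries — the latter crossing the >50-point Erlang
threshold with a deliberately wide, gamma-shaped spread — half-saturations
and energetic yields data-poor) around values conventional for the
Smolders/Oehmen-family models. They are not transcriptions of any published
table. Erlang sampling is untruncated (the fitted distribution is the
uncertainty statement; its support is already positive).

Arrhenius coefficients carry one adopted value each (the 50 % tier): the
temperature-dependence literature reduces to a single consolidated estimate
per process, and a wide band there is what exposes the exponential
interaction channel.

Initial conditions are *not* literature collections — they describe one
operated system — so each carries a measurement-reproducibility band:
5 % around the reference operating point (S_VFA 1.5 C-mmol/l, HAc fraction
0.67, P:C 1.5, X_PAO 4.43 C-mmol/l, fractions PHA/Gly/poly-P
0.14/0.36/0.30) and a Dirichlet split concentrated at the PHB-dominant
composition (α = 60/25/15, i.e. mean 0.60/0.25/0.15 with ~5 %-grade
dispersion). A maximum-entropy α = (1,1,1) split was considered and
rejected: uniform simplex weights make each PHA constituent's cycle mean a
near-linear copy of its own initial value, which contradicts the intended
interaction-dominated regime.

## Sampling and estimation

Sobol' sequences (scipy.stats.qmc, optionally Owen-scrambled by the seed;
the unscrambled sequence skips its initial all-zero point) populate a 2M-
dimensional base matrix split into A and B; the M hybrid blocks A_B^(i)
give N·(M+2) rows. First-order indices use the Saltelli-2010 estimator
mean(f_B·(f_AB,i − f_A))/Var(Y), total-order the Jansen estimator
mean((f_A − f_AB,i)²)/(2·Var(Y)), with Var(Y) on the pooled A∪B sample and
all outputs centred on the pooled mean first (this makes the estimates
exactly invariant to affine output rescaling). Failed simulations drop
their entire (A, B, A_B^i) tuple, preserving estimator validity.
Confidence intervals are percentile bootstrap over base-sample indices
(default 1000 resamples, 95 %), resampling tuples intact and deterministic
under a seed; constant outputs get zero-width intervals. Negative
first-order estimates are reported raw in the CSV exports and clamped at
zero only for normalization and ranking; ranking ties break by database
column order. SRC regressions run on the independent A and B blocks (the
plain Monte Carlo part of the design).

Estimator validation is oracle-based: an in-repo closed-form module
(`ebpr_gsa.oracles`) provides the exact variance decompositions of a linear
additive model (β² = S1 = ST) and of the Ishigami function at the standard
constants (a = 7, b = 0.1), chosen because its analytic decomposition
exercises non-linearity, non-monotonicity and a pure interaction input.
The estimators recover both within 0.02 at N = 2¹⁴, and a dummy input's
indices vanish within their CIs.

## Problem sizes

The package's own study scales are: 4,096 cycle simulations for the plain
Monte Carlo linearity diagnostic, a base sample of 512 (20,992 simulations)
for the Sobol experiment, 1000 bootstrap resamples, and 100 random draws
for the physics property checks — a deliberate reduced-scale re-run of a
design whose headline configuration (N = 4000, 164,000 evaluations) the
sampling layer reproduces exactly and the test suite checks by
construction. At ~0.5 ms per compiled cycle the full headline experiment is
itself ~2 min of compute, but the reduced scale already leaves estimator
noise, not simulation count, as the binding uncertainty on the reported
maxima.

## What the synthetic conditions do and do not show

Passing tests demonstrate that the pipeline — range rules, Erlang fits,
Saltelli design, mass-closed cycle simulation, SRC and Sobol estimation
with bootstrap uncertainty — is internally correct against independent
oracles and reproducible bit-for-bit under a seed and across worker
counts. The *scientific* conclusions computed on the shipped database
(strongly non-linear response, interaction-dominated variance led by
temperature and the Arrhenius coefficients, uniformly small first-order
effects) reflect the synthetic uncertainty characterization; they are not a
reanalysis of any published survey, and parameter rankings in particular
depend on stoichiometric constants transcribed from the cited model family
rather than from a supplementary source.

## Known limitations

* **Biomass output.** Mean X_PAO over a cycle inherits the initial biomass
  almost linearly: the model has no biomass-decay channel (maintenance
  draws on reserves only) and per-cycle growth is a few percent of standing
  biomass. Its first-order index for X_PAO_i (~0.2) and the corresponding
  R² contribution therefore sit above what a fully interaction-dominated
  regime would show, at any defensible biomass-measurement uncertainty.
* **Oxygen supply** is a fixed saturating aeration term; k_La and O₂sat are
  scenario constants, not sampled inputs, and no oxygen-limitation regime
  below K_O₂ is explored by the default database.
* **Anabolic redox bookkeeping** is absorbed into the growth yield Y_X;
  NADH₂ produced or consumed by anabolism itself is not tracked separately.
* Second-order Sobol indices, screening designs (elementary effects) and
  density-based measures are not implemented; LASSO/ridge/stepwise
  regression alternatives to OLS are deliberately excluded.
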