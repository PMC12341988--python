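# Methods

This note documents the models, numerical procedures and design
choices behind `redoxflux`, in the spirit of a package methods section:
what is computed, under which assumptions, and what the synthetic test
model does and does not establish about real genome-scale models.

## Flux balance analysis and ratio constraints

FBA is posed directly as a linear program over the flux vector v:
maximize the biomass flux subject to steady state (S v = 0) and bounds.
The LP is solved with HiGHS (through `scipy.optimize.linprog`) at a
primal/dual feasibility tolerance of 1e-9 (configurable via
`SolverSettings`; HiGHS enforces a floor of 1e-11).  Infeasible and
unbounded problems are reported as statuses, never clamped.

Flux-split hypotheses ("fraction f of a pool flows through reaction
R") are encoded as extra equality rows
`v_focal − f · Σ_{r∈D} v_r = 0` with the focal reaction a member of the
denominator set D.  Encoding them as rows rather than bound
manipulations means they compose transparently with flux variability
analysis and with sampling, where they simply extend the equality
system defining the polytope.  The fraction must lie in [0, 1] and
every denominator flux is expected to be nonnegative in the scenario;
this is the caller's responsibility (all built-in conditions satisfy
it).

**Degeneracy.** FBA optima are almost always degenerate, so any
per-reaction flux quoted from "the" optimum depends on the solver's
arbitrary vertex choice.  All reported fluxes therefore come from a
parsimonious second stage: with the objective pinned to its optimum,
total absolute flux Σ|v| is minimized using the standard t ≥ |v|
split reformulation.  This is a deterministic, documented tie-break;
it is also the stage at which yields, phase-plane fluxes and panel
fluxes are read.  The first-stage optimum is preserved to 1e-9.

Flux variability analysis is the textbook procedure: two LPs per
reaction with the objective constrained to ≥ fraction × optimum.

## Curation procedures

**Directionality from Gibbs energies.** A reaction with standard
reaction Gibbs energy dG0 and standard deviation sd is made
forward-irreversible when dG0 < −1 kJ/mol and sd < 0.03·|dG0|,
backward-irreversible in the symmetric case, and left untouched
otherwise.  Records are independent per reaction, so the assignment is
order-independent.

**Energy-generating cycles.** For each energy carrier a dissipation
reaction is added (ATP + H2O → ADP + Pi + H⁺; NAD(P)H → NAD(P)⁺ + H⁺;
menaquinol → menaquinone + 2 H⁺; acetyl-CoA hydrolysis; a periplasmic →
cytosolic proton leak for the membrane gradient), all exchange bounds
are closed, forced fluxes are relaxed (positive lower bounds and
negative upper bounds set to zero — otherwise a nonzero NGAM would make
the probe infeasible rather than informative), and the dissipation flux
is maximized.  Any positive optimum is an EGC; the members of the
parsimonious dissipating solution are reported as the cycle.  The
default carrier list covers the eleven common energy metabolites
(ATP/CTP/GTP/UTP/ITP, NAD(P)H, FADH2, FMNH2, quinol, acetyl-CoA)
adapted to a menaquinone-based chain, plus the proton gradient;
carriers absent from a model are skipped with a warning.  Repair is
deliberately out of scope: cycle removal is a manual curation decision.

**Biomass normalization.** Precursor coefficients are rescaled by one
common factor so that Σ |c_i|·MW_i = 1000 g/mol (1 g/mmol biomass),
with molecular weights computed from metabolite formulas.  The GAM
currency metabolites (ATP, ADP, Pi, H2O, H⁺) are excluded from both the
weight sum and the rescaling so that normalization and maintenance
installation commute.  Normalized coefficients are rounded to 12
significant digits — far inside the 0.1 % weight tolerance — so model
serialization round-trips exactly.

**Maintenance.** GAM is stored as mmol ATP per gDW biomass (the h⁻¹ in
the conventional printed unit enters through the growth rate); it adds
an ATP + H2O → ADP + Pi (+H⁺) term to the biomass reaction.  The
installation is idempotent: the current GAM is tracked on the model and
reapplication replaces rather than accumulates.  NGAM sets the lower
bound of the ATP-hydrolysis maintenance reaction, created if missing.

**GAM fitting.** Y_O2(GAM) is monotone non-decreasing (more ATP demand
per biomass diverts electrons from assimilation to respiration); this
is verified numerically across the bracket before bisection on
[0, 100] to a GAM tolerance of 0.01.  Flat plateaus of Y_O2(GAM) are
possible when growth is redox- rather than ATP-limited (the mini-model
is in this regime below GAM ≈ 55); a small yield slack (1e-6) makes the
bisection return the smallest matching GAM there.

**Yields.** Y_O2 and Y_CO2 are |exchange flux| / substrate uptake in
mol/mol; Y_X = (µ · 1000 / w_Cmol) / q with w_Cmol the biomass C-mol
formula weight (24.6 g C-mol⁻¹ by the published convention — a
reporting constant, not a property of the mini-model's biomass).

## Condition scans and the reverse-electron-flow analysis

Conditions are declarative: uptake bounds (uptake q is applied as
lower bound −q, the standard sign convention), ratio constraints,
reversibility overrides, and a maintenance spec.  The substrate panel
normalizes all conditions to the same carbon uptake (3.5 C-mmol gDW⁻¹
h⁻¹ by default, so C3 substrates get 3.5/3 ≈ 1.17 mmol gDW⁻¹ h⁻¹).
The methanotrophic condition attaches the formaldehyde split (default
fraction 0.2 of total formaldehyde oxidation through the
cytochrome-coupled branch); the autotrophic condition sets the H2
bound directly in mmol (default 13.2), opens CO2 uptake, attaches the
periplasmic-hydrogenase split (default 0.76) and makes complex I
reversible — reverse electron flow is only hypothesized for
autotrophic growth, so complex I stays forward-only elsewhere.

The split denominators are the flux sums of the formaldehyde-oxidizing
reactions and of the two hydrogenases respectively; on the mini-model
these are {FALDHpp, THFOX} and {HYD4pp, NAD_H2}, and the benchmark
code discovers the analogous sets on an external model by listing the
consumers of formaldehyde / H2.

The complex-I switch fraction f* is the zero crossing of the
parsimonious complex-I flux as a function of f at fixed H2 uptake,
found by bisection to 1e-3 after a coarse-grid monotonicity check; "no
sign change" is an explicit `None` result.  The minimum H2 uptake is
the bisection (resolution 1e-3) boundary of {q : µ(q) > 1e-6 h⁻¹} at
fixed f, defaulting to f = 1 where every NADH must come from reverse
electron flow.  Growth-vs-uptake regressions use ordinary least squares
(statsmodels) on parsimonious O2-uptake and CO2-production rates over a
configurable CH4 grid (default 20 points on [1, 6] mmol gDW⁻¹ h⁻¹,
covering the physiological uptake range); slope, intercept, R² and
log-likelihood are reported.

## Flux sampling

The sampler is hit-and-run over {v : A v = 0, lb ≤ v ≤ ub} where A
stacks S and any ratio rows.  The equality system is eliminated by an
orthonormal null-space basis, so iterates satisfy steady state to
machine precision by construction and only the box bounds clip each
chord.  Warmup points are the flux-variability vertices (minimize and
maximize every coordinate) plus optional random-direction vertices;
this matters: warmup from random directions alone can miss thin
features such as the biomass direction entirely, leaving chains stuck
at µ = 0.  Steps alternate between artificially-centered directions
(a stored point minus the running center, which adapts to the
polytope's elongation) and isotropic null-space directions (which
guarantee irreducibility); accepted samples are fed back into the
direction pool, capped at 500 points.  Both direction families are
symmetric and independent of the current point, and each step samples
uniformly along the feasible chord, so the uniform distribution on the
polytope is stationary.  Defaults: warmup 10 × dimension discarded
steps, thinning 100; both are recorded in the sample-set header.
Growth is left free during sampling (no optimality constraint), with a
`min-growth-fraction` style restriction available by bounding the
biomass reaction before sampling.  Determinism is per-seed
(`numpy.random.default_rng`).

Validity checking recomputes max |A v| per row, counts bound
violations, and compares empirical per-reaction ranges against flux
variability intervals.

## Differential fluxes

For each reaction shared by two sample sets the comparison reports the
two-sample Kolmogorov–Smirnov statistic (computed exactly as the
supremum of the ECDF difference over all sample points) and the log2
fold change of medians, log2((|m_alt|+ε)/(|m_ref|+ε)) with ε = 1e-6 on
the flux scale.  Absolute medians keep the logarithm defined when a
flux reverses direction; reversals are surfaced in a separate
`sign_flip` field.  Reactions with both |medians| < ε are "quiescent"
and never called significant.  Significance is the fixed descriptive
screen KS ≥ 0.2 and |log2FC| ≥ 0.5; no p-values are computed and no
multiple-testing correction applies, because the cutoffs describe
effect sizes rather than test hypotheses.  Pathway aggregation sums
median differences of significant reactions per subsystem.

## Mass flow graphs and centrality

A flux vector is first mapped onto unidirectional nodes (reversible
reactions split into `_fwd`/`_rev`; irreversible reactions keep their
plain id so node identities are stable across samples).  For each
metabolite m, producer i and consumer j, the edge i→j accumulates
p_i(m) · c_j(m) / P(m): each producer's output of m is divided over
consumers in proportion to their consumption.  Summed over metabolites
this conserves flow — a producer's total outgoing weight through m
equals its production of m — which the suite checks against an
independent recomputation.  All metabolites participate by default,
including currency pools (protons, water, ATP); because that choice is
a genuine modeling decision, an exclusion list is exposed and the
damping factor (default 0.85, the classical value) is reported with the
scores.  Metabolites with production below 1e-9 are skipped, since
sampled vectors carry numerical noise.  PageRank is computed by power
iteration on the column-stochastic weighted transition matrix with
uniform redistribution of dangling-node mass, converged at L1 change
< 1e-10; the suite checks it against both a dense eigen-solve of the
Google matrix and networkx.

## The synthetic mini-methanotroph

The generator builds a ~50-reaction, 47-metabolite, 3-compartment model
whose purpose is to embody the *architecture* whose consequences the
pipeline measures, at a size where everything can be verified by hand
or by independent solvers:

* **ETC**: complex I (NADH + 5 H⁺_c + MQ → NAD⁺ + MQH2 + 4 H⁺_p,
  reversible only when configured), an ACIII surrogate translocating a
  configurable number of protons (default 2; its true stoichiometry is
  unresolved), a cytochrome oxidase translocating 2 protons, and an ATP
  synthase whose H⁺/ATP ratio is (8 + ACIII protons)/(P/O), i.e. 4 at
  the defaults, giving exactly P/O = 2.5 on the NADH→O2 chain.
* **C1 oxidation**: the methane monooxygenase draws electrons from
  menaquinol (so methane oxidation *consumes* reducing power), methanol
  and the direct formaldehyde branch reduce periplasmic cytochrome c,
  and the THF route yields NADH plus substrate-level ATP — exactly the
  competition that makes the formaldehyde split a growth trade-off.
* **Assimilation**: a lumped CBB reaction (3 CO2 + 9 ATP + 6 NADPH →
  triose phosphate) is the only carbon-fixation route; lumped
  glycolysis (reversible, for gluconeogenesis on C3 substrates), PDH
  and TCA close central carbon; a reversible transhydrogenase links
  NADH and NADPH.
* **C3 chain**: propane → isopropanol (monooxygenase, menaquinol- and
  O2-consuming) → acetone (NADH-producing) → acetol (NADH- and
  O2-consuming monooxygenase) → methylglyoxal → pyruvate, the last
  conversion lumping a three-step pathway into one NAD-coupled step.
* **Biomass**: five lumped precursor pools (protein as alanine
  equivalents, nucleotides as AMP, lipids as octanoate, carbohydrate as
  glucan units, a cofactor pool), each with an elementally balanced
  synthesis reaction; raw demands 6.0/0.5/1.0/0.5/0.2 mmol gDW⁻¹ are
  normalized to exactly 1 g/mmol at build time.  GAM and NGAM are
  installed through the same code paths users call.

Every internal reaction balances C, H, N, O, P and S exactly (checked
by the validator with real formulas; cytochromes are modeled as an
Fe-carrying redox pair).  The proton economy is explicit: the
periplasmic proton pool has no exchange and is the sole PMF carrier; an
irreversible proton leak dissipates surplus gradient (without it, the
scalar periplasmic protons released by the dehydrogenases would force
the ATP-synthase flux); cytosolic protons have a charge-neutral
exchange so that lumped reaction stoichiometries cannot create
artificial proton bottlenecks.  Neither relief valve can generate
energy, and the EGC screen confirms the model is cycle-free.

**What the mini-model shows and does not show.**  It reproduces the
qualitative phenomena: µ decreases monotonically in the formaldehyde
fraction α, in the periplasmic-hydrogenase fraction f and in NGAM
(becoming infeasible above a finite NGAM, ≈ 18 mmol gDW⁻¹ h⁻¹ at 3.5
CH4); growth is GAM-insensitive below ≈ 55 (redox-limited regime);
complex I switches direction at f* ≈ 0.63 at 13.2 mmol H2; autotrophic
growth at f = 1 needs ≥ 2.3 mmol H2; isopropanol outgrows acetone
(0.075 vs 0.062 h⁻¹) because its dehydrogenation donates one extra
NADH.  Its numeric values are *not* calibrated to any genome-scale
model: lumping collapses hundreds of reactions, so growth rates,
yields, switch points and thresholds differ from full-model values
(e.g. its methanotrophic µ of 0.039 h⁻¹ and switch at 0.63 versus a
full model's 0.76).  Passing the suite therefore establishes
correctness of the algorithms and the direction of the biology, not
genome-scale numbers; the `benchmark` module reruns the headline
computations on a locally supplied genome-scale SBML for that purpose.

Sampled flux distributions on the mini-model also inherit one honest
artifact of uniform polytope sampling: free exchange cycles (e.g.
proton import/export) span wide flux ranges and dominate the polytope
volume, which is equally true of full models and is why the literature
reports medians and ranks rather than means.

## Problem sizes and tolerances in the shipped checks

The test suite and acceptance script run entirely on the mini-model:
10,000-row sampler validity at thinning 5; mixing and uniformity checks
on small boxes and 400–800-row chains at thinning 15–40; MFG/PageRank
distributions over 60–200 sampled vectors; 7–21-point scan grids.
These sizes were chosen so the whole suite solves in well under a
minute while each statistical check retains ≥3-sigma headroom; the
library defaults (10,000 samples, thinning 100, full grids) remain the
recommended settings for real models.  LP agreement with the
independent COBRApy/GLPK oracle is asserted at 1e-6, PageRank against
the eigen-solve at 1e-8, KS against brute force exactly, and steady
state of sampled rows at 1e-6.

## Known limitations

* No thermodynamic (loopless) FBA; ratio constraints assume
  nonnegative denominator fluxes in the scenario.
* The hit-and-run sampler ships no formal convergence diagnostics
  (only the seed-disagreement and uniformity sanity checks) and no
  rounding/whitening transform; strongly elongated polytopes need
  longer thinning.
* log2 fold changes use the absolute-median convention; analyses that
  need signed fold changes should consume the medians directly.
* Gene rules are stored and round-tripped but only emptiness is
  interpreted (no gene-deletion analysis).
* The EGC detector reports cycles; it does not repair them.
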