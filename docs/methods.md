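# Methods

## Population model

The demographic core is a continuous-time two-sex logistic model. Each
female produces offspring at total rate 2[*R*ₘ − γ(*t*)*N*(*t*)] × (her
fitness); every individual dies at rate 1, so time is measured in
generations and *R*ₘ = λ/μ is the intrinsic growth rate. Density
dependence acts on recruitment (a lumped stand-in for larval competition;
no explicit age or larval structure). The pre-release equilibrium is
*N*₀ = (*R*ₘ − 1)/γ; the deterministic solvers work in units of *N*₀.

Every birth draws a father from the male pool weighted by count × male
fitness. Sons inherit the father's Y and the mother's X; daughters one X
from each parent. A driving Y distorts transmission (fraction *m* sons)
only when its carrier's own X is susceptible (Model I) and he carries no
suppressor allele (Model II); in every other case transmission is
Mendelian. These rules are encoded once, as a per-variant stochastic
birth tensor T[mother, father, child] (`ydrive.genotypes`), which the ODE
right-hand sides, the branching linearization, and the Gillespie kernel
all consume — the three engines cannot drift apart, and with all male
fitnesses equal the father weighting reduces to the familiar H/(H+M)
drive-male fraction.

Genotype systems: `baseline` (M, F), `drive` (H, M, F), `modelI` (four
male × three female X-genotype classes), `modelII` (six male × three
female suppressor-genotype classes). Mutation enters at birth: a daughter
of an unsuppressed driving-Y father carries a resistant paternal X with
probability *u* (mutant Xs arise singly — resistant homozygotes only ever
form by mating of carriers); any suppressor-free newborn becomes
heterozygous with probability 2*v* (one chance per autosome copy; the
*v*² double-mutant path is neglected). Fitness costs are pleiotropic:
heterozygotes *w*, homozygotes and hemizygous resistant males *w*²,
everything else (including the driving Y itself) 1.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| *R*ₘ | intrinsic growth rate per generation | 6 | must exceed 1 |
| *m* | driving-Y transmission proportion | 0.95 | in [½, 1]; *m*₍crit₎ = 1 − 1/(2*R*ₘ) |
| *u* | resistant-X probability per daughter of a driving-Y male | 0 | Model I |
| *v* | suppressor mutation probability per autosome per birth | 0 | Model II |
| *w* | carrier fitness (heterozygote) | 1 | homozygote/hemizygote *w*² |
| *h*₀ | release size as fraction of *N*₀ | 0.05 | driving-Y males at *t* = 0 |
| *a*, *T* | seasonal amplitude and period | 0, 18.25 | *T* = 18.25 generations = 1 year at 1/μ = 20 days |

The stochastic engines work at absolute *N*₀ with the supply products
*uN*₀ / *vN*₀ held fixed when scaling down (both probabilities are linear
in the supply at small values, so scaled runs probe the same regime).

## Seasonal forcing

γ(*t*) = γ₀[*a*](1 + *a* sin 2π*t*/*T*), with γ₀[*a*] calibrated by
root-finding so the time-averaged pre-release limit cycle equals *N*₀
(the pre-release female dynamics are integrated to the attractor; the
cycle mean scales as 1/γ₀, so the bracket always straddles the root). The
calibration is cross-checked in the tests against the closed-form
periodic solution of the equivalent Bernoulli equation, which also
confirms that *a* = 0.9825 yields a 100:1 peak-to-trough female cycle at
*R*ₘ = 6. A release at seasonal time *t*₍release₎ starts the wild-type
population on the attractor at that phase while releasing the same
absolute number *h*₀*N*₀ (fraction of the time-averaged population).

## Branching process

Rescue probabilities treat rare mutant lineages as a multi-type branching
process whose birth rates βₙₖ(*t*) ride on the *non-mutant* deterministic
background (so the background is computed with *u* = *v* = 0). Mutant
types are the heterozygous/hemizygous founders only — F_R, M_R, H_R
(Model I) and F_S, M_S, H_S (Model II); homozygotes are second-order in
lineage frequency and excluded from the linearization. Extinction
probabilities solve the backward system
d*q*ₙ/d*t* = (*q*ₙ − 1) + *q*ₙ Σₖ βₙₖ(*t*)(1 − *q*ₖ),
integrated from a terminal condition at the background's elimination time
plus a 20-generation buffer. The terminal condition is the minimal fixed
point *q*ₙ = 1/(1 + Σₖ βₙₖ(1 − *q*ₖ)) of the late-time autonomous
process, whose rates use the exact asymptotic limits of the eliminating
background (drive fixed among fathers, recruitment → *R*ₘ,
F/(H+M) → (1−*m*)/*m*) rather than interpolated trajectory tails, where
class ratios fall below solver precision. If that process is subcritical,
establishment is identically zero and the result is flagged; the
branching answer is then not meaningful and the Gillespie engine should
be used (the linearization is anyway only trusted where the two agree —
the test suite checks them against each other at *N*₀ = 10⁵).

P_Mut integrates the population-wide mutant-creation rate along the
background; P₁ weights the same integrand by the founder's establishment
probability; P_Con = P₁/P_Mut. Quadratures use Simpson's rule on 4001
points of the dense ODE output. `small_mutation_limit` returns the bare
exponents — the linear-in-supply approximations valid for *uN*₀ ≪ 1.

## Stochastic simulator

`ydrive.ssa` is an exact Gillespie chain over individual births and
deaths; propensities are recomputed (incrementally) after every event,
and the child class is drawn from the same birth tensor as the ODEs, so
mutation at birth is exact. Seasonal runs thin proposed births against
the bound *r* ≤ *R*ₘ. Random numbers come from an inline xorshift64*
generator seeded per run through a splitmix64 scramble of
(base seed + run index): fast, reproducible pure-integer arithmetic,
independent of any global RNG state.

A run ends `eliminated` when the count reaches zero, `censored` at the
horizon (default 200 generations) or on population explosion past
10 *N*₀, and `rescued` when, having carried at least one mutant allele,
either the mutant copy number exceeds 500 or the total count recovers
above 50% of *N*₀ after dropping below 45%; rescued runs continue until
the female count regains half its initial value so that the
suppression-duration clocks (time below 33% and 5% of the pre-release
female count) are complete. The tests verify that doubling the copy
threshold moves the rescue fraction by less than one standard error.

## Numerical choices

- ODE integration: LSODA, rtol 10⁻⁹, atol 10⁻¹² (×*N*₀); dense output.
  Elimination is a terminal event at *N* < 10⁻⁸ *N*₀.
- Birth integrals are evaluated on the eliminated trajectory; they are
  horizon-independent once elimination has occurred (asserted to 10⁻⁶ on
  horizon doubling).
- Thresholds *w*₁ and *w*₍ex₎: bisection to |Δ*w*| ≤ 10⁻⁴ on the long-run
  (2000-generation) outcome of the genotype ODEs **started from a state
  with the mutant allele established** (~30% frequency, drive present).
  This matters: from the release state the deterministic dip passes
  arbitrarily far below any floor before a mutant lineage rebounds, so a
  transient-based classification misplaces the boundary. Slow exponential
  decay near a threshold is detected by comparing half-horizon
  checkpoints (decline ratio < 0.75) in addition to absolute floors
  (*N* < 10⁻⁵ for elimination, allele frequency < 10⁻³ for loss/fixation).
  In the suppressor model the fixation boundary is 1 − *v* and is
  returned in closed form.
- Degenerate inputs: an empty father pool silences all births; *w* = 0
  zeroes every mutant rate and establishment probability; *m* = 1
  eliminates the Model I mutation channel entirely.

## What the engines do and do not show

The deterministic model treats the population as infinite, so any *u* > 0
guarantees resistance eventually appears; only the stochastic layers say
how *probable* rescue is. The branching process assumes mutant lineages
never interact (rare-lineage linearization) and that the background is
exactly deterministic; both fail for weak drive, low *R*ₘ or strong
costs, which is why the Gillespie engine exists. Simulated ensembles here
run at *N*₀ = 10⁴–10⁵ with 10³–10⁴ runs (the package's chosen problem
sizes) rather than the 10⁶/10⁶ of the largest published ensembles;
rescue probabilities transfer directly because they depend on the supply
*uN*₀, but suppression durations contain a ln *N*₀ term (a one-copy
lineage must grow through ~ln *N*₀ e-foldings before recovery), so at
*N*₀ = 10⁵ the expected below-33%/below-5% durations are ≈15.0/9.5
generations versus ≈17.5/12.2 at *N*₀ = 10⁶. The tests therefore compare
the simulated durations with a hybrid deterministic oracle (one resistant
female seeded on the eliminating background at the typical surviving
arrival time) evaluated at the *same* *N*₀, and separately check that the
oracle at *N*₀ = 10⁶ reproduces the published durations.

## Known limitations

- No spatial structure, age structure, standing variation, partial
  resistance or multi-allele dynamics; females are assumed to mate per
  birth rather than once for life.
- Negative recruitment (*R*ₘ − γ*N* < 0, possible transiently under
  strong seasonal forcing) is integrated as written in the deterministic
  model and clipped to zero in the stochastic simulator, where a negative
  propensity would be meaningless.
- The long-run classifier's seeded initial state probes the attractor
  reachable from an established mutation; systems with multiple interior
  attractors (not observed in this parameter space) would need a basin
  scan.
- One printed anchor is internally inconsistent with the governing
  equations (the population at 30 generations post-release; the decay
  rate 1 − 2(1−*m*)*R*ₘ fixes it an order of magnitude lower than
  quoted); the corresponding check is left failing by design and
  documented in the test.
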