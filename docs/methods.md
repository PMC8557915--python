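# Methods

## The measurement model

`flyfitness` analyses gnotobiotic *Drosophila melanogaster* vial assays in
which cohorts of 30–60 female flies, each reared from the egg with a single
defined bacterial treatment (or left axenic), are followed for four weeks.
Twice a week the adults are transferred onto fresh diet for an 18-hour
egg-laying window; the pupae that later form in the spent vial are counted
and normalised to the number of live females at the start of the window,
and deaths and transfer losses are tallied per interval. Three
time-staggered experiments, each with triplicate vials per treatment, share
the same calendar transfer days, so flies in different experiments are up
to two days apart in age at any transfer. Weekly CFU plating of F1
offspring monitors contamination; a vial showing an unexpected colony
morphology at ≥200 CFU per fly in two consecutive weeks is removed from
all downstream analyses.

## Fitness as the dominant eigenvalue of a Leslie matrix

Each vial yields a vital schedule over k age classes: per-class fecundities
f (offspring per female per class) on the first row of a k×k Leslie matrix
and between-class survival fractions s on the subdiagonal. Three boundary
conventions complete the schedule:

1. a pre-adult class with f = 0 and s = 1 (complete egg-to-adult survival
   is assumed, so the female count at the first transfer stands in for the
   number of female eggs);
2. one class per measured interval, with f obtained by linear rate
   extrapolation of the 18-h count to the full 3- or 4-day window,
   `f = (pupae/females) · (24·days/18)`, and s computed with
   non-informative censoring, `s = (start − deaths − lost)/(start − lost)`;
3. a terminal class with f = 0, so the model does not extrapolate
   never-ending low-level reproduction.

The vial's fitness is λ, the dominant eigenvalue — real and equal to the
spectral radius by Perron–Frobenius for a nonnegative Leslie matrix. λ is
the asymptotic multiplicative growth rate per (3–4 day) age class.

Numerical choices: `numpy.linalg.eigvals` computes the spectrum; among
eigenvalues tied in modulus with the spectral radius (which occurs for
imprimitive schedules with reproduction concentrated in one late class)
the one with the smallest imaginary part is taken, and an imaginary
residual above 1e-9 raises rather than silently truncating. An independent
oracle solves the Euler–Lotka equation Σₓ lₓ fₓ λ⁻ˣ = 1 (l₁ = 1,
lₓ = Π s) by bracketed Brent root-finding; the two routes agree to better
than 1e-8 relative tolerance on random schedules, and the k = 2 case has
the closed form λ = (f₁ + √(f₁² + 4 s₁ f₂))/2, reproduced to 1e-12.

Design points that were genuinely open:

- *Subdiagonal placement.* The survivals are placed on the subdiagonal,
  the standard Leslie form; a true-diagonal placement would model
  self-persisting classes and is not an age-structured projection.
- *Extinct cohorts.* After the last surviving female, remaining classes
  keep f = 0 and s = 0 instead of being dropped, so matrix dimension is
  uniform within an experiment. By terminal-class neutrality this does not
  move λ (asserted numerically to 1e-12).
- *Extrapolation and censoring are modes, not constants.* `extrapolation=
  "raw"` uses the bare 18-h count as the class value; `censoring="death"`
  counts transfer losses as deaths. Defaults are "rate" and "remove".

## Perturbation analysis

To ask whether survival or reproduction drives the fitness differences,
the engine multiplies a single entry of a vial's schedule — one age
class's fecundity, or one survival transition — by a factor from the grid
{1/2, 1/10, 1/20, 1/100, 1/200, 1/10³, 1/10⁴, 1/10⁵} and recomputes λ.
Scaling is per vial; the default target is the first adult class (class 2
of the schedule; for the survival trait, index i scales the transition
*out of* class i, and the assumed pre-adult transition is also
selectable). Observed and permuted λ are compared by Spearman rank
correlation across vials, and treatments are compared on the permuted λ
by Kruskal–Wallis with a Benjamini–Hochberg-corrected Dunn post hoc when
significant. Pathogen-like treatments are excluded by default.

Three properties follow from the matrix structure and are enforced by
tests: factor 1 is a bit-exact identity; λ is monotone non-increasing in
the reduction for every vial, class and trait; and a survival reduction
at an early class depresses λ more than an equal fecundity reduction,
because the survival cut propagates to every later class's cumulative
survival while the fecundity cut removes only one class's own term.

A consequence worth spelling out: under a severe early-survival cut
(factor 1e-5) λ falls below 1 for every treatment, and in that regime the
Euler–Lotka terms λ⁻ˣ weight *late* reproduction most heavily — so
treatments conferring late fecundity and long life overtake treatments
conferring early fecundity, reversing the observed fitness ranking. The
synthetic defaults reproduce this rank reversal.

## Treatment statistics

Kruskal–Wallis (tie-corrected, chi-square reference) is delegated to
scipy; Dunn's test is implemented directly (no suitable pre-installed
implementation): pairwise z statistics on mean ranks with the pooled
tie-corrected variance, two-sided normal p values, B-H adjusted within
each family of pairwise comparisons. Lifespan records — one row per
female, event = 1 for an observed death at its interval end, event = 0
for a transfer loss or for survival to the experiment's end — are
compared by the two-sample log-rank test (lifelines), applied pairwise
with B-H adjustment. Wilcoxon rank-sum is available for two-group
contrasts. Compact letter displays use the insert–absorb algorithm with
lexicographic letter assignment; the defining invariant — two groups
share a letter iff their adjusted p ≥ α — is verified exhaustively over
every significance pattern for up to five groups. α defaults to 0.05 and
is configurable.

## Metagenome-wide association

Ortholog groups (OGs) with identical strain presence/absence patterns are
statistically indistinguishable, so they are collapsed into phylogenetic
distribution groups (PDGs) — one per distinct pattern, ordered
lexicographically; all-present and all-absent patterns are kept but
flagged untestable. Each testable PDG is tested against per-vial λ with a
linear mixed model, λ ~ β₀ + β₁·presence + u(experiment) + ε, fit by
REML with a two-sided Wald test on β₁ and Bonferroni correction over the
number of testable PDGs. The random intercept absorbs the shared
between-experiment shifts that the time-stagger induces. A Shapiro–Wilk
check of the λ response is logged as a diagnostic, never used as a gate.
The pathogen-like strain is excluded by default (configurable), which in
the synthetic panels leaves the response approximately normal.

The REML fit is implemented in-module as a profiled likelihood over the
variance ratio var(u)/var(ε) with Sherman–Morrison block inversion —
exact for the single-random-intercept design and fast enough to scan
hundreds of PDGs across hundreds of simulation replicates. Tests
cross-check β and p against `statsmodels` MixedLM and against the OLS
limit when the intercept variance vanishes. The reported
mean-fitness-with / mean-fitness-without columns pool per-vial λ across
member strains (matching the per-vial response of the model); a
strain-mean alternative is a documented variant. No correction for
phylogenetic relatedness among strains is applied — presence patterns are
treated as exchangeable — which is a known limitation: confounding with
strain phylogeny can inflate apparent associations in real panels.

## The synthetic-data generator

The generator emulates the assay so that every stage is testable without
any external data. Treatments are archetypes on the fast–slow
life-history continuum:

- per-female daily fecundity follows a gamma-shaped kernel of adult age
  with a 2-day post-eclosion maturity onset (newly eclosed females lay
  essentially nothing in their first age class), mode at `peak` days and
  maximum `amplitude` offspring/female/day;
- mortality is a piecewise-constant daily hazard; deaths per interval are
  binomial in the survival complement, transfer losses binomial at 1% per
  transfer;
- 18-h pupae counts are negative-binomial (dispersion 20, count CV ≈ 24%
  at typical means — overdispersed relative to Poisson, as egg counts
  are) around `females · rate · 18/24`.

Defaults: 15 treatments — five acetic-acid-bacteria-like (fecundity peak
4.5–6.5 days post-eclosion, i.e. ~12.5–14.5 days from egg collection,
elevated late hazard), six lactic-acid-bacteria-like (peak 10–13 days
post-eclosion, ~18–21 days from egg, low flat hazard), two neutral
controls, one axenic, one pathogen-like (low fecundity, high hazard) —
× 3 experiments × 3 vials, eight intervals of alternating 3 and 4 days
starting at fly age 10/9/8 days for experiments 1/2/3. These values place
the expected per-treatment λ ("truth", computed analytically by pushing
the expected schedule through the Euler–Lotka solver) at 1.65–1.95, give
the fast archetypes the higher observed fitness, and make the ranking
reverse under the 1e-5 early-survival cut. Dispersion 20 was chosen so
that treatment-level differences in λ are detectable by Kruskal–Wallis at
the study's sample sizes, as they are in the real assay.

What the generator does *not* model: male flies, egg-to-adult mortality
(the pre-adult class is deterministic by assumption), mechanistic
microbe–host interaction, diet, between-vial density effects, or
phylogenetic correlation among the simulated gene-presence patterns
(background OG patterns are i.i.d. Bernoulli(0.5)). Passing tests
therefore demonstrate correctness of the analysis chain under the stated
noise model, not robustness to these real-data complications.

## Problem sizes used in checks

The verification suite and `scripts/acceptance.py` use: 200 random
schedules (k ≤ 12) for the eigenvalue/Euler–Lotka agreement; the full
default study (135 vials before filtering) for boundary neutrality,
perturbation monotonicity (every class × trait × the 8-factor grid) and
the rank reversal; 2000 null simulations (15 groups × 9) for
Kruskal–Wallis type-I calibration; and for the association scan 100
planted-effect panels (δ = 0.3 added to λ for strains carrying a planted
PDG among 100 background OGs over 13 strains, 9 vials each) plus 200 null
panels (50 background OGs) pooling ~10,000 PDG tests for the
false-positive rate.
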