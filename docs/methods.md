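# Methods

## Model

A conjunctive clause over a subjects × features table is an AND of
feature–interval conditions; a subject matches when every condition
holds, with intervals closed on both ends (printed ranges like
"3500 to 4600" read inclusive).  The clause's *order* is its number of
conjuncts.  Candidate interval bounds are restricted to values actually
observed in the training table.  This makes the space of clauses finite,
makes reported bounds reproducible data points rather than arbitrary
reals, and loses nothing: between two consecutive observed values every
cut induces the same match set.

### Fitness

A clause matching n of N subjects, k of them among the K target-class
subjects, is scored by the hypergeometric PMF
P(k; N, K, n) = C(K,k)·C(N−K,n−k)/C(N,n) — the probability of that much
class enrichment under random sampling.  The PMF is an enrichment score,
not a p-value; no significance threshold is attached to it.  We report

    fitness = −log10 P(k; N, K, n)   if k/n > K/N (match set enriched),
    fitness = 0                       otherwise,

and maximize.  Two choices here deserve comment.  First, the direction:
"highest fitness" must mean "least probable by chance", so the PMF is
log-inverted; this also keeps the quantity finite and well-scaled for
very small probabilities.  Second, the one-sidedness: the raw PMF is
equally small for match sets *depleted* of the target class, and an
unrestricted search on null data happily converges to such anti-clauses
(PPV 0).  Since the method's outputs are read as descriptions of the
target class, only positive association counts; a non-enriched clause
scores 0.  A clause matching nobody also scores 0 (PMF 1 by convention)
and its PPV is flagged undefined.

Each clause additionally reports PPV = k/n and class coverage = k/K.
At the reference cohort shape (N = 21, K = 7), enumerating all (n, k)
confirms the minimum PMF is 1/C(21,7) = 1/116280, attained only at
n = k = 7 — a clause matching exactly the cases is maximally fit, with
fitness log10 116280 ≈ 5.0655.

### Sensitivity pruning

The sensitivity of feature i in a clause is fitness(clause) −
fitness(clause without conjunct i); for an order-1 clause the dropped
clause matches everyone (fitness 0), so sensitivity equals the clause's
own fitness.  A clause is archived only if every sensitivity is strictly
positive (threshold 0, configurable).  This removes free-rider conjuncts
— e.g. an interval spanning a feature's whole observed range changes
nothing and has sensitivity exactly 0 — and is the method's main
overfitting guard.

## Search

A generational evolutionary algorithm over genomes
{feature → (lower-index, upper-index)} into each feature's sorted unique
values.  Defaults (all exposed in `CCEAConfig`):

| parameter | default | note |
|---|---|---|
| population | 200 | |
| generations | 500 | per run |
| independent runs | 5 | seeds seed+r; archives merged with dedup |
| crossover | p = 0.5 | uniform conjunct exchange |
| add / drop conjunct | p = 0.2 / 0.2 | order kept in [1, max order] |
| move bound | p = 0.4 | one bound to an adjacent observed value |
| replace feature | p = 0.2 | new feature, fresh interval |
| tournament size | 3 | plus 1-elite carryover |
| max order | 5 | |
| archive size | 50 per order | elitist, unique canonical forms |

Random intervals (initialization, add-conjunct, replace-feature) draw
their endpoints from the feature's *target-class* values half the time
and from all observed values otherwise.  Fitness rewards covering the
cases, so proposals biased toward case-spanning rectangles explore the
productive part of the space; with uniform proposals the search
measurably stalls below the fitness ceiling on wide tables.

Ties in the archive sort are broken by lower order first (parsimony),
then lexicographic canonical form; clause identity is the canonical
(name-sorted) conjunct tuple.  Everything is deterministic given
(table, config).

`exhaustive_search` enumerates every order-1 and order-2 clause (all
interval pairs per feature, all feature pairs) under guards (≤ 12
features, order ≤ 2) and applies the same enrichment and sensitivity
criteria, so it is a provable optimality oracle over exactly the same
clause space the EA searches.  The test suite asserts the EA attains the
exhaustive optimum on small random tables and on planted-rule cohorts.

### Degeneracy at small N

At N = 21, K = 7 the fitness ceiling 1/C(21,7) is reached by *any*
rectangle matching exactly the 7 cases.  On a cohort with 50 noise
features, several pure-noise feature pairs typically attain it alongside
a planted rule (we measure 2–11 per dataset), so "the best second-order
clause" is a tie and feature *identity* is not recoverable from fitness
alone at that width.  The tests therefore assert identity only where the
exhaustive oracle certifies the optimum's feature set is unique (narrow
tables), and assert ceiling attainment (PPV = coverage = 100% of the top
clause) at full width.  This degeneracy is intrinsic to the study scale
and is precisely why selected feature sets need independent validation
(below).

## KNN validation

Selected feature unions are validated with a k-nearest-neighbors
classifier: leave-one-out cross-validation (one fold per subject) over
the whole cohort, and a train/test split with a balanced training set.
Distances are Euclidean (Manhattan available) on z-score-standardized
features, the standardization fit on training rows only and refit inside
every LOOCV fold; scaling defaults to on because the feature families
span five orders of magnitude (volumes ~10⁴ mm³ vs curvature ~10⁻¹) and
unscaled distances would be volume-dominated.  `scaling: none` is
available for sensitivity analysis.

Deterministic tie rules (even k forces them): an exact distance tie for
the last neighbor slot goes to the earlier training row; a tied
plurality vote goes to the class of the single nearest neighbor among
the tied classes.  k may be as large as the training-fold size.
Results are 2×2 confusion matrices (target class positive) with
accuracy, PPV and recall.

Note one fidelity choice in the pipeline: LOOCV runs on discovery +
later-enrolled subjects combined even though features were selected on
the discovery subjects only, mirroring the validation design this
pipeline reproduces.  The optimism this induces (the features have seen
most of the validation subjects) is documented rather than corrected.

## Synthetic cohorts

The generator emulates the statistical shape of the target application:
small unbalanced classes (default 7 cases / 14 controls), hundreds of
Gaussian features on heterogeneous scales chosen per measure type
(volume locations 3500–23000 mm³ with ~12% CV, areas 1400–8500 mm²,
thickness N(2.2–2.8, 0.15) mm, mean curvature N(0.12–0.2, 0.02),
behavioral scores roughly N(5–18, 2–4)), FreeSurfer-style column names,
and planted conjunctive rules of order 1–5.

Planted-rule guarantees are exact, not in expectation: every target
subject satisfies every rule (truncated-normal draws inside each
interval); at most ⌊leakage · n_other⌋ non-target subjects satisfy a
rule, and each remaining non-target subject is forced to violate at
least one conjunct (truncated-normal draw outside the interval, side
chosen by tail mass).  Rules must use disjoint feature sets; overlapping
rules would make these guarantees mutually unsatisfiable.  Noise
features are i.i.d. across classes.  Identical seeds give bit-identical
tables.

`plant_interaction_no_main_effect` builds the adversarial case for
univariate screening: the target class occupies one corner rectangle
I₁×I₂ of a feature pair, non-target subjects split between the two
adjacent corners, and the out-of-interval group of each feature is
translated (always further away from the interval) so that the
non-target class mean equals the target class mean *exactly*.  Each
marginal projection of the rule then has coverage 1 but PPV equal to
the corner mixture (≈ 0.5 at 7/14), while the joint rule has PPV 1 —
the regime where only conjunctive search succeeds.

What the generator does **not** emulate: inter-regional anatomical
correlation, site or scanner effects, measurement error structure, or
non-Gaussian tails.  Passing tests demonstrate algorithmic correctness
under the intended statistical shape, not clinical validity on real
cohorts.

## Numerical choices

- Hypergeometric PMF: exact integer binomials (correctly rounded via
  rational-to-float conversion) for N ≤ 2000; log-gamma evaluation
  above.  Accurate to ≥ 12 significant digits across the support.
- Fitness lookups inside the EA come from a precomputed (n, k) table
  per (N, K), zeroed where not enriched.
- Fitness ties in the oracle use a 1e-9 tolerance.
- Constant features in KNN scaling fall back to scale 1 with a warning.
- CSV I/O: comma-separated, UTF-8, dot decimals, header required; values
  written at 10 significant digits; missing/non-numeric cells are load
  errors (no imputation — with ~30 subjects silent imputation would
  corrupt clause intervals).
- Outcome labels are arbitrary strings with an explicit target class;
  derived tables (folds, class-pure splits) may hold one level, loaded
  cohorts must have exactly two.

## Problem sizes in the test suite

Oracle-equivalence and recovery tests run the EA at reduced effort
(population 100–200, 120–300 generations, 2–5 runs) on tables of 10–52
features, sizes chosen once so the whole suite completes in a few
minutes; the acceptance check of the headline quantity uses the full
default configuration.  Correctness at reduced effort is always anchored
to the exhaustive oracle rather than to the EA settings.

## Known limitations

- Two-class outcomes only; no multi-class or set-covering extension.
- Archive counts (how many clauses of each order survive) depend on EA
  effort and are not meaningful summaries; only the top clauses are.
- The hypergeometric score is shared by all clauses with the same
  (n, k), so feature identity is unidentifiable among tied perfect
  separators at small N (see Degeneracy above).
- `conditional_reproduction` of published cross-validation accuracies
  requires the original subject-level table, which is not shipped; with
  no file it reports not-evaluable by design.
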