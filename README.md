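# clauseminer

Conjunctive-clause feature selection for small two-class cohorts, with
KNN validation.

## The problem

Case/control studies in neurodevelopmental research routinely face tables
with a couple of dozen subjects and hundreds of measurements — e.g. 28
children (9 with an autism spectrum diagnosis, 19 neurotypical) described
by 276 FreeSurfer regional measures (cortical volume, surface area,
thickness, mean curvature) plus 13 behavioral assessment scores (theory-of-
mind batteries, language and nonverbal-IQ tests).  The discriminative
signal, if any, may live in *interactions*: no single feature separates
the groups, but a conjunction of feature ranges does.  Univariate
screening cannot find such structure, and most classifiers will not tell
you which features carry it.

`clauseminer` searches directly for interpretable **conjunctive clauses**

    CC = (F_i ∈ [a_i, b_i]) ∧ (F_j ∈ [a_j, b_j]) ∧ …

— "subjects whose posterior cingulate volume is 3500–4600 mm³ *and* whose
rostral middle frontal volume is 20000–25000 mm³" — scored by how unlikely
the clause's match set is under random sampling.  For a clause matching
*n* of *N* subjects, *k* of them among the *K* cases, the score is the
hypergeometric probability mass function

    P(k; N, K, n) = C(K,k) · C(N−K, n−k) / C(N,n)

and the fitness maximized by the search is `−log10 P` when the match set
is enriched for cases (PPV > K/N), else 0.  A clause matching exactly the
cases at N=21, K=7 attains the ceiling `log10 C(21,7) = log10 116280 ≈
5.0655`.  Alongside fitness each clause reports PPV (= k/n) and class
coverage (= k/K).  Candidate interval bounds snap to observed values, so
the search space is finite and results are exactly reproducible.

The search is a Michigan-style evolutionary algorithm with an elitist
archive of the best unique clauses *per order* (order = number of
conjuncts; lower order = more parsimonious).  To prevent overfitting, a
clause enters the archive only if every feature has strictly positive
**sensitivity** — the fitness lost when that conjunct is dropped — so
free-rider conjuncts are discarded.  Selected feature sets are then
validated with a k-nearest-neighbors classifier under leave-one-out
cross-validation and a train/test split, with z-score standardization fit
on training rows only (the features span five orders of magnitude).

A synthetic-cohort generator with *planted* conjunctive rules (optionally
with exactly zero marginal signal per feature) provides ground truth for
testing every stage, and an exhaustive enumerator provides provable
optimality checks at small scale.

## Worked example

```python
from clauseminer import CCEAConfig, ConjunctiveClauseModel
from clauseminer.clauses import Interval
from clauseminer.feature_table import FeatureSpec
from clauseminer.synthetic import (
    ColumnModel, PlantedRule, SyntheticSpec, asd_like_columns, generate_cohort,
)

# 7 cases / 14 controls; one planted two-feature rule among 50 noise features
rule = PlantedRule({"planted_vol_a": Interval(3500, 4600),
                    "planted_vol_b": Interval(20000, 25000)}, "ASD")
columns = tuple(
    [ColumnModel(FeatureSpec("planted_vol_a", "neuroanatomical", "volume", "mm3"), 4000, 400),
     ColumnModel(FeatureSpec("planted_vol_b", "neuroanatomical", "volume", "mm3"), 22000, 2000)]
    + asd_like_columns(50)
)
table, _ = generate_cohort(SyntheticSpec(planted=(rule,), columns=columns, seed=42))

res = ConjunctiveClauseModel(table, config=CCEAConfig(seed=1)).fit()
best = res.best(order=2)
print(best.clause)
print(f"fitness={best.metrics.fitness:.4f} "
      f"ppv={best.metrics.ppv:.2f} coverage={best.metrics.class_coverage:.2f}")
```

prints

```
planted_vol_a in [3582.33,4546.02] AND planted_vol_b in [20003.3,23403.8]
fitness=5.0655 ppv=1.00 coverage=1.00
```

The search recovered the planted pair: its interval bounds snap to the
observed case values inside the planted ranges, its fitness is the
N=21/K=7 ceiling `log10 116280`, and the clause matches all 7 cases
(coverage 1.00) and nothing else (PPV 1.00).

A full pipeline (discovery-cohort split → clause search → parsimonious
selection → feature unions → LOOCV and train/test KNN) runs from a single
YAML config:

```bash
clauseminer run --config config.yaml     # writes report.json, clauses_table.txt, knn_results.csv
clauseminer synth --spec spec.yaml --out cohort.csv
clauseminer knn --table cohort.csv --features planted_vol_a,planted_vol_b --k 3
```

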