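"""Conjunctive clauses over feature intervals, and their evaluation.

A conjunctive clause is a logical AND of feature-interval conditions,

    F_i in [a_i, b_i]  AND  F_j in [a_j, b_j]  AND ...

A subject *matches* the clause when every conjunct's closed interval
contains the subject's value for that feature.  The clause's *order* is
its number of conjuncts; lower order is more parsimonious.  Clauses are
scored against a two-class table with the hypergeometric-PMF fitness
(see :mod:`clauseminer.hypergeom`) together with the clinical screening
quantities PPV (precision of the matched set for the target class) and
class coverage (recall of the target class).

Per-feature *sensitivity* — the fitness lost when one conjunct is
dropped — guards against free-rider conjuncts that do not shrink the
match set; archives only retain clauses where every feature's
sensitivity is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .feature_table import FeatureLookupError, FeatureTable
from .hypergeom import fitness_from_counts, hypergeom_pmf

__all__ = [
    "Interval",
    "ConjunctiveClause",
    "ClauseMetrics",
    "clause_matches",
    "match_mask",
    "evaluate_clause",
    "feature_sensitivity",
    "passes_sensitivity",
]


@dataclass(frozen=True)
class Interval:
    """Closed numeric interval [lower, upper]; both bounds finite."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("interval bounds must be finite")
        if self.lower > self.upper:
            raise ValueError(f"interval lower {self.lower} exceeds upper {self.upper}")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def __str__(self) -> str:
        return f"[{self.lower:g},{self.upper:g}]"


@dataclass(frozen=True)
class ConjunctiveClause:
    """AND of feature-interval conditions, keyed by feature name.

    ``conjuncts`` maps each feature name to its closed interval; map keys
    enforce feature distinctness.  Equality and deduplication use the
    canonical form (conjuncts sorted by feature name).
    """

    conjuncts: tuple[tuple[str, Interval], ...]

    def __init__(self, conjuncts: Mapping[str, Interval] | Iterable[tuple[str, Interval]]):
        items = dict(conjuncts)
        if len(items) == 0:
            raise ValueError("a conjunctive clause needs at least one conjunct")
        object.__setattr__(
            self, "conjuncts", tuple(sorted(items.items(), key=lambda kv: kv[0]))
        )

    @property
    def order(self) -> int:
        return len(self.conjuncts)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.conjuncts)

    def interval(self, feature: str) -> Interval:
        for name, iv in self.conjuncts:
            if name == feature:
                return iv
        raise KeyError(feature)

    def drop(self, feature: str) -> "ConjunctiveClause | None":
        """The clause without ``feature``'s conjunct; None if that empties it."""
        rest = [(n, iv) for n, iv in self.conjuncts if n != feature]
        if len(rest) == len(self.conjuncts):
            raise KeyError(feature)
        return ConjunctiveClause(rest) if rest else None

    def canonical_key(self) -> tuple:
        return tuple((n, iv.lower, iv.upper) for n, iv in self.conjuncts)

    def __str__(self) -> str:
        return " AND ".join(f"{n} in {iv}" for n, iv in self.conjuncts)


@dataclass
class ClauseMetrics:
    """Evaluation of one clause against one table.

    ``ppv`` is NaN (flagged by ``ppv_defined``) when the clause matches
    nobody.  ``sensitivity`` is populated by :func:`feature_sensitivity`.
    """

    n_total: int
    n_class: int
    n_match: int
    k_match: int
    pmf: float
    fitness: float
    ppv: float
    class_coverage: float
    ppv_defined: bool = True
    sensitivity: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_class": self.n_class,
            "n_match": self.n_match,
            "k_match": self.k_match,
            "pmf": self.pmf,
            "fitness": self.fitness,
            "ppv": None if not self.ppv_defined else self.ppv,
            "class_coverage": self.class_coverage,
            "sensitivity": dict(self.sensitivity),
        }


def clause_matches(clause: ConjunctiveClause, row: Mapping[str, float]) -> bool:
    """True iff every conjunct's closed interval contains the row's value."""
    for name, iv in clause.conjuncts:
        if name not in row:
            raise FeatureLookupError(f"feature {name!r} absent from row")
        if not iv.contains(row[name]):
            return False
    return True


def match_mask(clause: ConjunctiveClause, table: FeatureTable) -> np.ndarray:
    """Boolean per-subject match vector (vectorized row scan)."""
    mask = np.ones(table.n_subjects, dtype=bool)
    for name, iv in clause.conjuncts:
        col = table.column(name)
        mask &= (col >= iv.lower) & (col <= iv.upper)
    return mask


def _metrics_from_mask(mask: np.ndarray, target: np.ndarray) -> ClauseMetrics:
    N = int(mask.size)
    K = int(target.sum())
    n = int(mask.sum())
    k = int((mask & target).sum())
    if n == 0:
        return ClauseMetrics(
            n_total=N, n_class=K, n_match=0, k_match=0,
            pmf=1.0, fitness=0.0, ppv=float("nan"),
            class_coverage=0.0, ppv_defined=False,
        )
    pmf = hypergeom_pmf(k, N, K, n)
    # fitness rewards positive association only: a match set not enriched
    # for the target class (PPV <= class prior) scores 0, since the PMF is
    # equally small for depletion and the search must not chase anti-clauses
    enriched = k * N > n * K
    return ClauseMetrics(
        n_total=N, n_class=K, n_match=n, k_match=k,
        pmf=pmf, fitness=fitness_from_counts(k, N, K, n) if enriched else 0.0,
        ppv=k / n, class_coverage=k / K,
    )


def evaluate_clause(
    clause: ConjunctiveClause, table: FeatureTable, target_class: str | None = None
) -> ClauseMetrics:
    """Score a clause on a table: match counts, PMF, fitness, PPV, coverage.

    ``target_class`` defaults to the table's own designation.  Sensitivity
    is left unpopulated; see :func:`feature_sensitivity`.
    """
    target = _target_mask(table, target_class)
    return _metrics_from_mask(match_mask(clause, table), target)


def _target_mask(table: FeatureTable, target_class: str | None) -> np.ndarray:
    if target_class is None or target_class == table.target_class:
        return table.target_mask
    levels = set(table.outcome)
    if target_class not in levels:
        raise ValueError(f"target class {target_class!r} not an outcome level of the table")
    return np.array([o == target_class for o in table.outcome], dtype=bool)


def feature_sensitivity(
    clause: ConjunctiveClause, table: FeatureTable, target_class: str | None = None
) -> dict[str, float]:
    """Fitness contribution of each conjunct.

    sensitivity(i) = fitness(clause) - fitness(clause minus conjunct i).
    Dropping the only conjunct of an order-1 clause leaves the
    match-everything clause (fitness 0), so an order-1 clause's
    sensitivity equals its own fitness.
    """
    target = _target_mask(table, target_class)
    full = _metrics_from_mask(match_mask(clause, table), target)
    out: dict[str, float] = {}
    for name, _ in clause.conjuncts:
        sub = clause.drop(name)
        sub_fitness = (
            0.0 if sub is None else _metrics_from_mask(match_mask(sub, table), target).fitness
        )
        out[name] = full.fitness - sub_fitness
    return out


def passes_sensitivity(metrics: ClauseMetrics, threshold: float = 0.0) -> bool:
    """True iff every feature's sensitivity strictly exceeds ``threshold``."""
    if not metrics.sensitivity:
        raise ValueError("sensitivity has not been populated on these metrics")
    return all(s > threshold for s in metrics.sensitivity.values())
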