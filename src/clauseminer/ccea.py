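"""Conjunctive clause evolutionary algorithm (CCEA).

An evolutionary search over conjunctions of feature-interval conditions
that discriminate a target class in a small two-class cohort.  The
search space is made finite by snapping candidate interval bounds to the
observed values of each feature in the training table; the printed,
rounded ranges such a search reports are then exactly reproducible.

Fitness is the hypergeometric-PMF enrichment score of a clause's match
set (``-log10 PMF``, maximized).  The algorithm keeps an elitist archive
of the best unique clauses *per order* (order = number of conjuncts),
and admits a clause only if every one of its features has strictly
positive sensitivity — i.e. each conjunct contributes fitness — which
suppresses free-rider conjuncts and overfitting.  Several independent
runs are merged (union + dedup) for a more thorough exploration of the
fitness landscape.

Because candidate bounds snap to observed values, small problems can be
solved exactly: :func:`exhaustive_search` enumerates every clause up to
order 2 and serves as a provable optimality oracle for the evolutionary
search in the test suite.

The statsmodels-style entry point is :class:`ConjunctiveClauseModel`
(``fit()`` -> :class:`CCEAResults`); the module-level functions are the
underlying primitives.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clauses import (
    ClauseMetrics,
    ConjunctiveClause,
    Interval,
    evaluate_clause,
    feature_sensitivity,
)
from .feature_table import FeatureTable
from .hypergeom import fitness_table

__all__ = [
    "CCEAConfig",
    "ArchiveEntry",
    "ClauseArchive",
    "run_ccea",
    "exhaustive_search",
    "select_parsimonious",
    "ConjunctiveClauseModel",
    "CCEAResults",
]


@dataclass(frozen=True)
class CCEAConfig:
    """Hyperparameters of the evolutionary search.

    Defaults: generational EA, population 200, 500 generations, five
    independent runs, tournament selection of size 3, elitist per-order
    archive of 50, operator rates as below.  Correctness of results is
    anchored to the exhaustive oracle, not to these defaults.
    """

    population_size: int = 200
    generations: int = 500
    p_add_conjunct: float = 0.2
    p_drop_conjunct: float = 0.2
    p_move_bound: float = 0.4
    p_replace_feature: float = 0.2
    crossover_rate: float = 0.5
    max_order: int = 5
    runs: int = 5
    archive_size: int = 50
    sensitivity_threshold: float = 0.0
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_add_conjunct", "p_drop_conjunct", "p_move_bound",
                     "p_replace_feature", "crossover_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for name in ("generations", "max_order", "runs", "archive_size", "tournament_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ArchiveEntry:
    clause: ConjunctiveClause
    metrics: ClauseMetrics
    run: int
    generation: int

    def sort_key(self) -> tuple:
        return (-self.metrics.fitness, self.clause.order, self.clause.canonical_key())


class ClauseArchive:
    """Elitist per-order store of the best unique sensitivity-passing clauses."""

    def __init__(self, archive_size: int = 50):
        self.archive_size = archive_size
        self._by_order: dict[int, list[ArchiveEntry]] = {}
        self._keys: set[tuple] = set()

    def insert(self, entry: ArchiveEntry) -> bool:
        key = entry.clause.canonical_key()
        if key in self._keys:
            return False
        order = entry.clause.order
        bucket = self._by_order.setdefault(order, [])
        if len(bucket) >= self.archive_size and entry.sort_key() >= bucket[-1].sort_key():
            return False
        bucket.append(entry)
        bucket.sort(key=ArchiveEntry.sort_key)
        self._keys.add(key)
        if len(bucket) > self.archive_size:
            dropped = bucket.pop()
            self._keys.discard(dropped.clause.canonical_key())
        return True

    def orders(self) -> list[int]:
        return sorted(o for o, b in self._by_order.items() if b)

    def at_order(self, order: int) -> list[ArchiveEntry]:
        return list(self._by_order.get(order, []))

    def entries(self) -> list[ArchiveEntry]:
        """All entries, best fitness first (ties: lower order, then canonical form)."""
        out = [e for b in self._by_order.values() for e in b]
        out.sort(key=ArchiveEntry.sort_key)
        return out

    def best(self, order: int | None = None) -> ArchiveEntry | None:
        pool = self.at_order(order) if order is not None else self.entries()
        return pool[0] if pool else None

    def merge(self, other: "ClauseArchive") -> None:
        for e in other.entries():
            self.insert(e)

    def __len__(self) -> int:
        return sum(len(b) for b in self._by_order.values())

    def to_records(self) -> list[dict]:
        return [
            {
                "order": e.clause.order,
                "conjuncts": [
                    {"feature": n, "lower": iv.lower, "upper": iv.upper}
                    for n, iv in e.clause.conjuncts
                ],
                "metrics": e.metrics.as_dict(),
                "run": e.run,
                "generation": e.generation,
            }
            for e in self.entries()
        ]


# ---------------------------------------------------------------------------
# Internal genome representation: {feature index: (lo index, hi index)} into
# the per-feature sorted unique observed values.
# ---------------------------------------------------------------------------


class _SearchSpace:
    def __init__(self, table: FeatureTable, target_class: str | None):
        self.table = table
        self.X = table.values
        if target_class is None:
            target_class = table.target_class
        self.target_class = target_class
        self.target = np.array([o == target_class for o in table.outcome], dtype=bool)
        if not self.target.any() or self.target.all():
            raise ValueError("target class must be a proper subset of subjects")
        self.N = table.n_subjects
        self.K = int(self.target.sum())
        self.uniq = [np.unique(self.X[:, j]) for j in range(table.n_features)]
        # fitness lookup zeroed where the match set is not enriched for the
        # target class (k/n <= K/N): only positive association counts
        tab = fitness_table(self.N, self.K)
        n_grid = np.arange(self.N + 1)[:, None]
        k_grid = np.arange(self.K + 1)[None, :]
        self.fit_tab = np.where(k_grid * self.N > n_grid * self.K, tab, 0.0)
        self.names = table.feature_names
        # indices (into uniq) of values observed in target-class rows; used to
        # bias random intervals toward spanning cases, which the fitness rewards
        self.target_idx = [
            np.unique(np.searchsorted(self.uniq[j], self.X[self.target, j]))
            for j in range(table.n_features)
        ]

    def genome_mask(self, genome: dict[int, tuple[int, int]]) -> np.ndarray:
        mask = np.ones(self.N, dtype=bool)
        for f, (i, j) in genome.items():
            col = self.X[:, f]
            mask &= (col >= self.uniq[f][i]) & (col <= self.uniq[f][j])
        return mask

    def conjunct_masks(self, genome: dict[int, tuple[int, int]]) -> dict[int, np.ndarray]:
        out = {}
        for f, (i, j) in genome.items():
            col = self.X[:, f]
            out[f] = (col >= self.uniq[f][i]) & (col <= self.uniq[f][j])
        return out

    def fitness_of_mask(self, mask: np.ndarray) -> float:
        n = int(mask.sum())
        if n == 0:
            return 0.0
        k = int((mask & self.target).sum())
        return float(self.fit_tab[n, k])

    def to_clause(self, genome: dict[int, tuple[int, int]]) -> ConjunctiveClause:
        return ConjunctiveClause(
            {
                self.names[f]: Interval(float(self.uniq[f][i]), float(self.uniq[f][j]))
                for f, (i, j) in genome.items()
            }
        )


def _random_interval(space: _SearchSpace, f: int, rng: np.random.Generator) -> tuple[int, int]:
    """Random closed interval over observed values; half the time the
    endpoints are drawn from target-class values only, so proposals tend to
    span cases rather than arbitrary slices of the range."""
    if rng.random() < 0.5:
        pool = space.target_idx[f]
        a, b = (int(v) for v in pool[rng.integers(len(pool), size=2)])
    else:
        m = len(space.uniq[f])
        a, b = int(rng.integers(m)), int(rng.integers(m))
    return (a, b) if a <= b else (b, a)


def _random_genome(space: _SearchSpace, rng: np.random.Generator, max_order: int) -> dict:
    order = int(rng.integers(1, min(3, max_order) + 1))
    order = min(order, space.table.n_features)
    feats = rng.choice(space.table.n_features, size=order, replace=False)
    return {int(f): _random_interval(space, int(f), rng) for f in feats}


def _mutate(
    genome: dict, space: _SearchSpace, rng: np.random.Generator, cfg: CCEAConfig
) -> dict:
    g = dict(genome)
    P = space.table.n_features
    if rng.random() < cfg.p_add_conjunct and len(g) < min(cfg.max_order, P):
        free = [f for f in range(P) if f not in g]
        f = int(free[rng.integers(len(free))])
        g[f] = _random_interval(space, f, rng)
    if rng.random() < cfg.p_drop_conjunct and len(g) > 1:
        f = sorted(g)[rng.integers(len(g))]
        del g[f]
    if rng.random() < cfg.p_move_bound:
        f = sorted(g)[rng.integers(len(g))]
        i, j = g[f]
        m = len(space.uniq[f])
        if rng.random() < 0.5:  # move lower bound to an adjacent observed value
            i = max(0, min(j, i + (1 if rng.random() < 0.5 else -1)))
        else:
            j = min(m - 1, max(i, j + (1 if rng.random() < 0.5 else -1)))
        g[f] = (i, j)
    if rng.random() < cfg.p_replace_feature and P > len(g):
        f_old = sorted(g)[rng.integers(len(g))]
        free = [f for f in range(P) if f not in g]
        f_new = int(free[rng.integers(len(free))])
        del g[f_old]
        g[f_new] = _random_interval(space, f_new, rng)
    return g


def _crossover(g1: dict, g2: dict, rng: np.random.Generator, max_order: int) -> dict:
    """Uniform conjunct exchange: shared features pick one parent's interval,
    private features are inherited with probability 1/2."""
    child: dict = {}
    for f in sorted(set(g1) | set(g2)):
        if f in g1 and f in g2:
            child[f] = g1[f] if rng.random() < 0.5 else g2[f]
        else:
            if rng.random() < 0.5:
                child[f] = g1.get(f, g2.get(f))
    if not child:
        src = g1 if rng.random() < 0.5 else g2
        f = sorted(src)[rng.integers(len(src))]
        child[f] = src[f]
    while len(child) > max_order:
        f = sorted(child)[rng.integers(len(child))]
        del child[f]
    return child


def _try_archive(
    genome: dict,
    fit: float,
    space: _SearchSpace,
    archive: ClauseArchive,
    cfg: CCEAConfig,
    run: int,
    generation: int,
) -> None:
    if fit <= 0.0:
        return
    order = len(genome)
    bucket = archive.at_order(order)
    if len(bucket) >= cfg.archive_size and fit <= bucket[-1].metrics.fitness:
        return
    # sensitivity: fitness lost when each conjunct is dropped
    cmasks = space.conjunct_masks(genome)
    full_mask = np.ones(space.N, dtype=bool)
    for m in cmasks.values():
        full_mask &= m
    sens: dict[str, float] = {}
    for f in cmasks:
        rest = np.ones(space.N, dtype=bool)
        for f2, m in cmasks.items():
            if f2 != f:
                rest &= m
        sens[space.names[f]] = fit - space.fitness_of_mask(rest)
    if not all(s > cfg.sensitivity_threshold for s in sens.values()):
        return
    clause = space.to_clause(genome)
    metrics = evaluate_clause(clause, space.table, target_class=space.target_class)
    metrics.sensitivity = sens
    archive.insert(ArchiveEntry(clause=clause, metrics=metrics, run=run, generation=generation))


def _single_run(
    space: _SearchSpace, cfg: CCEAConfig, run: int, seed: int
) -> ClauseArchive:
    rng = np.random.default_rng(seed)
    archive = ClauseArchive(cfg.archive_size)
    pop = [_random_genome(space, rng, cfg.max_order) for _ in range(cfg.population_size)]
    fits = [space.fitness_of_mask(space.genome_mask(g)) for g in pop]
    for g, f in zip(pop, fits):
        _try_archive(g, f, space, archive, cfg, run, 0)

    def tournament() -> dict:
        best_i = int(rng.integers(len(pop)))
        for _ in range(cfg.tournament_size - 1):
            i = int(rng.integers(len(pop)))
            if fits[i] > fits[best_i]:
                best_i = i
        return pop[best_i]

    for gen in range(1, cfg.generations + 1):
        elite_i = int(np.argmax(fits))
        new_pop = [dict(pop[elite_i])]
        while len(new_pop) < cfg.population_size:
            p1 = tournament()
            if rng.random() < cfg.crossover_rate:
                child = _crossover(p1, tournament(), rng, cfg.max_order)
            else:
                child = dict(p1)
            new_pop.append(_mutate(child, space, rng, cfg))
        pop = new_pop
        fits = [space.fitness_of_mask(space.genome_mask(g)) for g in pop]
        for g, f in zip(pop, fits):
            _try_archive(g, f, space, archive, cfg, run, gen)
    return archive


def run_ccea(
    table: FeatureTable, target_class: str | None = None, config: CCEAConfig | None = None
) -> ClauseArchive:
    """Run ``config.runs`` independent evolutionary searches and merge archives.

    Deterministic given (table, config): run ``r`` uses seed
    ``config.seed + r``.  Every archived clause has strictly positive
    per-feature sensitivity; the merged archive is deduplicated and
    sorted by fitness (ties: lower order first, then canonical form).
    """
    cfg = config or CCEAConfig()
    space = _SearchSpace(table, target_class)
    merged = ClauseArchive(cfg.archive_size)
    for r in range(cfg.runs):
        merged.merge(_single_run(space, cfg, run=r, seed=cfg.seed + r))
    return merged


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------


def exhaustive_search(
    table: FeatureTable,
    target_class: str | None = None,
    max_order: int = 2,
    max_features: int = 12,
    sensitivity_threshold: float = 0.0,
) -> dict[int, list[tuple[ConjunctiveClause, ClauseMetrics]]]:
    """Provably optimal clauses per order by full enumeration (orders 1-2).

    Candidate interval bounds are all pairs of observed values per
    feature.  Clauses must pass the same per-feature sensitivity
    criterion as archive insertion, so the enumeration and the
    evolutionary search range over the same set of valid clauses.
    Returns, per order, the list of fitness-maximal clauses (all ties).

    Guards refuse tables with more than ``max_features`` columns or
    ``max_order`` > 2 to prevent combinatorial explosion.
    """
    if max_order > 2:
        raise ValueError("exhaustive_search supports max_order <= 2 only")
    if table.n_features > max_features:
        raise ValueError(
            f"table has {table.n_features} features, over the max_features={max_features} guard"
        )
    space = _SearchSpace(table, target_class)
    tgt = space.target.astype(np.float64)
    TIE = 1e-9

    # Per feature: masks of every closed interval [v_i, v_j], i <= j.
    feat_masks: list[np.ndarray] = []       # (I_f, N) float64
    feat_bounds: list[list[tuple[float, float]]] = []
    feat_fit1: list[np.ndarray] = []        # order-1 fitness per interval
    for f in range(table.n_features):
        v = space.uniq[f]
        col = space.X[:, f]
        masks, bounds = [], []
        for i in range(len(v)):
            ge = col >= v[i]
            for j in range(i, len(v)):
                masks.append(ge & (col <= v[j]))
                bounds.append((float(v[i]), float(v[j])))
        M = np.array(masks, dtype=np.float64)
        n = M.sum(axis=1)
        k = M @ tgt
        fit1 = space.fit_tab[n.astype(int), k.astype(int)]
        fit1 = np.where(n == 0, 0.0, fit1)
        feat_masks.append(M)
        feat_bounds.append(bounds)
        feat_fit1.append(fit1)

    results: dict[int, list[tuple[ConjunctiveClause, ClauseMetrics]]] = {}

    # order 1: valid iff sensitivity (= own fitness) exceeds the threshold
    best1 = -np.inf
    winners1: list[tuple[int, int]] = []
    for f in range(table.n_features):
        fit1 = feat_fit1[f]
        valid = fit1 > sensitivity_threshold
        if not valid.any():
            continue
        m = fit1[valid].max()
        if m > best1 + TIE:
            best1, winners1 = m, []
        if m > best1 - TIE:
            for idx in np.flatnonzero(valid & (fit1 > best1 - TIE)):
                winners1.append((f, int(idx)))
    results[1] = [
        _named(space, {f: feat_bounds[f][i]}, run=-1) for f, i in winners1
    ]

    if max_order >= 2:
        best2 = -np.inf
        winners2: list[tuple[int, int, int, int]] = []
        for f, g in itertools.combinations(range(table.n_features), 2):
            Mf, Mg = feat_masks[f], feat_masks[g]
            n2 = Mf @ Mg.T
            k2 = (Mf * tgt) @ Mg.T
            fit2 = space.fit_tab[n2.astype(int), k2.astype(int)]
            fit2 = np.where(n2 == 0, 0.0, fit2)
            valid = (
                (fit2 - feat_fit1[f][:, None] > sensitivity_threshold)
                & (fit2 - feat_fit1[g][None, :] > sensitivity_threshold)
            )
            if not valid.any():
                continue
            m = fit2[valid].max()
            if m > best2 + TIE:
                best2, winners2 = m, []
            if m > best2 - TIE:
                ii, jj = np.nonzero(valid & (fit2 > best2 - TIE))
                for i, j in zip(ii, jj):
                    winners2.append((f, int(i), g, int(j)))
        results[2] = [
            _named(space, {f: feat_bounds[f][i], g: feat_bounds[g][j]}, run=-1)
            for f, i, g, j in winners2
        ]
    return results


def _named(space: _SearchSpace, bounds: Mapping[int, tuple[float, float]], run: int):
    clause = ConjunctiveClause(
        {space.names[f]: Interval(lo, hi) for f, (lo, hi) in bounds.items()}
    )
    metrics = evaluate_clause(clause, space.table, target_class=space.target_class)
    metrics.sensitivity = feature_sensitivity(clause, space.table, target_class=space.target_class)
    return clause, metrics


def select_parsimonious(
    archive: ClauseArchive, order: int, top_m: int
) -> list[tuple[ConjunctiveClause, ClauseMetrics]]:
    """The ``top_m`` highest-fitness clauses of exactly the given order.

    Mirrors the study design of keeping only the most parsimonious
    high-fitness models for interpretation.  Returns fewer than ``top_m``
    (possibly an empty list, with a warning) when the archive is short.
    """
    bucket = archive.at_order(order)
    if not bucket:
        warnings.warn(f"archive holds no clauses of order {order}", stacklevel=2)
        return []
    return [(e.clause, e.metrics) for e in bucket[:top_m]]


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class ConjunctiveClauseModel:
    """Conjunctive-clause feature selection model for a two-class cohort.

    Parameters
    ----------
    table
        The discovery cohort.
    target_class
        Outcome level to treat as positive; defaults to the table's own.
    config
        :class:`CCEAConfig`; defaults are the standard search settings.

    Examples
    --------
    >>> model = ConjunctiveClauseModel(table, config=CCEAConfig(seed=7))
    >>> res = model.fit()
    >>> res.best(order=2).metrics.ppv
    """

    def __init__(
        self,
        table: FeatureTable,
        target_class: str | None = None,
        config: CCEAConfig | None = None,
    ):
        self.table = table
        self.target_class = target_class or table.target_class
        self.config = config or CCEAConfig()
        _SearchSpace(table, target_class)  # validate up front

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject_col: str,
        outcome_col: str,
        target_class: str,
        config: CCEAConfig | None = None,
    ) -> "ConjunctiveClauseModel":
        table = FeatureTable.from_dataframe(df, subject_col, outcome_col, target_class)
        return cls(table, target_class=target_class, config=config)

    def fit(self) -> "CCEAResults":
        archive = run_ccea(self.table, self.target_class, self.config)
        return CCEAResults(self, archive)


class CCEAResults:
    """Fitted clause archive with selection, summary and plotting helpers."""

    def __init__(self, model: ConjunctiveClauseModel, archive: ClauseArchive):
        self.model = model
        self.archive = archive

    def best(self, order: int | None = None) -> ArchiveEntry | None:
        return self.archive.best(order)

    def select_parsimonious(self, order: int, top_m: int):
        return select_parsimonious(self.archive, order, top_m)

    def feature_union(
        self, orders: Sequence[int] | None = None, top_m: int | None = None,
        extra: Sequence[str] = (),
    ) -> list[str]:
        from .pipeline import unique_feature_union

        models: list[tuple[ConjunctiveClause, ClauseMetrics]] = []
        for order in orders or self.archive.orders():
            bucket = self.archive.at_order(order)
            take = bucket if top_m is None else bucket[:top_m]
            models.extend((e.clause, e.metrics) for e in take)
        return unique_feature_union(models, extra=list(extra))

    def summary(self, max_rows: int | None = 20) -> str:
        """Human-readable clause table (id, order, conjuncts, fitness, PPV, coverage)."""
        df = self.summary_frame()
        if max_rows is not None:
            df = df.head(max_rows)
        lines = [
            "Conjunctive Clause Evolutionary Algorithm Results",
            f"  subjects: {self.model.table.n_subjects} "
            f"({self.model.table.n_target} {self.model.target_class})",
            f"  features: {self.model.table.n_features}; runs: {self.model.config.runs}",
            f"  archived clauses: {len(self.archive)}",
            "",
            df.to_string(index=False),
        ]
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for cc_id, e in enumerate(self.archive.entries(), start=1):
            rows.append(
                {
                    "cc": cc_id,
                    "order": e.clause.order,
                    "clause": str(e.clause),
                    "fitness": round(e.metrics.fitness, 4),
                    "ppv": round(e.metrics.ppv, 4),
                    "coverage": round(e.metrics.class_coverage, 4),
                    "n_match": e.metrics.n_match,
                }
            )
        return pd.DataFrame(
            rows, columns=["cc", "order", "clause", "fitness", "ppv", "coverage", "n_match"]
        )

    def plot_clause_regions(self, entries=None, output_dir=None, prefix="clause"):
        from .plotting import plot_clause_regions

        if entries is None:
            picks = []
            for order in (2, 3):
                b = self.archive.at_order(order)
                if b:
                    picks.append((b[0].clause, b[0].metrics))
            entries = picks
        return plot_clause_regions(entries, self.model.table, output_dir, prefix=prefix)
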