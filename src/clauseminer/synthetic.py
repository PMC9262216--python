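"""Synthetic cohorts with planted conjunctive rules.

Real discovery cohorts of the kind the clause miner targets are small
(two unbalanced classes, a couple of dozen subjects), wide (hundreds of
continuous measures) and heterogeneous in scale: regional cortical
volumes live in the thousands of mm^3, surface areas in the thousands of
mm^2, thickness around 2-3 mm, mean curvature around 0.1-0.2, and
behavioral assessment scores in the 0-20 range.  This module fabricates
tables with exactly that shape and — crucially — with known ground
truth: *planted rules*, conjunctions of feature intervals that every
target-class subject satisfies and at most a controlled "leakage"
fraction of the other class satisfies.

Planted structure can be made main-effect free
(:func:`plant_interaction_no_main_effect`): each planted feature's
class means are exactly equal by construction while the joint rectangle
separates the classes, the regime where marginal screening fails and
conjunctive search is the point.

Feature noise is Gaussian per measure type.  That is a deliberate
simplification: real neuroanatomical measures are correlated across
regions and subjects; these tables are not.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, truncnorm

from .clauses import Interval, ConjunctiveClause
from .feature_table import FeatureSpec, FeatureTable

__all__ = [
    "SpecError",
    "ColumnModel",
    "PlantedRule",
    "SyntheticSpec",
    "asd_like_columns",
    "full_asd_columns",
    "generate_cohort",
    "generate_null_cohort",
    "plant_interaction_no_main_effect",
    "ground_truth_json",
]

MAX_PLANTED_ORDER = 5


class SpecError(ValueError):
    """Invalid synthetic-cohort specification."""


@dataclass(frozen=True)
class ColumnModel:
    """One feature column: its spec plus the Gaussian noise model N(loc, scale)."""

    spec: FeatureSpec
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise SpecError(f"scale for {self.spec.name!r} must be positive")


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth conjunction of feature intervals tied to the target class."""

    conjuncts: tuple[tuple[str, Interval], ...]
    target_class: str

    def __init__(self, conjuncts, target_class: str):
        items = list(dict(conjuncts).items())
        if not (1 <= len(items) <= MAX_PLANTED_ORDER):
            raise SpecError(
                f"planted rule order must be 1..{MAX_PLANTED_ORDER}, got {len(items)}"
            )
        object.__setattr__(self, "conjuncts", tuple(items))
        object.__setattr__(self, "target_class", target_class)

    @property
    def order(self) -> int:
        return len(self.conjuncts)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.conjuncts)

    def to_clause(self) -> ConjunctiveClause:
        return ConjunctiveClause(dict(self.conjuncts))


# Default per-measure noise scales; locations vary per column (volumes and
# areas differ enormously across regions, thickness and curvature do not).
_MEASURE_RANGES = {
    "volume": ((3500.0, 23000.0), 0.12),   # (loc range, scale as fraction of loc)
    "area": ((1400.0, 8500.0), 0.15),
    "thickness": ((2.2, 2.8), None),
    "meancurv": ((0.12, 0.2), None),
    "score": ((5.0, 18.0), None),
}
_FIXED_SCALES = {"thickness": 0.15, "meancurv": 0.02, "score": 3.0}

_APARC_REGIONS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

_BEHAVIORAL = [
    ("casl_total", 100.0, 15.0),
    ("unit2_full_scale", 105.0, 15.0),
    ("unit2_abbreviated", 105.0, 12.0),
    ("tomtb_total", 12.0, 2.5),
    ("tomi2_total_composite_mean", 15.0, 3.0),
    ("tomi2_early_subscale_mean", 16.0, 2.0),
    ("tomi2_basic_subscale_mean", 16.0, 2.5),
    ("tomi2_advanced_subscale_mean", 13.0, 3.5),
    ("tomi2_happy", 18.0, 1.5),
    ("tomi2_sad", 17.0, 2.0),
    ("tomi2_surprise", 16.5, 2.5),
    ("tomi2_embarrassment", 13.0, 4.0),
    ("tomi2_desire_based_emotion", 18.0, 1.5),
]

_MEASURE_UNITS = {"volume": "mm3", "area": "mm2", "thickness": "mm",
                  "meancurv": "", "score": "score-points", "other": ""}


def _brain_column(name: str, measure: str, u: float) -> ColumnModel:
    """One neuroanatomical column; ``u`` in [0,1) picks the location in range."""
    (lo, hi), frac = _MEASURE_RANGES[measure]
    loc = lo + u * (hi - lo)
    scale = _FIXED_SCALES.get(measure, None)
    if scale is None:
        scale = frac * loc
    return ColumnModel(
        spec=FeatureSpec(name=name, kind="neuroanatomical", measure=measure,
                         units=_MEASURE_UNITS[measure]),
        loc=float(loc), scale=float(scale),
    )


def asd_like_columns(n_features: int, prefix: str = "noise") -> list[ColumnModel]:
    """``n_features`` FreeSurfer-flavoured noise columns cycling through
    volume / area / thickness / meancurv, heterogeneous in scale.

    Deterministic in its arguments.
    """
    if n_features < 0:
        raise SpecError("n_features must be non-negative")
    measures = ("volume", "area", "thickness", "meancurv")
    rng = np.random.default_rng(202206)  # fixed: the schema is a constant, not a sample
    cols = []
    for i in range(n_features):
        measure = measures[i % 4]
        region = _APARC_REGIONS[(i // 4) % len(_APARC_REGIONS)]
        hemi = "lh" if (i // (4 * len(_APARC_REGIONS))) % 2 == 0 else "rh"
        name = f"{prefix}_{hemi}_{region}_{measure}_{i:03d}"
        cols.append(_brain_column(name, measure, float(rng.random())))
    return cols


def full_asd_columns() -> list[ColumnModel]:
    """The full study-like schema: 276 brain columns + 13 behavioral = 289.

    34 cortical regions x 2 hemispheres x 4 measures (272) plus four
    hemisphere-level summaries, then the 13 behavioral assessment scores.
    """
    rng = np.random.default_rng(202207)
    cols: list[ColumnModel] = []
    for hemi in ("lh", "rh"):
        for region in _APARC_REGIONS:
            for measure in ("volume", "area", "thickness", "meancurv"):
                name = f"{hemi}_{region}_{measure}"
                cols.append(_brain_column(name, measure, float(rng.random())))
    for hemi in ("lh", "rh"):
        cols.append(_brain_column(f"{hemi}_meanthickness", "thickness", 0.5))
        cols.append(_brain_column(f"{hemi}_whitesurfarea", "area", 0.9))
    for name, loc, scale in _BEHAVIORAL:
        cols.append(
            ColumnModel(
                spec=FeatureSpec(name=name, kind="behavioral", measure="score",
                                 units="score-points"),
                loc=loc, scale=scale,
            )
        )
    return cols


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic cohort.

    Defaults mirror the discovery-cohort conditions the analysis is
    designed for: 7 target-class vs 14 other subjects, 50 noise
    features, planted rules satisfied by every target subject and
    (leakage = 0) by no other subject.
    """

    n_target: int = 7
    n_other: int = 14
    planted: tuple[PlantedRule, ...] = ()
    n_noise_features: int = 50
    columns: tuple[ColumnModel, ...] = ()
    leakage: float = 0.0
    target_label: str = "ASD"
    other_label: str = "NT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target < 1 or self.n_other < 1:
            raise SpecError("class counts must be positive")
        if not (0.0 <= self.leakage <= 1.0):
            raise SpecError("leakage must lie in [0, 1]")
        if self.target_label == self.other_label:
            raise SpecError("class labels must differ")
        object.__setattr__(self, "planted", tuple(self.planted))
        cols = tuple(self.columns) if self.columns else tuple(
            asd_like_columns(self.n_noise_features)
        )
        object.__setattr__(self, "columns", cols)
        names = [c.spec.name for c in cols]
        if len(set(names)) != len(names):
            raise SpecError("duplicate column names in schema")

    def all_columns(self) -> list[ColumnModel]:
        """Planted-feature columns (auto-created if absent) followed by noise."""
        by_name = {c.spec.name: c for c in self.columns}
        planted_cols: list[ColumnModel] = []
        seen: set[str] = set()
        for rule in self.planted:
            for fname, iv in rule.conjuncts:
                if fname in seen:
                    raise SpecError(
                        f"feature {fname!r} appears in more than one planted rule; "
                        "planted rules must use disjoint features"
                    )
                seen.add(fname)
                col = by_name.get(fname)
                if col is None:
                    # synthesize a column whose noise model brackets the interval
                    mid = 0.5 * (iv.lower + iv.upper)
                    width = max(iv.upper - iv.lower, abs(mid) * 1e-3, 1e-6)
                    col = ColumnModel(
                        spec=FeatureSpec(name=fname, kind="neuroanatomical",
                                         measure="other"),
                        loc=mid, scale=width,
                    )
                _check_support(col, iv)
                planted_cols.append(col)
        noise_cols = [c for c in self.columns if c.spec.name not in seen]
        return planted_cols + noise_cols


def _check_support(col: ColumnModel, iv: Interval) -> None:
    lo, hi = col.loc - 4 * col.scale, col.loc + 4 * col.scale
    if iv.upper < lo or iv.lower > hi:
        raise SpecError(
            f"planted interval {iv} for {col.spec.name!r} lies outside the "
            f"feature's support [{lo:g}, {hi:g}]"
        )


def _trunc_inside(rng, col: ColumnModel, iv: Interval, size: int) -> np.ndarray:
    a = (iv.lower - col.loc) / col.scale
    b = (iv.upper - col.loc) / col.scale
    return truncnorm.rvs(a, b, loc=col.loc, scale=col.scale, size=size, random_state=rng)

def _trunc_outside(rng, col: ColumnModel, iv: Interval, size: int) -> np.ndarray:
    a = (iv.lower - col.loc) / col.scale
    b = (iv.upper - col.loc) / col.scale
    p_below, p_above = norm.cdf(a), 1.0 - norm.cdf(b)
    total = p_below + p_above
    if total < 1e-12:
        raise SpecError(
            f"interval {iv} for {col.spec.name!r} spans the feature's support; "
            "no subject can violate it"
        )
    below = rng.random(size) < (p_below / total)
    out = np.empty(size)
    n_b = int(below.sum())
    if n_b:
        out[below] = truncnorm.rvs(-np.inf, a, loc=col.loc, scale=col.scale,
                                   size=n_b, random_state=rng)
    if size - n_b:
        out[~below] = truncnorm.rvs(b, np.inf, loc=col.loc, scale=col.scale,
                                    size=size - n_b, random_state=rng)
    return out


def generate_cohort(spec: SyntheticSpec) -> tuple[FeatureTable, list[PlantedRule]]:
    """Generate a cohort honouring every planted rule.

    Guarantees (exact, assertable by row scan):

    * every target-class subject satisfies every planted rule;
    * at most ``floor(leakage * n_other)`` non-target subjects satisfy
      any given rule (each remaining non-target subject violates at
      least one conjunct of each rule);
    * noise features are i.i.d. across subjects regardless of class;
    * identical seed => bit-identical table.
    """
    cols = spec.all_columns()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_target + spec.n_other
    name_to_j = {c.spec.name: j for j, c in enumerate(cols)}

    # base i.i.d. draws for every cell, then planted structure overwrites
    values = np.column_stack([rng.normal(c.loc, c.scale, size=n) for c in cols])
    target_rows = np.arange(spec.n_target)
    other_rows = np.arange(spec.n_target, n)

    n_leak = int(math.floor(spec.leakage * spec.n_other))
    for rule in spec.planted:
        leak_rows = rng.choice(other_rows, size=n_leak, replace=False) if n_leak else []
        strict_rows = [r for r in other_rows if r not in set(np.atleast_1d(leak_rows))]
        # which conjunct each strict non-target subject violates
        viol_pick = rng.integers(rule.order, size=len(strict_rows))
        for ci, (fname, iv) in enumerate(rule.conjuncts):
            j = name_to_j[fname]
            col = cols[j]
            values[target_rows, j] = _trunc_inside(rng, col, iv, spec.n_target)
            if n_leak:
                values[leak_rows, j] = _trunc_inside(rng, col, iv, n_leak)
            hit = [r for r, v in zip(strict_rows, viol_pick) if v == ci]
            if hit:
                values[hit, j] = _trunc_outside(rng, col, iv, len(hit))

    subjects = [f"S{i + 1:03d}" for i in range(n)]
    outcome = [spec.target_label] * spec.n_target + [spec.other_label] * spec.n_other
    table = FeatureTable(
        subjects=subjects,
        features=[c.spec for c in cols],
        values=values,
        outcome=outcome,
        target_class=spec.target_label,
    )
    return table, list(spec.planted)


def generate_null_cohort(
    n_target: int, n_other: int, n_features: int, seed: int = 0,
    target_label: str = "ASD", other_label: str = "NT",
) -> FeatureTable:
    """Cohort with no class structure at all: i.i.d. standard-normal
    features, labels independent of values.  The null for testing how
    large clause fitness gets by selection alone."""
    if n_target < 1 or n_other < 1:
        raise SpecError("class counts must be positive")
    if n_features < 1:
        raise SpecError("n_features must be positive")
    rng = np.random.default_rng(seed)
    n = n_target + n_other
    values = rng.normal(size=(n, n_features))
    return FeatureTable(
        subjects=[f"S{i + 1:03d}" for i in range(n)],
        features=[FeatureSpec(name=f"noise_{j:03d}", kind="neuroanatomical",
                              measure="other") for j in range(n_features)],
        values=values,
        outcome=[target_label] * n_target + [other_label] * n_other,
        target_class=target_label,
    )


def plant_interaction_no_main_effect(
    spec: SyntheticSpec, features: tuple[str, str], seed: int | None = None
) -> tuple[FeatureTable, PlantedRule]:
    """Plant a two-feature interaction with *exactly* no marginal signal.

    XOR-corner layout on the two named features: the target class
    occupies one rectangle (I1 x I2); the non-target class splits into
    the two adjacent corners (inside I1 / outside I2, and outside I1 /
    inside I2).  The out-of-interval group of each feature is then
    translated so that the non-target class mean equals the target class
    mean *exactly*, not merely in expectation.  Consequences, exact by
    construction: each single-feature projection of the rule has class
    coverage 1 but precision no better than the corner mixture, the
    two-sample location difference per planted feature is 0, and no
    non-target subject satisfies the full rule.

    Requires at least 4 subjects per class.
    """
    f1, f2 = features
    if f1 == f2:
        raise SpecError("the two planted features must be distinct")
    if spec.n_target < 4 or spec.n_other < 4:
        raise SpecError("need at least 4 subjects per class to balance the mixture")
    cols = {c.spec.name: c for c in spec.columns}
    for f in (f1, f2):
        if f not in cols:
            raise SpecError(f"feature {f!r} is not in the schema")
    c1, c2 = cols[f1], cols[f2]
    iv1 = Interval(c1.loc - c1.scale, c1.loc + c1.scale)
    iv2 = Interval(c2.loc - c2.scale, c2.loc + c2.scale)
    rule = PlantedRule({f1: iv1, f2: iv2}, target_class=spec.target_label)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_target + spec.n_other
    all_cols = list(spec.columns)
    values = np.column_stack([rng.normal(c.loc, c.scale, size=n) for c in all_cols])
    j1 = [c.spec.name for c in all_cols].index(f1)
    j2 = [c.spec.name for c in all_cols].index(f2)

    tgt = np.arange(spec.n_target)
    oth = np.arange(spec.n_target, n)
    gx = oth[: spec.n_other // 2]      # corner (in I1, out of I2)
    gy = oth[spec.n_other // 2:]       # corner (out of I1, in I2)

    values[tgt, j1] = _trunc_inside(rng, c1, iv1, spec.n_target)
    values[tgt, j2] = _trunc_inside(rng, c2, iv2, spec.n_target)
    values[gx, j1] = _trunc_inside(rng, c1, iv1, len(gx))
    values[gy, j2] = _trunc_inside(rng, c2, iv2, len(gy))
    values[gy, j1] = _balanced_outside(rng, c1, iv1, len(gy),
                                       required_sum=n_req_sum(values, tgt, gx, j1, spec))
    values[gx, j2] = _balanced_outside(rng, c2, iv2, len(gx),
                                       required_sum=n_req_sum(values, tgt, gy, j2, spec))
    outcome = [spec.target_label] * spec.n_target + [spec.other_label] * spec.n_other
    table = FeatureTable(
        subjects=[f"S{i + 1:03d}" for i in range(n)],
        features=[c.spec for c in all_cols],
        values=values,
        outcome=outcome,
        target_class=spec.target_label,
    )
    return table, rule


def n_req_sum(values, tgt, inside_group, j, spec) -> float:
    """Sum the outside group must hit so both class means agree exactly."""
    target_mean = values[tgt, j].mean()
    return spec.n_other * target_mean - values[inside_group, j].sum()


def _balanced_outside(rng, col: ColumnModel, iv: Interval, size: int,
                      required_sum: float) -> np.ndarray:
    """``size`` values strictly outside ``iv`` whose sum is exactly
    ``required_sum``: split below/above the interval, then translate one
    side (always further away from the interval) to fix the sum."""
    if size < 2:
        raise SpecError("outside group needs at least 2 subjects")
    k_below = size // 2
    k_above = size - k_below
    margin_b = np.abs(rng.normal(0.0, col.scale, size=k_below)) + 1e-9 * col.scale
    margin_a = np.abs(rng.normal(0.0, col.scale, size=k_above)) + 1e-9 * col.scale
    below = iv.lower - margin_b
    above = iv.upper + margin_a
    delta = required_sum - (below.sum() + above.sum())
    if delta <= 0:
        below += delta / k_below      # pushes further below the interval
    else:
        above += delta / k_above      # pushes further above
    return np.concatenate([below, above])


def ground_truth_json(rules: list[PlantedRule], spec: SyntheticSpec) -> str:
    """Serialize planted ground truth (rules + generation recipe) for archiving."""
    payload = {
        "seed": spec.seed,
        "n_target": spec.n_target,
        "n_other": spec.n_other,
        "leakage": spec.leakage,
        "target_label": spec.target_label,
        "other_label": spec.other_label,
        "rules": [
            {
                "target_class": r.target_class,
                "conjuncts": [
                    {"feature": f, "lower": iv.lower, "upper": iv.upper}
                    for f, iv in r.conjuncts
                ],
            }
            for r in rules
        ],
    }
    return json.dumps(payload, indent=2)
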