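"""Synthetic cohort generator: planted-rule guarantees and null models."""

import json
import math

import numpy as np
import pytest

from clauseminer.clauses import ConjunctiveClause, Interval, evaluate_clause, match_mask
from clauseminer.feature_table import FeatureSpec
from clauseminer.synthetic import (
    ColumnModel,
    PlantedRule,
    SpecError,
    SyntheticSpec,
    asd_like_columns,
    full_asd_columns,
    generate_cohort,
    generate_null_cohort,
    ground_truth_json,
    plant_interaction_no_main_effect,
)
from clauseminer.ccea import exhaustive_search
from tests.conftest import PLANTED_RULE, planted_cohort, planted_columns


def brute_force_matches(rule: PlantedRule, table) -> np.ndarray:
    """Independent row scan against the ground-truth rule."""
    out = np.ones(table.n_subjects, dtype=bool)
    for f, iv in rule.conjuncts:
        col = table.column(f)
        out &= (col >= iv.lower) & (col <= iv.upper)
    return out


def test_planted_rule_is_perfect_at_zero_leakage():
    table, rule = planted_cohort(n_noise=20, seed=0)
    m = evaluate_clause(rule.to_clause(), table)
    assert m.ppv == 1.0 and m.class_coverage == 1.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_planted_satisfaction_exact_by_row_scan(seed):
    table, rule = planted_cohort(n_noise=10, seed=seed)
    hits = brute_force_matches(rule, table)
    tgt = table.target_mask
    assert hits[tgt].all()           # every case satisfies the rule
    assert not hits[~tgt].any()      # leakage 0: no control does


def test_same_seed_is_bit_identical():
    t1, _ = planted_cohort(n_noise=30, seed=9)
    t2, _ = planted_cohort(n_noise=30, seed=9)
    assert np.array_equal(t1.values, t2.values)
    assert t1.subjects == t2.subjects and t1.outcome == t2.outcome
    t3, _ = planted_cohort(n_noise=30, seed=10)
    assert not np.array_equal(t1.values, t3.values)


@pytest.mark.parametrize("seed", range(6))
def test_leakage_bound_by_brute_force(seed):
    table, rule = planted_cohort(n_noise=10, seed=seed, leakage=0.5)
    hits = brute_force_matches(rule, table)
    tgt = table.target_mask
    assert hits[tgt].all()
    assert hits[~tgt].sum() <= math.ceil(0.5 * 14)


def test_schema_complete_output():
    cols = planted_columns(15)
    spec = SyntheticSpec(planted=(PLANTED_RULE,), columns=cols, seed=2)
    table, _ = generate_cohort(spec)
    assert sorted(table.feature_names) == sorted(c.spec.name for c in cols)
    assert table.n_features == len(cols)


def test_planted_interval_outside_support_is_rejected():
    cols = (
        ColumnModel(FeatureSpec("tiny", "neuroanatomical", "other"), 0.0, 1.0),
    )
    rule = PlantedRule({"tiny": Interval(50.0, 60.0)}, "ASD")
    spec = SyntheticSpec(planted=(rule,), columns=cols, seed=0)
    with pytest.raises(SpecError, match="support"):
        generate_cohort(spec)


def test_overlapping_planted_rules_rejected():
    r1 = PlantedRule({"x": Interval(0, 1)}, "ASD")
    r2 = PlantedRule({"x": Interval(0, 2), "y": Interval(0, 1)}, "ASD")
    cols = tuple(
        ColumnModel(FeatureSpec(n, "neuroanatomical", "other"), 0.5, 1.0) for n in "xy"
    )
    spec = SyntheticSpec(planted=(r1, r2), columns=cols, seed=0)
    with pytest.raises(SpecError, match="disjoint"):
        generate_cohort(spec)


def test_rule_order_bounds():
    with pytest.raises(SpecError):
        PlantedRule({f"f{i}": Interval(0, 1) for i in range(6)}, "ASD")  # order 6
    with pytest.raises(SpecError):
        PlantedRule({}, "ASD")


def test_null_cohort_validation_and_determinism():
    with pytest.raises(SpecError):
        generate_null_cohort(7, 14, 0)
    with pytest.raises(SpecError):
        generate_null_cohort(0, 14, 5)
    a = generate_null_cohort(7, 14, 5, seed=4)
    b = generate_null_cohort(7, 14, 5, seed=4)
    assert np.array_equal(a.values, b.values)


def test_null_cohort_best_clause_beats_prior_by_selection():
    """Even with no signal, the best exhaustively-found first-order clause has
    PPV above the class prior: the multiplicity of candidate intervals alone
    inflates apparent precision, which is why sensitivity pruning and
    parsimony matter."""
    ppvs = []
    for seed in range(5):
        table = generate_null_cohort(7, 14, 50, seed=seed)
        ex = exhaustive_search(table, max_order=1, max_features=50)
        assert ex[1], "some interval always beats fitness 0 on 50 null features"
        ppvs.append(max(m.ppv for _, m in ex[1]))
    prior = 7 / 21
    assert all(p > prior for p in ppvs)


def test_no_main_effect_class_means_equal_exactly():
    cols = tuple(asd_like_columns(10))
    pair = (cols[2].spec.name, cols[5].spec.name)
    for seed in range(8):
        spec = SyntheticSpec(n_target=7, n_other=14, columns=cols, seed=seed)
        table, rule = plant_interaction_no_main_effect(spec, pair, seed=seed)
        tgt = table.target_mask
        for f, _ in rule.conjuncts:
            col = table.column(f)
            scale = max(1.0, abs(col).mean())
            assert abs(col[tgt].mean() - col[~tgt].mean()) < 1e-9 * scale


def test_no_main_effect_projections_versus_joint():
    cols = tuple(asd_like_columns(6))
    spec = SyntheticSpec(n_target=7, n_other=14, columns=cols, seed=5)
    table, rule = plant_interaction_no_main_effect(
        spec, (cols[0].spec.name, cols[1].spec.name), seed=9
    )
    joint = evaluate_clause(rule.to_clause(), table)
    assert joint.ppv == 1.0 and joint.class_coverage == 1.0
    for f, iv in rule.conjuncts:
        proj = evaluate_clause(ConjunctiveClause({f: iv}), table)
        assert proj.class_coverage == 1.0
        # corner mixture: half the controls share each marginal interval
        assert proj.ppv == pytest.approx(7 / 14)


def test_no_main_effect_needs_four_per_class():
    cols = tuple(asd_like_columns(4))
    spec = SyntheticSpec(n_target=3, n_other=14, columns=cols, seed=0)
    with pytest.raises(SpecError, match="4"):
        plant_interaction_no_main_effect(spec, (cols[0].spec.name, cols[1].spec.name))


def test_ground_truth_json_round_trip():
    table, rule = planted_cohort(n_noise=5, seed=1)
    spec = SyntheticSpec(planted=(PLANTED_RULE,), columns=planted_columns(5), seed=1)
    payload = json.loads(ground_truth_json([rule], spec))
    assert payload["seed"] == 1
    assert payload["rules"][0]["conjuncts"][0]["feature"] == rule.conjuncts[0][0]


def test_full_schema_shape():
    cols = full_asd_columns()
    assert len(cols) == 289
    kinds = {c.spec.kind for c in cols}
    assert kinds == {"behavioral", "neuroanatomical"}
    assert sum(c.spec.kind == "behavioral" for c in cols) == 13
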