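"""Shared fixtures: small hand-built tables and planted synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from clauseminer.clauses import Interval
from clauseminer.feature_table import FeatureSpec, FeatureTable
from clauseminer.synthetic import (
    ColumnModel,
    PlantedRule,
    SyntheticSpec,
    asd_like_columns,
    generate_cohort,
)

PLANTED_A = "planted_vol_a"
PLANTED_B = "planted_vol_b"
PLANTED_RULE = PlantedRule(
    {PLANTED_A: Interval(3500, 4600), PLANTED_B: Interval(20000, 25000)},
    target_class="ASD",
)


def planted_columns(n_noise: int) -> tuple[ColumnModel, ...]:
    return tuple(
        [
            ColumnModel(FeatureSpec(PLANTED_A, "neuroanatomical", "volume", "mm3"), 4000, 400),
            ColumnModel(FeatureSpec(PLANTED_B, "neuroanatomical", "volume", "mm3"), 22000, 2000),
        ]
        + asd_like_columns(n_noise)
    )


def planted_cohort(n_noise: int = 50, seed: int = 42, leakage: float = 0.0,
                   n_target: int = 7, n_other: int = 14):
    spec = SyntheticSpec(
        n_target=n_target, n_other=n_other, planted=(PLANTED_RULE,),
        columns=planted_columns(n_noise), leakage=leakage, seed=seed,
    )
    table, rules = generate_cohort(spec)
    return table, rules[0]


def make_table(values, outcome, target="ASD", names=None, subjects=None) -> FeatureTable:
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    names = names or [f"f{j}" for j in range(p)]
    subjects = subjects or [f"S{i}" for i in range(values.shape[0])]
    return FeatureTable(
        subjects=subjects,
        features=[FeatureSpec(n, "neuroanatomical", "other") for n in names],
        values=values,
        outcome=list(outcome),
        target_class=target,
    )


@pytest.fixture(scope="session")
def small_planted_cohort():
    """14 NT / 7 ASD cohort, one planted 2-feature rule, 50 noise features."""
    return planted_cohort(n_noise=50, seed=42)


@pytest.fixture
def four_point_table():
    """A(0,0,+) B(0.1,0,+) C(5,5,-) D(5.1,5,-)."""
    return make_table(
        [[0, 0], [0.1, 0], [5, 5], [5.1, 5]],
        ["pos", "pos", "neg", "neg"],
        target="pos",
        subjects=["A", "B", "C", "D"],
    )
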