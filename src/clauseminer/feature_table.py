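"""Subjects x features table with a binary nominal outcome.

The :class:`FeatureTable` is the single in-memory currency of the whole
pipeline: clause mining, KNN validation, and the synthetic generator all
consume and produce it.  It wraps a dense numeric matrix (one row per
subject, one column per named feature), a two-level outcome label per
subject, and a designated *target class* (the "case" level, e.g. ASD in
a case/control neurodevelopmental cohort).

Columns carry light metadata (:class:`FeatureSpec`) distinguishing
behavioral assessment scores from regional neuroanatomical measures
(volume mm^3, surface area mm^2, cortical thickness mm, mean curvature),
because those families live on wildly different numeric scales and
downstream consumers (scaling for KNN, synthetic generation) care.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "FeatureTable",
    "SchemaError",
    "TableParseError",
    "OutcomeError",
    "FeatureLookupError",
    "read_feature_table",
    "write_feature_table",
    "subset_features",
    "split_subjects",
]

KINDS = ("behavioral", "neuroanatomical")
MEASURES = ("volume", "area", "thickness", "meancurv", "score", "other")


class SchemaError(ValueError):
    """Header / column-role mapping problems."""


class TableParseError(ValueError):
    """Non-numeric, empty or non-finite cell in a feature column."""


class OutcomeError(ValueError):
    """Outcome column does not define a valid two-level labelling."""


class FeatureLookupError(KeyError):
    """A requested feature name is not present in the table."""


@dataclass(frozen=True)
class FeatureSpec:
    """Name plus typed metadata for one feature column."""

    name: str
    kind: str = "neuroanatomical"
    measure: str = "other"
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("feature name must be non-empty")
        if self.kind not in KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r}; expected one of {KINDS}")
        if self.measure not in MEASURES:
            raise SchemaError(
                f"unknown measure {self.measure!r}; expected one of {MEASURES}"
            )


@dataclass
class FeatureTable:
    """Validated subjects x features matrix with binary outcome labels.

    Parameters
    ----------
    subjects
        Unique subject identifiers, one per row.
    features
        One :class:`FeatureSpec` per column, unique names, order = column order.
    values
        N x P float matrix; every entry must be finite.
    outcome
        Per-subject label; exactly two distinct levels overall.
    target_class
        The outcome level treated as "positive" (e.g. the case group).
    """

    subjects: list[str]
    features: list[FeatureSpec]
    values: np.ndarray
    outcome: list[str]
    target_class: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subjects = [str(s) for s in self.subjects]
        self.outcome = [str(o) for o in self.outcome]
        n, p = len(self.subjects), len(self.features)
        if self.values.shape != (n, p):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{n} subjects x {p} features"
            )
        if p == 0:
            raise SchemaError("a feature table needs at least one feature column")
        if len(set(self.subjects)) != n:
            raise SchemaError("subject identifiers must be unique")
        names = [f.name for f in self.features]
        if len(set(names)) != p:
            raise SchemaError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise TableParseError(
                f"non-finite value at subject {self.subjects[bad[0]]!r}, "
                f"feature {names[bad[1]]!r}"
            )
        if len(self.outcome) != n:
            raise OutcomeError("outcome must have one label per subject")
        levels = sorted(set(self.outcome))
        # a loaded cohort must have exactly 2 levels (enforced at read time);
        # derived tables (cross-validation folds, class-pure splits) may
        # temporarily hold a single level
        if not (1 <= len(levels) <= 2):
            raise OutcomeError(f"outcome must have 1 or 2 levels, found {levels}")
        if len(levels) == 2 and self.target_class not in levels:
            raise OutcomeError(
                f"target class {self.target_class!r} not among outcome levels {levels}"
            )
        self._index = {name: i for i, name in enumerate(names)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def target_mask(self) -> np.ndarray:
        """Boolean row mask of target-class (positive) subjects."""
        return np.array([o == self.target_class for o in self.outcome], dtype=bool)

    @property
    def n_target(self) -> int:
        return int(self.target_mask.sum())

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for o in self.outcome:
            out[o] = out.get(o, 0) + 1
        return out

    def column_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise FeatureLookupError(f"unknown feature {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_index(name)]

    def row(self, subject_id: str) -> dict[str, float]:
        """One subject's values as a feature-name -> value mapping."""
        try:
            i = self.subjects.index(subject_id)
        except ValueError:
            raise FeatureLookupError(f"unknown subject {subject_id!r}") from None
        return dict(zip(self.feature_names, self.values[i]))

    def to_dataframe(self, subject_col: str = "subject_id", outcome_col: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, subject_col, self.subjects)
        df[outcome_col] = self.outcome
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject_col: str,
        outcome_col: str,
        target_class: str,
        feature_specs: Mapping[str, FeatureSpec] | None = None,
    ) -> "FeatureTable":
        feature_cols = [c for c in df.columns if c not in (subject_col, outcome_col)]
        specs = []
        for c in feature_cols:
            if feature_specs and c in feature_specs:
                specs.append(feature_specs[c])
            else:
                specs.append(FeatureSpec(name=c, kind="neuroanatomical", measure="other"))
        vals = np.empty((len(df), len(feature_cols)), dtype=float)
        for j, c in enumerate(feature_cols):
            col = pd.to_numeric(df[c], errors="coerce")
            bad = col.isna() | df[c].isna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise TableParseError(
                    f"non-numeric or empty cell at row {i} "
                    f"(subject {df[subject_col].iloc[i]!r}), column {c!r}"
                )
            vals[:, j] = col.to_numpy(dtype=float)
        return cls(
            subjects=list(df[subject_col].astype(str)),
            features=specs,
            values=vals,
            outcome=list(df[outcome_col].astype(str)),
            target_class=target_class,
        )


# -- CSV I/O -----------------------------------------------------------------


def read_feature_table(source: str | IO[str] | IO[bytes], schema: Mapping) -> FeatureTable:
    """Load a CSV into a validated :class:`FeatureTable`.

    ``schema`` is a column-role mapping with keys ``subject_col``,
    ``outcome_col``, ``target_class`` and optionally ``features``
    (per-column dicts with ``kind`` / ``measure`` / ``units``).
    The CSV must be comma-separated with a header and dot decimals.
    """
    for key in ("subject_col", "outcome_col", "target_class"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if df.columns.duplicated().any() or any(c.endswith(".1") for c in df.columns):
        # pandas mangles duplicate headers to name.1; detect both forms
        raise SchemaError("duplicate header names in CSV")
    for col in (schema["subject_col"], schema["outcome_col"]):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} named in schema is missing from the CSV header")
    spec_meta = {}
    for name, meta in (schema.get("features") or {}).items():
        spec_meta[name] = FeatureSpec(name=name, **meta)
    table = FeatureTable.from_dataframe(
        df,
        subject_col=schema["subject_col"],
        outcome_col=schema["outcome_col"],
        target_class=str(schema["target_class"]),
        feature_specs=spec_meta,
    )
    levels = sorted(set(table.outcome))
    if len(levels) != 2:
        raise OutcomeError(f"outcome column must have exactly 2 levels, found {levels}")
    if table.target_class not in levels:
        raise OutcomeError(
            f"target class {table.target_class!r} not among outcome levels {levels}"
        )
    return table


def write_feature_table(
    table: FeatureTable,
    dest: str | IO[str],
    subject_col: str = "subject_id",
    outcome_col: str = "label",
) -> None:
    """Write the table as CSV, numeric cells at 10 significant digits."""
    df = table.to_dataframe(subject_col=subject_col, outcome_col=outcome_col)
    df.to_csv(dest, index=False, float_format="%.10g")


def schema_to_json(schema: Mapping) -> str:
    """Serialize a column-role mapping (the CSV schema) to JSON."""
    return json.dumps(schema, indent=2, sort_keys=True)


def schema_from_json(text: str | bytes) -> dict:
    schema = json.loads(text)
    if not isinstance(schema, dict):
        raise SchemaError("schema JSON must be an object")
    return schema


# -- structural operations ---------------------------------------------------


def subset_features(table: FeatureTable, names: Sequence[str]) -> FeatureTable:
    """Return a copy of ``table`` restricted to the named columns (in the given order)."""
    if len(names) == 0:
        raise FeatureLookupError("an empty feature subset is invalid")
    missing = [n for n in names if n not in table._index]
    if missing:
        raise FeatureLookupError(f"unknown feature name(s): {missing}")
    idx = [table.column_index(n) for n in names]
    return FeatureTable(
        subjects=list(table.subjects),
        features=[table.features[i] for i in idx],
        values=table.values[:, idx].copy(),
        outcome=list(table.outcome),
        target_class=table.target_class,
    )


def split_subjects(table: FeatureTable, ids: Iterable[str]) -> tuple[FeatureTable, FeatureTable]:
    """Partition rows into (subjects in ``ids``, complement), both non-empty.

    Row order within each part follows the original table order.
    """
    ids = list(ids)
    unknown = [i for i in ids if i not in table.subjects]
    if unknown:
        raise FeatureLookupError(f"unknown subject id(s): {unknown}")
    id_set = set(ids)
    in_rows = [i for i, s in enumerate(table.subjects) if s in id_set]
    out_rows = [i for i, s in enumerate(table.subjects) if s not in id_set]
    if not in_rows or not out_rows:
        raise SchemaError("split_subjects would produce an empty table on one side")

    def take(rows: list[int]) -> FeatureTable:
        return FeatureTable(
            subjects=[table.subjects[i] for i in rows],
            features=list(table.features),
            values=table.values[rows, :].copy(),
            outcome=[table.outcome[i] for i in rows],
            target_class=table.target_class,
        )

    return take(in_rows), take(out_rows)
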