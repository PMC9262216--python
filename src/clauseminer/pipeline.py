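"""End-to-end orchestration: clause discovery, selection, KNN validation.

The full study analog runs in fixed stages: (1) split off the discovery
cohort; (2) evolutionary clause search on it; (3) keep the top
parsimonious models per order; (4) build deduplicated feature unions
from them; (5) leave-one-out cross-validate a KNN on all subjects per
experiment; (6) optionally train/test-classify on an explicit balanced
split.  Everything is driven by one :class:`PipelineConfig` (YAML-
loadable) and all randomness flows from its single seed, so a rerun
reproduces the report byte-for-byte (modulo timestamps).

Note the deliberate fidelity choice in stage 5: cross-validation runs
on discovery + holdout subjects *combined*, even though the feature
sets were selected on the discovery subjects — the validation design of
the original analysis.  The optimism this induces is inherent to that
design and is the analyst's to keep in mind.

The module also carries the published second- and third-order clause
tables as data (:data:`TABLE3_CLAUSES`, :data:`TABLE4_CLAUSES`), used
to rebuild the printed feature unions and — when a subject-level data
file is available — to attempt :func:`conditional_reproduction` of the
printed cross-validation accuracies.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .ccea import CCEAConfig, ClauseArchive, run_ccea, select_parsimonious
from .clauses import ClauseMetrics, ConjunctiveClause, Interval
from .feature_table import (
    FeatureTable,
    read_feature_table,
    split_subjects,
    subset_features,
    write_feature_table,
)
from .knn import KNNConfig, loocv, matrix_metrics, train_test_classify
from .synthetic import PlantedRule, SyntheticSpec, generate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "RunReport",
    "unique_feature_union",
    "run_pipeline",
    "conditional_reproduction",
    "NotEvaluable",
    "TABLE3_CLAUSES",
    "TABLE4_CLAUSES",
    "PUBLISHED_KNN_EXPERIMENTS",
]

logger = logging.getLogger("clauseminer")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


# -- published clause tables (second- and third-order models) ----------------
# Feature names are normalized to hemi_region_measure.

TABLE3_CLAUSES: list[dict] = [
    {"cc": 113, "conjuncts": {"lh_posteriorcingulate_volume": (3500, 4600),
                              "lh_rostralmiddlefrontal_volume": (20000, 25000)}},
    {"cc": 679, "conjuncts": {"lh_posteriorcingulate_volume": (3500, 4600),
                              "rh_rostralmiddlefrontal_volume": (21000, 26000)}},
    {"cc": 1449, "conjuncts": {"lh_posteriorcingulate_volume": (3500, 4600),
                               "lh_medialorbitofrontal_thickness": (2.6, 2.8)}},
    {"cc": 2199, "conjuncts": {"lh_posteriorcingulate_volume": (3500, 4600),
                               "rh_rostralmiddlefrontal_area": (6400, 8500)}},
    {"cc": 887, "conjuncts": {"rh_isthmuscingulate_volume": (3300, 4100),
                              "rh_posteriorcingulate_volume": (4100, 6200)}},
    {"cc": 1488, "conjuncts": {"rh_isthmuscingulate_volume": (3300, 4100),
                               "lh_medialorbitofrontal_thickness": (2.6, 2.8)}},
    {"cc": 2200, "conjuncts": {"rh_isthmuscingulate_volume": (3300, 4100),
                               "rh_rostralmiddlefrontal_area": (6400, 8500)}},
    {"cc": 2269, "conjuncts": {"rh_isthmuscingulate_volume": (3300, 4100),
                               "rh_posteriorcingulate_area": (1400, 2900)}},
]

TABLE4_CLAUSES: list[dict] = [
    {"cc": 46, "conjuncts": {"tomtb_total": (5, 13),
                             "tomi2_early_subscale_mean": (12, 18),
                             "lh_parsorbitalis_meancurv": (0.17, 0.2)}},
    {"cc": 191, "conjuncts": {"tomtb_total": (5, 13),
                              "tomi2_early_subscale_mean": (12, 18),
                              "rh_superiorparietal_thickness": (2.4, 2.7)}},
    {"cc": 264, "conjuncts": {"tomtb_total": (5, 13),
                              "tomi2_early_subscale_mean": (12, 18),
                              "rh_parsorbitalis_meancurv": (0.18, 0.2)}},
    {"cc": 317, "conjuncts": {"tomtb_total": (5, 13),
                              "tomi2_early_subscale_mean": (12, 18),
                              "rh_inferiortemporal_meancurv": (0.15, 0.18)}},
    {"cc": 1163, "conjuncts": {"tomtb_total": (5, 13),
                               "tomi2_total_composite_mean": (9, 18),
                               "lh_postcentral_thickness": (2.2, 2.5)}},
    {"cc": 1446, "conjuncts": {"tomtb_total": (5, 13),
                               "tomi2_early_subscale_mean": (12, 18),
                               "lh_medialorbitofrontal_thickness": (2.6, 2.8)}},
]

BEHAVIORAL_TRIO = ["tomtb_total", "tomi2_total_composite_mean", "tomi2_early_subscale_mean"]

# (name, feature-set builder key, k, published LOOCV accuracy %)
PUBLISHED_KNN_EXPERIMENTS = [
    ("second_order", "table3_union", 3, 89.29),
    ("third_order", "table4_union", 7, 78.57),
    ("second_order_plus_behavioral", "table3_union_plus_behavioral", 2, 85.71),
]


def published_clauses(table_rows: Sequence[dict]) -> list[tuple[ConjunctiveClause, None]]:
    out = []
    for row in table_rows:
        clause = ConjunctiveClause(
            {f: Interval(float(lo), float(hi)) for f, (lo, hi) in row["conjuncts"].items()}
        )
        out.append((clause, None))
    return out


def unique_feature_union(
    models: Sequence[tuple[ConjunctiveClause, ClauseMetrics | None]],
    extra: Sequence[str] = (),
) -> list[str]:
    """Deduplicated union of all conjunct features across models, in
    first-appearance order, followed by extras not already present."""
    if not models and not extra:
        raise ValueError("need at least one model or one extra feature")
    seen: list[str] = []
    for clause, _ in models:
        for name in clause.feature_names:
            if name not in seen:
                seen.append(name)
    for name in extra:
        if name not in seen:
            seen.append(name)
    return seen


# -- configuration -----------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; YAML-loadable; one root seed."""

    input_csv: str | None = None
    input_schema: dict | None = None
    synthetic: dict | None = None
    target_class: str = "ASD"
    discovery_ids: list[str] | None = None
    ccea: dict = field(default_factory=dict)
    selections: list[dict] = field(
        default_factory=lambda: [{"order": 2, "top_m": 8}, {"order": 3, "top_m": 6}]
    )
    experiments: list[dict] = field(default_factory=list)
    train_ids: list[str] | None = None
    output_dir: str | None = None
    make_plots: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "input_csv": self.input_csv,
            "input_schema": self.input_schema,
            "synthetic": self.synthetic,
            "target_class": self.target_class,
            "discovery_ids": self.discovery_ids,
            "ccea": dict(self.ccea),
            "selections": [dict(s) for s in self.selections],
            "experiments": [dict(e) for e in self.experiments],
            "train_ids": self.train_ids,
            "output_dir": self.output_dir,
            "make_plots": self.make_plots,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _rules_from_config(raw: Sequence[Mapping], target_label: str) -> tuple[PlantedRule, ...]:
    rules = []
    for r in raw:
        conj = {f: Interval(float(lo), float(hi)) for f, (lo, hi) in r["conjuncts"].items()}
        rules.append(PlantedRule(conj, target_class=r.get("target_class", target_label)))
    return tuple(rules)


@dataclass
class RunReport:
    """Every number the pipeline computed, plus provenance to recompute it."""

    config_hash: str
    seed: int
    cohort: dict
    clauses: list[dict]
    selections: dict[str, list[dict]]
    feature_unions: dict[str, list[str]]
    experiments: list[dict]
    ground_truth: dict | None = None
    generated_at: str = ""

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "generated_at": self.generated_at,
            "cohort": self.cohort,
            "clauses": self.clauses,
            "selections": self.selections,
            "feature_unions": self.feature_unions,
            "experiments": self.experiments,
            "ground_truth": self.ground_truth,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# -- stages ------------------------------------------------------------------


def _load_table(config: PipelineConfig) -> tuple[FeatureTable, dict | None]:
    if config.input_csv is not None:
        schema = config.input_schema or {}
        schema.setdefault("target_class", config.target_class)
        return read_feature_table(config.input_csv, schema), None
    if config.synthetic is not None:
        raw = dict(config.synthetic)
        raw.setdefault("seed", config.seed)
        raw.setdefault("target_label", config.target_class)
        planted = _rules_from_config(raw.pop("planted", []), raw["target_label"])
        spec = SyntheticSpec(planted=planted, **raw)
        table, rules = generate_cohort(spec)
        gt = {
            "rules": [
                {"target_class": r.target_class,
                 "conjuncts": {f: [iv.lower, iv.upper] for f, iv in r.conjuncts}}
                for r in rules
            ],
            "seed": spec.seed,
        }
        return table, gt
    raise PipelineError("stage load: config provides neither input_csv nor synthetic")


def _resolve_features(
    source: str | Sequence[str],
    unions: Mapping[str, list[str]],
    extra: Sequence[str],
) -> list[str]:
    if isinstance(source, str):
        if source not in unions:
            raise PipelineError(
                f"stage experiments: unknown feature-set source {source!r}; "
                f"available: {sorted(unions)}"
            )
        base = list(unions[source])
    else:
        base = list(source)
    for name in extra:
        if name not in base:
            base.append(name)
    return base


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order; deterministic given the config."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.strftime("%Y-%m-%dT%H:%M:%S")
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, exc: Exception):
        if out_dir:
            (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # stage 1: load / synthesize and split off the discovery cohort
    try:
        table, ground_truth = _load_table(config)
        if config.discovery_ids:
            discovery, holdout = split_subjects(table, config.discovery_ids)
        else:
            discovery, holdout = table, None
        logger.info(
            "cohort: %d subjects (%s), discovery %d",
            table.n_subjects, table.class_counts(), discovery.n_subjects,
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage tagging
        fail("split", e)

    # stage 2: clause discovery
    try:
        ccea_cfg = CCEAConfig(seed=config.seed, **config.ccea)
        archive = run_ccea(discovery, config.target_class, ccea_cfg)
        logger.info("archive: %d clauses at orders %s", len(archive), archive.orders())
    except Exception as e:  # noqa: BLE001
        fail("ccea", e)

    # stage 3: parsimonious selection per order
    selections: dict[str, list[dict]] = {}
    selected_models: dict[int, list] = {}
    try:
        for sel in config.selections:
            order, top_m = int(sel["order"]), int(sel["top_m"])
            models = select_parsimonious(archive, order, top_m)
            selected_models[order] = models
            selections[f"order{order}"] = [
                {"clause": str(c), "conjuncts": {f: [iv.lower, iv.upper]
                                                 for f, iv in c.conjuncts},
                 "fitness": m.fitness, "ppv": m.ppv, "coverage": m.class_coverage}
                for c, m in models
            ]
    except Exception as e:  # noqa: BLE001
        fail("select", e)

    # stage 4: feature unions
    unions: dict[str, list[str]] = {}
    try:
        kind_of = {f.name: f.kind for f in table.features}
        for order, models in selected_models.items():
            if models:
                unions[f"order{order}_union"] = unique_feature_union(models)
        if "order2_union" in unions:
            behavioral = []
            for order, models in selected_models.items():
                if order == 2:
                    continue
                for c, _ in models:
                    behavioral.extend(
                        f for f in c.feature_names if kind_of.get(f) == "behavioral"
                    )
            unions["combined_union"] = unique_feature_union(
                selected_models.get(2, []), extra=list(dict.fromkeys(behavioral))
            )
    except Exception as e:  # noqa: BLE001
        fail("union", e)

    # stages 5-6: KNN experiments (LOOCV on all subjects; optional train/test)
    experiments: list[dict] = []
    try:
        for exp in config.experiments:
            feats = _resolve_features(exp["features"], unions, exp.get("extra", []))
            knn_cfg = KNNConfig(
                k=int(exp.get("k", 3)),
                distance=exp.get("distance", "euclidean"),
                scaling=exp.get("scaling", "zscore"),
            )
            sub = subset_features(table, feats)
            cm, preds = loocv(sub, knn_cfg)
            record: dict[str, Any] = {
                "name": exp.get("name", str(exp["features"])),
                "features": feats,
                "k": knn_cfg.k,
                "scaling": knn_cfg.scaling,
                "distance": knn_cfg.distance,
                "loocv": {"confusion": cm.as_dict(), **matrix_metrics(cm)},
                "loocv_predictions": preds,
            }
            if config.train_ids:
                train, test = split_subjects(sub, config.train_ids)
                cm2, preds2 = train_test_classify(train, test, knn_cfg)
                record["train_test"] = {"confusion": cm2.as_dict(), **matrix_metrics(cm2)}
                record["test_predictions"] = preds2
            experiments.append(record)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        fail("knn", e)

    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        cohort={
            "n_subjects": table.n_subjects,
            "class_counts": table.class_counts(),
            "n_features": table.n_features,
            "discovery_n": discovery.n_subjects,
            "holdout_n": holdout.n_subjects if holdout is not None else 0,
        },
        clauses=archive.to_records(),
        selections=selections,
        feature_unions=unions,
        experiments=experiments,
        ground_truth=ground_truth,
        generated_at=t0,
    )

    if out_dir:
        try:
            _write_outputs(report, table, archive, config, out_dir)
        except Exception as e:  # noqa: BLE001
            fail("report", e)
    return report


def _write_outputs(
    report: RunReport,
    table: FeatureTable,
    archive: ClauseArchive,
    config: PipelineConfig,
    out_dir: Path,
) -> None:
    (out_dir / "report.json").write_text(report.to_json())
    (out_dir / "clauses.json").write_text(json.dumps(archive.to_records(), indent=2))
    (out_dir / "clauses_table.txt").write_text(_clauses_table_text(archive))
    lines = ["experiment,k,scaling,tp,fn,fp,tn,accuracy"]
    for exp in report.experiments:
        cm = exp["loocv"]["confusion"]
        lines.append(
            f"{exp['name']},{exp['k']},{exp['scaling']},"
            f"{cm['tp']},{cm['fn']},{cm['fp']},{cm['tn']},"
            f"{exp['loocv']['accuracy']:.4f}"
        )
    (out_dir / "knn_results.csv").write_text("\n".join(lines) + "\n")
    if config.synthetic is not None:
        write_feature_table(table, str(out_dir / "cohort.csv"))
    if config.make_plots:
        from .plotting import plot_clause_regions

        drawable = [
            (e.clause, e.metrics)
            for order in (2, 3)
            for e in archive.at_order(order)[:1]
        ]
        if drawable:
            plot_clause_regions(drawable, table, out_dir / "plots")


def _clauses_table_text(archive: ClauseArchive) -> str:
    lines = []
    for order in archive.orders():
        lines.append(f"== order {order} ==")
        lines.append(f"{'CC':>4}  {'fitness':>8}  {'PPV':>6}  {'cov':>6}  clause")
        for i, e in enumerate(archive.at_order(order), start=1):
            m = e.metrics
            lines.append(
                f"{i:>4}  {m.fitness:8.4f}  {m.ppv:6.3f}  {m.class_coverage:6.3f}  "
                + " AND ".join(f"{n} [{iv.lower:g},{iv.upper:g}]" for n, iv in e.clause.conjuncts)
            )
        lines.append("")
    return "\n".join(lines)


# -- conditional reproduction of the published accuracies --------------------


@dataclass(frozen=True)
class NotEvaluable:
    """Marker: the published-accuracy check could not be run, and why."""

    reason: str


def conditional_reproduction(
    data: FeatureTable | str | Path | None,
    schema: Mapping | None = None,
    scaling: str = "zscore",
    distance: str = "euclidean",
) -> dict[str, dict] | NotEvaluable:
    """Re-run the published LOOCV experiments on a subject-level data file.

    The three experiments use the published feature unions (8 second-
    order features, 9 third-order features, 11 combined) with their
    published k values (3, 7, 2).  Requires a table containing all the
    named columns (normalized ``hemi_region_measure`` / behavioral
    names); returns :class:`NotEvaluable` when no usable table is
    supplied, since the deposited supplementary files are not
    distributed with this package.
    """
    if data is None:
        return NotEvaluable("no subject-level data file supplied")
    if not isinstance(data, FeatureTable):
        path = Path(data)
        if not path.exists():
            return NotEvaluable(f"data file {path} does not exist")
        try:
            data = read_feature_table(str(path), schema or {
                "subject_col": "subject_id", "outcome_col": "label",
                "target_class": "ASD",
            })
        except Exception as e:  # noqa: BLE001
            return NotEvaluable(f"data file could not be parsed as a feature table: {e}")

    t3 = unique_feature_union(published_clauses(TABLE3_CLAUSES))
    t4 = unique_feature_union(published_clauses(TABLE4_CLAUSES))
    combined = unique_feature_union(published_clauses(TABLE3_CLAUSES), extra=BEHAVIORAL_TRIO)
    feature_sets = {"table3_union": t3, "table4_union": t4,
                    "table3_union_plus_behavioral": combined}

    missing = sorted(
        {f for fs in feature_sets.values() for f in fs} - set(data.feature_names)
    )
    if missing:
        return NotEvaluable(
            f"data table lacks required feature columns (e.g. {missing[:3]})"
        )

    results = {}
    for name, source, k, published_acc in PUBLISHED_KNN_EXPERIMENTS:
        sub = subset_features(data, feature_sets[source])
        cm, _ = loocv(sub, KNNConfig(k=k, scaling=scaling, distance=distance))
        results[name] = {
            "k": k,
            "n_features": sub.n_features,
            "accuracy_pct": 100.0 * cm.accuracy,
            "published_accuracy_pct": published_acc,
            "confusion": cm.as_dict(),
        }
    return results
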