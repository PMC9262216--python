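"""Minimal clause-region visualizations.

Second-order clauses plot as a 2-D scatter of subjects on the clause's
two feature axes with the clause rectangle overlaid; third-order clauses
as a 3-D scatter with the clause cuboid's edges.  For a perfect clause
every target-class subject falls inside the region.  Higher orders have
no such direct picture and are refused.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .clauses import ClauseMetrics, ConjunctiveClause
from .feature_table import FeatureTable

__all__ = ["plot_clause_regions"]


def plot_clause_regions(
    models: Sequence[tuple[ConjunctiveClause, ClauseMetrics | None]],
    table: FeatureTable,
    output_dir: str | Path,
    prefix: str = "clause",
) -> list[Path]:
    """Write one PNG per clause; returns the written paths.

    Raises :class:`ValueError` for clause orders other than 2 or 3.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for idx, (clause, _metrics) in enumerate(models, start=1):
        if clause.order not in (2, 3):
            raise ValueError(
                f"clause of order {clause.order} cannot be drawn as a rectangle/cuboid"
            )
        path = out / f"{prefix}_{idx:02d}_order{clause.order}.png"
        if clause.order == 2:
            _plot_2d(clause, table, path)
        else:
            _plot_3d(clause, table, path)
        paths.append(path)
    return paths


def _split_xy(table: FeatureTable, name: str):
    col = table.column(name)
    tgt = table.target_mask
    return col[tgt], col[~tgt]


def _plot_2d(clause: ConjunctiveClause, table: FeatureTable, path: Path) -> None:
    (fx, ivx), (fy, ivy) = clause.conjuncts
    fig, ax = plt.subplots(figsize=(5, 4))
    x_t, x_o = _split_xy(table, fx)
    y_t, y_o = _split_xy(table, fy)
    ax.scatter(x_o, y_o, c="tab:blue", label=f"other ({table.n_subjects - table.n_target})")
    ax.scatter(x_t, y_t, c="tab:green", label=f"{table.target_class} ({table.n_target})")
    ax.add_patch(
        Rectangle(
            (ivx.lower, ivy.lower), ivx.upper - ivx.lower, ivy.upper - ivy.lower,
            fill=False, edgecolor="crimson", linewidth=1.5,
        )
    )
    ax.set_xlabel(fx)
    ax.set_ylabel(fy)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_3d(clause: ConjunctiveClause, table: FeatureTable, path: Path) -> None:
    (fx, ivx), (fy, ivy), (fz, ivz) = clause.conjuncts
    fig = plt.figure(figsize=(5.5, 4.5))
    ax = fig.add_subplot(projection="3d")
    tgt = table.target_mask
    cols = [table.column(f) for f in (fx, fy, fz)]
    ax.scatter(*(c[~tgt] for c in cols), c="tab:blue", label="other")
    ax.scatter(*(c[tgt] for c in cols), c="tab:green", label=table.target_class)
    corners = list(itertools.product(
        (ivx.lower, ivx.upper), (ivy.lower, ivy.upper), (ivz.lower, ivz.upper)
    ))
    for a, b in itertools.combinations(corners, 2):
        if sum(u != v for u, v in zip(a, b)) == 1:  # cuboid edge
            ax.plot(*zip(a, b), c="crimson", linewidth=1.0)
    ax.set_xlabel(fx, fontsize=7)
    ax.set_ylabel(fy, fontsize=7)
    ax.set_zlabel(fz, fontsize=7)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=110)
    plt.close(fig)
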