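"""Quadrant scatter plots of influence vs difficulty.

One plot per behaviour: influence group rank on the horizontal axis
(further right = more influential), difficulty group rank on the vertical
axis (higher = less difficult), so the most desirable barrier to target
sits in the top-right corner.  Exactly coincident barriers are offset by a
small deterministic jitter (derived from a hash of the barrier id, never
from a random source, so figures are reproducible) and flagged as tied.
"""

from __future__ import annotations

import hashlib
import math
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe; no-op if already set

import matplotlib.pyplot as plt
import pandas as pd

from .catalogue import ValidationError
from .desirability import DESIRABLE, LEAST, MOST, AttributePoint, DesirabilityResult

__all__ = ["scatter_coordinates", "plot_behaviour", "plot_results"]

#: maximum jitter radius applied to coincident points, in rank units
JITTER_RADIUS = 0.12

_STYLE = {
    MOST: dict(marker="*", color="#2ca02c", s=220, label="most desirable"),
    DESIRABLE: dict(marker="o", color="#1f77b4", s=70, label="desirable"),
    LEAST: dict(marker="x", color="#d62728", s=70, label="least desirable"),
}


def _hash_angle(barrier_id: str) -> float:
    digest = hashlib.md5(barrier_id.encode()).hexdigest()
    return 2.0 * math.pi * (int(digest[:8], 16) / 0xFFFFFFFF)


def scatter_coordinates(points: Sequence[AttributePoint]) -> pd.DataFrame:
    """Plotted coordinates before rendering (testable contract).

    Columns: ``barrier_id, x, y, tied``.  Coordinates equal the group
    ranks except for coincident points, which are offset on a circle of
    radius :data:`JITTER_RADIUS` (< 0.15) at a deterministic
    barrier-id-hash angle and flagged ``tied=True``.
    """
    by_coord: dict[tuple[int, int], list[AttributePoint]] = {}
    for p in points:
        by_coord.setdefault((p.influence_rank, p.difficulty_rank), []).append(p)
    rows = []
    for (x, y), group in by_coord.items():
        tied = len(group) > 1
        for p in group:
            dx = dy = 0.0
            if tied:
                angle = _hash_angle(p.barrier_id)
                dx = JITTER_RADIUS * math.cos(angle)
                dy = JITTER_RADIUS * math.sin(angle)
            rows.append(
                {"barrier_id": p.barrier_id, "x": x + dx, "y": y + dy,
                 "tied": tied}
            )
    df = pd.DataFrame(rows, columns=["barrier_id", "x", "y", "tied"])
    return df.sort_values("barrier_id", ignore_index=True)


def plot_behaviour(
    result: DesirabilityResult,
    points: Sequence[AttributePoint],
    out,
    title: str = "",
) -> None:
    """Render one behaviour's quadrant scatter to *out* (.png or .svg)."""
    ids_points = {p.barrier_id for p in points}
    if ids_points != set(result.labels):
        raise ValidationError(
            "points and desirability labels cover different barriers"
        )
    coords = scatter_coordinates(points).set_index("barrier_id")
    n = len(points)
    lo, hi = 0.5, n + 0.5
    mid = (n + 1) / 2.0

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.axvline(mid, color="0.85", lw=1, zorder=0)
    ax.axhline(mid, color="0.85", lw=1, zorder=0)
    for label in (LEAST, DESIRABLE, MOST):
        ids = [b for b in result.labels if result.labels[b] == label]
        if not ids:
            continue
        sub = coords.loc[ids]
        ax.scatter(sub["x"], sub["y"], zorder=2, **_STYLE[label])
    for barrier_id, row in coords.iterrows():
        text = barrier_id + (" (tied)" if row["tied"] else "")
        ax.annotate(
            text, (row["x"], row["y"]), textcoords="offset points",
            xytext=(6, 6), fontsize=8,
        )
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xticks(range(1, n + 1))
    ax.set_yticks(range(1, n + 1))
    ax.set_xlabel("Group rank: influence (higher = more influential)")
    ax.set_ylabel("Group rank: difficulty (higher = less difficult)")
    if title:
        ax.set_title(title, fontsize=10)
    ax.legend(loc="lower left", fontsize=8, frameon=True)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


def plot_results(
    results: Iterable[DesirabilityResult],
    group_rankings,
    outdir,
    fmt: str = "png",
    names: dict[str, str] | None = None,
) -> list:
    """One file per behaviour under *outdir*; returns the written paths."""
    from pathlib import Path

    from .desirability import points_from_rankings

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_behaviour: dict[str, dict[str, object]] = {}
    for g in group_rankings:
        by_behaviour.setdefault(g.behaviour_id, {})[g.attribute] = g
    written = []
    for result in results:
        slot = by_behaviour[result.behaviour_id]
        points = points_from_rankings(slot["influence"], slot["difficulty"])
        path = outdir / f"behaviour_{result.behaviour_id}.{fmt}"
        title = (names or {}).get(result.behaviour_id, "")
        plot_behaviour(result, points, path, title=title)
        written.append(path)
    return written
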