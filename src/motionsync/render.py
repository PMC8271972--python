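"""Static renderings: arc diagram, mirrored comparison, band summaries,
projection scatter.

All renderers are pure functions of their inputs and write deterministic
SVG (or any format matplotlib infers from the path suffix).  Colors follow
the clinical convention used throughout: red for stroke, green for
control, gray for shared, black for a highlighted individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .descriptors import GroupSummary
from .errors import InvalidInputError

plt.rcParams["svg.hashsalt"] = "motionsync"

COLOR = {"stroke-only": "#c62828", "control-only": "#2e7d32", "shared": "#757575"}
GROUP_COLOR = {"stroke": "#c62828", "control": "#2e7d32"}


@dataclass
class ArcDiagramSpec:
    """Arc-view input: angle labels in display order, plus arcs.

    Each arc is (pair, support, color_class) where pair indexes into
    ``labels`` and color_class is one of "stroke-only", "control-only",
    "shared".
    """

    labels: list[str]
    arcs: list[tuple[tuple[int, int], int, str]]

    def __post_init__(self) -> None:
        n = len(self.labels)
        for (i, j), support, cls in self.arcs:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise InvalidInputError(f"arc ({i}, {j}) references unknown angles")
            if cls not in COLOR:
                raise InvalidInputError(f"unknown color class {cls!r}")
            if support < 1:
                raise InvalidInputError("arc support must be >= 1")


def _save(fig, path) -> None:
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def render_arc_diagram(spec: ArcDiagramSpec, path) -> None:
    """One semicircular arc per pair; thickness grows with support."""
    n = len(spec.labels)
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * n), 4))
    xs = np.arange(n)
    max_support = max((s for _, s, _ in spec.arcs), default=1)
    theta = np.linspace(0, np.pi, 100)
    for (i, j), support, cls in sorted(spec.arcs):
        lo, hi = min(i, j), max(i, j)
        center, radius = (lo + hi) / 2.0, (hi - lo) / 2.0
        lw = 0.8 + 3.2 * support / max_support
        line = ax.plot(
            center + radius * np.cos(theta),
            radius * np.sin(theta),
            color=COLOR[cls],
            lw=lw,
            solid_capstyle="round",
        )[0]
        line.set_gid(f"motionsync-arc-{lo}-{hi}")
    ax.plot(xs, np.zeros(n), "o", color="#37474f", ms=5, zorder=3)
    ax.set_xticks(xs)
    ax.set_xticklabels(spec.labels, rotation=60, ha="right", fontsize=7)
    ax.set_yticks([])
    for side in ("left", "right", "top"):
        ax.spines[side].set_visible(False)
    ax.set_ylim(-0.5, max(1.0, n / 2 + 0.5))
    fig.tight_layout()
    _save(fig, path)


def render_mirrored_comparison(
    summary_a: GroupSummary,
    summary_b: GroupSummary,
    path,
    individual=None,
    individual_group: str = "stroke",
    mode: str = "SameLength",
) -> None:
    """Group A upright, group B mirrored below the time axis.

    In Proportional mode each group's horizontal extent is scaled by its
    mean original duration; an optional individual trace is overlaid
    un-mirrored on its group's half.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    for summary, sign in ((summary_a, 1.0), (summary_b, -1.0)):
        m = summary.mean_curve
        sd = summary.sd_curve
        if mode == "Proportional":
            x = np.linspace(0, summary.display_length, m.size)
        else:
            x = np.arange(m.size)
        color = GROUP_COLOR.get(summary.group, "#555555")
        ax.plot(x, sign * m, color=color, lw=1.5, label=summary.group or None)
        ax.fill_between(x, sign * (m - sd), sign * (m + sd), color=color, alpha=0.25)
    if individual is not None:
        vals = np.asarray(getattr(individual, "values", individual), dtype=float)
        sign = 1.0 if individual_group == summary_a.group else -1.0
        ref = summary_a if sign > 0 else summary_b
        if mode == "Proportional":
            x = np.linspace(0, ref.display_length, vals.size)
        else:
            x = np.arange(vals.size)
        ax.plot(x, sign * vals, color="black", lw=1.0)
    ax.axhline(0.0, color="#999999", lw=0.8)
    ax.set_xlabel("time step" if mode != "Proportional" else "time (samples, original)")
    ax.set_ylabel("angle (deg; lower half mirrored)")
    if summary_a.group or summary_b.group:
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    _save(fig, path)


def render_band_summary(panels, path, highlight: dict | None = None) -> None:
    """Per-angle mean +/- sd bands for two groups.

    ``panels`` is an ordered list of (angle_label, summary_a, summary_b);
    callers are expected to order it by display rank.  ``highlight``
    optionally maps angle_label -> individual trace (drawn black).
    """
    if not panels:
        raise InvalidInputError("band summary needs at least one panel")
    ncols = min(4, len(panels))
    nrows = int(np.ceil(len(panels) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False
    )
    for k, (label, sa, sb) in enumerate(panels):
        ax = axes[k // ncols][k % ncols]
        for summary in (sa, sb):
            m, sd = summary.mean_curve, summary.sd_curve
            x = np.arange(m.size)
            color = GROUP_COLOR.get(summary.group, "#555555")
            ax.plot(x, m, color=color, lw=1.2)
            ax.fill_between(x, m - sd, m + sd, color=color, alpha=0.25)
        if highlight and label in highlight:
            vals = np.asarray(getattr(highlight[label], "values", highlight[label]))
            ax.plot(np.arange(len(vals)), vals, color="black", lw=0.9)
        ax.set_title(label, fontsize=8)
        ax.tick_params(labelsize=7)
    for k in range(len(panels), nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.tight_layout()
    _save(fig, path)


def render_projection(coords: pd.DataFrame, path) -> None:
    """Scatter of 2-D coordinates with group colors and impairment sizing.

    ``coords`` needs columns participant, x, y, group and optionally
    fma_total.  Marker radius decreases affinely with the Fugl-Meyer total
    over the observed range, so the most impaired individuals draw the
    largest circles; missing scores fall back to a default radius with a
    warning.
    """
    required = {"participant", "x", "y", "group"}
    if not required.issubset(coords.columns):
        raise InvalidInputError(f"coords must have columns {sorted(required)}")
    fma = coords.get("fma_total")
    smin, smax = 30.0, 200.0
    if fma is not None and fma.notna().any():
        lo, hi = float(fma.min()), float(fma.max())
    else:
        lo = hi = None
    fig, ax = plt.subplots(figsize=(5, 5))
    for _, row in coords.sort_values("participant").iterrows():
        size = 0.5 * (smin + smax)
        if lo is not None:
            val = row.get("fma_total")
            if pd.isna(val):
                warnings.warn(
                    f"participant {row['participant']!r} has no FMA total; "
                    "using default marker size"
                )
            elif hi > lo:
                size = smax - (smax - smin) * (float(val) - lo) / (hi - lo)
            else:
                size = smin
        ax.scatter(
            row["x"],
            row["y"],
            s=size,
            color=GROUP_COLOR.get(row["group"], "#555555"),
            alpha=0.75,
            edgecolors="white",
            linewidths=0.5,
        )
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    _save(fig, path)
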