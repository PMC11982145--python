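"""Center-anchored Sankey flow sets and baseline -> on-treatment cross-tables.

The Sankey layout pools both arms' baseline categories in a center column,
severity-descending (Hy's Law topmost).  Each arm's subjects flow outward to
their on-treatment peak category: comparator/placebo to the left, active
drug to the right.  Upward shifts (potential DILI) render pink, downward
shifts (potential efficacy) green, no-change flat grey, and lateral shifts
yellow.  Ribbon widths are within-arm *proportions* by default so that a
1:3 randomization stays visually comparable (absolute-count mode by flag).

Cross-tables give the numeric tallies: rows = origin category, columns =
destination, with the same color classes (red = upward, green = downward,
grey = none, yellow = lateral).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .categorize import BandingScheme, classify_shift
from .trial_data import TrialManifest

COLOR_CLASS = {"upward": "red", "downward": "green", "none": "grey", "lateral": "yellow"}
RIBBON_COLOR = {"upward": "#f4a6b8", "downward": "#9fd9a8", "none": "#d9d9d9", "lateral": "#f2e39a"}

__all__ = [
    "SankeyFlowSet",
    "CrossTable",
    "build_flows",
    "build_cross_table",
    "upward_shift_summary",
    "render_sankey",
]


@dataclass
class CrossTable:
    """Per-arm matrix of baseline -> on-treatment category counts."""

    arm: str
    counts: pd.DataFrame  # rows = origin, cols = destination, int counts
    color_classes: pd.DataFrame  # same shape; red/green/grey/yellow

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def red_total(self) -> int:
        return int(self.counts.to_numpy()[(self.color_classes == "red").to_numpy()].sum())

    def red_paths(self) -> int:
        red = (self.color_classes == "red").to_numpy() & (self.counts.to_numpy() > 0)
        return int(red.sum())

    def to_csv(self, path: str | Path) -> Path:
        """Long-format export: origin, destination, count, color_class."""
        path = Path(path)
        long = (
            self.counts.stack().rename("count").reset_index()
            .merge(
                self.color_classes.stack().rename("color_class").reset_index(),
                on=["origin", "destination"],
            )
        )
        long.insert(0, "arm", self.arm)
        long.to_csv(path, index=False)
        return path


@dataclass
class SankeyFlowSet:
    """Flows for the two-arm, center-anchored Sankey."""

    baseline_counts: pd.Series  # pooled over arms, severity-descending index
    left_flows: pd.DataFrame  # comparator arm: origin, destination, count, direction
    right_flows: pd.DataFrame  # active arm
    left_arm: str = "placebo"
    right_arm: str = "active"
    category_order: list[str] = field(default_factory=list)


def _flow_frame(shifts: pd.DataFrame, order: list[str]) -> pd.DataFrame:
    if shifts.empty:
        return pd.DataFrame(columns=["origin", "destination", "count", "direction"])
    grp = (
        shifts.groupby(["origin", "destination", "direction"]).size().rename("count").reset_index()
    )
    grp["origin"] = pd.Categorical(grp["origin"], categories=order, ordered=True)
    grp["destination"] = pd.Categorical(grp["destination"], categories=order, ordered=True)
    grp = grp.sort_values(["origin", "destination"]).reset_index(drop=True)
    return grp[["origin", "destination", "count", "direction"]]


def build_flows(
    shift_records: pd.DataFrame,
    manifest: TrialManifest,
    scheme: BandingScheme | None = None,
) -> SankeyFlowSet:
    """Aggregate per-subject shift records into the two-arm flow set.

    Conservation holds by construction: for each arm and baseline category,
    the flow counts out of that category sum to the arm's subject count in
    the category (no-change subjects appear as flat flows).

    Raises
    ------
    ValueError
        If a record's arm label is not in the manifest.
    """
    scheme = scheme or BandingScheme()
    order = [c.name for c in scheme.categories()]
    known = set(manifest.arms)
    bad = set(shift_records["arm"].unique()) - known
    if bad:
        raise ValueError(f"arm label(s) not in manifest: {sorted(bad)}")
    left = shift_records[shift_records["arm"] == manifest.comparator_arm]
    right = shift_records[shift_records["arm"] == manifest.active_arm]
    baseline = (
        shift_records["origin"].value_counts().reindex(order, fill_value=0).rename("count")
    )
    return SankeyFlowSet(
        baseline_counts=baseline,
        left_flows=_flow_frame(left, order),
        right_flows=_flow_frame(right, order),
        left_arm=manifest.comparator_arm,
        right_arm=manifest.active_arm,
        category_order=order,
    )


def build_cross_table(
    shift_records: pd.DataFrame, arm: str, scheme: BandingScheme | None = None
) -> CrossTable:
    """Tally one arm's shifts into an origin x destination count matrix."""
    scheme = scheme or BandingScheme()
    cats = {c.name: c for c in scheme.categories()}
    order = list(cats)
    sub = shift_records[shift_records["arm"] == arm]
    counts = pd.crosstab(sub["origin"], sub["destination"]).reindex(
        index=order, columns=order, fill_value=0
    ).astype(int)
    counts.index.name = "origin"
    counts.columns.name = "destination"
    colors = pd.DataFrame(
        [[COLOR_CLASS[classify_shift(cats[o], cats[d])] for d in order] for o in order],
        index=counts.index.copy(),
        columns=counts.columns.copy(),
    )
    return CrossTable(arm=arm, counts=counts, color_classes=colors)


def upward_shift_summary(cross_tables: list[CrossTable]) -> dict[str, dict[str, int]]:
    """Per-arm totals of upward (red) shifts and distinct upward paths."""
    return {
        t.arm: {"total": t.red_total(), "paths": t.red_paths()} for t in cross_tables
    }


# --------------------------------------------------------------------------
# rendering


def _stack_positions(
    counts: pd.Series, denom: float | None = None, gap: float = 0.04
) -> dict[str, tuple[float, float]]:
    """Vertical (bottom, top) spans, severity-descending from y=1 downward.

    ``denom`` defaults to the column's own total (proportional mode); pass
    the pooled trial size for absolute-count mode.
    """
    total = denom if denom else counts.sum()
    spans: dict[str, tuple[float, float]] = {}
    y = 1.0
    n_gaps = max(1, int((counts > 0).sum()) - 1)
    usable = 1.0 - gap * n_gaps
    for name, c in counts.items():
        h = usable * (c / total) if total else 0.0
        spans[name] = (y - h, y)
        if c > 0:
            y -= h + gap
        # zero-count categories collapse to a zero-height span at the cursor
    return spans


def _ribbon(ax, x0, y0a, y0b, x1, y1a, y1b, color):
    """Draw a cubic-Bezier ribbon between two vertical intervals."""
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path as MPath

    xm = (x0 + x1) / 2
    verts = [
        (x0, y0a), (xm, y0a), (xm, y1a), (x1, y1a),
        (x1, y1b), (xm, y1b), (xm, y0b), (x0, y0b), (x0, y0a),
    ]
    codes = [
        MPath.MOVETO, MPath.CURVE4, MPath.CURVE4, MPath.CURVE4,
        MPath.LINETO, MPath.CURVE4, MPath.CURVE4, MPath.CURVE4, MPath.CLOSEPOLY,
    ]
    ax.add_patch(PathPatch(MPath(verts, codes), facecolor=color, edgecolor="none", alpha=0.85))


def _draw_side(ax, flows: pd.DataFrame, center_spans, dest_spans, x_center, x_dest):
    """Lay ribbons from the center column to one destination column.

    Each origin's center-side span is divided among its outgoing flows in
    severity order, and each destination's span among its incoming flows,
    so ribbon thickness is proportional to within-column share.
    """
    if flows.empty:
        return
    rows = flows.to_dict("records")
    out_cursor = {k: v[1] for k, v in center_spans.items()}
    in_cursor = {k: v[1] for k, v in dest_spans.items()}
    origin_totals = flows.groupby("origin", observed=False)["count"].sum()
    dest_totals = flows.groupby("destination", observed=False)["count"].sum()
    for row in rows:
        o, d, n = str(row["origin"]), str(row["destination"]), int(row["count"])
        span_o = center_spans[o][1] - center_spans[o][0]
        span_d = dest_spans[d][1] - dest_spans[d][0]
        h_out = span_o * n / origin_totals[o] if origin_totals[o] else 0.0
        h_in = span_d * n / dest_totals[d] if dest_totals[d] else 0.0
        y0a, y0b = out_cursor[o], out_cursor[o] - h_out
        y1a, y1b = in_cursor[d], in_cursor[d] - h_in
        out_cursor[o] -= h_out
        in_cursor[d] -= h_in
        _ribbon(ax, x_center, y0a, y0b, x_dest, y1a, y1b, RIBBON_COLOR[row["direction"]])


def render_sankey(
    flow_set: SankeyFlowSet,
    path: str | Path,
    proportional: bool = True,
    cross_tables: list[CrossTable] | None = None,
    title: str = "Baseline to on-treatment category shifts",
):
    """Render the center-anchored two-arm Sankey (SVG or PNG).

    ``proportional`` scales each side's destination column by within-arm
    proportions; with ``False`` column heights use absolute counts pooled
    across arms.  When ``cross_tables`` are given, each arm's tally table is
    printed beneath its side of the figure.
    """
    import matplotlib.pyplot as plt

    path = Path(path)
    order = flow_set.category_order
    fig_h = 6.5 if cross_tables else 5.0
    fig, ax = plt.subplots(figsize=(9, fig_h))
    ax.set_xlim(0, 1)
    ax.set_ylim(-0.45 if cross_tables else -0.02, 1.05)
    ax.axis("off")

    center = flow_set.baseline_counts.reindex(order, fill_value=0)
    center_spans = _stack_positions(center)

    def side_counts(flows):
        if flows.empty:
            return pd.Series(0, index=order)
        return flows.groupby("destination", observed=False)["count"].sum().reindex(order, fill_value=0)

    lc, rc = side_counts(flow_set.left_flows), side_counts(flow_set.right_flows)
    if proportional:
        # each side normalized to its own arm size → comparable ribbon fractions
        left_spans = _stack_positions(lc)
        right_spans = _stack_positions(rc)
    else:
        pool = float(center.sum())
        left_spans = _stack_positions(lc, denom=pool)
        right_spans = _stack_positions(rc, denom=pool)

    xl, xc, xr, w = 0.06, 0.47, 0.88, 0.06
    _draw_side(ax, flow_set.left_flows, center_spans, left_spans, xc, xl + w)
    _draw_side(ax, flow_set.right_flows, center_spans, right_spans, xc + w, xr)

    for x, spans, counts in ((xc, center_spans, center), (xl, left_spans, lc), (xr, right_spans, rc)):
        for name in order:
            b, t = spans[name]
            if t - b <= 0:
                continue
            ax.add_patch(plt.Rectangle((x, b), w, t - b, facecolor="#555555", edgecolor="white", lw=0.5))
            ax.text(x + w / 2, (b + t) / 2, f"{name}\n{int(counts[name])}", ha="center",
                    va="center", fontsize=6, color="white")
    ax.text(xl + w / 2, 1.03, flow_set.left_arm, ha="center", fontsize=9)
    ax.text(xc + w, 1.03, "baseline (both arms)", ha="center", fontsize=9)
    ax.text(xr + w / 2, 1.03, flow_set.right_arm, ha="center", fontsize=9)
    ax.set_title(title)

    if cross_tables:
        for i, table in enumerate(cross_tables[:2]):
            x0 = 0.05 + 0.5 * i
            ax.text(x0, -0.06, f"{table.arm} shifts (origin rows, destination cols)", fontsize=7)
            cell_w, cell_h = 0.085, 0.055
            for r, o in enumerate(order):
                for c, d in enumerate(order):
                    y = -0.12 - r * cell_h
                    color = table.color_classes.loc[o, d]
                    face = {"red": "#f4a6b8", "green": "#9fd9a8", "grey": "#e0e0e0", "yellow": "#f2e39a"}[color]
                    ax.add_patch(plt.Rectangle((x0 + c * cell_w, y - cell_h), cell_w, cell_h,
                                               facecolor=face, edgecolor="k", lw=0.3))
                    ax.text(x0 + (c + 0.5) * cell_w, y - cell_h / 2,
                            str(int(table.counts.loc[o, d])), ha="center", va="center", fontsize=6)
                ax.text(x0 - 0.005, -0.12 - (r + 0.5) * cell_h, o, ha="right", va="center", fontsize=6)
            for c, d in enumerate(order):
                ax.text(x0 + (c + 0.5) * cell_w, -0.115, d, ha="center", va="bottom", fontsize=6)

    from .edish import _deterministic_savefig

    fig.tight_layout()
    _deterministic_savefig(fig, path)
    plt.close(fig)
    return path
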