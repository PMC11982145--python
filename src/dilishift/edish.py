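"""eDISH and mDISH scatter coordinates, Hy's Law flagging, composite plots.

eDISH plots each subject's peak on-treatment aminotransferase (x) against
peak total bilirubin (y), both in xULN, with quadrant reference lines at the
banding cuts.  mDISH plots the same peaks in multiples of each subject's own
baseline (xBL); it visualizes shift but deliberately carries no quadrant
lines, since xBL boundaries have no severity meaning (two subjects with
identical xBL ratios can differ ten-fold in absolute values).

Composite plots recover subject identification in abnormal-baseline trials:
one mDISH panel per *destination* quadrant (the xULN category of the peak),
with each subject's marker encoding their *origin* (baseline) quadrant.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .categorize import BandingScheme, QuadrantCategory, assign_quadrant
from .trial_data import SubjectProfile

logger = logging.getLogger(__name__)

#: Fixed origin-category marker encoding, stable across all composite panels.
ORIGIN_MARKERS = {
    "NNN": ("s", "green"),
    "Temple": ("P", "blue"),
    "Cholestasis": ("^", "orange"),
    "HyLaw": ("*", "red"),
}
_FALLBACK_MARKER = ("o", "grey")

#: Display-only floor for zero multiples on log axes; never used in categorization.
DISPLAY_EPS = 0.01

POINT_COLUMNS = ["subject_id", "arm", "x", "y", "origin", "destination"]

__all__ = [
    "edish_points",
    "mdish_points",
    "composite_points",
    "flag_potential_hys_law",
    "render_edish",
    "render_mdish",
    "render_composite",
    "ORIGIN_MARKERS",
]


def _categories_for(p: SubjectProfile, scheme: BandingScheme):
    coords = p.shift_coordinates()
    if coords is None:
        return None
    (b_at, b_tb), (pk_at, pk_tb) = coords
    return (
        assign_quadrant(b_at, b_tb, scheme),
        assign_quadrant(pk_at, pk_tb, scheme),
        (b_at, b_tb),
        (pk_at, pk_tb),
    )


def edish_points(
    profiles: Iterable[SubjectProfile], scheme: BandingScheme | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak-xULN scatter points plus per-arm destination-quadrant counts.

    Returns ``(points, counts)`` where ``points`` has the columns
    subject_id, arm, x (peak AT xULN), y (peak TB xULN), origin, destination
    and ``counts`` is indexed by arm with one column per category.
    """
    scheme = scheme or BandingScheme()
    rows = []
    for p in profiles:
        cats = _categories_for(p, scheme)
        if cats is None:
            continue
        origin, dest, _, (pk_at, pk_tb) = cats
        rows.append({"subject_id": p.subject_id, "arm": p.arm, "x": pk_at, "y": pk_tb,
                     "origin": origin.name, "destination": dest.name})
    points = pd.DataFrame(rows, columns=POINT_COLUMNS)
    names = [c.name for c in scheme.categories()]
    counts = (
        points.groupby("arm")["destination"].value_counts().unstack(fill_value=0)
        .reindex(columns=names, fill_value=0)
        if not points.empty
        else pd.DataFrame(columns=names)
    )
    return points, counts


def mdish_points(
    profiles: Iterable[SubjectProfile], scheme: BandingScheme | None = None
) -> pd.DataFrame:
    """Peak-xBL scatter points (x = peak ALT xBL, y = peak TB xBL).

    Subjects with an undefined xBL for either analyte (zero or missing
    baseline) are excluded with a logged reason.  Categories remain the
    xULN-based origin/destination quadrants so that composite plots can
    filter and mark points.
    """
    scheme = scheme or BandingScheme()
    rows = []
    for p in profiles:
        alt, tb = p.analytes.get("ALT"), p.analytes.get("TB")
        if alt is None or tb is None or alt.peak_xbl is None or tb.peak_xbl is None:
            logger.debug("subject %s excluded from xBL plot (undefined baseline multiple)", p.subject_id)
            continue
        cats = _categories_for(p, scheme)
        if cats is None:
            continue
        origin, dest = cats[0], cats[1]
        rows.append({"subject_id": p.subject_id, "arm": p.arm, "x": alt.peak_xbl,
                     "y": tb.peak_xbl, "origin": origin.name, "destination": dest.name})
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


def composite_points(
    profiles: Iterable[SubjectProfile],
    destination: QuadrantCategory | str,
    scheme: BandingScheme | None = None,
) -> pd.DataFrame:
    """mDISH points restricted to subjects whose peak lands in ``destination``.

    Each point carries its origin category; marker code is a pure function
    of origin (:data:`ORIGIN_MARKERS`), so the legend is stable across the
    per-destination panels.  An empty destination set returns an empty frame.
    """
    scheme = scheme or BandingScheme()
    name = destination.name if isinstance(destination, QuadrantCategory) else destination
    scheme.by_name(name)  # validates the destination exists in this scheme
    pts = mdish_points(profiles, scheme)
    return pts[pts["destination"] == name].reset_index(drop=True)


def flag_potential_hys_law(
    profile: SubjectProfile, scheme: BandingScheme | None = None
) -> tuple[bool, str]:
    """Flag a subject whose peak category is the Hy's Law quadrant.

    The annotation carries the peak ALP xULN when available, for reviewer
    context only — no ALP threshold modifies the flag (cholestatic
    adjudication is a case-level judgement, not a cut-off).
    """
    scheme = scheme or BandingScheme()
    cats = _categories_for(profile, scheme)
    if cats is None:
        return False, "not analyzable (missing AT or TB baseline/peak)"
    dest = cats[1]
    flagged = dest.name == "HyLaw"
    alp = profile.peak_xuln("ALP")
    note = f"destination {dest.name}"
    if alp is not None:
        note += f"; ALP {alp:.1f}xULN"
    return flagged, note


# --------------------------------------------------------------------------
# rendering


def _deterministic_savefig(fig, path: Path) -> None:
    import matplotlib

    matplotlib.rcParams["svg.hashsalt"] = "dilishift"
    kw = {"metadata": {"Date": None}} if path.suffix == ".svg" else {}
    fig.savefig(path, **kw)


def _scatter_by_arm(ax, points: pd.DataFrame, arms: Sequence[str]) -> None:
    palette = {arms[0]: ("tab:blue", "o"), arms[1]: ("tab:red", "^")} if len(arms) == 2 else {}
    for arm, grp in points.groupby("arm"):
        color, marker = palette.get(arm, ("grey", "o"))
        x = grp["x"].clip(lower=DISPLAY_EPS)
        y = grp["y"].clip(lower=DISPLAY_EPS)
        ax.scatter(x, y, s=24, alpha=0.7, color=color, marker=marker, label=str(arm))


def render_edish(
    points: pd.DataFrame,
    path: str | Path,
    scheme: BandingScheme | None = None,
    arms: Sequence[str] = (),
    title: str = "eDISH (peak on-treatment values, xULN)",
):
    """eDISH scatter with quadrant reference lines at the scheme cuts."""
    import matplotlib.pyplot as plt

    scheme = scheme or BandingScheme()
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    arms = list(arms) or sorted(points["arm"].unique()) if not points.empty else list(arms)
    _scatter_by_arm(ax, points, arms)
    ax.axvline(scheme.alt_cut, color="k", lw=0.8)
    ax.axhline(scheme.tb_cut, color="k", lw=0.8)
    if scheme.extra_tb_band:
        ax.axhline(scheme.extra_tb_low, color="k", lw=0.5, ls="--")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("peak AT (xULN)")
    ax.set_ylabel("peak TB (xULN)")
    ax.set_title(title)
    if arms:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    _deterministic_savefig(fig, path)
    plt.close(fig)
    return path


def render_mdish(
    points: pd.DataFrame,
    path: str | Path,
    arms: Sequence[str] = (),
    title: str = "mDISH (peak on-treatment values, xBL)",
):
    """mDISH scatter; no quadrant lines (xBL boundaries carry no severity meaning)."""
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    arms = list(arms) or sorted(points["arm"].unique()) if not points.empty else list(arms)
    _scatter_by_arm(ax, points, arms)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("peak ALT (xBL)")
    ax.set_ylabel("peak TB (xBL)")
    ax.set_title(title)
    if arms:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    _deterministic_savefig(fig, path)
    plt.close(fig)
    return path


def render_composite(
    points: pd.DataFrame,
    destination: str,
    path: str | Path,
):
    """One composite mDISH panel: points marked by origin category."""
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    for origin, grp in points.groupby("origin"):
        marker, color = ORIGIN_MARKERS.get(origin, _FALLBACK_MARKER)
        ax.scatter(grp["x"].clip(lower=DISPLAY_EPS), grp["y"].clip(lower=DISPLAY_EPS),
                   s=60, marker=marker, color=color, label=f"origin {origin}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("peak ALT (xBL)")
    ax.set_ylabel("peak TB (xBL)")
    ax.set_title(f"Composite mDISH — destination {destination} (n={len(points)})")
    if len(points):
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    _deterministic_savefig(fig, path)
    plt.close(fig)
    return path
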