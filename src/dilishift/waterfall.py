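"""Modified waterfall plot of baseline-anchored maximum ALT change.

Applicable in trials that restrict hyperbilirubinemia at enrollment: with no
(or almost no) baseline jaundice, one figure can show the baseline ALT of
every subject, the maximum on-treatment change, and new-onset jaundice, and
so recovers shift visualization, severity categorization (via horizontal
ALT cut-off lines), and case identification at once.

Layout: comparator/placebo subjects on the left ranked by ascending baseline
ALT, active-arm subjects on the right ranked descending, so the black
baseline profile peaks in the middle.  Each subject's bar runs from their
baseline to baseline + bar_value, where bar_value depends on the mode:

* ``max_magnitude`` — the signed on-treatment change of largest magnitude
  (captures efficacy declines, but a DILI rise smaller than the subject's
  own decline is masked);
* ``max_increase`` — max on-treatment ALT minus baseline (never masks a
  rise; the planned DILI-focused variant).

New-onset jaundice (peak TB above the jaundice cut with a non-jaundiced
baseline) colors the bar green regardless of arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .categorize import BandingScheme
from .trial_data import SubjectProfile, TrialManifest

MODES = ("max_magnitude", "max_increase")
DEFAULT_SEVERITY_LINES = (300.0, 600.0, 900.0)

__all__ = [
    "WaterfallEntry",
    "check_applicability",
    "build_waterfall",
    "box_whisker_stats",
    "render_waterfall",
    "entries_to_frame",
]


@dataclass(frozen=True)
class WaterfallEntry:
    subject_id: str
    arm: str
    baseline_alt: float
    bar_value: float  # signed ALT change in U/L, per mode
    new_jaundice: bool
    rank: int


def check_applicability(
    profiles: Iterable[SubjectProfile],
    scheme: BandingScheme | None = None,
    max_baseline_jaundice_fraction: float = 0.02,
) -> tuple[bool, dict]:
    """Is the waterfall meaningful here?  Only if baseline jaundice is rare.

    Returns ``(applicable, report)``; the report names the jaundiced-at-
    baseline subjects so they can be reviewed individually.
    """
    scheme = scheme or BandingScheme()
    offenders = []
    n = 0
    for p in profiles:
        tb = p.baseline_xuln("TB")
        if tb is None:
            continue
        n += 1
        if tb > scheme.tb_cut:
            offenders.append(p.subject_id)
    frac = len(offenders) / n if n else 0.0
    applicable = n > 0 and frac <= max_baseline_jaundice_fraction
    return applicable, {
        "n_subjects": n,
        "baseline_jaundice_fraction": frac,
        "baseline_jaundice_subjects": offenders,
        "threshold": max_baseline_jaundice_fraction,
    }


def _bar_value(s, mode: str) -> float:
    rise = s.peak - s.baseline
    fall = s.trough - s.baseline
    if mode == "max_increase":
        return rise
    # max_magnitude: signed change of largest |.|; ties keep the increase
    # (safety-conservative)
    return rise if abs(rise) >= abs(fall) else fall


def build_waterfall(
    profiles: Iterable[SubjectProfile],
    manifest: TrialManifest,
    mode: str = "max_magnitude",
    scheme: BandingScheme | None = None,
) -> tuple[list[WaterfallEntry], dict[str, dict]]:
    """Order subjects and compute bars; returns (entries, per-arm box stats).

    Placebo entries come first in ascending baseline ALT, then active
    entries in descending baseline ALT (ties broken by subject id), so the
    highest baselines meet in the middle of the plot.
    """
    if mode not in MODES:
        raise ValueError(f"unknown waterfall mode {mode!r}; expected one of {MODES}")
    scheme = scheme or BandingScheme()
    per_arm: dict[str, list] = {manifest.comparator_arm: [], manifest.active_arm: []}
    for p in profiles:
        alt = p.analytes.get("ALT")
        if alt is None or alt.baseline is None or alt.peak is None or p.arm not in per_arm:
            continue
        tb = p.analytes.get("TB")
        new_jaundice = bool(
            tb is not None
            and tb.peak_xuln is not None
            and tb.baseline_xuln is not None
            and tb.peak_xuln > scheme.tb_cut
            and tb.baseline_xuln <= scheme.tb_cut
        )
        per_arm[p.arm].append((p.subject_id, alt.baseline, _bar_value(alt, mode), new_jaundice))

    left = sorted(per_arm[manifest.comparator_arm], key=lambda t: (t[1], t[0]))
    right = sorted(per_arm[manifest.active_arm], key=lambda t: (-t[1], t[0]))
    entries = [
        WaterfallEntry(sid, arm, base, bar, nj, rank)
        for rank, (arm, (sid, base, bar, nj)) in enumerate(
            [(manifest.comparator_arm, t) for t in left] + [(manifest.active_arm, t) for t in right]
        )
    ]
    summaries = {
        arm: box_whisker_stats([e.bar_value for e in entries if e.arm == arm])
        for arm in manifest.arms
    }
    return entries, summaries


def box_whisker_stats(values: Sequence[float]) -> dict:
    """Tukey box-whisker summary (whiskers at 1.5*IQR inside the fences)."""
    if len(values) == 0:
        return {"n": 0}
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": [float(x) for x in np.sort(v[(v < lo_fence) | (v > hi_fence)])],
    }


def entries_to_frame(entries: Sequence[WaterfallEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "arm": e.arm,
                "baseline_alt": e.baseline_alt,
                "bar_value": e.bar_value,
                "new_jaundice": e.new_jaundice,
                "rank": e.rank,
            }
            for e in entries
        ],
        columns=["subject_id", "arm", "baseline_alt", "bar_value", "new_jaundice", "rank"],
    )


def render_waterfall(
    entries: Sequence[WaterfallEntry],
    summaries: dict[str, dict],
    path: str | Path,
    severity_lines: Sequence[float] = DEFAULT_SEVERITY_LINES,
    comparator_arm: str | None = None,
):
    """Render the modified waterfall (SVG or PNG).

    Blue bars = comparator, bronze = active, green = new-onset jaundice;
    black lines trace each arm's baseline profile; dashed horizontal lines
    mark the severity cut-offs; box-whisker panels flank the plot.
    """
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, (ax_l, ax, ax_r) = plt.subplots(
        1, 3, figsize=(11, 5), width_ratios=[1, 10, 1], sharey=True
    )
    arms = list(dict.fromkeys(e.arm for e in entries)) or list(summaries)
    comp = comparator_arm if comparator_arm is not None else (arms[0] if arms else None)
    colors = {}
    for e in entries:
        if e.new_jaundice:
            colors[e.rank] = "#2ca02c"
        elif e.arm == comp:
            colors[e.rank] = "#1f77b4"
        else:
            colors[e.rank] = "#b08d57"
    if entries:
        ranks = [e.rank for e in entries]
        ax.bar(
            ranks,
            [e.bar_value for e in entries],
            bottom=[e.baseline_alt for e in entries],
            width=1.0,
            color=[colors[r] for r in ranks],
        )
        for arm in arms:
            sub = [e for e in entries if e.arm == arm]
            ax.plot([e.rank for e in sub], [e.baseline_alt for e in sub], color="k", lw=1.2)
    for y in severity_lines:
        ax.axhline(y, color="0.3", lw=0.7, ls="--")
        ax.text(0.5, y, f"{y:g} U/L", fontsize=6, va="bottom")
    ax.set_xlabel("subjects (ordered by baseline ALT; comparator left, active right)")
    ax.set_ylabel("ALT (U/L)")
    ax.set_title("Modified waterfall: baseline ALT and maximum on-treatment change")

    for panel, arm in zip((ax_l, ax_r), (arms + [None, None])[:2]):
        panel.set_xticks([])
        if arm is None or summaries.get(arm, {}).get("n", 0) == 0:
            continue
        s = summaries[arm]
        # box drawn on the bar_value scale
        panel.add_patch(plt.Rectangle((0.25, s["q1"]), 0.5, s["q3"] - s["q1"],
                                      facecolor="none", edgecolor="k"))
        panel.hlines(s["median"], 0.25, 0.75, color="k")
        panel.vlines(0.5, s["whisker_low"], s["q1"], color="k", lw=0.8)
        panel.vlines(0.5, s["q3"], s["whisker_high"], color="k", lw=0.8)
        panel.scatter([0.5] * len(s["outliers"]), s["outliers"], s=6, color="k")
        panel.set_xlim(0, 1)
        panel.set_title(str(arm), fontsize=7)

    from .edish import _deterministic_savefig

    fig.tight_layout()
    _deterministic_savefig(fig, path)
    plt.close(fig)
    return path
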