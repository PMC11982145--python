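"""End-to-end screening pipeline: ingest -> derive -> categorize -> artifacts.

``run_screen`` executes the whole workflow from a :class:`RunConfig` and
writes an output bundle: Sankey figure + cross-table CSVs (always),
composite mDISH data/figures per destination category (always), the
modified waterfall when applicable or forced, an eDISH/mDISH pair, a
prioritized list of subjects in upward shifts, and a JSON summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import advisor as advisor_mod
from . import categorize, edish, sankey, waterfall
from .config import RunConfig
from .trial_data import TrialManifest, derive_profiles, read_lab_csv, write_profiles_csv

logger = logging.getLogger(__name__)

__all__ = ["run_screen", "priority_list"]


def priority_list(
    shifts: pd.DataFrame, profiles, scheme, active_only: bool = False, active_arm: str | None = None
) -> pd.DataFrame:
    """Subjects in upward shifts, ordered for in-depth review.

    Ordering: destination severity (most severe first), then peak TB xULN,
    then peak AT xULN, all descending.  Placebo-arm upward shifts are
    included by default — they contextualize background disease progression.
    """
    sev = {c.name: i for i, c in enumerate(scheme.categories())}  # 0 = most severe
    peaks = {p.subject_id: (p.peak_xuln("TB"), p.at_peak_xuln()) for p in profiles}
    up = shifts[shifts["direction"] == "upward"].copy()
    if active_only and active_arm is not None:
        up = up[up["arm"] == active_arm]
    if up.empty:
        return pd.DataFrame(columns=["subject_id", "arm", "origin", "destination",
                                     "peak_tb_xuln", "peak_at_xuln"])
    up["peak_tb_xuln"] = up["subject_id"].map(lambda s: peaks[s][0])
    up["peak_at_xuln"] = up["subject_id"].map(lambda s: peaks[s][1])
    up["_sev"] = up["destination"].map(sev)
    up = up.sort_values(
        ["_sev", "peak_tb_xuln", "peak_at_xuln", "subject_id"],
        ascending=[True, False, False, True],
    ).drop(columns=["_sev", "direction"])
    return up.reset_index(drop=True)


def run_screen(config: RunConfig, records: pd.DataFrame | None = None,
               manifest: TrialManifest | None = None) -> dict:
    """Run the full screen and write the output bundle.

    ``records``/``manifest`` may be passed directly (e.g. from the
    simulator); otherwise ``config.input_csv`` is ingested.  Returns a dict
    with the bundle paths and the summary.  Re-running with the same config
    and inputs produces byte-identical outputs, figures included.
    """
    out = Path(config.output_dir)
    scheme = config.scheme()
    if records is None:
        records, ingest = read_lab_csv(config.input_csv, config.column_map or None)
    else:
        ingest = None
    if manifest is None:
        manifest = TrialManifest(
            active_arm=config.active_arm,
            comparator_arm=config.comparator_arm,
            treatment_end_day=config.treatment_end_day,
            followup_lag_days=config.followup_lag_days,
        )
    profiles = derive_profiles(records, manifest, at_policy=config.at_policy)
    if not profiles:
        raise ValueError("no analyzable subjects in input")
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    write_profiles_csv(profiles, out / "profiles.csv")
    paths["profiles"] = str(out / "profiles.csv")

    # categorize & classify
    shifts = categorize.shift_records(profiles, scheme)
    baseline_summary = categorize.classify_trial_baseline(
        profiles, abnormal_fraction_threshold=config.abnormal_fraction_threshold
    )
    rec = advisor_mod.recommend_tools(
        advisor_mod.pattern_from_summary(baseline_summary),
        substantial_threshold=config.abnormal_fraction_threshold,
    )

    # Sankey + cross-tables (always)
    flow_set = sankey.build_flows(shifts, manifest, scheme)
    tables = [sankey.build_cross_table(shifts, arm, scheme) for arm in manifest.arms]
    for t in tables:
        p = out / f"crosstab_{t.arm}.csv"
        t.to_csv(p)
        paths[f"crosstab_{t.arm}"] = str(p)
    sankey.render_sankey(flow_set, out / "sankey.svg", cross_tables=tables)
    paths["sankey"] = str(out / "sankey.svg")

    # eDISH / mDISH overview
    e_pts, e_counts = edish.edish_points(profiles, scheme)
    e_pts.to_csv(out / "edish_points.csv", index=False)
    edish.render_edish(e_pts, out / "edish.svg", scheme, arms=manifest.arms)
    m_pts = edish.mdish_points(profiles, scheme)
    m_pts.to_csv(out / "mdish_points.csv", index=False)
    edish.render_mdish(m_pts, out / "mdish.svg", arms=manifest.arms)
    paths.update(edish=str(out / "edish.svg"), mdish=str(out / "mdish.svg"))

    # composite mDISH per destination category (always)
    for cat in scheme.categories():
        pts = edish.composite_points(profiles, cat, scheme)
        p = out / f"composite_{cat.name}.csv"
        pts.to_csv(p, index=False)
        edish.render_composite(pts, cat.name, out / f"composite_{cat.name}.svg")
        paths[f"composite_{cat.name}"] = str(p)

    # waterfall when applicable (or forced)
    applicable, wf_report = waterfall.check_applicability(profiles, scheme)
    if applicable or config.force_waterfall:
        entries, summaries = waterfall.build_waterfall(
            profiles, manifest, mode=config.waterfall_mode, scheme=scheme
        )
        waterfall.entries_to_frame(entries).to_csv(out / "waterfall_entries.csv", index=False)
        waterfall.render_waterfall(
            entries, summaries, out / "waterfall.svg",
            severity_lines=config.severity_lines, comparator_arm=manifest.comparator_arm,
        )
        paths["waterfall"] = str(out / "waterfall.svg")
    else:
        logger.info(
            "waterfall skipped: baseline jaundice fraction %.3f exceeds %.3f",
            wf_report["baseline_jaundice_fraction"], wf_report["threshold"],
        )

    prio = priority_list(shifts, profiles, scheme,
                         active_only=config.active_only, active_arm=manifest.active_arm)
    prio.to_csv(out / "priority_list.csv", index=False)
    paths["priority_list"] = str(out / "priority_list.csv")

    summary = {
        "n_subjects": len(profiles),
        "arms": list(manifest.arms),
        "trial_baseline": baseline_summary,
        "advisor": rec.as_dict(),
        "upward_shifts": sankey.upward_shift_summary(tables),
        "waterfall_applicable": applicable,
        "waterfall_report": {k: v for k, v in wf_report.items() if k != "baseline_jaundice_subjects"},
        "n_priority_subjects": int(len(prio)),
        "destination_counts": {
            str(a): {k: int(v) for k, v in row.items()} for a, row in e_counts.iterrows()
        },
    }
    if ingest is not None:
        summary["ingest"] = {
            "rows_read": ingest.n_rows_read,
            "dropped_unparseable": ingest.n_dropped_unparseable,
            "duplicates_resolved": ingest.n_duplicates_resolved,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["summary"] = str(out / "summary.json")
    return {"paths": paths, "summary": summary, "shifts": shifts, "tables": tables}
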