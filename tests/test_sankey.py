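"""Flow aggregation, cross-tables, conservation, rendering determinism."""

import pandas as pd
import pytest

from dilishift.categorize import BandingScheme, shift_records
from dilishift.sankey import (
    build_cross_table,
    build_flows,
    render_sankey,
    upward_shift_summary,
)
from dilishift.synthetic import ArmSignalSpec, SyntheticSpec, simulate_trial
from dilishift.trial_data import TrialManifest, derive_profiles

MANIFEST = TrialManifest(active_arm="active", comparator_arm="placebo",
                         treatment_end_day=84)


def _shifts(rows):
    return pd.DataFrame(rows, columns=["subject_id", "arm", "origin", "destination", "direction"])


def test_single_upward_flow():
    sh = _shifts([("s1", "active", "NNN", "HyLaw", "upward")])
    fs = build_flows(sh, MANIFEST)
    assert len(fs.right_flows) == 1
    row = fs.right_flows.iloc[0]
    assert row["count"] == 1 and row["direction"] == "upward"
    assert fs.left_flows.empty


def test_outflow_conservation_small():
    rows = [(f"s{i}", "placebo", "NNN", "NNN", "none") for i in range(8)]
    rows += [(f"t{i}", "placebo", "NNN", "Temple", "upward") for i in range(2)]
    fs = build_flows(_shifts(rows), MANIFEST)
    outflow = fs.left_flows.groupby("origin", observed=True)["count"].sum()
    assert outflow["NNN"] == 10 == fs.baseline_counts["NNN"]


def test_unknown_arm_is_hard_error():
    sh = _shifts([("s1", "armX", "NNN", "NNN", "none")])
    with pytest.raises(ValueError, match="armX"):
        build_flows(sh, MANIFEST)


def test_cross_table_colors_and_counts():
    sh = _shifts(
        [("a", "placebo", "NNN", "NNN", "none"),
         ("b", "placebo", "NNN", "Temple", "upward"),
         ("c", "placebo", "Temple", "NNN", "downward")]
    )
    t = build_cross_table(sh, "placebo")
    assert t.counts.loc["NNN", "NNN"] == 1 and t.color_classes.loc["NNN", "NNN"] == "grey"
    assert t.counts.loc["NNN", "Temple"] == 1 and t.color_classes.loc["NNN", "Temple"] == "red"
    assert t.counts.loc["Temple", "NNN"] == 1 and t.color_classes.loc["Temple", "NNN"] == "green"
    assert t.color_classes.loc["Temple", "Cholestasis"] == "yellow"
    assert (pd.Series([t.color_classes.loc[c, c] for c in t.counts.index]) == "grey").all()


def test_empty_arm_gives_all_zero_table():
    t = build_cross_table(_shifts([]), "placebo")
    assert t.grand_total == 0
    assert t.red_total() == 0 and t.red_paths() == 0


def test_upward_summary_counts_cells_and_paths():
    sh = _shifts(
        [("a", "placebo", "NNN", "Temple", "upward")] * 1
        + [(f"b{i}", "placebo", "Temple", "HyLaw", "upward") for i in range(2)]
    )
    t = build_cross_table(sh, "placebo")
    out = upward_shift_summary([t])
    assert out["placebo"] == {"total": 3, "paths": 2}


def test_study1_fixture_upward_structure(study1):
    """Five upward paths totaling 15 in placebo vs three totaling 13 on drug."""
    _, manifest, profiles = study1
    sh = shift_records(profiles)
    tables = {arm: build_cross_table(sh, arm) for arm in manifest.arms}
    assert tables["placebo"].red_paths() == 5
    assert tables["active"].red_paths() == 3
    assert tables["placebo"].red_total() == 15
    assert tables["active"].red_total() == 13
    assert tables["placebo"].counts.loc["NNN", "HyLaw"] == 2
    assert tables["active"].counts.loc["NNN", "HyLaw"] == 0


def test_study2_placebo_has_no_active_upward_paths(study2):
    """The active arm's pink paths do not occur in placebo."""
    _, manifest, profiles = study2
    sh = shift_records(profiles)
    tabs = {arm: build_cross_table(sh, arm) for arm in manifest.arms}
    active_red = (tabs["active"].color_classes == "red") & (tabs["active"].counts > 0)
    placebo_counts_on_those = tabs["placebo"].counts.to_numpy()[active_red.to_numpy()]
    assert placebo_counts_on_those.sum() == 0
    assert tabs["active"].red_paths() >= 1  # and they do exist on drug


def _sim(seed):
    spec = SyntheticSpec(
        n_placebo=25,
        n_active=25,
        baseline_mix={
            "placebo": {"NNN": 0.5, "Temple": 0.25, "Cholestasis": 0.15, "HyLaw": 0.1},
            "active": {"NNN": 0.5, "Temple": 0.25, "Cholestasis": 0.15, "HyLaw": 0.1},
        },
        signals={
            "placebo": ArmSignalSpec(noise_sigma=0.15),
            "active": ArmSignalSpec(dili_prob=0.1, efficacy_prob=0.2, hemolysis_prob=0.05,
                                    dili_tb_xbl=2.5, noise_sigma=0.15),
        },
        visit_days=(-14, -1, 28, 56, 84),
        seed=seed,
    )
    return simulate_trial(spec)


@pytest.mark.parametrize("seed", range(10))
def test_conservation_on_simulated_trials(seed):
    """Outflow per baseline category equals the arm's category count; the
    cross-table and flow-set aggregation paths agree; grand total = arm size."""
    records, manifest = _sim(seed)
    profiles = derive_profiles(records, manifest)
    sh = shift_records(profiles)
    fs = build_flows(sh, manifest)
    for arm, flows in (("placebo", fs.left_flows), ("active", fs.right_flows)):
        table = build_cross_table(sh, arm)
        arm_n = (sh["arm"] == arm).sum()
        assert table.grand_total == arm_n == 25
        arm_base = sh[sh["arm"] == arm]["origin"].value_counts()
        outflow = flows.groupby("origin", observed=True)["count"].sum()
        for cat, n in arm_base.items():
            assert outflow[cat] == n
        # two aggregation paths agree cell by cell
        for row in flows.to_dict("records"):
            assert table.counts.loc[str(row["origin"]), str(row["destination"])] == row["count"]


def test_pooled_baseline_is_sum_of_arms():
    records, manifest = _sim(3)
    sh = shift_records(derive_profiles(records, manifest))
    fs = build_flows(sh, manifest)
    assert fs.baseline_counts.sum() == 50


def test_proportional_layout_invariant_to_arm_imbalance(tmp_path):
    """A 1:3 trial with identical within-arm shift distributions yields
    identical within-arm flow fractions."""
    rows = []
    for i in range(10):
        rows.append((f"p{i}", "placebo", "NNN", "Temple" if i < 2 else "NNN",
                     "upward" if i < 2 else "none"))
    for i in range(30):
        rows.append((f"a{i}", "active", "NNN", "Temple" if i < 6 else "NNN",
                     "upward" if i < 6 else "none"))
    fs = build_flows(_shifts(rows), MANIFEST)
    left = fs.left_flows.set_index(["origin", "destination"])["count"] / 10
    right = fs.right_flows.set_index(["origin", "destination"])["count"] / 30
    pd.testing.assert_series_equal(left, right, check_names=False)


def test_render_sankey_byte_stable_svg(tmp_path, study1):
    _, manifest, profiles = study1
    sh = shift_records(profiles)
    fs = build_flows(sh, manifest)
    tables = [build_cross_table(sh, arm) for arm in manifest.arms]
    p1 = render_sankey(fs, tmp_path / "s1.svg", cross_tables=tables)
    p2 = render_sankey(fs, tmp_path / "s2.svg", cross_tables=tables)
    assert p1.read_bytes() == p2.read_bytes()


def test_cross_table_csv_export(tmp_path):
    sh = _shifts([("a", "placebo", "NNN", "Temple", "upward")])
    t = build_cross_table(sh, "placebo")
    path = t.to_csv(tmp_path / "ct.csv")
    out = pd.read_csv(path)
    assert set(out.columns) == {"arm", "origin", "destination", "count", "color_class"}
    row = out[(out["origin"] == "NNN") & (out["destination"] == "Temple")].iloc[0]
    assert row["count"] == 1 and row["color_class"] == "red"
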