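"""Ingest, baseline derivation, peak derivation, round-trips."""

import pandas as pd
import pytest

from dilishift.trial_data import (
    SDTM_LB_MAP,
    TrialManifest,
    derive_baseline,
    derive_profiles,
    profiles_to_frame,
    read_lab_csv,
    write_profiles_csv,
)

MANIFEST = TrialManifest(active_arm="drug", comparator_arm="placebo",
                         treatment_end_day=84, followup_lag_days=30)


def _write(tmp_path, text, name="labs.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_toy_csv(tmp_path):
    p = _write(
        tmp_path,
        "subject_id,arm,analyte,study_day,value,uln\n"
        "s1,drug,ALT,-1,50,40\n"
        "s1,drug,ALT,28,400,40\n"
        "s1,drug,TB,-1,0.8,1.2\n",
    )
    df, report = read_lab_csv(p)
    assert len(df) == 3
    assert df["subject_id"].nunique() == 1
    assert report.n_dropped_unparseable == 0


def test_unparseable_rows_dropped_and_counted(tmp_path):
    p = _write(
        tmp_path,
        "subject_id,arm,analyte,study_day,value,uln\n"
        "s1,drug,ALT,-1,NA,40\n"
        "s1,drug,ALT,28,400,40\n",
    )
    df, report = read_lab_csv(p)
    assert len(df) == 1
    assert report.n_dropped_unparseable == 1


def test_duplicate_resolves_to_max(tmp_path):
    p = _write(
        tmp_path,
        "subject_id,arm,analyte,study_day,value,uln\n"
        "s1,drug,ALT,28,100,40\n"
        "s1,drug,ALT,28,120,40\n",
    )
    df, report = read_lab_csv(p)
    assert len(df) == 1
    assert df["value"].iloc[0] == 120
    assert report.n_duplicates_resolved == 1


def test_missing_mapped_column_is_hard_error(tmp_path):
    p = _write(tmp_path, "USUBJID,LBTESTCD\nx,ALT\n")
    with pytest.raises(ValueError, match="LBDY"):
        read_lab_csv(p, SDTM_LB_MAP)


def test_empty_file_is_hard_error(tmp_path):
    p = _write(tmp_path, "")
    with pytest.raises(ValueError, match="empty"):
        read_lab_csv(p)


def test_sdtm_style_mapping(tmp_path):
    p = _write(
        tmp_path,
        "USUBJID,ARM,LBTESTCD,LBDY,LBSTRESN,LBSTNRHI\n"
        "s1,drug,ALT,-1,50,40\n"
        "s1,drug,BILI,-1,0.8,1.2\n",
    )
    df, _ = read_lab_csv(p, SDTM_LB_MAP)
    assert set(df["analyte"]) == {"ALT", "TB"}  # BILI normalized to TB


def _records(rows):
    return pd.DataFrame(rows, columns=["subject_id", "arm", "analyte", "study_day", "value", "uln"])


def test_baseline_is_latest_predose():
    rec = _records([("s1", "drug", "ALT", -14, 80, 40), ("s1", "drug", "ALT", -1, 95, 40)])
    base = derive_baseline(rec)
    assert base["baseline"].iloc[0] == 95


def test_day_zero_counts_as_predose():
    rec = _records([("s1", "drug", "ALT", -7, 100, 40), ("s1", "drug", "ALT", 0, 110, 40)])
    base = derive_baseline(rec)
    assert base["baseline"].iloc[0] == 110


def test_subject_without_baseline_is_flagged():
    rec = _records([("s1", "drug", "ALT", 28, 100, 40)])
    profs = derive_profiles(rec, MANIFEST)
    assert profs[0].flags == ["no-baseline:ALT"]
    assert not profs[0].analyzable("ALT")


def test_peak_and_multiples():
    rec = _records(
        [("s1", "drug", "ALT", -1, 200, 40)]
        + [("s1", "drug", "ALT", d, v, 40) for d, v in [(14, 50), (28, 400), (56, 200)]]
    )
    (p,) = derive_profiles(rec, MANIFEST)
    s = p.analytes["ALT"]
    assert s.peak == 400 and s.peak_day == 28
    assert s.peak_xuln == pytest.approx(10.0)
    assert s.peak_xbl == pytest.approx(2.0)
    assert s.trough == 50


def test_xbl_five_from_baseline_200_peak_1000():
    rec = _records([("s1", "drug", "ALT", -1, 200, 40), ("s1", "drug", "ALT", 28, 1000, 40)])
    (p,) = derive_profiles(rec, MANIFEST)
    assert p.analytes["ALT"].peak_xbl == pytest.approx(5.0)


def test_on_treatment_window_excludes_beyond_lag():
    # window = (0, 84 + 30]; day 200 value must not contribute to the peak
    rec = _records(
        [("s1", "drug", "ALT", -1, 100, 40), ("s1", "drug", "ALT", 28, 150, 40),
         ("s1", "drug", "ALT", 200, 900, 40)]
    )
    (p,) = derive_profiles(rec, MANIFEST)
    assert p.analytes["ALT"].peak == 150


def test_at_policy_max_alt_ast_per_day():
    # ALT 4xULN on day 10, AST 6xULN on day 12 -> AT peak 6.0 under max policy
    rec = _records(
        [("s1", "drug", "ALT", -1, 40, 40), ("s1", "drug", "AST", -1, 40, 40),
         ("s1", "drug", "ALT", 10, 160, 40), ("s1", "drug", "AST", 10, 80, 40),
         ("s1", "drug", "ALT", 12, 60, 40), ("s1", "drug", "AST", 12, 240, 40)]
    )
    (p_max,) = derive_profiles(rec, MANIFEST, at_policy="max_alt_ast")
    assert p_max.at_peak_xuln() == pytest.approx(6.0)
    (p_alt,) = derive_profiles(rec, MANIFEST, at_policy="alt")
    assert p_alt.at_peak_xuln() == pytest.approx(4.0)


def test_zero_baseline_leaves_xbl_undefined():
    rec = _records([("s1", "drug", "ALT", -1, 0, 40), ("s1", "drug", "ALT", 28, 100, 40)])
    (p,) = derive_profiles(rec, MANIFEST)
    assert p.analytes["ALT"].peak_xbl is None
    assert "xbl-undefined:ALT" in p.flags
    assert p.analytes["ALT"].peak_xuln == pytest.approx(2.5)  # stays in xULN analyses


def test_profiles_csv_round_trip(tmp_path, study1):
    """Re-deriving from the writer's own CSV reproduces identical profiles."""
    records, manifest, profiles = study1
    csv1 = tmp_path / "labs.csv"
    records.to_csv(csv1, index=False)
    re_records, _ = read_lab_csv(csv1)
    re_profiles = derive_profiles(re_records, manifest)
    f1 = profiles_to_frame(profiles).sort_values("subject_id").reset_index(drop=True)
    f2 = profiles_to_frame(re_profiles).sort_values("subject_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(f1, f2)


def test_analyzable_plus_flagged_covers_enrolled():
    rec = _records(
        [("s1", "drug", "ALT", -1, 50, 40), ("s1", "drug", "ALT", 28, 60, 40),
         ("s2", "drug", "ALT", 28, 60, 40),  # no baseline
         ("s3", "drug", "ALT", -1, 50, 40)]  # no on-treatment
    )
    profs = derive_profiles(rec, MANIFEST)
    analyzable = sum(p.analyzable("ALT") for p in profs)
    flagged = sum(1 for p in profs if any(f.endswith(":ALT") for f in p.flags))
    assert analyzable + flagged == 3
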