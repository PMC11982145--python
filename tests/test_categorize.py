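"""Quadrant assignment, shift lattice, trial-baseline classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dilishift.categorize import (
    BandingScheme,
    QuadrantCategory,
    assign_quadrant,
    classify_shift,
    classify_trial_baseline,
    report_proportion,
)
from dilishift.trial_data import AnalyteSummary, SubjectProfile


def oracle_quadrant(at: float, tb: float) -> str:
    """Independent brute-force reference for the standard four quadrants."""
    if at >= 3.0:
        return "HyLaw" if tb > 2.0 else "Temple"
    return "Cholestasis" if tb > 2.0 else "NNN"


@pytest.mark.parametrize(
    "at,tb,expected",
    [
        (5.0, 3.0, "HyLaw"),
        (3.0, 2.0, "Temple"),  # ALT boundary inclusive, TB boundary strict
        (0.8, 0.5, "NNN"),
        (1.2, 2.5, "Cholestasis"),
        (2.999, 2.001, "Cholestasis"),
        (0.0, 0.0, "NNN"),
    ],
)
def test_assign_quadrant_boundaries(at, tb, expected):
    assert assign_quadrant(at, tb).name == expected


def test_assign_quadrant_matches_oracle_on_grid():
    """21x25 grid including both boundary values (3.0, 2.0)."""
    ats = np.arange(0, 10.5, 0.5)  # 21 values, includes 3.0
    tbs = np.arange(0, 6.25, 0.25)  # 25 values, includes 2.0
    assert 3.0 in ats and 2.0 in tbs
    for at in ats:
        for tb in tbs:
            assert assign_quadrant(float(at), float(tb)).name == oracle_quadrant(at, tb)


@pytest.mark.parametrize("at,tb", [(-0.1, 1.0), (1.0, float("nan")), (float("inf"), 1.0)])
def test_assign_quadrant_rejects_invalid(at, tb):
    with pytest.raises(ValueError):
        assign_quadrant(at, tb)


@pytest.mark.parametrize(
    "origin,dest,expected",
    [
        ("NNN", "HyLaw", "upward"),
        ("Temple", "NNN", "downward"),
        ("Temple", "Cholestasis", "lateral"),
        ("Cholestasis", "Temple", "lateral"),
        ("HyLaw", "HyLaw", "none"),
        ("NNN", "Temple", "upward"),
        ("Cholestasis", "HyLaw", "upward"),
        ("HyLaw", "Temple", "downward"),
    ],
)
def test_classify_shift_lattice(origin, dest, expected):
    scheme = BandingScheme()
    assert classify_shift(scheme.by_name(origin), scheme.by_name(dest)) == expected


_cat = st.sampled_from([c.name for c in BandingScheme().categories()])


@settings(derandomize=True, max_examples=100)
@given(a=_cat, b=_cat)
def test_shift_antisymmetry(a, b):
    """up(a,b) iff down(b,a); none iff identical; lateral is symmetric."""
    scheme = BandingScheme()
    fwd = classify_shift(scheme.by_name(a), scheme.by_name(b))
    rev = classify_shift(scheme.by_name(b), scheme.by_name(a))
    if a == b:
        assert fwd == rev == "none"
    else:
        assert {"upward": "downward", "downward": "upward", "lateral": "lateral"}[fwd] == rev


def test_exhaustive_single_category():
    """Every finite non-negative pair maps to exactly one category."""
    scheme = BandingScheme(extra_tb_band=True)
    names = [c.name for c in scheme.categories()]
    assert len(names) == 6 and len(set(names)) == 6
    rng = np.random.default_rng(7)
    for at, tb in zip(rng.uniform(0, 12, 300), rng.uniform(0, 8, 300)):
        cat = assign_quadrant(float(at), float(tb), scheme)
        assert cat.name in names


def test_extra_tb_band_partitions_midband():
    scheme = BandingScheme(extra_tb_band=True)
    assert assign_quadrant(4.0, 1.7, scheme).name == "Temple+TB1.5"
    assert assign_quadrant(1.0, 1.7, scheme).name == "TB1.5"
    assert assign_quadrant(4.0, 1.5, scheme).name == "Temple"  # boundary strict
    assert assign_quadrant(4.0, 2.2, scheme).name == "HyLaw"


def test_split_nnn_scheme():
    scheme = BandingScheme(split_nnn=True)
    assert assign_quadrant(0.9, 0.5, scheme).name == "Normal"
    assert assign_quadrant(1.0, 0.5, scheme).name == "Normal"  # ALT <= 1 is Normal
    assert assign_quadrant(1.5, 0.5, scheme).name == "NearNormal"
    assert assign_quadrant(3.2, 0.5, scheme).name == "Temple"


def test_category_order_severity_descending():
    names = [c.name for c in BandingScheme().categories()]
    assert names == ["HyLaw", "Cholestasis", "Temple", "NNN"]


@pytest.mark.parametrize(
    "num,den,expected",
    [(13, 46, 28), (17, 46, 37), (26, 254, 10), (81, 765, 11), (0, 5, 0), (5, 5, 100), (1, 8, 13)],
)
def test_report_proportion_half_up(num, den, expected):
    assert report_proportion(num, den) == expected


def test_report_proportion_rejects_bad_inputs():
    with pytest.raises(ValueError):
        report_proportion(1, 0)
    with pytest.raises(ValueError):
        report_proportion(5, 4)


def _profile(sid, alt_xuln, tb_xuln, arm="a"):
    p = SubjectProfile(subject_id=sid, arm=arm)
    p.analytes["ALT"] = AnalyteSummary(baseline=alt_xuln * 40, baseline_xuln=alt_xuln)
    p.analytes["TB"] = AnalyteSummary(baseline=tb_xuln * 1.2, baseline_xuln=tb_xuln)
    return p


def test_classify_trial_baseline_all_normal():
    profs = [_profile(f"s{i}", 0.8, 0.5) for i in range(20)]
    out = classify_trial_baseline(profs)
    assert out["label"] == "NNN-BL"
    assert out["alt_high_fraction"] == 0.0


def test_classify_trial_baseline_abnormal():
    profs = [_profile(f"s{i}", 4.0, 0.5) for i in range(8)] + [
        _profile(f"t{i}", 0.8, 0.5) for i in range(12)
    ]
    out = classify_trial_baseline(profs)
    assert out["label"] == "ABN-BL"
    assert out["alt_high_fraction"] == pytest.approx(0.4)


def test_classify_trial_baseline_study1_placebo(study1):
    """13 of 46 placebo subjects at baseline Hy's Law -> ABN-BL, 28%."""
    _, manifest, profiles = study1
    placebo = [p for p in profiles if p.arm == manifest.comparator_arm]
    out = classify_trial_baseline(placebo)
    assert out["label"] == "ABN-BL"
    n_hylaw = sum(
        1 for p in placebo
        if p.baseline_xuln("ALT") >= 3 and p.baseline_xuln("TB") > 2
    )
    assert n_hylaw == 13
    assert report_proportion(n_hylaw, len(placebo)) == 28


def test_classify_trial_baseline_requires_subjects():
    with pytest.raises(ValueError):
        classify_trial_baseline([])
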