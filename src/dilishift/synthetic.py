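"""Synthetic two-arm trial laboratory data.

Two kinds of artifact:

* :func:`simulate_trial` — a stochastic simulator with a configurable
  baseline severity mix per arm and injectable on-treatment signals
  (hepatocellular DILI, efficacy-type improvement, hemolysis-type isolated
  jaundice) on top of lognormal visit-to-visit noise.  Deterministic for a
  fixed seed.

* :func:`study1_fixture` / :func:`study2_fixture` — *constructed* (not
  sampled) trials whose category marginals reproduce two published-style
  screening scenarios: a 1:1 severe chronic-liver-disease trial with mostly
  abnormal baselines (Study 1) and a 1:3 trial with mostly normal baselines
  and a Temple's-quadrant subpopulation (Study 2).  Only the marginals are
  pinned; unpinned origin->destination cells are filled deterministically
  on the diagonal (no category change).  These are test harnesses for the
  categorization and aggregation machinery, not reconstructions of any
  real trial's data.

All generated values are positive; ULNs are constant within an analyte
(ALT 40 U/L, AST 40 U/L, TB 1.2 mg/dL, ALP 120 U/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .categorize import BandingScheme
from .trial_data import RECORD_COLUMNS, TrialManifest

ULN = {"ALT": 40.0, "AST": 40.0, "TB": 1.2, "ALP": 120.0}

#: day −14 and −1 pre-dose draws, then every 28 days on treatment
DEFAULT_VISIT_DAYS = (-14, -1) + tuple(range(28, 337, 28))

#: band caps (xULN) for baseline sampling/placement, chosen for realism
ALT_CAP = 10.0
TB_CAP = 6.0
FLOOR = 0.3  # lower edge (xULN) of the lowest band

__all__ = [
    "SyntheticSpec",
    "ArmSignalSpec",
    "simulate_trial",
    "study1_fixture",
    "study2_fixture",
    "write_trial_csv",
]


# --------------------------------------------------------------------------
# band geometry shared by the simulator and the fixtures


def _band_edges(scheme: BandingScheme, category_name: str) -> tuple[tuple[float, float], tuple[float, float]]:
    """((alt_lo, alt_hi), (tb_lo, tb_hi)) in xULN for a category's cell.

    ALT edges: the cut is inclusive upward, so the low band is
    [FLOOR, alt_cut) and the high band [alt_cut, ALT_CAP].  TB edges: the
    cut is strict upward, low band (FLOOR, tb_cut], high (tb_cut, TB_CAP].
    """
    cat = scheme.by_name(category_name)
    alt_cuts = [FLOOR]
    if scheme.split_nnn:
        alt_cuts.append(1.0)
    alt_cuts += [scheme.alt_cut, ALT_CAP]
    tb_cuts = [FLOOR]
    if scheme.extra_tb_band:
        tb_cuts.append(scheme.extra_tb_low)
    tb_cuts += [scheme.tb_cut, TB_CAP]
    alt_lo, alt_hi = alt_cuts[cat.alt_band], alt_cuts[cat.alt_band + 1]
    tb_lo, tb_hi = tb_cuts[cat.tb_band], tb_cuts[cat.tb_band + 1]
    if alt_lo >= alt_hi or tb_lo >= tb_hi:
        raise ValueError(f"infeasible band for category {category_name}")
    return (alt_lo, alt_hi), (tb_lo, tb_hi)


def _interior(lo: float, hi: float, frac: float) -> float:
    """Log-interpolated interior point of a band, kept off both boundaries."""
    pad = 0.02
    f = pad + (1 - 2 * pad) * frac
    return float(lo * (hi / lo) ** f)


def _place_in_category(scheme: BandingScheme, name: str, frac_alt: float, frac_tb: float) -> tuple[float, float]:
    """Deterministic (ALT, TB) xULN pair strictly inside a category's cell.

    The padding in :func:`_interior` keeps values off the band edges, so
    the inclusive-vs-strict boundary conventions cannot be tripped by
    value rounding downstream.
    """
    (alo, ahi), (tlo, thi) = _band_edges(scheme, name)
    alt = _interior(alo, ahi * 0.999, frac_alt)
    tb = _interior(tlo, thi * 0.999, frac_tb)
    return alt, tb


# --------------------------------------------------------------------------
# constructed fixtures


def _fixture_records(
    cells: dict[str, list[tuple[str, str, int]]],
    manifest: TrialManifest,
    visit_days=( -14, -1, 28, 56, 84),
    id_prefix: str = "S",
) -> pd.DataFrame:
    """Build lab records realizing exact (origin, destination) cell counts.

    ``cells`` maps arm -> list of (origin, destination, count).  Each
    subject gets baseline draws in the origin cell and an on-treatment
    trajectory whose per-analyte maxima land in the destination cell.
    """
    scheme = BandingScheme()
    rows = []
    sid_counter = 0
    pre_days = [d for d in visit_days if d <= 0]
    on_days = [d for d in visit_days if d > 0]
    for arm in manifest.arms:
        for origin, dest, count in cells[arm]:
            for i in range(count):
                sid_counter += 1
                sid = f"{id_prefix}{sid_counter:04d}"
                spread = ((i % 7) + 1) / 8.0
                spread2 = ((i % 5) + 1) / 6.0
                b_alt, b_tb = _place_in_category(scheme, origin, spread, spread2)
                p_alt, p_tb = _place_in_category(scheme, dest, 1 - spread2, 1 - spread)
                for day in pre_days:
                    rows.append((sid, arm, "ALT", day, round(b_alt * ULN["ALT"], 1), ULN["ALT"]))
                    rows.append((sid, arm, "TB", day, round(b_tb * ULN["TB"], 2), ULN["TB"]))
                peak_day = on_days[len(on_days) // 2]
                for day in on_days:
                    scale = 1.0 if day == peak_day else 0.85
                    rows.append((sid, arm, "ALT", day, round(p_alt * scale * ULN["ALT"], 1), ULN["ALT"]))
                    rows.append((sid, arm, "TB", day, round(p_tb * scale * ULN["TB"], 2), ULN["TB"]))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def study1_fixture() -> tuple[pd.DataFrame, TrialManifest]:
    """A 1:1, 92-subject severe chronic-liver-disease trial (abnormal baselines).

    Pinned marginals: baseline Hy's Law counts 13 (placebo) and 17 (active);
    five distinct upward shift paths totaling 15 in placebo, including two
    NNN->HyLaw; three upward paths totaling 13 in active, with no
    NNN->HyLaw.  Remaining subjects stay in their baseline category.
    """
    manifest = TrialManifest(active_arm="active", comparator_arm="placebo",
                             treatment_end_day=84, followup_lag_days=30)
    cells = {
        "placebo": [
            # five upward paths, total 15 (incl. the two NNN→HyLaw)
            ("NNN", "HyLaw", 2),
            ("NNN", "Temple", 4),
            ("NNN", "Cholestasis", 3),
            ("Temple", "HyLaw", 3),
            ("Cholestasis", "HyLaw", 3),
            # diagonal fill to baseline counts NNN 20, Temple 7, Chol 6, HyLaw 13
            ("NNN", "NNN", 11),
            ("Temple", "Temple", 4),
            ("Cholestasis", "Cholestasis", 3),
            ("HyLaw", "HyLaw", 13),
        ],
        "active": [
            # three upward paths, total 13, none NNN→HyLaw; the two shared
            # paths are thicker than placebo's
            ("NNN", "Temple", 6),
            ("Temple", "HyLaw", 4),
            ("Cholestasis", "HyLaw", 3),
            # diagonal fill to baseline counts NNN 15, Temple 8, Chol 6, HyLaw 17
            ("NNN", "NNN", 9),
            ("Temple", "Temple", 4),
            ("Cholestasis", "Cholestasis", 3),
            ("HyLaw", "HyLaw", 17),
        ],
    }
    return _fixture_records(cells, manifest, id_prefix="A"), manifest


def study2_fixture() -> tuple[pd.DataFrame, TrialManifest]:
    """A 1:3, 1019-subject trial with mostly normal baselines.

    Pinned marginals: 254 placebo + 765 active subjects; baseline Temple
    counts 26 (placebo) and 81 (active); exactly one baseline-jaundiced
    subject in the whole trial; five active-arm subjects whose peaks land
    in the Hy's Law quadrant (four from NNN, one from Temple); substantial
    downward (improvement) mass in the active arm only, and the placebo
    arm's only upward path (NNN->Temple progression) is absent from the
    active arm.
    """
    manifest = TrialManifest(active_arm="active", comparator_arm="placebo",
                             treatment_end_day=84, followup_lag_days=30)
    cells = {
        "placebo": [  # 254: NNN 228, Temple 26
            ("NNN", "Temple", 6),  # background disease progression
            ("Temple", "NNN", 2),  # very little improvement
            ("NNN", "NNN", 222),
            ("Temple", "Temple", 24),
        ],
        "active": [  # 765: NNN 683, Temple 81, Cholestasis 1 (the jaundiced baseline)
            ("NNN", "HyLaw", 4),
            ("Temple", "HyLaw", 1),
            ("NNN", "Cholestasis", 3),  # hemolysis-type isolated jaundice
            ("Temple", "NNN", 40),  # efficacy: substantial downward mass
            ("Cholestasis", "NNN", 1),
            ("NNN", "NNN", 676),
            ("Temple", "Temple", 40),
        ],
    }
    return _fixture_records(cells, manifest, id_prefix="B"), manifest


# --------------------------------------------------------------------------
# stochastic simulator


@dataclass
class ArmSignalSpec:
    """On-treatment signal probabilities and magnitudes for one arm."""

    dili_prob: float = 0.0
    dili_alt_xbl: float = 5.0  # ALT surge as a multiple of baseline
    dili_tb_xbl: float = 1.0  # accompanying TB rise (1 = none)
    efficacy_prob: float = 0.0
    efficacy_factor: float = 0.5  # multiplicative ALT/TB decline
    hemolysis_prob: float = 0.0
    hemolysis_tb_xuln: float = 3.0  # TB rise without ALT rise
    noise_sigma: float = 0.08  # lognormal visit-to-visit variation

    def __post_init__(self) -> None:
        for p in (self.dili_prob, self.efficacy_prob, self.hemolysis_prob):
            if not 0 <= p <= 1:
                raise ValueError("signal probabilities must lie in [0, 1]")


@dataclass
class SyntheticSpec:
    """Design of a simulated two-arm trial."""

    n_placebo: int = 100
    n_active: int = 100
    baseline_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "placebo": {"NNN": 1.0},
            "active": {"NNN": 1.0},
        }
    )
    signals: dict[str, ArmSignalSpec] = field(
        default_factory=lambda: {"placebo": ArmSignalSpec(), "active": ArmSignalSpec()}
    )
    visit_days: tuple[int, ...] = DEFAULT_VISIT_DAYS
    followup_lag_days: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for arm, mix in self.baseline_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"baseline mix for arm {arm!r} sums to {total}, not 1")
            if any(f < 0 for f in mix.values()):
                raise ValueError("baseline mix fractions must be >= 0")


def simulate_trial(
    spec: SyntheticSpec, scheme: BandingScheme | None = None
) -> tuple[pd.DataFrame, TrialManifest]:
    """Simulate lab records for a two-arm trial.

    Baseline categories are drawn per subject from the arm's mix; the
    (ALT, TB) baseline pair is sampled log-uniformly within the category's
    band cell (rejection-free by construction), so every subject lands in
    its assigned category with probability 1.  On-treatment values follow
    the baseline with lognormal noise; at most one signal event (DILI,
    efficacy, or hemolysis — in that priority order) modifies the
    trajectory from a random mid-study visit onward.

    Deterministic for a fixed ``spec.seed``.
    """
    scheme = scheme or BandingScheme()
    rng = np.random.default_rng(spec.seed)
    on_days = [d for d in spec.visit_days if d > 0]
    pre_days = [d for d in spec.visit_days if d <= 0]
    if not on_days or not pre_days:
        raise ValueError("visit schedule needs pre-dose and on-treatment days")
    manifest = TrialManifest(
        active_arm="active",
        comparator_arm="placebo",
        treatment_end_day=max(on_days),
        followup_lag_days=spec.followup_lag_days,
    )
    rows = []
    sid = 0
    for arm, n in (("placebo", spec.n_placebo), ("active", spec.n_active)):
        mix = spec.baseline_mix[arm]
        names = list(mix)
        probs = np.array([mix[k] for k in names], dtype=float)
        probs = probs / probs.sum()
        sig = spec.signals[arm]
        cats = rng.choice(len(names), size=n, p=probs)
        for k in range(n):
            sid += 1
            subject = f"SIM{sid:05d}"
            (alo, ahi), (tlo, thi) = _band_edges(scheme, names[cats[k]])
            # log-uniform within the cell, strictly inside the edges
            alt_x = math.exp(rng.uniform(math.log(alo * 1.02), math.log(ahi * 0.98)))
            tb_x = math.exp(rng.uniform(math.log(tlo * 1.02), math.log(thi * 0.98)))
            base_alt, base_tb = alt_x * ULN["ALT"], tb_x * ULN["TB"]
            u = rng.uniform()
            event = None
            if u < sig.dili_prob:
                event = "dili"
            elif u < sig.dili_prob + sig.efficacy_prob:
                event = "efficacy"
            elif u < sig.dili_prob + sig.efficacy_prob + sig.hemolysis_prob:
                event = "hemolysis"
            onset = int(rng.integers(0, len(on_days)))
            for day in pre_days:
                jit = math.exp(rng.normal(0, sig.noise_sigma / 2))
                rows.append((subject, arm, "ALT", day, round(base_alt * (jit if day != pre_days[-1] else 1.0), 1), ULN["ALT"]))
                rows.append((subject, arm, "TB", day, round(base_tb * (jit if day != pre_days[-1] else 1.0), 2), ULN["TB"]))
            for j, day in enumerate(on_days):
                alt = base_alt * math.exp(rng.normal(0, sig.noise_sigma))
                tb = base_tb * math.exp(rng.normal(0, sig.noise_sigma))
                if event == "dili" and j >= onset:
                    ramp = 1.0 if j == onset else 0.7
                    alt = base_alt * (1 + (sig.dili_alt_xbl - 1) * ramp)
                    tb = base_tb * (1 + (sig.dili_tb_xbl - 1) * ramp)
                elif event == "efficacy" and j >= onset:
                    alt *= sig.efficacy_factor
                    tb *= sig.efficacy_factor
                elif event == "hemolysis" and j >= onset:
                    tb = max(tb, sig.hemolysis_tb_xuln * ULN["TB"])
                rows.append((subject, arm, "ALT", day, round(max(alt, 0.5), 1), ULN["ALT"]))
                rows.append((subject, arm, "TB", day, round(max(tb, 0.05), 2), ULN["TB"]))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, manifest


def write_trial_csv(records: pd.DataFrame, path: str | Path) -> Path:
    """Write records in the same CSV dialect ``read_lab_csv`` ingests."""
    path = Path(path)
    records.to_csv(path, index=False)
    return path
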