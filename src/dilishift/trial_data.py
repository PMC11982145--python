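"""Ingest of long-format trial laboratory data and per-subject derivation.

The in-memory container for laboratory records is a pandas DataFrame with
the canonical columns ``subject_id, arm, analyte, study_day, value, uln``
(one row per measurement; :class:`LabRecord` documents one row).  From it we
derive one :class:`SubjectProfile` per subject: the baseline value per
analyte (latest draw at study_day <= 0), the on-treatment peak and trough,
and the peak expressed as a multiple of the upper limit of normal (xULN)
and of the subject's own baseline (xBL).

Conventions (trial-standard where the underlying method is silent):

* baseline = latest value with study_day <= 0 (a day-0 pre-dose draw counts);
* duplicate (subject, analyte, day) rows resolve to the maximum value —
  conservative for safety screening — and are counted in the ingest report;
* the on-treatment window is (0, treatment_end_day + followup_lag_days],
  with a default 30-day follow-up lag;
* the aminotransferase ("AT") summary is ALT-only by default; the
  ``max(ALT, AST)`` policy takes, per study day, the larger xULN of the two
  enzymes and then the maximum over days (classical eDISH convention);
* a zero or missing baseline leaves xBL undefined: the subject remains in
  xULN analyses but is excluded, with a logged reason, from xBL plots.

Units are not converted: enzymes are assumed U/L and bilirubin mg/dL; the
xULN normalization makes units moot for categorization, but absolute-value
displays (the waterfall plot) assume U/L for ALT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ANALYTES = ("ALT", "AST", "TB", "ALP")
RECORD_COLUMNS = ["subject_id", "arm", "analyte", "study_day", "value", "uln"]

#: Column mapping for SDTM LB-domain style exports.
SDTM_LB_MAP = {
    "USUBJID": "subject_id",
    "ARM": "arm",
    "LBTESTCD": "analyte",
    "LBDY": "study_day",
    "LBSTRESN": "value",
    "LBSTNRHI": "uln",
}

__all__ = [
    "LabRecord",
    "TrialManifest",
    "SubjectProfile",
    "AnalyteSummary",
    "IngestReport",
    "read_lab_csv",
    "derive_baseline",
    "derive_profiles",
    "profiles_to_frame",
    "write_profiles_csv",
    "SDTM_LB_MAP",
]


@dataclass(frozen=True)
class LabRecord:
    """One analyte measurement for one subject at one study day."""

    subject_id: str
    arm: str
    analyte: str
    study_day: int
    value: float
    uln: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("value must be >= 0")
        if self.uln <= 0:
            raise ValueError("uln must be > 0")


@dataclass
class TrialManifest:
    """Arm labels and the analysis window for a two-arm trial."""

    active_arm: str
    comparator_arm: str
    treatment_end_day: int = 336
    followup_lag_days: int = 30

    def __post_init__(self) -> None:
        if self.active_arm == self.comparator_arm:
            raise ValueError("active and comparator arms must differ")
        if self.followup_lag_days < 0:
            raise ValueError("followup_lag_days must be >= 0")

    @property
    def arms(self) -> tuple[str, str]:
        return (self.comparator_arm, self.active_arm)

    @property
    def window_end(self) -> int:
        return self.treatment_end_day + self.followup_lag_days


@dataclass
class IngestReport:
    n_rows_read: int = 0
    n_dropped_unparseable: int = 0
    n_duplicates_resolved: int = 0
    n_records: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class AnalyteSummary:
    """Per-analyte derived quantities for one subject."""

    baseline: float | None = None
    baseline_xuln: float | None = None
    peak: float | None = None
    peak_xuln: float | None = None
    peak_xbl: float | None = None
    peak_day: int | None = None
    trough: float | None = None
    n_on_treatment: int = 0


@dataclass
class SubjectProfile:
    """Baseline and on-treatment summary for one subject."""

    subject_id: str
    arm: str
    analytes: dict[str, AnalyteSummary] = field(default_factory=dict)
    at_policy: str = "alt"  # "alt" or "max_alt_ast"
    flags: list[str] = field(default_factory=list)

    def summary(self, analyte: str) -> AnalyteSummary:
        return self.analytes.setdefault(analyte, AnalyteSummary())

    def baseline_xuln(self, analyte: str) -> float | None:
        s = self.analytes.get(analyte)
        return None if s is None else s.baseline_xuln

    def peak_xuln(self, analyte: str) -> float | None:
        s = self.analytes.get(analyte)
        return None if s is None else s.peak_xuln

    def analyzable(self, analyte: str) -> bool:
        s = self.analytes.get(analyte)
        return s is not None and s.peak is not None and s.baseline is not None

    # -- aminotransferase under the active policy -------------------------

    def at_baseline_xuln(self) -> float | None:
        if self.at_policy == "max_alt_ast":
            vals = [v for v in (self.baseline_xuln("ALT"), self.baseline_xuln("AST")) if v is not None]
            return max(vals) if vals else None
        return self.baseline_xuln("ALT")

    def at_peak_xuln(self) -> float | None:
        if self.at_policy == "max_alt_ast":
            vals = [v for v in (self.peak_xuln("ALT"), self.peak_xuln("AST")) if v is not None]
            return max(vals) if vals else None
        return self.peak_xuln("ALT")

    def shift_coordinates(self):
        """((baseline AT, baseline TB), (peak AT, peak TB)) in xULN, or None."""
        b_at, b_tb = self.at_baseline_xuln(), self.baseline_xuln("TB")
        p_at, p_tb = self.at_peak_xuln(), self.peak_xuln("TB")
        if None in (b_at, b_tb, p_at, p_tb):
            return None
        return (b_at, b_tb), (p_at, p_tb)


def read_lab_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, IngestReport]:
    """Read long-format laboratory data into the canonical record frame.

    Parameters
    ----------
    path : path to a CSV file
    column_map : mapping of source column name -> canonical field name
        (``subject_id, arm, analyte, study_day, value, uln``).  ``None``
        means the file already uses canonical names; :data:`SDTM_LB_MAP`
        covers SDTM LB-domain exports.

    Rows whose numeric fields do not parse are dropped and counted in the
    returned :class:`IngestReport`; duplicate (subject, analyte, day)
    triples resolve to the maximum value.

    Raises
    ------
    ValueError
        If the file is empty or a mapped column is missing.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if raw.empty:
        raise ValueError(f"{path}: no data rows")

    if column_map:
        missing = [c for c in column_map if c not in raw.columns]
        if missing:
            raise ValueError(f"{path}: mapped column(s) not found: {', '.join(missing)}")
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: required column(s) not found: {', '.join(missing)}")

    report = IngestReport(n_rows_read=len(raw))
    df = raw[RECORD_COLUMNS].copy()
    for col in ("study_day", "value", "uln"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["study_day", "value", "uln"]].isna().any(axis=1) | (df["value"] < 0) | (df["uln"] <= 0)
    report.n_dropped_unparseable = int(bad.sum())
    if report.n_dropped_unparseable:
        report.messages.append(f"dropped {report.n_dropped_unparseable} unparseable/invalid row(s)")
    df = df[~bad].copy()
    df["study_day"] = df["study_day"].astype(int)
    df["analyte"] = df["analyte"].str.upper().str.strip()
    # SDTM test codes for bilirubin differ from our short label
    df["analyte"] = df["analyte"].replace({"BILI": "TB", "TBIL": "TB"})

    key = ["subject_id", "analyte", "study_day"]
    n_dup = int(df.duplicated(key).sum())
    if n_dup:
        report.n_duplicates_resolved = n_dup
        report.messages.append(f"resolved {n_dup} duplicate (subject, analyte, day) row(s) by maximum")
        df = df.sort_values("value").drop_duplicates(key, keep="last")
    df = df.sort_values(["subject_id", "analyte", "study_day"]).reset_index(drop=True)
    report.n_records = len(df)
    for msg in report.messages:
        logger.info("%s: %s", path.name, msg)
    return df, report


def derive_baseline(records: pd.DataFrame, manifest: TrialManifest | None = None) -> pd.DataFrame:
    """Baseline per (subject, analyte): the value at the latest study_day <= 0.

    Returns a DataFrame with columns subject_id, analyte, baseline, uln,
    baseline_xuln.  Subjects lacking any pre-dose value for an analyte simply
    have no row; downstream derivation flags them.
    """
    pre = records[records["study_day"] <= 0]
    if pre.empty:
        return pd.DataFrame(columns=["subject_id", "analyte", "baseline", "uln", "baseline_xuln"])
    idx = pre.groupby(["subject_id", "analyte"])["study_day"].idxmax()
    base = pre.loc[idx, ["subject_id", "analyte", "value", "uln"]].rename(columns={"value": "baseline"})
    base["baseline_xuln"] = base["baseline"] / base["uln"]
    return base.reset_index(drop=True)


def derive_profiles(
    records: pd.DataFrame,
    manifest: TrialManifest,
    at_policy: str = "alt",
) -> list[SubjectProfile]:
    """Derive one :class:`SubjectProfile` per subject.

    The on-treatment window is ``(0, treatment_end_day + followup_lag_days]``.
    Subjects with no baseline or no on-treatment value for an analyte are
    flagged (``no-baseline:<analyte>`` / ``no-on-treatment:<analyte>``) rather
    than erroring; a zero baseline flags ``xbl-undefined:<analyte>``.
    """
    if at_policy not in ("alt", "max_alt_ast"):
        raise ValueError(f"unknown AT policy {at_policy!r}")
    base = derive_baseline(records, manifest)
    base_map = {(r.subject_id, r.analyte): r for r in base.itertuples()}
    on = records[(records["study_day"] > 0) & (records["study_day"] <= manifest.window_end)]

    profiles: dict[str, SubjectProfile] = {}
    arm_of = records.groupby("subject_id")["arm"].first()
    for sid, arm in arm_of.items():
        profiles[sid] = SubjectProfile(subject_id=str(sid), arm=str(arm), at_policy=at_policy)

    analytes_present = sorted(records["analyte"].unique())
    measured_pairs = set(map(tuple, records[["subject_id", "analyte"]].drop_duplicates().itertuples(index=False)))
    for (sid, analyte), grp in on.groupby(["subject_id", "analyte"]):
        prof = profiles[sid]
        s = prof.summary(analyte)
        i_peak = grp["value"].idxmax()
        s.peak = float(grp.loc[i_peak, "value"])
        s.peak_day = int(grp.loc[i_peak, "study_day"])
        s.peak_xuln = s.peak / float(grp.loc[i_peak, "uln"])
        s.trough = float(grp["value"].min())
        s.n_on_treatment = len(grp)

    for sid, prof in profiles.items():
        for analyte in analytes_present:
            s = prof.analytes.get(analyte)
            b = base_map.get((sid, analyte))
            if (sid, analyte) not in measured_pairs:
                continue
            if b is None:
                prof.flags.append(f"no-baseline:{analyte}")
            else:
                s = prof.summary(analyte)
                s.baseline = float(b.baseline)
                s.baseline_xuln = float(b.baseline_xuln)
            if s is None or s.peak is None:
                prof.flags.append(f"no-on-treatment:{analyte}")
            elif s.baseline is not None:
                if s.baseline > 0:
                    s.peak_xbl = s.peak / s.baseline
                else:
                    prof.flags.append(f"xbl-undefined:{analyte}")
    for prof in profiles.values():
        for flag in prof.flags:
            logger.debug("subject %s: %s", prof.subject_id, flag)
    return list(profiles.values())


def profiles_to_frame(profiles: Iterable[SubjectProfile]) -> pd.DataFrame:
    """Flatten profiles to one audit row per subject."""
    rows = []
    for p in profiles:
        row: dict = {"subject_id": p.subject_id, "arm": p.arm, "at_policy": p.at_policy,
                     "flags": ";".join(p.flags)}
        for analyte, s in sorted(p.analytes.items()):
            a = analyte.lower()
            row[f"{a}_baseline"] = s.baseline
            row[f"{a}_baseline_xuln"] = s.baseline_xuln
            row[f"{a}_peak"] = s.peak
            row[f"{a}_peak_xuln"] = s.peak_xuln
            row[f"{a}_peak_xbl"] = s.peak_xbl
            row[f"{a}_peak_day"] = s.peak_day
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles_csv(profiles: Iterable[SubjectProfile], path: str | Path) -> Path:
    path = Path(path)
    profiles_to_frame(profiles).to_csv(path, index=False)
    return path
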