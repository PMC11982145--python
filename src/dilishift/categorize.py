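"""Quadrant categorization of liver-test multiples and shift classification.

The screening grid divides the (aminotransferase, total bilirubin) plane —
both expressed as multiples of the upper limit of normal (xULN) — into
severity categories.  The standard four-quadrant scheme uses an AT cut of
3xULN (inclusive) and a TB cut of 2xULN (strict):

    NNN          AT < 3,  TB <= 2   (normal / near-normal)
    Temple       AT >= 3, TB <= 2   (Temple's Corollary: enzyme rise, no jaundice)
    Cholestasis  AT < 3,  TB > 2    (jaundice without substantial enzyme rise)
    HyLaw        AT >= 3, TB > 2    (potential Hy's Law: hepatocellular injury
                                     with jaundice, >=10% fatality risk)

Categories form a lattice ordered componentwise on the (AT band, TB band)
pair: a subject whose on-treatment category is strictly above their baseline
category has shifted *upward* (potential drug-induced liver injury), strictly
below is *downward* (improvement / efficacy), and incomparable pairs
(Temple vs Cholestasis) are *lateral* shifts.

Optional refinements supported by :class:`BandingScheme`: an extra TB band at
(1.5, 2]xULN for finer resolution in cirrhotic populations, and a split of
the low-AT band into Normal (ALT <= 1xULN) and NearNormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "QuadrantCategory",
    "BandingScheme",
    "ShiftRecord",
    "assign_quadrant",
    "classify_shift",
    "shift_records",
    "classify_trial_baseline",
    "report_proportion",
]


@dataclass(frozen=True)
class QuadrantCategory:
    """One cell of the severity grid.

    ``alt_band`` and ``tb_band`` are 0-based band indices (0 = least severe).
    In the standard scheme both run over {0, 1} and the four cells carry the
    canonical names NNN, Temple, Cholestasis, HyLaw.
    """

    name: str
    alt_band: int
    tb_band: int

    def dominates(self, other: "QuadrantCategory") -> bool:
        """Componentwise >= in the severity lattice."""
        return self.alt_band >= other.alt_band and self.tb_band >= other.tb_band

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


# Fixed severity-descending display order for the standard scheme.  The
# lattice leaves Cholestasis/Temple unordered; the TB-dominant category is
# placed higher because jaundice drives Hy's Law fatality risk.
STANDARD_ORDER = ("HyLaw", "Cholestasis", "Temple", "NNN")


@dataclass(frozen=True)
class BandingScheme:
    """Cut-offs defining the severity grid.

    Parameters
    ----------
    alt_cut : float
        Aminotransferase cut in xULN; the band boundary is *inclusive*
        (AT >= alt_cut is elevated).  Default 3.
    tb_cut : float
        Total bilirubin cut in xULN; the boundary is *strict*
        (TB > tb_cut is jaundiced).  Default 2.
    extra_tb_band : bool
        Add an intermediate TB band (1.5, tb_cut] for finer shift resolution
        (six categories).
    split_nnn : bool
        Split the low-AT band into Normal (ALT <= 1xULN) and NearNormal.
    """

    alt_cut: float = 3.0
    tb_cut: float = 2.0
    extra_tb_band: bool = False
    split_nnn: bool = False
    extra_tb_low: float = 1.5

    def __post_init__(self) -> None:
        if self.alt_cut <= 0 or self.tb_cut <= 0:
            raise ValueError("band cuts must be strictly positive")
        if self.extra_tb_band and not (0 < self.extra_tb_low < self.tb_cut):
            raise ValueError("extra TB band must sit below tb_cut")

    # --- band arithmetic -------------------------------------------------

    def _alt_band(self, at_xuln: float) -> int:
        band = 0
        if self.split_nnn and at_xuln > 1.0:
            band += 1
        if at_xuln >= self.alt_cut:
            band = self.n_alt_bands - 1
        return band

    def _tb_band(self, tb_xuln: float) -> int:
        band = 0
        if self.extra_tb_band and tb_xuln > self.extra_tb_low:
            band += 1
        if tb_xuln > self.tb_cut:
            band = self.n_tb_bands - 1
        return band

    @property
    def n_alt_bands(self) -> int:
        return 3 if self.split_nnn else 2

    @property
    def n_tb_bands(self) -> int:
        return 3 if self.extra_tb_band else 2

    def _name(self, alt_band: int, tb_band: int) -> str:
        top_alt = alt_band == self.n_alt_bands - 1
        top_tb = tb_band == self.n_tb_bands - 1
        if top_alt and top_tb:
            return "HyLaw"
        alt_part = ""
        if top_alt:
            alt_part = "Temple"
        elif self.split_nnn:
            alt_part = "Normal" if alt_band == 0 else "NearNormal"
        tb_part = ""
        if top_tb:
            tb_part = "Cholestasis"
        elif tb_band > 0:
            tb_part = f"TB{self.extra_tb_low:g}"
        if not alt_part and not tb_part:
            return "NNN"
        if alt_part and tb_part:
            return f"{alt_part}+{tb_part}"
        return alt_part or tb_part

    def category(self, alt_band: int, tb_band: int) -> QuadrantCategory:
        return QuadrantCategory(self._name(alt_band, tb_band), alt_band, tb_band)

    def categories(self) -> list[QuadrantCategory]:
        """All categories, severity-descending (top of a Sankey first)."""
        cats = [
            self.category(a, t)
            for a in range(self.n_alt_bands)
            for t in range(self.n_tb_bands)
        ]
        na, nt = self.n_alt_bands - 1, self.n_tb_bands - 1

        def key(c: QuadrantCategory) -> tuple:
            return (c.alt_band / na + c.tb_band / nt, c.tb_band / nt, c.alt_band)

        return sorted(cats, key=key, reverse=True)

    def by_name(self, name: str) -> QuadrantCategory:
        for c in self.categories():
            if c.name == name:
                return c
        raise KeyError(f"no category named {name!r} in this scheme")

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alt_cut": self.alt_cut,
            "tb_cut": self.tb_cut,
            "extra_tb_band": self.extra_tb_band,
            "split_nnn": self.split_nnn,
            "extra_tb_low": self.extra_tb_low,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandingScheme":
        return cls(**d)


def assign_quadrant(
    at_xuln: float, tb_xuln: float, scheme: BandingScheme | None = None
) -> QuadrantCategory:
    """Assign the severity category for peak (or baseline) multiples.

    The AT boundary is inclusive (>= alt_cut elevates) and the TB boundary
    strict (> tb_cut is jaundice); (3.0, 2.0) is therefore Temple, not HyLaw.

    Raises
    ------
    ValueError
        If either multiple is negative or non-finite.
    """
    scheme = scheme or BandingScheme()
    for v, label in ((at_xuln, "AT"), (tb_xuln, "TB")):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{label} multiple must be finite and >= 0, got {v!r}")
    return scheme.category(scheme._alt_band(at_xuln), scheme._tb_band(tb_xuln))


def classify_shift(origin: QuadrantCategory, destination: QuadrantCategory) -> str:
    """Direction of a baseline -> on-treatment category move.

    Returns one of ``upward`` (strictly more severe: potential DILI),
    ``downward`` (strictly less severe: improvement), ``lateral``
    (incomparable, e.g. Temple <-> Cholestasis), or ``none`` (no change).
    """
    if origin == destination:
        return "none"
    if destination.dominates(origin):
        return "upward"
    if origin.dominates(destination):
        return "downward"
    return "lateral"


@dataclass(frozen=True)
class ShiftRecord:
    subject_id: str
    arm: str
    origin: QuadrantCategory
    destination: QuadrantCategory
    direction: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", classify_shift(self.origin, self.destination))


def shift_records(profiles: Iterable, scheme: BandingScheme | None = None) -> pd.DataFrame:
    """Tabulate each analyzable subject's baseline -> peak category shift.

    Subjects lacking a baseline or on-treatment peak for AT or TB are
    omitted (upstream derivation flags them).  Returns a DataFrame with
    columns subject_id, arm, origin, destination, direction (category
    *names*; resolve with ``scheme.by_name`` if the objects are needed).
    """
    scheme = scheme or BandingScheme()
    rows = []
    for p in profiles:
        coords = p.shift_coordinates()
        if coords is None:
            continue
        (b_at, b_tb), (pk_at, pk_tb) = coords
        origin = assign_quadrant(b_at, b_tb, scheme)
        dest = assign_quadrant(pk_at, pk_tb, scheme)
        rows.append(
            {
                "subject_id": p.subject_id,
                "arm": p.arm,
                "origin": origin.name,
                "destination": dest.name,
                "direction": classify_shift(origin, dest),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "arm", "origin", "destination", "direction"])


def report_proportion(numerator: int, denominator: int) -> int:
    """Whole-number percent, rounded half-up (13 of 46 -> 28)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def classify_trial_baseline(
    profiles: Sequence,
    nnn_alt_cut: float = 3.0,
    nnn_tb_cut: float = 2.0,
    abnormal_fraction_threshold: float = 0.05,
) -> dict:
    """Classify a trial as normal/near-normal-baseline (NNN-BL) or not (ABN-BL).

    A trial is ABN-BL when the fraction of subjects whose *baseline*
    ALT >= ``nnn_alt_cut`` xULN or baseline TB >= ``nnn_tb_cut`` xULN exceeds
    ``abnormal_fraction_threshold``.  ``nnn_alt_cut`` is conventionally in
    [2, 3]; the default 3 aligns with the quadrant cut.

    Returns a summary dict including the per-band baseline fractions the
    applicability advisor consumes.
    """
    n = 0
    n_abnormal = 0
    n_alt_high = 0
    tb_low = tb_mid = tb_high = 0
    for p in profiles:
        b = p.baseline_xuln("ALT"), p.baseline_xuln("TB")
        if b[0] is None or b[1] is None:
            continue
        n += 1
        alt_x, tb_x = b
        if alt_x >= nnn_alt_cut or tb_x >= nnn_tb_cut:
            n_abnormal += 1
        if alt_x >= 3.0:
            n_alt_high += 1
        if tb_x > 2.0:
            tb_high += 1
        elif tb_x > 1.5:
            tb_mid += 1
        else:
            tb_low += 1
    if n == 0:
        raise ValueError("no subjects with complete ALT/TB baselines")
    frac = n_abnormal / n
    return {
        "label": "ABN-BL" if frac > abnormal_fraction_threshold else "NNN-BL",
        "n_subjects": n,
        "abnormal_fraction": frac,
        "abnormal_percent": report_proportion(n_abnormal, n),
        "alt_high_fraction": n_alt_high / n,
        "tb_band_fractions": {
            "le_1.5": tb_low / n,
            "1.5_to_2": tb_mid / n,
            "gt_2": tb_high / n,
        },
    }
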