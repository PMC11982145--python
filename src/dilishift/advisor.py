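"""Which screening toolset fits a trial's baseline liver-test pattern.

The two-step Sankey + cross-table + composite-plot workflow handles any
abnormal-baseline pattern.  The single-figure modified waterfall needs the
baseline bilirubin of (essentially) all subjects in the normal/near-normal
range — a substantial baseline-jaundiced (TB > 2xULN) subpopulation defeats
its new-jaundice highlighting.  "Substantial" is quantified here as a
configurable fraction (default 5%).

When no baseline abnormality is substantial the trial is a normal-baseline
trial and classical eDISH applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BaselinePattern", "Recommendation", "recommend_tools", "pattern_from_summary"]


@dataclass(frozen=True)
class BaselinePattern:
    """Baseline severity mix of a trial population.

    ``alt_high_fraction``: fraction with baseline ALT >= 3xULN.
    ``tb_low/mid/high_fraction``: fractions with baseline TB <= 1.5,
    in (1.5, 2], and > 2 xULN; they must sum to ~1.
    """

    alt_high_fraction: float
    tb_low_fraction: float
    tb_mid_fraction: float
    tb_high_fraction: float

    def __post_init__(self) -> None:
        fracs = (self.alt_high_fraction, self.tb_low_fraction,
                 self.tb_mid_fraction, self.tb_high_fraction)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        tb_sum = self.tb_low_fraction + self.tb_mid_fraction + self.tb_high_fraction
        if abs(tb_sum - 1.0) > 1e-6:
            raise ValueError(f"TB band fractions must sum to 1, got {tb_sum}")


@dataclass(frozen=True)
class Recommendation:
    sankey_composite: bool
    modified_waterfall: bool
    classical_edish: bool
    rationale: str

    def as_dict(self) -> dict:
        verdict = lambda b: "recommended" if b else "not_recommended"
        return {
            "sankey_composite": verdict(self.sankey_composite),
            "modified_waterfall": verdict(self.modified_waterfall),
            "classical_edish": verdict(self.classical_edish),
            "rationale": self.rationale,
        }


def pattern_from_summary(summary: dict) -> BaselinePattern:
    """Build a pattern from a ``classify_trial_baseline`` summary dict."""
    tb = summary["tb_band_fractions"]
    return BaselinePattern(
        alt_high_fraction=summary["alt_high_fraction"],
        tb_low_fraction=tb["le_1.5"],
        tb_mid_fraction=tb["1.5_to_2"],
        tb_high_fraction=tb["gt_2"],
    )


def recommend_tools(
    pattern: BaselinePattern, substantial_threshold: float = 0.05
) -> Recommendation:
    """Per-tool applicability from the baseline ALT/TB pattern.

    Sankey + cross-table + composite plotting is recommended for every
    abnormal-baseline pattern.  The modified waterfall is recommended only
    when the substantial TB mass sits at or below 2xULN (no substantial
    baseline jaundice); it is monotone: more baseline jaundice can only
    revoke, never grant, the recommendation.
    """
    sub = lambda f: f > substantial_threshold
    alt_abn = sub(pattern.alt_high_fraction)
    tb_jaundice = sub(pattern.tb_high_fraction)
    tb_mid = sub(pattern.tb_mid_fraction)
    any_abnormal = alt_abn or tb_jaundice or tb_mid

    if not any_abnormal:
        return Recommendation(
            sankey_composite=True,
            modified_waterfall=True,
            classical_edish=True,
            rationale=(
                "No substantial baseline ALT or TB abnormality: a normal/near-normal-"
                "baseline trial; classical eDISH applies directly (shift tools remain valid)."
            ),
        )
    waterfall = not tb_jaundice
    bits = []
    if alt_abn:
        bits.append(f"baseline ALT >= 3xULN in {pattern.alt_high_fraction:.0%} of subjects")
    if tb_mid:
        bits.append(f"baseline TB in (1.5, 2]xULN in {pattern.tb_mid_fraction:.0%}")
    if tb_jaundice:
        bits.append(f"baseline jaundice (TB > 2xULN) in {pattern.tb_high_fraction:.0%}")
    rationale = (
        "Abnormal-baseline trial (" + "; ".join(bits) + "). "
        + "Sankey + cross-tables with composite plotting recommended. "
        + (
            "Modified waterfall also applicable (no substantial baseline jaundice)."
            if waterfall
            else "Modified waterfall not recommended: substantial baseline jaundice "
            "defeats its new-jaundice highlighting."
        )
    )
    return Recommendation(
        sankey_composite=True,
        modified_waterfall=waterfall,
        classical_edish=False,
        rationale=rationale,
    )
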