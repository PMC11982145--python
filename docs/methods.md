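# Methods

## Categorization model

Subjects are categorized on the (AT, TB) plane in multiples of the upper
limit of normal (×ULN). The standard scheme cuts at AT 3×ULN (inclusive:
AT ≥ 3 is elevated) and TB 2×ULN (strict: TB > 2 is jaundice); the
figure-level definition of the quadrants uses exactly these conventions, so
the boundary point (3.0, 2.0) is Temple, not Hy's Law. Categories are
ordered componentwise on the (AT band, TB band) pair: strictly dominating
moves are *upward* shifts (potential DILI), strictly dominated moves
*downward* (improvement), and incomparable pairs (Temple ↔ Cholestasis)
*lateral* — colored yellow in cross-tables, since neither worsening nor
improvement is implied. Two refinements are available: an extra TB band at
(1.5, 2]×ULN (six categories) and a Normal (ALT ≤ 1×ULN) / NearNormal split
(the split cut is strict-above-1 so that ALT = 1×ULN is Normal). All
schemes partition the plane with no gaps or overlaps; a property test
checks this against an independently written brute-force oracle.

Display order (Sankey center column, cross-table axes) is severity-
descending with the fixed tie-break HyLaw > Cholestasis > Temple > NNN: the
lattice leaves Cholestasis/Temple unordered, and the TB-dominant category
is placed higher because jaundice drives Hy's Law fatality risk.

## Derivation conventions

* **Baseline** = the value at the latest study day ≤ 0 (a day-0 pre-dose
  draw counts). Subjects without a pre-dose value for a required analyte
  are flagged and excluded from analyses needing it, never erroring.
* **On-treatment window** = days in (0, treatment_end + lag], with a 30-day
  default follow-up lag — a convention, chosen as a typical washout/safety
  follow-up, not a fact of the underlying method.
* **Duplicates** (same subject, analyte, day) resolve to the maximum value:
  conservative for safety screening. The collision is counted in the ingest
  report.
* **AT policy**: ALT-only by default (the Sankey/waterfall analyses are
  ALT-based); `max_alt_ast` takes, per study day, the larger ×ULN of
  ALT/AST, then the maximum over days — the classical eDISH convention.
* **×BL** = peak / baseline; undefined when the baseline is 0 or missing.
  Such subjects stay in ×ULN analyses and are excluded, with a logged
  reason, from ×BL plots.
* **Percentages** are reported as whole numbers rounded half-up.
* Units are not converted. ×ULN makes units moot for categorization, but
  absolute-value displays (the waterfall) assume U/L for ALT.
* The trial-level NNN-BL/ABN-BL classifier uses ≥ for both its ALT and TB
  cuts (its cuts are its own parameters, distinct from the quadrant
  boundaries), and calls a trial ABN-BL when more than 5% (configurable) of
  subjects exceed either cut.

## Plots

* **eDISH** axes are log-scaled with reference lines at the scheme cuts;
  zero multiples are floored at 0.01 for display only. **mDISH** carries no
  quadrant lines — ×BL boundaries have no severity meaning.
* **Sankey** ribbon widths are within-arm proportions by default so a 1:3
  randomization stays comparable (absolute-count mode by flag); no-change
  subjects are drawn as flat grey ribbons so conservation is visually true.
  Composite-plot markers are fixed: NNN → green square, Temple → blue plus,
  Cholestasis → orange triangle, HyLaw → red star.
* **Waterfall** `max_magnitude` takes the signed on-treatment change of
  largest magnitude (ties keep the increase — safety-conservative); its
  known pathology is that a rise smaller than the subject's own decline is
  masked, which `max_increase` repairs. New-onset jaundice = peak TB above
  the jaundice cut with baseline TB at or below it. The waterfall is
  considered applicable when at most 2% (configurable) of subjects are
  jaundiced at baseline. Box-whisker flanks use the Tukey convention
  (1.5·IQR) and summarize *bar values* — a deliberate choice; summarizing
  absolute peaks is the other defensible reading.
* Figures are byte-deterministic for fixed input (fixed SVG hash salt, no
  embedded dates), so re-running a screen is byte-identical.

## Advisor

Sankey + cross-table + composite plotting is recommended for every
abnormal-baseline pattern; the modified waterfall only when the substantial
TB mass sits at or below 2×ULN. "Substantial" is quantified at 5% of
subjects (configurable) — the underlying guidance is deliberately
qualitative. When no baseline abnormality is substantial, the advisor
reports that classical eDISH applies. The waterfall recommendation is
monotone in the baseline-jaundice fraction.

## Priority list

Subjects in upward shifts, ordered by destination severity, then peak TB
×ULN, then peak AT ×ULN, descending. Both arms are listed by default:
placebo upward shifts contextualize background disease progression
(`--active-only` restricts to the active arm).

## Synthetic data

The **simulator** draws each subject's baseline category from the arm's
mix, samples (ALT, TB) log-uniformly strictly inside the category's band
cell (bands capped at 10×ULN ALT and 6×ULN TB for realism, floored at
0.3×ULN), and evolves on-treatment values as baseline × lognormal noise
(σ = 0.08 per visit by default). At most one signal event per subject
(priority DILI > efficacy > hemolysis) modifies the trajectory from a
random onset visit: a DILI surge scales ALT (and optionally TB) in ×BL, an
efficacy event multiplies ALT/TB down, a hemolysis event raises TB without
touching ALT — emulating drugs whose isolated jaundice is hemolytic, not
hepatocellular. The default visit schedule is days −14 and −1, then every
28 days to day 336. Output is deterministic per seed.

The **fixtures** are constructed, not sampled: only published-style
marginals are pinned (arm sizes 46+46 and 254+765; baseline Hy's Law counts
13/17; baseline Temple counts 26/81; upward paths 5 vs 3 totaling 15 vs 13
with placebo NNN→HyLaw = 2; five Hy's Law-destination subjects, 4 from NNN
and 1 from Temple; exactly one baseline-jaundiced subject), and all
remaining mass is placed deterministically on the diagonal (no category
change). Within-cell values are spread deterministically by subject index.
Fixture visit schedules are short (−14, −1, 28, 56, 84) to keep the test
and reproduction runs fast at these subject counts. The fixtures exercise
the categorization/aggregation machinery end to end; they are not
reconstructions of any real trial's patient data, whose unpinned cells are
unknowable.

What passing tests on synthetic data do **not** show: real laboratory data
have visit-level missingness, assay switches with changing ULNs, dose
interruptions, and disease-driven drift that the generator does not
emulate; the toolkit's ingest flags handle missingness, but its screening
value on real data is a scientific question, not a tested property.

## Numerical choices and edge cases

* Category assignment requires finite, non-negative multiples; anything
  else is a hard error (upstream validation should have caught it).
* Band sampling/placement pads away from cut boundaries so that CSV
  rounding (1 decimal for enzymes, 2 for TB) cannot flip a category.
* Empty arms, empty destination sets, and placebo-only waterfalls render
  without error; an empty input file is a hard error before any output.
* The simulator's conservation properties (outflow per baseline category =
  category count; cross-table grand total = arm size; flow-set and
  cross-table counts agree cell-by-cell) are audited over 100 seeds in the
  test suite and re-audited by `scripts/acceptance.py`.

## Known limitations

* Two arms only; multi-arm trials and dose-interruption windows are out of
  scope.
* No ALP-based cholestatic analogue: ALP is carried as an annotation on the
  Hy's Law flag only, since no numeric "substantial ALP elevation"
  threshold is defined.
* No causality adjudication and no fatality-rate estimates: upward-shift
  groupings in abnormal-baseline trials have no validated fatality rates,
  so the priority list is a review queue, not a risk estimate.
* eDISH peaks pair independent per-analyte maxima (possibly from different
  days), which can overstate simultaneity of the AT and TB elevations.
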