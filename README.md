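# dilishift

Liver-safety screening graphics for clinical trials whose subjects may have
**abnormal baseline liver tests** — the populations (chronic liver disease,
MASLD) where the classical eDISH plot stops working.

## The problem

eDISH (evaluation of Drug-Induced Serious Hepatotoxicity) plots each
subject's peak on-treatment aminotransferase (AT) against peak total
bilirubin (TB), both in multiples of the upper limit of normal (×ULN), and
divides the plane at AT ≥ 3×ULN and TB > 2×ULN into four quadrants: NNN
(normal/near-normal), Temple's Corollary (AT elevated, no jaundice),
Cholestasis (jaundice without AT elevation), and the potential **Hy's Law**
quadrant (hepatocellular injury with jaundice, ≥ 10% fatality risk). In a
trial with normal baselines this one figure shows between-arm shift,
severity categorization, and which subjects to review in depth. When
subjects are *already* abnormal at baseline, a peak in the Hy's Law quadrant
may be no change at all — or even an improvement — and eDISH loses all
three functions. Plotting peaks in multiples of each subject's own baseline
(×BL, "mDISH") restores shift visualization but destroys categorization:
subjects with identical ×BL ratios can differ ten-fold in absolute values.

`dilishift` implements the screening toolkit for such trials:

* **Quadrant categorization & shift classification** — baseline and
  on-treatment peak categories form a lattice; moves strictly up are
  potential DILI, strictly down are improvement, Temple ↔ Cholestasis is
  lateral. Optional extra TB band (1.5, 2]×ULN and a Normal/NearNormal
  split.
* **Sankey plots + cross-tables** — pooled baseline categories in a center
  column (Hy's Law topmost), placebo flows left, active drug right; upward
  ribbons pink, downward green. Cross-tables tally each shift with
  red/green/grey/yellow classes. Proportional ribbon widths keep unequal
  (e.g. 1:3) randomizations comparable.
* **Composite mDISH plots** — one ×BL panel per destination quadrant, each
  subject marked by its origin quadrant, recovering case identification.
* **Modified waterfall plot** — subjects ordered by baseline ALT (placebo
  ascending, active descending, highest baselines meeting in the middle),
  bars for the maximum on-treatment ALT change, green bars for new-onset
  jaundice, horizontal severity cut-offs (300/600/900 U/L), Tukey
  box-whisker flanks. Modes: `max_magnitude` (signed change of largest
  magnitude) and `max_increase` (never masks a rise).
* **Advisor** — which toolset applies, from the trial's baseline ALT/TB
  pattern.
* **Synthetic trials** — a seeded simulator with configurable baseline
  severity mixes and injectable signals (hepatocellular DILI, efficacy,
  hemolysis-type isolated jaundice), plus two constructed fixtures with
  pinned category marginals for testing.

## Worked example

```python
from dilishift import (study2_fixture, derive_profiles, shift_records,
                       build_cross_table, composite_points, report_proportion)

records, manifest = study2_fixture()          # 1:3 trial, 1019 subjects
profiles = derive_profiles(records, manifest)
shifts = shift_records(profiles)

temple = shifts.query("arm == 'active' and origin == 'Temple'")
print(report_proportion(len(temple), (shifts.arm == 'active').sum()))  # 11

table = build_cross_table(shifts, "active")
print(table.red_total(), table.red_paths())   # 8 3

hy = composite_points(profiles, "HyLaw")
print(len(hy), hy.origin.value_counts().to_dict())  # 5 {'NNN': 4, 'Temple': 1}
```

11% of active-arm subjects start in Temple's quadrant; during treatment 8
subjects across 3 distinct paths shift upward; 5 subjects end in the Hy's
Law quadrant (4 from NNN, 1 from Temple) — these head the priority list for
case-level review.

From the shell:

```bash
dilishift fixtures --study 2 --out labs.csv
dilishift screen config.yaml                # full bundle: figures, tables, priority list
dilishift simulate design.yaml --seed 7 --out sim.csv
dilishift advise --alt-high-frac 0.3 --tb-low-frac 0.5 --tb-mid-frac 0.1 --tb-high-frac 0.4
```

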