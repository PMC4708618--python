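# spillover-cea

Decision rules and analysis tools for **internalizing family health
spillovers in cost-effectiveness analysis**.

Health care interventions often change the health of more people than the
patient: treating a child's behavioral problems relieves the strain on the
parents who care for them; withdrawing a service elsewhere in the system
raises the anxiety of *those* patients' families. Extra-welfarist economic
evaluation — which funds an intervention when it generates more health than
its budget displaces — conventionally counts only patient health on both
sides of that comparison, implicitly valuing every spillover at zero. This
package implements a framework that brings spillovers into the decision
rule without requiring every displaced activity to be measured.

## The model

The conventional funding rule compares the incremental cost-effectiveness
ratio with a threshold *k*<sub>p</sub> (cost per unit of patient health
displaced elsewhere):

&nbsp;&nbsp;&nbsp;&nbsp;fund ⇔ Δ*c* / Δ*h*<sub>p</sub> < *k*<sub>p</sub>

Spillovers enter through two **multiplier effects** — ratios of total
(patient + network) to patient incremental health, one for the stream of
health *generated* by the intervention and one for the stream *displaced*
by funding it:

&nbsp;&nbsp;&nbsp;&nbsp;*m*<sub>i</sub> = (Δ*h*<sub>p</sub> + Δ*h*<sub>n</sub>) / Δ*h*<sub>p</sub>,&nbsp;&nbsp;&nbsp;
*m*<sub>d</sub> = (Δ*h*<sub>dp</sub> + Δ*h*<sub>dn</sub>) / Δ*h*<sub>dp</sub>

and the adjusted rule becomes

&nbsp;&nbsp;&nbsp;&nbsp;fund ⇔ (Δ*c* / Δ*h*<sub>p</sub>) · (*m*<sub>d</sub> / *m*<sub>i</sub>) < *k*<sub>p</sub>

When the two multipliers are equal the correction cancels: patient-only
decision making already maximizes societal health. Decisions change — and
health is gained or lost — exactly when spillovers differ between what an
intervention generates and what its funding displaces.

The package provides, as both a Python library and a `spillover-cea`
command-line tool:

- **`decision_core`** — the conventional, multiplier-adjusted and direct
  two-stream funding rules, with strict-inequality threshold semantics;
- **`portfolio`** — funding a menu of care packages under information
  scenarios that recognize 0, 1 or 2 affected network members, and the
  realized (full-information) net health benefit of each scenario's choices;
- **`marginal_analysis`** — linear marginal-benefit/loss schedules scaled
  by multipliers: equilibrium quantities, welfare triangles, and the
  corner-solution test for when an intervention should not be funded at all;
- **`spillover_estimation`** — per-role OLS regression of a health-utility
  index (EQ-5D-5L-like, adjusted for age, sex and years since illness
  onset) on condition indicators, and conversion of the estimated patient
  and carer decrements into multipliers;
- **`synthetic_cohort`** — a seeded generator of patient–carer dyads with
  known decrements, so the whole estimation pipeline is testable without
  any external dataset.

## Worked example

The built-in reference example analyzes six £2 million packages of care
for three after-effects of meningitis. Each £2 million of spending
displaces 100 units of patient health (a £20,000/unit threshold) and 16
units of carer health per affected carer. Condition-specific multipliers
come from measured utility decrements: e.g. behavioral problems depress
the patient index by 0.109 and each carer's by 0.030, giving
*m*<sub>i</sub> = 1.28 with one carer and 1.56 with two.

```text
$ spillover-cea reproduce
[ok] multiplier behavioral_problems n=1: computed 1.28, pinned 1.28
[ok] multiplier behavioral_problems n=2: computed 1.56, pinned 1.56
[ok] multiplier learning_disability n=1: computed 1.56, pinned 1.56
[ok] multiplier learning_disability n=2: computed 2.12, pinned 2.12
[ok] multiplier amputation n=1: computed 1.02, pinned 1.02
[ok] multiplier amputation n=2: computed 1.04, pinned 1.04
[ok] threshold n=0: computed 100.0, pinned 100.0
[ok] threshold n=1: computed 116.0, pinned 116.0
[ok] threshold n=2: computed 132.0, pinned 132.0
[ok] displacement multiplier n=1: computed 1.16, pinned 1.16
[ok] displacement multiplier n=2: computed 1.32, pinned 1.32

perceived benefits (rows: package; columns: recognized members)
  behavioral_problems:A       120     154     187
  behavioral_problems:B        80     102     125
  learning_disability:A        80     125     170
  learning_disability:B        70     109     148
  amputation:A                120     122     125
  amputation:B                110     112     114
[ok] net benefit, patient-only decisions: computed 30.0, pinned 30.0
[ok] net benefit, full information: computed 109.0, pinned 109.0
[ok] loss from ignoring displaced spillovers: computed 32.0, pinned 32.0

all pinned values reproduced
```

Reading the table: with spillovers unrecognized (first column, threshold
100) the decision maker funds behavioral A and both amputation packages —
choices that actually deliver only 30 units of net health once all
spillovers are counted. Recognizing both carers (last column, threshold
132) funds behavioral A and both learning-disability packages instead,
delivering 109 units. Recognizing generated spillovers but leaving the
threshold unadjusted (*m*<sub>d</sub> treated as 1) would fund all six
packages and lose a further 32 units relative to the optimum: spillovers
must be counted on both sides of the ledger.

The same numbers are available programmatically:

```python
from spillover_cea import (reference_care_packages, reference_scenario,
                           select_funding, realized_net_benefit)

menu = reference_care_packages()
full = reference_scenario(2)          # both carers recognized
funded = select_funding(menu, full)   # perceived benefit > 132 units
print(funded)
# ('behavioral_problems:A', 'learning_disability:A', 'learning_disability:B')
print(realized_net_benefit(funded, menu, full))
# 109.0
```

Other subcommands: `decide` (verdict table for an intervention CSV against
a threshold config), `multipliers`, `portfolio`, `marginal` (equilibrium
quantities, welfare triangle and corner verdict, with an optional schedule
plot), `estimate` (decrements and multipliers from a cohort CSV) and
`simulate` (synthetic cohort generation). See `spillover-cea COMMAND
--help` for each.

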