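# Methods

## Model structure and assumptions

The model is a discrete-time Markov cohort simulation over five states: WHO
functional class (FC) I–IV and death, with death absorbing. Cycles are 26
weeks (0.5 years); the horizon is 30 years, i.e. 60 cycles. The cohort
enters at age 36, 75.72% female, split 50/50 between FC II and FC III, and
every surviving patient stays on therapy for the whole horizon.

Two treatment strategies are compared: dual oral therapy (macitentan +
tadalafil) and triple therapy adding selexipag. In the **first** cycle a
patient may stay, improve to the adjacent class (FC II→I, FC III→II — the
trial recorded no improvement out of FC IV), worsen to the adjacent class,
or die. In **subsequent** cycles improvement is assumed impossible (therapy
delays progression but no long-term improvement data exist), leaving stay /
worsen / die. This one-cycle-improvement assumption is conservative for the
triple arm.

### Transition probabilities

Improvement probabilities are subgroup proportions k/n at the 26-week
assessment; worsening events were rare, so a pooled per-arm proportion is
applied identically to FC I→II, II→III and III→IV. No continuity correction
is used. The published table's triple-arm FC II→I value (0.261) is
inconsistent with the narrative count of 6 improvements among 22 FC II
patients (6/22 = 0.273; 6/23 = 0.261); the tabulated 0.261 is taken as
canonical and the discrepancy is noted here rather than silently resolved.

### Mortality

Background mortality comes from a life table of annual death probabilities
by single year of age and sex. Each class's per-cycle death probability is

    q_cycle = 1 − exp(−HR · r · t),   r = −ln(1 − q_annual)

with t = 0.5 years. Design choices where the source analysis is silent:

* The hazard ratio multiplies the **rate**, not the probability — HRs are
  hazard ratios, and this makes doubling the HR square the cycle survival.
* Male and female annual probabilities are converted to rates first and the
  **rates** are mixed with the (constant) 0.7572 female fraction;
  differential sex survival is not propagated. At these magnitudes the
  difference from probability-space mixing is negligible.
* The cohort ages 0.5 years per cycle; the life-table row is selected by
  floor(age), and ages beyond the table maximum clamp to the last row.
* Exact reproduction of the source totals would require the original census
  life table and knowledge of its sex-weighting; neither is available, so
  agreement is assessed qualitatively (see "What the tests show").

### Matrix composition

Death competes first: the per-cycle death probability d_i is taken off the
top and the trial-derived improvement/worsening probabilities apply
conditionally on survival (multiplied by 1 − d_i), with "stay" absorbing the
remainder. This keeps every row stochastic for all valid inputs. FC IV never
improves; FC I worsens with the pooled probability.

### Costs, utilities, discounting

Costs are USD per 26-week cycle (converted at 7.17 RMB/USD): drug costs
(selexipag has a cheaper titration-phase first cycle, $9,850.78, then
$10,769.93 per maintenance cycle; macitentan $3,502.98; tadalafil $480.64),
hospitalization ($1,290.40 for FC I–III, $2,580.80 for FC IV), outpatient
registration ($16.874 per cycle, already aggregating the 6.5 four-weekly
visits) and follow-up examinations ($182.354). Only direct medical costs are
included; adverse-event management is out of scope. Annual utilities are
0.730/0.670/0.600/0.520 for FC I–IV.

Accrual timing: the occupancy at the **start** of each cycle earns a full
cycle of cost and utility (QALYs = occupancy × utility × 0.5 y); deaths
during a cycle forfeit that cycle. No half-cycle correction is applied by
default, but `EconSettings(half_cycle_correction=True)` averages start- and
end-of-cycle occupancy for exploration. Discounting is discrete at 5%/year
(0–8% in sensitivity analysis): cycle k is discounted by (1.05)^(−0.5k), the
same factor for costs and QALYs. This accrual convention is the main lever
if exact reproduction with a real census table is attempted.

## Uncertainty analyses

**Distribution fitting.** Ranges are treated as symmetric 95% intervals, so
sd = (high − low)/3.92. Probabilities and utilities get beta distributions
and costs gamma distributions by method of moments with mean = base value;
hazard ratios get log-normal distributions with **median** = base value
(meanlog = ln base, sdlog = (ln high − ln low)/3.92), the usual convention
for published HRs. Whether the original analysis used moment matching is not
stated; PSA summaries could differ for that reason. Median-anchoring of the
HRs means the PSA mean effect can drift slightly from the deterministic
base case; the tests bound this drift instead of assuming it away.

**One-way sensitivity analysis** moves each parameter to its lower and upper
limits with everything else fixed, plus the discount rate over 0–8%. The two
selexipag cycle costs move jointly as a single "cost of selexipag" bar (they
are two expressions of one price). The FC I hazard ratio has no published
range and is excluded. Entries are sorted by ICER span, largest first.

**PSA** draws every non-fixed parameter independently (no correlation
structure was published) from one seeded `numpy.random.Generator` in
parameter-set field order, 5,000 draws by default. Each arm's pooled
worsening probability is drawn once and shared across its three transitions.
Draws whose improvement + worsening probabilities exceed 1 are resampled
(preserving the stated families) and counted; hazard-ratio ordering
inversions are counted but kept, since no ordering constraint was imposed.
The acceptability curve evaluates P(WTP·ΔE − ΔC > 0) on a $0–600,000 grid in
$5,000 steps.

**Threshold pricing** scales both selexipag cycle costs proportionally to a
monthly price (one 26-week cycle ≈ 6 months, matching how the drug-cost
table treats a cycle) and bisects on [0, 5000] USD/month to $0.01. Only
triple-arm costs depend on the price, linearly, so the ICER is affine and
increasing in price and the root is unique once bracketed.

**Scenarios.** Fixed-dose scenarios cost selexipag at a flat monthly price
($430 at 0.2 mg bid, $2,483 at 1.6 mg bid) × 6 months per cycle from cycle 0
(a fixed dose has no titration discount); efficacy is unchanged. Cohort
scenarios start everyone in FC II or FC III. The per-cycle conversion behind
the originally published scenario ICERs is not derivable from the text, so
scenario agreement is directional.

## Synthetic life table

The generator emulates adult mortality with a Gompertz hazard:
q(x, sex) = 1 − exp(−a·m_sex·e^(bx)), defaults a = 6×10⁻⁵, b = 0.09 per
year, female multiplier 0.5, ages 0–105. This puts the male annual death
probability at the cohort entry age (36) near 1.5×10⁻³ and q(100) near 0.4 —
order-of-magnitude realism for a contemporary East Asian population. It is
**not** a census table: it has no infant-mortality hump, no accident bump in
young adulthood, and a smooth old-age tail. Consequently the pipeline's
totals (costs ≈ $105.8k vs $327.3k, QALYs ≈ 6.11 vs 6.64, ICER ≈ $416k/QALY
at base case) are close to but not equal to the originally published totals;
passing tests demonstrate the pipeline's internal correctness and the
robustness of the qualitative conclusion (ICER an order of magnitude above
the WTP), not numeric agreement with the original life table.

Trial-count simulation is binomial per functional-class subgroup (pooled for
worsening), so the count-based estimator can be checked for parameter
recovery; parameter-set jitter draws each base value uniformly within its
printed range (rejecting draws that break the utility/HR orderings), all
under explicit seeds.

## Numerical choices and limitations

* Row-stochasticity is enforced to 1e-12 at assembly and 1e-10 over traces.
* ICERs are computed from full-precision totals, never from rounded
  increments; dominance cases are labelled instead of reported as ratios.
* Degenerate parameter ranges yield zero-span tornado bars; they cannot be
  sampled (requesting a distribution for them is an error by design).
* Problem sizes: 60 cycles per run; 5,000 PSA draws in the reproduction
  script and 300–500 in the test suite, which recover sampling anchors
  within 3 standard errors at those sizes.
* Cohort-level expectation only (no microsimulation, no EVPI); no
  correlation between sampled parameters; no adverse-event or societal
  costs; efficacy held fixed across dose scenarios.
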