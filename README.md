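# pahcea

Markov cohort cost-effectiveness analysis of adding **selexipag** (an oral
prostacyclin receptor agonist) to dual background therapy with **macitentan**
(endothelin receptor antagonist) and **tadalafil** (PDE5 inhibitor) in
pulmonary arterial hypertension (PAH), from a healthcare-system perspective.
It is written for health-economics analysts who want a scriptable,
reproducible alternative to spreadsheet/TreeAge-style cohort models.

## The model

Patients occupy one of five mutually exclusive Markov states: WHO functional
class I–IV and death (absorbing). The cycle length is 26 weeks (matching the
trial's assessment window) over a 30-year horizon (60 cycles). In the first
cycle a patient may stay, improve one class, worsen one class, or die; in
every later cycle therapy can only delay progression, so improvement is no
longer possible.

Transition probabilities come from trial counts: improvement is the subgroup
proportion k/n per functional class (e.g. 3/23 = 0.130 for FC II→I on dual
therapy), and a pooled worsening probability per arm applies to each
adjacent-class deterioration. Mortality applies published hazard ratios per
class (HR_FCI = 5.18 … HR_FCIV = 57.47) to general-population life-table
rates via

    r = −ln(1 − p) / t,   p = 1 − e^(−HR·r·t)

Discounted costs (USD per cycle: drugs, hospitalization by class,
registration, follow-up) and QALYs (annual utilities 0.73/0.67/0.60/0.52 by
class × life-years) accumulate over the trace at a 5% annual rate, yielding
the incremental cost-effectiveness ratio ICER = ΔC/ΔE against a
willingness-to-pay (WTP) threshold of $38,223.339/QALY. Uncertainty is
handled by one-way sensitivity analysis (tornado), 5,000-draw probabilistic
sensitivity analysis (beta/gamma/log-normal parameter distributions fitted
by method of moments), cost-effectiveness acceptability curves, threshold
pricing of selexipag, and dose/initial-severity scenarios.

The national census life table behind the original analysis is not
redistributable, so the package ships a synthetic Gompertz "china-like" life
table (`pahcea.synthetic`) and reads any real table from CSV
(`age,q_male,q_female`).

## Worked example

```python
from pahcea import MarkovCEA

res = MarkovCEA().fit()          # base case, synthetic life table
print(res.summary())
```

prints

```
Markov cohort cost-effectiveness analysis: add-on selexipag in PAH
horizon 30 y (60 cycles of 26 weeks), discount 5.0%/y, WTP $38,223.339/QALY

                     strategy    cost_usd  qalys  incremental_cost_usd  incremental_qalys  icer_usd_per_qaly
dual (macitentan + tadalafil) 105,809.781  6.111                   NaN                NaN                NaN
         triple (+ selexipag) 327,320.335  6.644           221,510.555              0.533        415,681.524

NMB at WTP: $-201,141.901
triple arm cost-effective at WTP: no
```

Adding selexipag buys 0.533 QALYs at an extra $221.5k — an ICER of
$415.7k/QALY, roughly eleven times the WTP, so triple therapy is not
cost-effective at current prices. Downstream analyses hang off the same
objects:

```python
res.owsa()                    # tornado table (DataFrame)
draws = res.psa(n=5000, seed=1)
draws.prob_cost_effective(38_223.339)   # 0.0
res.price_threshold()         # ~$126/month: selexipag price at which ICER = WTP
```

The same pipeline is scriptable from the shell:

```bash
pahcea basecase --outdir out          # traces, CEA summary, manifest
pahcea psa --n 5000 --seed 1 --outdir out
pahcea threshold --outdir out
pahcea scenario --outdir out          # fixed-dose and all-FC-II/III scenarios
```

Every subcommand accepts `--config cfg.yaml` (any subset of parameters;
omitted fields take the published base values) and `--life-table lt.csv`.

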