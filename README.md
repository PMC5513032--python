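# cervical-ce

Markov cohort cost-effectiveness model of once-in-a-lifetime cervical
cancer screen-and-treat strategies for HIV-infected women attending an HIV
treatment clinic, parameterized for a Kenyan setting (2014 USD).

Cervical cancer is a leading cause of cancer death among women in
sub-Saharan Africa, and HIV-infected women face both higher lesion
prevalence and competing HIV-related mortality. This package is for health
economists and epidemiologists who need a transparent, fully tested
implementation of the standard decision-analytic comparison for this
setting: screen (and treat screen-positives) once at a fixed age, versus
treating every woman with cryotherapy without screening.

## Model

A deterministic cohort of women aged 38 moves monthly through eleven
health states

> Normal, LSIL, HSIL, local/regional/distant invasive cancer, three
> treated-cancer states, death from cancer, death from other causes

with stage-specific monthly progression, regression and cancer-mortality
probabilities, and age-specific background mortality *q*(age) scaled by a
standardized mortality ratio (SMR 1.77) on the hazard scale:
*q*ₘ = 1 − (1 − *q*)^(SMR/12). Seven strategies are compared: preventative
cryotherapy for all (no screen, 1 visit), VIA (1 visit), Pap or HPV testing
(2 visits), and the three test pairs (3 visits), with loss to follow-up of
32%/48% before the treatment visit of 2-/3-visit cascades. Test positivity
is against a CIN2+ (HSIL or worse) gold standard; treated HSIL reverts to
Normal with 90% efficacy (80% cryotherapy / 20% LEEP); screen-detected
cancers are staged (colposcopy) and treated (monthly cure probability 0.15,
residual cancer mortality ×0.1). Costs and life-years are discounted at
0.25% per month (3%/year). Lifetime cost is reported from a societal and a
clinic perspective; life expectancy from screening is reported discounted
and undiscounted.

An individual-level Monte-Carlo simulator with the identical cascade and
transition logic cross-validates the cohort engine.

## Worked example

```python
from cervical_ce import (load_parameters, kenya_female_2011_synthetic,
                         run_all, ltfu_threshold)

params = load_parameters()                 # bundled base case, CD4 200-500
lt = kenya_female_2011_synthetic()         # synthetic Kenya-like mortality
print(run_all(params, lt).round(2))
print(ltfu_threshold(params, lt))
```

prints (costs in 2014 USD, life expectancy in discounted years from
screening):

```
   strategy  cost_societal  le_discounted  le_undiscounted  cost_clinic
0  cryo_all         154.47          19.01            31.10        28.91
1       VIA         191.66          18.91            30.88        37.88
2       Pap         208.35          18.88            30.80        48.75
3       HPV         209.40          18.89            30.84        45.86
4   VIA+HPV         245.28          18.81            30.66        56.38
5   VIA+Pap         252.80          18.80            30.64        61.87
6   HPV+Pap         259.77          18.82            30.68        69.02
0.06908373671374511
```

Preventative cryotherapy is the cheapest strategy from both perspectives
and yields the highest life expectancy; VIA is the cheapest screening test;
test pairs cost more and save fewer life-years than their component tests
(joint testing is less sensitive). The final number is the threshold
analysis: a two-visit HPV programme would match single-visit VIA's societal
cost if loss to follow-up fell from 32% to about 7% on this life table.
Absolute cost and life-expectancy levels depend on the mortality schedule:
substitute a WHO life-table export (see
`src/cervical_ce/data/life_table_format.md`) via `read_life_table` for
country-accurate numbers.

The numbered drivers under `analysis/` run the full study — life table,
base-case/CD4-scenario table, single-visit conversion, tornado sensitivity
analyses, LTFU threshold, microsimulation cross-check — writing tables to
`results/`.

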