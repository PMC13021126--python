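# triscreen

Tools for analysing **concurrent participation in the three cancer screening
programmes** offered to English women — breast, cervical and bowel — during
the years (early 60s) when all three invite simultaneously.  The package is
aimed at screening epidemiologists who want to ask not "what is the uptake of
programme X?" but "how many people are up to date with *all* the screening
recommended to them, and is joint participation explainable by chance?"

## The model

Each woman has a reference date (the last date she was known to be alive).
She counts as a last-round participant in a programme if she has at least one
completed screen in a programme-specific look-back window ending at the
reference date — the recommended interval plus one year of slack: **6 years
(cervical), 4 years (breast), 3 years (bowel)**.  Windows are half-open
`[anchor − L years, anchor)`.

To test whether joint participation is a random event, the cohort is split
into *ever participants* (N<sub>EP</sub>, at least one screen ever in any
programme) and *never participants* (N<sub>NP</sub>).  Under the randomness
null, participation is independent across programmes among ever participants
and never participants never participate:

```
E[all three] = N_EP · (N_breast/N_EP)(N_cervix/N_EP)(N_bowel/N_EP)
E[none]      = N_EP · ((N_EP−N_breast)/N_EP)((N_EP−N_cervix)/N_EP)((N_EP−N_bowel)/N_EP) + N_NP
```

Each headline cell is compared with its expectation by a 1-df Pearson χ² on
the dichotomy {in cell, not in cell}.  Group contrasts use **relative
proportions** RP = (a/n₁)/(b/n₂) with 95% CIs from the log-scale delta
method, var(ln RP) = 1/a − 1/n₁ + 1/b − 1/n₂.

A companion ecological analysis labels general practices **below / mixed /
above** the national average coverage (72.1 / 71.7 / 57.3 %) in all three
programmes concurrently, tertiles six practice characteristics (deprivation,
unemployment, long-term conditions, carers, smoking, patient satisfaction),
and estimates unadjusted (contingency-table) and mutually adjusted
(logistic-regression) odds ratios.

Because the individual-level microdata are an undeposited NHS extract, the
package ships a **Gaussian-copula synthetic-data generator**: a latent
trivariate normal with equicorrelation ρ thresholded at the marginal
quantiles, a structural never-participant class, event dates placed inside
the appropriate windows, and a practice generator whose coverage class
follows a known logistic model — so every pipeline stage is testable
end-to-end without any download.

## Worked example

```python
from triscreen import (WomanSimParams, simulate_women, classify_last_round,
                       count_concurrence, null_test)
from triscreen.records import ever_participant_flags

women = simulate_women(WomanSimParams(seed=20260929))   # 3060 women, calibrated defaults
patterns = [classify_last_round(w) for w in women]
c = count_concurrence(patterns, ever_participant_flags(women))
nt = null_test(c)
print(c.obs_all3, round(nt.exp_all3, 1), f"{nt.p_all3:.2e}")
```

prints

```
1094 879.2 9.25e-18
```

— 1094 simulated women participated in all three programmes against 879.2
expected under randomness, so the generator's positive cross-programme
dependence (ρ = 0.30, calibrated to the studied cohort's 35% all-three rate)
is correctly detected as a gross departure from chance.

The same pipeline is packaged as numbered drivers under `analysis/`
(simulate → concurrence → robustness → practice ecology → published-count
reanalysis), and as a CLI:

```
triscreen simulate-women --seed 1 --out-dir data/
triscreen concurrence --events data/events.csv --roster data/roster.csv --out-dir out/
triscreen report --events data/events.csv --roster data/roster.csv
```

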