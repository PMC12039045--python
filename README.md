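# rxits — interrupted time-series analysis of monthly prescribing rates

`rxits` implements the full analysis pipeline behind population-scale drug
utilisation studies of the "did the pandemic change prescribing?" kind: it
takes patient-level prescription-event and registration records, aggregates
them into monthly prevalent and new-user (incident) prescribing series per
demographic/clinical subgroup under statistical disclosure control, fits a
segmented Poisson regression with seasonal adjustment and Newey-West
errors, and summarises the departure from a no-interruption counterfactual
as relative risks and rate differences. Because real primary-care records
of this kind cannot be shared, the package ships a patient-level synthetic
cohort generator with a closed-form ground truth, so every stage is
verifiable at desk scale.

It is written for epidemiologists and health-data scientists who work with
monthly event counts from electronic health records (or any registry with
the same shape) and want a tested, reproducible implementation of the
standard interrupted time-series toolkit.

## The model

Monthly counts $y_t$ of patients prescribed (out of a registered population
$N_t$) are modelled as Poisson with

$$
\log \mu_t = \beta_0 + \beta_1 t
 + \beta_2 s^{(1)}_t + \beta_3 r^{(1)}_t
 + \beta_4 s^{(2)}_t + \beta_5 r^{(2)}_t
 + \gamma_1 \sin\tfrac{2\pi t}{12} + \gamma_2 \cos\tfrac{2\pi t}{12}
 + \textstyle\sum_m \delta_m \, \mathbf{1}[t = m]
 + \log N_t ,
$$

where $s^{(k)}_t$ are step indicators at the two interruption points
(restrictions onset; recovery onset), $r^{(k)}_t = \max(0,\,t - T_k + 1)$
are the post-interruption slope-change terms, one Fourier pair captures
annual seasonality, and the $\delta_m$ absorb designated extreme outlier
months. Coefficient uncertainty uses the Newey-West
heteroscedasticity-and-autocorrelation-consistent sandwich with Bartlett
weights (lag 2 by default).

Effect summaries come from the fitted model's no-interruption
counterfactual (all step, slope-change and outlier terms set to zero):

* **monthly RR** — $RR_t = \mu_t/\mu^{cf}_t = \exp(c_t^\top\beta)$, where
  $c_t$ keeps only the interruption columns of $x_t$; exactly 1 before the
  first interruption;
* **average RR** — the geometric mean of the monthly ratios over a window,
  $\exp(\bar d^\top \beta)$ with $\bar d$ the window mean of the $c_t$; a
  linear functional of $\beta$, so its CI is exact normal theory under the
  HAC covariance;
* **rate difference** — $(\mu_t - \mu^{cf}_t)/N_t \times 1000$ at a named
  month, with a delta-method CI.

Cohort rules follow standard drug-utilisation practice: a patient with
several issues in a month counts once; "new" prescribing requires no issue
in the 24 months before the index month, counted against the drug-naive
registered denominator; published counts of five or fewer are redacted and
the rest rounded to the nearest ten.

## Worked example

Simulate five years of monthly counts whose log-rate carries a −24.8% step
and +1.5%/month slope change at the restrictions onset and a +9.1% step and
−2.2%/month slope change at recovery, then fit and summarise
(`examples/03_segmented_fit.py` and `examples/04_counterfactual_effects.py`):

```text
converged in 5 iterations (score max-norm 2.7e-09)
                     term  estimate_pct  ci_low_pct  ci_high_pct
 pre-period monthly slope           0.2         0.2          0.3
 restrictions level shift         -23.2       -25.7        -20.7
restrictions slope change           0.8         0.3          1.2
     recovery level shift          12.5         8.7         16.4
    recovery slope change          -1.6        -2.0         -1.2

RR 2019-06: 1.00 (1.00 to 1.00)
RR 2020-04: 0.57 (0.56 to 0.58)
RR 2021-06: 0.92 (0.90 to 0.93)
RR 2022-12: 0.78 (0.76 to 0.80)

post-restriction average RR: 0.83 (95% CI 0.82 to 0.84)
rate difference in 2022-12: -0.8 (-0.9 to -0.7) per 1000
```

Each coefficient is reported as $(e^\beta - 1)\times 100$, the percentage
change in the monthly rate: the fitted restrictions level shift (−23.2%,
CI −25.7 to −20.7) covers the generating −24.8%. Pre-interruption RRs are
exactly 1 by construction; the average RR of 0.83 says prescribing ran 17%
below its no-interruption expectation across the post-restriction window,
and the rate difference translates that into an absolute shortfall of 0.8
prescribed patients per 1000 in the final month.

The other examples cover the synthetic cohort and its closed-form oracle
(`01`), cohort aggregation and disclosure control (`02`), and the
one-config pipeline with its manifest (`05`). The same pipeline is
available from a shell:

```bash
rxits run --config config.yaml
rxits simulate|aggregate|fit|effects|report --help
```

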