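# vo2overlap

Are two oxygen-uptake (VO₂) measurements *really* different, or are they
within the day-to-day error of the device that produced them?

Gas-exchange indirect calorimetry reports VO₂ to several decimal places,
but its test–retest error is substantial and — crucially — *differential*:
the error grows with the gas flow being measured. `vo2overlap` models each
VO₂ reading (in L/min) as a univariate normal distribution

> W ~ N(μ, σ(μ)²)

where μ is the measured value and σ(μ) is a device-specific polynomial
calibration of the day-to-day standard deviation against the measured
level. The probability that two readings are "the same measurement" is
then the **overlapping coefficient** (OVL) of their two densities,

> OVL = ∫ min(f₁(x), f₂(x)) dx ∈ [0, 1],

computed in closed form from the normal CDF (density crossing points from
the quadratic obtained by equating log-densities). A default threshold of
10% similarity separates "truly different" from "not distinguishable".

The package targets single-subject, test–retest designs — a clinician or
sport scientist asking whether a patient's post-intervention VO₂ actually
changed — and "stacked" cohort summaries (the mean of per-subject overlap
probabilities, the *net probability of similarity*).

Two device calibrations ship by default: the **ParvoMedics 2400 TrueOne**
automated metabolic cart (linear σ(μ)) and the classical **Douglas bag**
(cubic σ(μ)). Because the raw repeatability data behind the original
calibrations is not public, the shipped coefficients are recovered by an
inverse solve from published overlap values; one published cross-system
comparison is excluded from the fit and reproduced out of sample (see
`docs/methods.md`). You can fit and register calibrations for your own
device from a two-day repeatability study CSV.

## Worked example

Baseline 1.5 L/min vs. post-intervention 1.7 L/min on the ParvoMedics
cart:

```sh
$ vo2overlap compare --a 1.5 --b 1.7
P(same measure) = 0.103 (10.3%)
verdict at 10% threshold: not distinguishable
a: 1.5 L/min on parvo_2400 (sigma = 0.0587 L/min)
b: 1.7 L/min on parvo_2400 (sigma = 0.0640 L/min)
```

A 0.2 L/min "improvement" at low flow still has a 10.3% chance of being
the same measurement — right at the default threshold, so it cannot be
called truly different. Mixed systems work too (baseline on Douglas bag,
follow-up on the cart):

```sh
$ vo2overlap compare --a 3.0 --b 3.3 --system-a douglas_bag --system-b parvo_2400
P(same measure) = 0.216 (21.6%)
verdict at 10% threshold: not distinguishable
a: 3.0 L/min on douglas_bag (sigma = 0.1374 L/min)
b: 3.3 L/min on parvo_2400 (sigma = 0.1062 L/min)
```

The same analysis from Python:

```python
from vo2overlap import compare, net_similarity

res = compare(1.5, 1.7)            # defaults to parvo_2400 on both sides
res.prob_same                      # 0.103000...
net_similarity([1.5, 3.3], [1.7, 3.5])   # 0.2305 — stacked cohort summary
```

Other subcommands: `vo2overlap batch` (CSV of subject pre/post pairs →
per-subject probabilities plus the net probability), `vo2overlap
calibrate` (fit a σ(μ) polynomial from test–retest CSV data),
`vo2overlap recover-defaults` (re-derive the shipped calibrations), and
`--plot PATH` on `compare` for the shaded-overlap figure.

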