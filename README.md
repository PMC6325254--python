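# discmeta

Tools for studying how individual differences in striatal dopamine relate to
reward discounting: a per-subject computational model of discounting
behavior, and a meta-analytic pipeline that harmonizes published PET
effect sizes and fits moderated random-effects models with heterogeneity and
publication-bias diagnostics.

## Who this is for

Decision-neuroscience and biostatistics researchers who need to (a) estimate
hyperbolic discount rates from two-alternative choice tasks over delayed,
probabilistic, or effortful rewards, and (b) combine heterogeneous published
correlation effects (dopamine PET measure vs. discounting behavior) on a
common scale and ask whether clinical group or radiotracer target moderates
them.

## The models

**Behavior.** Each choice pits a smaller reward at a lower cost against a
larger reward at a higher cost. Subjective value is hyperbolic,

    SV = R / (1 + k·C)

with R the monetary magnitude, k ≥ 0 the discount rate, and C the
transformed cost: delay in days (time), odds against winning (1 − p)/p
(probability), or the proportion of the maximum press rate (effort). Choice
is stochastic via a softmax: P(smaller) = logistic(β·(SV_small − SV_large))
with a single slope β. Both parameters are estimated per subject by maximum
likelihood; Ln(k + 1) and the model-free proportion of smaller-reward
choices are reported alongside k.

**Meta-analysis.** Published effects rᵢ (or t statistics, converted via
r = t/√(t² + df)) are Fisher-transformed, zᵢ = artanh(rᵢ), with
SE = 1/√(nᵢ − 3), and sign-aligned so positive z means "more of the dopamine
measure, more discounting". The random-effects meta-regression

    zᵢ ~ Normal(xᵢ'β, seᵢ² + τ²)

is fit by REML (τ² profiled), with dummy-coded clinical group
(healthy / addiction / other psychopathology) and radiotracer target
(D2 receptor / DA synthesis / DAT) moderators, Cochran's Q, I²,
AIC model comparison, tanh back-transformed group correlations, and an
Egger-type asymmetry test (standard error added as a moderator to the same
REML model).

A bundled table (`discmeta/data/table1_time_effects.csv`) carries the 14
published time-discounting PET effects from 7 studies that this pipeline
reproduces end to end.

## Worked example

Fit the group-moderated random-effects model to the bundled effect table and
test for small-study asymmetry:

```sh
$ discmeta meta --model group
                               intercept  b=-0.138  SE=0.110  Z=-1.26  p=0.2070
                        group[addiction]  b=-0.616  SE=0.202  Z=-3.05  p=0.0023
            group[other_psychopathology]  b= 0.793  SE=0.199  Z= 3.99  p=0.0001
tau2=0.0274  I2=31.8%  QE=16.30  QM=35.73  AIC=14.3

$ discmeta bias --model group
Egger's test (group model): Z = -2.24, p = 0.0249, slope = -1.640
```

Reading: on the Fisher-z scale, healthy groups show a small, nonsignificant
negative association between the dopamine measure and discounting (intercept
−0.138, i.e. r = tanh(−0.138) ≈ −0.137); addiction groups sit 0.616 z-units
below that (r ≈ −0.64, significantly negative), while other psychopathology
(Parkinson's disease, obesity, ADHD) sits 0.793 z-units above (r ≈ 0.58).
Group membership absorbs most heterogeneity (I² drops from ~85% in the
common-correlation model to ~32%). The negative Egger Z indicates that less
precise studies report more negative harmonized effects — some small-study
asymmetry.

The same from Python:

```python
from discmeta import load_bundled_effects, reml_fit, predict_group

table = load_bundled_effects()
fit = reml_fit(table, "group")
print(predict_group(fit, "addiction").r_hat)   # -0.6377...
```

Simulation and per-subject fitting:

```sh
discmeta simulate choices --domain time --k 0.02 --slope 1.0 \
    --n-subjects 5 --seed 7 --out choices.csv
discmeta fit-discounting --input choices.csv --out fits.csv
```

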