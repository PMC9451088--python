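# isotemporal

Compositional isotemporal substitution modelling for 24-hour time-use data.

How we divide the day between sleep, screen time, physical activity and other
behaviours is associated with health — but the 24 hours are a closed budget:
more of one activity always means less of another. `isotemporal` is for
researchers and tool builders in time-use epidemiology who want to answer
questions of the form *"what difference in an outcome is associated with
moving 60 minutes from screen time into physical activity, for a child with a
given starting day?"*, with honest confidence intervals, and to serve those
answers from a fitted model artifact that contains **no participant-level
data**.

## The model

A day is a 7-part composition **x** = (sleep, screen, physical activity,
quiet time, passive transport, school-related, domestic/self-care), in
min/day, closed to 1440. Compositions carry only relative information, so the
model works in isometric log-ratio (ilr) coordinates *z* ∈ ℝ⁶, defined by a
sequential binary partition (pivot coordinates by default — any valid basis
gives identical substitutions). Each health outcome *y* (body fat % on the
log scale; psychosocial and academic scores untransformed) is fit by OLS:

    y = β₀ + Σβₖzₖ + Σβₖₖzₖ² + Σ_{j<k} βⱼₖ zⱼzₖ + γᵀc + ε

with 27 composition-derived columns (6 linear + 6 squared + 15 interaction
terms — the second-order terms let effects depend on the starting
composition) and 7 covariate columns (sex, age, socioeconomic z-score,
pubertal status), 35 columns in all. A 27-df partial F-test assesses the
composition block; AIC compares the polynomial against a linear-only fit.

For a reallocation (a zero-net-sum vector of minute deltas, each |δ| ≤ 60 by
default), the engine predicts at the initial and reallocated compositions
from stored parameters only. Untransformed outcomes get the exact linear
contrast d = (x₁−x₀)ᵀβ̂ with Var(d) = (x₁−x₀)ᵀV(x₁−x₀) and a t(residual df)
interval; the log-modelled outcome gets the difference of exponentiated
predictions exp(ŷ₁) − exp(ŷ₀) with a MOVER interval (Zou's construction)
that combines the two lognormal limits with the correlation of the
predictions. Zero durations are imputed at 3.25 min (65% of the 5-minute
recall frame) for user input, or by a log-ratio regression-imputation scheme
for datasets.

Because the underlying cohort data are restricted-access, the package ships a
synthetic-cohort generator (`GeneratorConfig`, `generate_dataset`) that
emulates the published sample structure with known ground-truth coefficients,
so every estimator is exercised — and its frequentist calibration measured —
end to end.

## Worked example

```python
import isotemporal as it
from isotemporal.coda import PART_NAMES

cfg = it.GeneratorConfig()                     # synthetic cohort, n=1685
data, truth = it.generate_dataset(cfg, seed=42)
comps = it.replace_zeros_dataset(data[list(PART_NAMES)])

models = [it.fit_outcome_model(comps, data, data[n], n,
                               transform=cfg.outcomes[n].transform)
          for n in ("bodyfat", "psychosocial", "academic")]

start = it.close(it.DEFAULT_CENTRE)            # cohort compositional mean
swap = it.Reallocation({"screen": -60, "physical_activity": 60})
profile = it.CovariateProfile(sex="female", age=12.0)
for name, est in it.substitution_report(models, start, swap, profile).items():
    print(name, round(est.difference, 2), [round(est.ci_low, 2),
          round(est.ci_high, 2)], f"{est.percent_difference:+.1f}%")
```

prints (seed 42):

```
bodyfat -0.4 [-1.08, 0.28] -1.8%
psychosocial 2.19 [1.03, 3.35] +2.8%
academic 6.3 [0.77, 11.83] +1.2%
```

i.e. in this simulated cohort, an hour moved from screens into physical
activity at the average day is associated with 0.4 lower %body fat (a 1.8%
relative drop, CI crossing zero), 2.2 points better psychosocial health and
6.3 points higher writing score. `examples/` walks through the primitives,
fitting, reallocation (including how estimates change with the starting
composition) and a calibration study.

The same pipeline is available from a shell:

```bash
isotemporal simulate --n 1685 --seed 42 --out data.csv
isotemporal fit --data data.csv --outcome bodyfat --transform log --out models/bodyfat.json
isotemporal reallocate --model-dir models/ --initial initial.json \
    --deltas deltas.json --sex female --age 12 --out report.json
isotemporal report --input report.json
```

Invalid requests (deltas not netting to zero, a part driven negative, the
per-part cap exceeded) exit non-zero with a message naming the violation.

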