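# bifactor-grm

Bifactor graded-response multidimensional IRT for polytomous Likert
batteries: full-information marginal-maximum-likelihood estimation of one
general plus orthogonal specific traits, the derived bifactor strength
indices, item surfaces, and the standard IRT assumption diagnostics.

## The problem

Subjective well-being questionnaires — and many clinical or personality
batteries like them — mix subscales (positive affect, negative affect, life
satisfaction, harmony in life) that are all saturated by one common factor.
Classical sum scores can neither separate the common factor from the
subscale-specific ones nor say which items measure which.  The bifactor
graded response model does both: every item with K ordered categories gets a
conditional slope a_g on a general trait θ₁, a conditional slope a_s on its
single specific trait θ₂, and K−1 strictly decreasing intercepts d_k, with
cumulative boundary probabilities

    P*(X ≥ k | θ₁, θ₂) = logistic(a_g θ₁ + a_s θ₂ + d_k),

category probabilities as differences of adjacent boundaries, and all traits
orthogonal standard normal.  From the fitted slopes the package derives the
quantities an item-level report needs: MDISC = √(a_g²+a_s²), per-boundary
MDIFF = −d_k/MDISC, marginal factor loadings λ = a/√(a_g²+a_s²+D²)
(D = 1.702), marginal slopes a* = Dλ/√(1−λ²) with their characteristic
shrinkage, communality, and the explained-common-variance decomposition
(ECVg/ECVs at battery level, IECVg/IECVs per item).

Estimation is EM with bifactor dimension reduction (no integral above two
dimensions), an order-preserving intercept reparameterisation, Ramsay-type
step acceleration, and a dense equally-spaced quadrature re-evaluation of the
final log-likelihood so AIC/BIC model comparisons are not distorted by
quadrature error — see `docs/methods.md` for why that matters.

Because the motivating study's data are not publicly deposited, the package
ships a synthetic generator for the 30-item battery (10 PA + 10 NA items on
1–5, 5 LS + 5 HIL items on 1–7, NA negatively keyed) whose `paper_like`
preset encodes the reported per-scale conditional-slope means: 2.81 general,
1.39 PA, 2.45 NA, 1.85 LS, 1.56 HIL.

## Worked example

```python
import numpy as np
from bifactor_grm import (
    FitOptions, apply_reverse_coding, fit_bifactor_grm,
    make_preset, parameter_table, sample_responses,
)

preset = make_preset("paper_like")          # 30 items, 4 specific factors
raw = sample_responses(preset, preset.battery, n_persons=500, seed=1)
data = apply_reverse_coding(raw, preset.battery)   # recode NA items
fit = fit_bifactor_grm(data, preset.battery, FitOptions(n_quadrature_points=21))
table, model = parameter_table(fit, preset.battery)

print(round(np.mean([p.slope_general for p in fit.params]), 3))
print(round(model.ecv_general, 3))
print(table.loc["PA01", ["slope_general", "slope_specific", "mdisc",
                         "iecv_general"]].astype(float).round(3))
```

prints (seed 1, n = 500):

```
2.862
0.711
slope_general     2.666
slope_specific    1.110
mdisc             2.888
iecv_general      0.852
Name: PA01, dtype: float64
```

The mean estimated general slope (2.86) recovers the generating value 2.81
at this modest sample size; ECVg = 0.711 against the preset's true 0.698
says ~70% of the common variance is attributable to the general well-being
factor; and item PA01's IECVg = 0.85 marks it as predominantly a general-
factor indicator.

The same chain is scripted in `analysis/01_simulate_battery.py` …
`analysis/05_assumption_checks.py` (simulate → fit + model comparison →
indices → surfaces → diagnostics, writing tables under `results/`), and is
available as a CLI:

```sh
bifactor-grm pipeline --preset paper_like --n 500 --seed 1 --out results/
```

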