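# glucoheat

Noninvasive blood-glucose estimation from wrist-worn sensors, built on an
energy-conservation view of metabolism: at rest, the heat a body produces
equals the heat it sheds through its skin, and because glucose oxidation is
the dominant fuel, metabolic heat production carries information about blood
glucose. The package implements the full measurement chain for researchers
working on cuffless physiological monitoring:

1. **Metabolic heat** `H` (W/m²) from a wrist sensor frame, as the sum of
   three surface heat-loss channels:

   `H = ε σ Tr⁴ + 2.38 (tw − ts)^1.25 + 3.054 (0.256 tw − 3.37)(1 − He)`

   with radiometric wrist temperature `Tr` (K), skin and ambient
   temperatures `tw`, `ts` (°C), relative humidity `He` (fraction),
   emissivity `ε = 0.96` and `σ = 5.67×10⁻⁸` W m⁻² K⁻⁴.
2. **Vitals from dual-wavelength reflective PPG** (660/880 nm): systolic
   peak detection, heart rate `HR = Fs (Npeak − 1)/(x_end − x_start) × 60`,
   the ratio of ratios `r = (AC/DC)₆₆₀ / (AC/DC)₈₈₀`, and oxygen saturation
   `SpO₂ = 100 (K₂ᶦʳ r − K₂ʳᵉᵈ) / ((K₂ᶦʳ − K₁ᶦʳ) r + (K₁ʳᵉᵈ − K₂ʳᵉᵈ))`.
3. **Glucose regression** on the predictor vector (H, SpO₂, HR, BF), where
   BF is laser-Doppler blood flow: either **MPR4**, a fourth-degree
   polynomial restricted to the 15 distinct-predictor interaction products
   (ordinary least squares), or **BPNN**, a 4-9-1 tansig feedforward network
   (`Nhid = 2 Nin + 1`) trained by regularized Levenberg–Marquardt.
4. **Accuracy evaluation** with the glucose-specific metrics mARD, CORR,
   MAD, RMSE and SEP, plus Clarke error-grid zone analysis.
5. A seeded **synthetic cohort generator** with an explicit, invertible
   ground-truth relation BG = F(H, SpO₂, HR, BF), emulating a 211-record
   meal-protocol study (reference BG in [4.1, 10] mmol/L), so that every
   stage is testable end to end without clinical data.

Models follow the statsmodels idiom: build a model from data, `fit()`
returns a results object with estimates, diagnostics, `predict` and
`summary()`.

## Worked example

```python
import numpy as np
from glucoheat import (CohortConfig, generate_cohort, cohort_feature_table,
                       holdout_split, MPR4, BPNN, evaluate)

records = generate_cohort(CohortConfig(seed=42, truth_family="saturating"))
df = cohort_feature_table(records)
train, test = holdout_split(df, seed=42)          # 118 / 93 records

mpr4 = MPR4.from_dataframe(df.iloc[train]).fit()
bpnn = BPNN.from_dataframe(df.iloc[train], seed=42).fit()

for name, res in [("MPR4", mpr4), ("BPNN", bpnn)]:
    report = evaluate(df.iloc[test]["BG_ref"], res.predict(df.iloc[test]))
    print(f"--- {name} (test set, n={report.n}) ---")
    print(report.summary())
```

prints

```
--- MPR4 (test set, n=93) ---
n                = 93
mARD             = 4.878 %
CORR             = 0.951
MAD (pred-mean)  = 0.918 mmol/L
MAD (|Y - X|)    = 0.309 mmol/L
RMSE             = 0.395 mmol/L
SEP              = 0.387 mmol/L
Clarke zones     : A: 100.000%, B: 0.000%, C: 0.000%, D: 0.000%, E: 0.000%
--- BPNN (test set, n=93) ---
n                = 93
mARD             = 4.772 %
CORR             = 0.958
MAD (pred-mean)  = 0.905 mmol/L
MAD (|Y - X|)    = 0.299 mmol/L
RMSE             = 0.374 mmol/L
SEP              = 0.370 mmol/L
Clarke zones     : A: 100.000%, B: 0.000%, C: 0.000%, D: 0.000%, E: 0.000%
```

The cohort here carries 5% multiplicative observation noise on the
reference glucose, which puts a floor of about 4% on the achievable test
mARD; both models sit close to that floor, the network slightly closer
because the "saturating" truth family bends glucose through a logistic in H
that the interaction polynomial cannot represent. mARD is the mean absolute
relative difference to the reference; SEP the standard deviation of the
prediction residuals; 100% zone A means every prediction lies within 20% of
its reference (or jointly hypoglycemic with it) on the Clarke grid —
clinically accurate.

The same workflow is available from the shell:

```bash
glucoheat simulate --out cohort --seed 42
glucoheat extract  --dataset cohort/dataset.csv --out features.csv
glucoheat train    --features features.csv --model bpnn --out bpnn.json --seed 42
glucoheat predict  --model bpnn.json --features features.csv --out pred.csv
glucoheat evaluate --predictions pred.csv --out report.json
```

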