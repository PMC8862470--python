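# tickrate

Deconvolution-aware epigenetic clocks for heterogeneous methylation
samples.

Cervical smears, buccal swabs and similar specimens are mixtures of
epithelial, fibroblast and immune cells. A conventional epigenetic clock
fitted to such samples learns the *shared* methylation drift present in
every compartment; but many age-associated differentially methylated
positions (aDMPs) drift in only one cell type, and the *difference*
between a cell-type-specific clock and the general clock — the relative
epithelial age (REA) or relative immune age (RIA) — is a readout of
discordant tick rates that is informative in its own right.

`tickrate` implements the full pipeline:

* **QC** — detection-p / intensity / failure-rate filtering and
  probe-space KNN imputation of failed beta values.
* **Deconvolution** — a constrained-least-squares stand-in estimating
  epithelial/fibroblast/immune fractions from reference profiles
  (externally computed fractions can be supplied instead).
* **aDMP screen** — per CpG, OLS of beta on
  `[1, ic, ec, age, ic·age, ec·age]`; the interaction coefficients
  `b_ec·age` and `b_ic·age` are the epithelial- and immune-specific aging
  rates, and CpGs are classified as epithelial-specific, immune-specific,
  shared or other by magnitude thresholds (defaults 10⁻³ and 10⁻⁵
  beta/year, strict).
* **Clocks** — a lasso general clock over all CpGs
  (`Σ wᵢβᵢ + intercept`, CV-chosen penalty) and ridge cell-type clocks
  over one aDMP category with beta×ic interaction features
  (`Σ w¹ᵢβᵢ + w²ᵢβᵢ·ic + intercept`).
* **Relative age** — age-acceleration (general − chronological age),
  REA (epithelial − general), RIA (immune − general), each optionally
  adjusted by OLS residuals against age and ic fitted on a reference
  (control) subset.
* **Statistics** — quartile odds ratios with Wald (or mid-p) CIs against
  reference-defined quartiles, mean-methylation mitotic-proxy scores,
  and standard two-group / ANOVA+Tukey comparisons.
* **Synthetic cohorts** — a generator planting shared and cell-type-
  specific linear aging signal in three-compartment mixtures, so the
  whole pipeline is testable without any controlled-access data.

The library is organised as scikit-learn-style estimators
(`GeneralClock`, `CellTypeClock`, `AdmpScreen`, `CellDeconvolver`,
`ReferenceAdjuster`) with thin functional wrappers
(`train_general_clock`, `fit_admp_model`, …) and a `tickrate` CLI.

## Worked example

```python
import numpy as np
from tickrate import (SynthConfig, generate_cohort, fit_admp_model,
                      classify_admps, train_general_clock,
                      train_celltype_clock, predict_age, clock_error)

beta, samples, truth = generate_cohort(SynthConfig(seed=1))   # 2000 CpGs x 800 samples
catalog = classify_admps(fit_admp_model(beta, samples))
print(catalog.counts())

train = samples.sample_ids[:600]
test = samples.sample_ids[600:]
general = train_general_clock(beta.select_samples(train),
                              samples.select(train).age, seed=1)
mae, r = clock_error(predict_age(general, beta.select_samples(test)),
                     samples.select(test).age)
print(f"{len(general.cpgs)} CpGs, held-out median error {mae:.2f} y, r {r:.3f}")
```

prints

```
{'epithelial_specific': 100, 'immune_specific': 100, 'shared': 300, 'other': 1500}
15 CpGs, held-out median error 0.47 y, r 0.999
```

The noiseless cohort plants 300 shared, 100 epithelial-specific and 100
immune-specific aDMPs among 1500 null CpGs; the screen recovers every
category exactly, and the lasso clock needs only a small subset of the
CpGs to predict held-out age to a fraction of a year.

The same flow is available from the shell:

```bash
tickrate simulate --config synth.yaml --out-prefix sim/
tickrate admp --beta sim/beta.tsv --samples sim/samples.tsv --out sim/admp.tsv
tickrate train-general --beta sim/beta.tsv --samples sim/samples.tsv --out sim/general.tsv
tickrate train-celltype --beta sim/beta.tsv --samples sim/samples.tsv \
    --admp-table sim/admp.tsv --category epithelial --out sim/epithelial.tsv
tickrate score --general sim/general.tsv --epithelial sim/epithelial.tsv \
    --immune sim/immune.tsv --beta sim/beta.tsv --samples sim/samples.tsv \
    --out sim/scores.tsv
tickrate rea --scores sim/scores.tsv --samples sim/samples.tsv --out sim/adjusted.tsv
tickrate or --values sim/adjusted.tsv --samples sim/samples.tsv
```

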