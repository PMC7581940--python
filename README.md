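# mepflux

Kinetic ¹³CO₂-labeling flux analysis for the plastidial methylerythritol
4-phosphate (MEP) pathway, built for drought-physiology experiments on
isoprene-emitting conifers (and any system where isoprene labeling reads
out the IDP + DMADP pool).

When a plant is switched from ¹²CO₂ to ¹³CO₂, label flows through the
MEP pathway intermediates DXP → MEcDP → IDP + DMADP and appears in
emitted isoprene, which the PTR-MS tracks on-line at m/z 69–74.
`mepflux` turns such measurements into a pathway flux estimate:

* **Cascade labeling model.** The pathway is a linear chain of three
  pools A (DXP), B (MEcDP), C (IDP + DMADP) carrying a steady flux *J*
  (nmol g⁻¹ DW min⁻¹). The fractional labeling of the terminal pool is

  f(t) = m·[1 − A²/((A−B)(A−C))·e^(−Jt/A)
            − B²/((B−A)(B−C))·e^(−Jt/B)
            − C²/((C−A)(C−B))·e^(−Jt/C)],

  with plateau m < 1 when unlabeled ("alternative") carbon also feeds
  the pathway. `CascadeFluxModel` (a scikit-learn style estimator) fits
  (m, J) by Levenberg–Marquardt least squares with the pool sizes fixed;
  an independent ODE integration of the chain serves as numerical oracle
  and handles coinciding pool sizes.
* **Isotopologue arithmetic.** Fractional ¹³C enrichment
  (Σᵢ i·Iᵢ)/(n·ΣᵢIᵢ) from M+0…M+n intensities, binomial
  natural-abundance correction (`NaturalAbundanceCorrector`),
  standard-addition and external-standard quantification, PTR-MS channel
  mapping and ncps normalization.
* **Plastidial pool partitioning.** Whole-tissue DXP and MEcDP pools are
  scaled by the ratio of their final enrichment to that of IDP + DMADP
  (assumed exclusively plastidial).
* **Drought staging.** FTSW = (daily − final)/(initial − final) pot
  weight; RTR = 100·TR/ATR with triggers 50 % (moderate), 20 % (severe),
  10 % (endpoint).
* **Group statistics.** One-way ANOVA, Tukey HSD with compact
  significance letters, Shapiro–Wilk, percent-/fold-change summaries.
* **Synthetic experiments.** `simulate_experiment` generates a complete
  replicated control/moderate/severe study with known ground truth, so
  the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
from mepflux import CascadeFluxModel, CascadeParams, cascade_fraction, \
    simulate_time_course

true = CascadeParams(pool_dxp=2.0, pool_mecdp=1.0, pool_idpdmadp=0.5,
                     flux=0.2, plateau=0.85)
t = np.linspace(2, 50, 25)                       # minutes after the switch
tc = simulate_time_course(true, t, noise_cv=0.03, seed=1)

model = CascadeFluxModel(pool_dxp=2.0, pool_mecdp=1.0, pool_idpdmadp=0.5)
model.fit(tc.times, tc.fractions)
print(f"J = {model.flux_:.4f} nmol/gDW/min, m = {model.plateau_:.3f}, "
      f"detectable = {model.detectable_}")
```

prints

```
J = 0.2027 nmol/gDW/min, m = 0.843, detectable = True
```

i.e. from a 50-min labeling curve with 3 % multiplicative noise the fit
recovers the true flux (0.2) within ~1.5 % and the labeling plateau
(0.85) within ~1 %. A severe-drought-like curve plateauing at ~0.15
is instead flagged `detectable = False`: below ~20 % incorporation the
kinetics no longer support an accurate flux estimate.

The same analysis runs from the shell over CSV tables:

```bash
mepflux simulate --seed 1 --out data/          # synthetic study bundle
mepflux run --inputs data/ --out results/      # enrich → pools → fit → ftsw → report
```

`results/fits.tsv` then holds per-tree `J_hat`, `m_hat`, convergence and
detectability flags; `results/report.csv` the ANOVA/Tukey letter summary
of the physiological variables.

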