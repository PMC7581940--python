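# Methods

## The cascade labeling model

The MEP pathway is treated as a linear chain of three metabolite pools
at metabolic steady state: A = DXP, B = MEcDP, C = IDP + DMADP (all in
nmol g⁻¹ DW), carrying a single pathway flux J (nmol g⁻¹ DW min⁻¹).
At t = 0 the carbon source switches from ¹²CO₂ to ¹³CO₂ and the
fractional labeling lₓ(t) of each pool obeys

    A dl_A/dt = J (m − l_A)
    B dl_B/dt = J (l_A − l_B)
    C dl_C/dt = J (l_B − l_C),      l(0) = 0.

The plateau m ∈ [0, 1] is the asymptotic labeling of the input; m < 1
means a fraction 1 − m of pathway carbon comes from unlabeled
("alternative") sources such as starch, recycled respiratory CO₂ or
imported sugars. Solving the chain for distinct pools gives the
terminal-pool step response

    f(t) = m [1 − A²/((A−B)(A−C)) e^(−Jt/A)
                − B²/((B−A)(B−C)) e^(−Jt/B)
                − C²/((C−A)(C−B)) e^(−Jt/C)].

The partial-fraction coefficients sum to 1 (equivalently f(0) = 0), a
property the test suite checks to 1e−10 over 10⁴ random parameter sets.
Because isoprene is made from DMADP in a single enzymatic step and
escapes the leaf immediately, its on-line PTR-MS labeling signal is used
as the instantaneous labeling state f(t) of the IDP + DMADP pool.

Assumptions: the small intermediates between the measured pools (MEP,
CDP-ME, CDP-MEP, HMBDP) are taken as zero-size — they are typically
below detection and add no appreciable delay; the pathway carries one
throughput J with no branch-point partitioning; pool sizes are constant
over the 50-min labeling window.

### Numerical evaluation

The closed form has removable singularities where pool sizes coincide,
and its floating-point cancellation error grows like ε_machine / gap²
in the smallest relative pool gap. When any relative gap is below 1e−4
the model is therefore evaluated by numerically integrating the chain
ODEs (LSODA, rtol 1e−9, atol 1e−12) rather than by the closed form;
either branch then agrees with the other to better than ~1e−8. The ODE
path doubles as the independent oracle for the closed form in the test
suite, including the triple-confluent Erlang-3 case
f(t) = m[1 − e^(−Jt/A)(1 + Jt/A + (Jt/A)²/2)] checked by hand algebra.

Scale invariance — multiplying A, B, C and J by a common factor leaves
f(t) unchanged — means only the ratios pool/J (the pool turnover times)
are kinetically meaningful; this is also tested.

## Flux fitting

`CascadeFluxModel` follows the scikit-learn estimator protocol:
`fit(times, fractions)` minimises Σ(f_model − f_data)² over (m, J) with
the plastidial pool sizes fixed, using the Levenberg–Marquardt
implementation in lmfit; if LM fails with the bounds J ≥ 0, 0 ≤ m ≤ 1
active, a bounded trust-region solve is the fallback. Standard errors
come from the least-squares covariance (no Bayesian/MCMC machinery, by
design).

Numerical choices:

* **Initialisation** is deterministic and data-driven: m₀ = the last
  observed fraction (clipped into (0, 1]); J₀ = max(A, B, C)/t_half with
  t_half the first time the signal exceeds m₀/2. A noiseless round trip
  recovers (m, J) to the optimizer tolerance (relative 1e−6 asserted).
* **Plateau handling**: m is co-fitted by default; `fit_plateau=False`
  fixes it (to a supplied value or the last observation) for the
  alternative reading in which only J is free. Both modes are provided
  because either is defensible; co-fitting is the default since the
  optimiser is described as minimising over both parameters.
* **Detectability**: a fit is reported "not detectable" when the fitted
  plateau, or the entire observed time course, does not exceed 0.2
  enrichment. Below roughly 20 % incorporation the labeling signal is
  dominated by noise and the (m, J) estimate carries no usable flux
  information — the regime observed under severe drought. The
  threshold is a parameter (`detect_threshold`). A time course that is
  identically zero short-circuits to a non-converged, non-detectable
  result with J at its lower bound.
* **Identifiability**: with data covering less than twice the slowest
  turnover time max(A, B, C)/J, the plateau and the flux are confounded
  (a single late point cannot separate "slow and fully labeled" from
  "fast and partially labeled"); such fits carry `identifiable_ = False`
  and a warning.
* **Time origin**: t = 0 is the moment of the ¹³CO₂ switch; instrument
  dead time is a configurable offset, default 0.

## Plastidial pool partitioning

IDP + DMADP is assumed exclusively plastidial, and only plastidial DXP
and MEcDP become labeled on the 50-min time scale. The plastidial share
of a whole-tissue pool is therefore total × (final enrichment of the
species / final enrichment of IDP + DMADP). Ratios above 1 (possible
through measurement noise) are capped at 1 with a warning; an unlabeled
reference pool is an error.

## Isotopologue arithmetic

Fractional enrichment of an n-carbon analyte from M+0…M+n intensities
Iᵢ is (Σᵢ i·Iᵢ)/(n·Σᵢ Iᵢ): labeled carbon atoms over all carbon atoms.
It is invariant under uniform intensity scaling.

Natural ¹³C abundance (p = 0.0107 by default, configurable) is removed
with a binomial convolution operator on the tracer-unlabeled carbons:
column j of the (n+1)×(n+1) matrix holds Binomial(n−j, p), so columns
sum to 1 and total intensity is conserved. The matrix is
lower-triangular with positive diagonal for p < 0.5, hence exactly
invertible by forward substitution; correction is the exact inverse of
convolution in the absence of clamping (round trip asserted to 1e−9).
Small negative solutions from measurement noise are clamped to zero and
the spectrum rescaled to its observed total; clamping that removes more
than 5 % of the signal raises a warning. Only carbon is corrected — the
monitored mass shifts are carbon shifts; H/O/N/P isotopes are ignored.
By default correction precedes quantification (correct-then-quantify);
the order is switchable.

Standard-addition quantification uses the signal increment of a known
unlabeled spike as the response factor: amount = spike × unspiked /
(spiked − unspiked); a spike that does not raise the signal is an error.
External-standard quantification fits an ordinary least-squares line
through (concentration, signal) calibration points and inverts it,
warning on extrapolation outside the calibrated range. Multi-point OLS
is used for the gas-calibration standard as well, the exact calibration
model of such units being instrument-specific.

PTR-MS handling: channels m/z 69 + k map to isoprene isotopologues M+k
(protonated C₅H₉⁺), k = 0…5. Raw counts are normalised to ncps against
a reference primary-ion level of 10⁶ cps (primary ion + water cluster)
and a reference drift pressure of 2.2 mbar — the conventional ncps
definition; both references are parameters. Emission rate =
(steady ncps − background ncps) × calibration slope / dry weight,
floored at zero with a warning. Fragment interference on m/z 69–74 from
other C₅ species is not modelled. Sucrose-type analytes with several
product ions per precursor are reduced to one M+0…M+n series by summing
product-ion variants per precursor mass before enrichment.

## Drought staging

FTSW = (daily − final)/(initial − final) pot weight; values marginally
outside [0, 1] — possible at 1 g weighing precision — are clamped with
a warning. TR is the daily pot-weight loss (pots are bagged, so the
loss is transpiration); ATR is the well-watered reference group's mean
daily transpiration, per-day by default (experiment-wide mean optional)
with missing days linearly interpolated. RTR = 100·TR/ATR.

Stage boundaries are inclusive ("a tree at exactly the target RTR is
sampled"): RTR ≤ 10 % endpoint, ≤ 20 % severe, ≤ 50 % moderate,
otherwise unstressed. All rates are reported per g dry weight using
fresh/dry conversion factors from weighed freeze-dried aliquots.

## Group statistics

One-way fixed-effects ANOVA per variable; Tukey's HSD (Tukey–Kramer for
unbalanced groups, via the studentized range distribution) for pairwise
comparisons at α = 0.05; compact letters assigned by the
insertion–absorption algorithm so that two groups share a letter exactly
when their comparison is non-significant (verified against exhaustive
enumeration of all significance patterns for ≤ 4 groups; minimal letter
count is not guaranteed). Shapiro–Wilk tests residual normality; a
failure only raises a warning — no transformation is applied, and the
report still shows the parametric results. Effect sizes vs. the control
group: percent change 100·(mean_ctrl − mean_trt)/mean_ctrl and fold
change mean_trt/mean_ctrl, flagged undefined when the control mean is
zero. Variables are analysed independently (no multiple-testing
correction across variables, no mixed models).

## Synthetic experiment generator

`ScenarioConfig` defines a replicated drought study with known ground
truth. Defaults describe the emulated study conditions:

| Parameter | Control | Moderate | Severe |
|---|---|---|---|
| plastidial pools A/B/C, nmol g⁻¹ DW | 2.0/1.0/0.5 | 1.1/0.55/0.5 | 1.0/0.5/0.5 |
| flux J, nmol g⁻¹ DW min⁻¹ | 0.2 | 0.126 (−37 %) | 0.08 |
| isoprene plateau m | 0.85 | 0.60 | 0.15 |
| end-of-run enrichment DXP/MEcDP | 0.75 | 0.45 | 0.15 |
| end-of-run enrichment IDP+DMADP | 0.87 | 0.60 | 0.15 |
| photosynthesis (rel. to control) | 1 | 0.30 | 0.04 |
| ABA (fold of control) | 1 | 6.7 | 12.8 |

Five replicate trees per treatment; 25 time points over a 50-min
labeling window; multiplicative Gaussian noise with CV 3 % on labeling
fractions and 5 % on spectral intensities (typical MRM repeatability),
10 % on physiological replicates; natural abundance p = 0.0107. The
flux magnitudes are order-of-magnitude choices set so the slowest
turnover time max(A,B,C)/J ≈ 10 min, i.e. the 50-min window spans ≈ 5
time constants and labeled treatments reach a near-plateau. Whole-tissue
DXP/MEcDP pools are back-computed from the plastidial pools and the
enrichment ratios, so the pipeline's partitioning step recovers them by
construction. Pot weights dry exponentially from 10 000 g toward a
6 000 g endpoint (k = 0.12 day⁻¹ for stressed trees over 20 days,
rounded to 1 g), and a well-watered reference group supplies a constant
ATR.

What the generator does **not** emulate: chromatographic peak shape and
integration, ion suppression and detector drift, position-specific
(non-binomial) labeling patterns, day-to-day physiological trends, and
between-tree variation in pool sizes beyond independent multiplicative
noise. Passing recovery tests therefore demonstrate the correctness of
the arithmetic and the estimator under the stated noise model, not
robustness to every artefact of real chromatography or instrument
physics. Isotopologue spectra assume each carbon is labeled
independently with probability equal to the pool enrichment (binomial
mixing) — the simplest model reproducing the observed dominance of the
fully labeled isotopologue at high enrichment — with natural abundance
convolved on the remaining positions, so correcting a noiseless
spectrum returns the configured enrichment exactly.

Everything is generated from `numpy.random.default_rng(seed)`; a given
(config, seed) is bit-reproducible, and the ground-truth manifest (true
J, m, pools per replicate) is written next to the data.

## Pipeline and I/O

CSV/TSV tables with header row, UTF-8, "." decimals, empty cells for
missing values; schema validation errors name the file, column and row.
The `mepflux` CLI wires the stages together (simulate → enrich → pools
→ fit-flux → ftsw → report); `run` executes the whole chain
deterministically and writes a JSON run log with a config digest and
all collected warnings (clamping, non-detectable fits). Rates in
outputs are on a dry-weight basis.

## Problem sizes and known limitations

The test-suite simulations use 200 Monte-Carlo fits for recovery, 100
for severe-drought detectability, 2000 null replicates for the ANOVA
type-I check and 10⁴ parameter sets for the coefficient identity; the
acceptance script uses the same sizes with the default five-replicate
scenario. Known limitations: single-flux chain (no branch fluxes to
pigments vs. isoprene), least-squares uncertainties only, carbon-only
isotope correction, and plateau/flux confounding for time courses much
shorter than the slowest pool turnover — flagged, not resolved.
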