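# Methods

## The decision problem

`oncocea` implements a cost-utility comparison of two third-line treatment
strategies for metastatic colorectal cancer — trifluridine/tipiracil (FTD/TPI)
plus bevacizumab versus FTD/TPI alone — from the perspective of the Chinese
healthcare system. The unit of benefit is the quality-adjusted life year
(QALY); the decision statistic is the incremental cost-effectiveness ratio
ICER = ΔC/ΔE compared against a willingness-to-pay (WTP) threshold of
¥268,200/QALY (three times 2023 Chinese per-capita GDP). The combination is
judged cost-effective when ICER ≤ WTP, equivalently when the incremental net
monetary benefit NMB = WTP·ΔE − ΔC is non-negative.

## Survival extrapolation

Trial survival is available only as published Kaplan–Meier figures. The
pipeline therefore works from digitized (time, survival) coordinates:

1. **Reconstruction** (`km_reconstruction`): the product-limit relation
   S(t_j) = S(t_{j−1})(1 − d_j/n_j) is inverted interval by interval to
   recover integer event counts, given the arm size (246 per arm here). With
   a published number-at-risk table, censorings per at-risk interval follow
   the standard balance n_k − n_{k+1} − events and are spread evenly within
   the interval (a two-pass allocation: events first, then the implied
   censorings, then events again). Without one, in-study censoring is
   unidentifiable from the curve, so survivors are censored administratively
   at the last digitized time. Event times sit at interval midpoints by
   default (`event_placement="drop"` uses the right edge).
2. **Fitting** (`survival_models`): six families — exponential, Weibull,
   log-normal, log-logistic, Gompertz, gamma — are fitted to the
   reconstructed records by maximising the right-censored log-likelihood
   Σ_events ln f(t) + Σ_censored ln S(t). Positive parameters are optimised
   on the log scale by L-BFGS-B (gradient tolerance 1e-8) from three
   deterministic starts around moment-based initial values; the best
   converged start wins, and non-convergence is an explicit failure result.
   Families are compared by AIC/BIC with ties broken by a fixed family
   order. A least-squares fit on log(−log S) of the raw coordinates is
   available as a cross-check that reconstruction did not distort the fit.

Parameter conventions are documented in `survival_models`; the one that
matters most is the log-normal, whose published "shape/scale" values are
meanlog/sdlog on the month scale (so the combination arm's OS parameters
2.398/0.808 put median survival at exp(2.398) ≈ 11.0 months, matching the
12-month follow-up of the source trial). The Gompertz is parameterised as
S(t) = exp(−(λ/γ)(e^{γt} − 1)) and may be defective for γ < 0 (survival
plateaus above zero); the gamma uses shape/rate.

The base-case log-normal parameters shipped in `params_sunlight_cn.yaml`
are the published best-fit values for the four curves (combination PFS
1.660/0.850, OS 2.398/0.808; monotherapy PFS 1.110/0.644, OS 2.030/0.793).

## Cohort model

Three irreversible states — progression-free (PFS), progressed disease (PD),
death — over 28-day cycles for 10 years: ⌊10·365.25/28⌋ = 130 cycles, with
cycle c evaluated at t_c = c·28/30.4375 months. Everyone starts in PFS.

Transition probabilities come from the fitted curves as conditional event
probabilities over one cycle, p = 1 − S(t)/S(t−u). The per-cycle death
probability (from the OS curve) applies from both living states; the
PFS→PD probability is the excess of the PFS-exit probability over the death
probability, floored at zero. Note the sign convention: the conditional
*survival* ratio is S(t)/S(t−u); the death probability is its complement.

A partitioned-survival construction (PFS = S_PFS, dead = 1 − S_OS, PD the
difference, clamped at zero where the curves cross) is retained alongside
the Markov mode. When S_PFS ≤ S_OS on the cycle grid the two are
algebraically identical (the Markov recursion telescopes), so their
agreement — asserted within 0.02 per cycle in the tests — is a diagnostic
for curve-crossing pathologies rather than an approximation check. Crossing
beyond 5% of cycles logs a warning; the `stress_crossing` synthetic preset
exercises this deliberately.

Half-cycle correction (averaging adjacent cycle-start occupancies) is
available but off by default; with the 28-day cycle its effect on the ICER
is well under 1%.

## Costs and QALYs

Per cycle, in 2023 CNY: drug acquisition (combination ¥23,625.40,
monotherapy ¥13,947.40) plus laboratory (¥317.36) and imaging (¥677.70)
follow-up accrue while progression-free (treatment-to-progression);
subsequent-line therapy (fruquintinib, ¥7,541.10) plus supportive care
(¥2,141.20) accrue in PD; end-of-life care (¥11,299.00) is charged once to
the death mass entering each cycle; adverse-event management is a one-time
expected lump sum at entry (Σ incidence × unit cost over the arm's event
list), since trials report per-patient incidences rather than per-cycle
rates. The published source states follow-up costs "per visit" without a
frequency; one visit per cycle is assumed and overridable. Utilities are
0.84 (PFS) and 0.57 (PD), death 0. Costs and QALYs are discounted at 5%/year
continuously in cycle time, (1.05)^(−28c/365.25).

Dosing arithmetic uses the Chinese-population body-surface-area formula
BSA = 0.0061·height + 0.0124·weight − 0.0099 with the sex-weighted
(256:236) average patient (164.09 cm, 64.52 kg → 1.79 m²).

### Reproducibility of the published totals

The published absolute results (combination ¥838,492.74 / 2.45 QALYs,
monotherapy ¥357,396.97 / 1.54 QALYs, ICER ¥527,577.36/QALY) are **not**
recoverable from the published inputs, and this package does not try to
match them numerically. Two reasons, both checkable with the package
itself: (i) the cost-accrual frequencies behind the totals are unstated;
(ii) more fundamentally, the published QALY totals are inconsistent with
the published survival parameters — a log-normal(2.398, 0.808) OS curve
has mean exp(2.398 + 0.808²/2) ≈ 15.2 months, so even at utility 1 and no
discounting the combination arm accrues ≈ 1.27 life-years over the horizon,
far below the printed 2.45 QALYs. With the shipped inputs this
implementation obtains ≈ ¥148,409 incremental cost, ≈ 0.29 incremental
QALYs and an ICER ≈ ¥515,000/QALY — the same *decision* (ICER far above
the ¥268,200 threshold, PSA acceptability near zero at the threshold and
reaching 50% only above ¥500,000/QALY), which is the property the tests
gate on.

## Sensitivity analysis

**One-way:** each Table-2 parameter is set to its lower and upper limit in
turn (95% CI where published, else ±20%; discount rate 0–8%) and the
deterministic model rerun; parameters are ranked by ICER spread. With the
shipped inputs the combination drug cost and the PFS utility dominate,
with the discount rate next — mirroring the qualitative finding of the
source analysis.

**Probabilistic:** 10,000 Monte-Carlo draws, sampling every non-fixed
parameter independently — gamma for costs, beta for utilities and the
discount rate — with method-of-moments parameters from mean = baseline and
sd = (high − low)/(2·1.96). Betas are matched on the parameter rescaled to
its natural support ([0, 1] for utilities, [0, 0.08] for the discount
rate); infeasible moments are a config-load error, not a sampling-time
surprise. Survival parameters are held fixed (no sampling distributions
are published for them). Draws violating the structural constraint
u_pd ≤ u_pfs are resampled and counted. With the shipped distributions the
rejection probability is ≈ 1% (a property of the two independent betas,
measurable by simulation), so the abort valve for pathological
specifications is set at 5% of n_sims rather than at a level the expected
behaviour would routinely trip. The CEAC reports, on a grid of 0 to ¥1M in
¥5,000 steps, the fraction of draws with positive incremental NMB; it is
monotone whenever all ΔQALY draws are positive, which holds under the
shipped ranges.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seed and config give byte-identical
sample files.

## Synthetic data

`synthetic_data` generates every input the pipeline consumes, with known
truth: inverse-transform event times; non-informative uniform censoring
C ~ U(0, c_max) with c_max solved so the marginal censoring probability
equals the requested rate; administrative censoring at 12 months (the
observed follow-up window of the source trial, so extrapolation beyond the
data is genuinely exercised); Kaplan–Meier estimation (via lifelines);
digitization emulated by sampling the step function on an even 30-point
grid with truncated-Gaussian jitter (sd 0.005 survival units) followed by
isotonic clipping. What passing tests on these data show is that the
*pipeline* recovers its inputs under realistic sampling, censoring and
digitization noise; they cannot show that the parametric extrapolation is
correct beyond 12 months for real patients, that censoring in the trial was
non-informative, or that digitization error from real figures is unbiased.

Round-trip calibration (fixed before the recovery tests were wired up): over
50 seeded replicates per curve of simulate → KM → digitize → reconstruct →
refit at the four published truths, the largest per-replicate parameter
error observed was 0.22 (the OS curves are ~55% censored at 12 months, so
sdlog is the weakly identified quantity) and the largest bias +0.04; the
tests assert per-replicate error ≤ 0.30 and |bias| ≤ 0.06.

## Numerical choices and edge cases

- Cycle count 130 = ⌊10·365.25/28⌋; month = 30.4375 days.
- Optimiser tolerance 1e-8 (gradient), three deterministic starts; the
  censored exponential MLE reproduces its closed form events/Σt to 1e-8.
- S(t−u) = 0 in a conditional probability → probability 1 with a logged
  warning (cohort exhausted).
- −ln S(t) returns +inf where S(t) = 0 (documented sentinel).
- Defective Gompertz (γ < 0) is allowed; quantiles beyond the attainable
  event fraction return +inf.
- Dominance handling: the ICER is suppressed (None) and a flag
  (dominant/dominated/equivalent) reported whenever the increment signs
  disagree or vanish; the verdict is driven by NMB, which coincides with
  the ICER-vs-WTP rule whenever ΔQALY > 0.
- Config validation is strict (unknown keys rejected, messages name the
  key); the discount rate is confined to the sensitivity support [0, 0.08]
  unless `allow_extended_discount` is set.

## Known limitations

- Transitions derived from marginal OS and PFS curves cannot identify
  state-specific death hazards; PD mortality equals overall mortality by
  construction.
- PSA parameters are sampled independently; no correlation structure, and
  no parameter uncertainty on the survival fits.
- No treatment-switching adjustment, tunnel states, microsimulation,
  indirect/societal costs, currency conversion, or price-year adjustment.
- The published absolute cost/QALY totals are not reproducible from the
  published inputs (see above); all quantitative checks in this repository
  are against the package's own computed values or published *inputs*, not
  against the published outputs.
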