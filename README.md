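# oncocea

Markov cohort cost-effectiveness modelling for oncology treatment
comparisons, built around the common situation where the only survival
evidence available is a published Kaplan–Meier figure.

The package implements, as a reusable and tested pipeline, a cost-utility
analysis of trifluridine/tipiracil (FTD/TPI) plus bevacizumab versus FTD/TPI
monotherapy as third-line treatment for metastatic colorectal cancer, from
the Chinese healthcare-system perspective. It is aimed at health-economics
and HTA analysts who want every stage of such an analysis — curve
reconstruction, extrapolation, the state-transition engine, and the
sensitivity machinery — as inspectable, scriptable code rather than a
point-and-click model.

## What it computes

- **Pseudo individual-patient data** from digitized KM coordinates, by
  inverting the product-limit relation S(t_j) = S(t_{j−1})(1 − d_j/n_j)
  interval by interval (with or without a number-at-risk table).
- **Parametric extrapolation**: censored maximum-likelihood fits of six
  families (exponential, Weibull, log-normal, log-logistic, Gompertz,
  gamma), selected by AIC/BIC.
- **A three-state cohort model** (progression-free → progressed → dead)
  over 130 × 28-day cycles (10 years), with per-cycle transition
  probabilities 1 − S(t)/S(t−u) from the fitted OS and PFS curves, and a
  partitioned-survival mode as a cross-check.
- **Discounted costs and QALYs** (5%/year), the incremental
  cost-effectiveness ratio ICER = ΔC/ΔE, and the net monetary benefit
  NMB = WTP·ΔE − ΔC against a willingness-to-pay threshold of
  ¥268,200/QALY (3× per-capita GDP).
- **Sensitivity analyses**: one-way (tornado, 95% CI or ±20% ranges) and
  probabilistic (10,000 Monte-Carlo draws; gamma for costs, beta for
  utilities and the discount rate), summarised as a cost-effectiveness
  acceptability curve.
- **Synthetic trial data** with known ground truth, emulating the whole
  input chain (event times → KM step → noisy digitization) for end-to-end
  testing.

See `docs/methods.md` for the model, its assumptions, and its limitations —
including why the published absolute totals of the source analysis are not
reproducible from its published inputs, and what this package gates on
instead.

## Worked example

Run the shipped base case (published drug costs, Table-based unit costs and
utilities, log-normal survival parameters for all four curves):

```sh
$ oncocea run --out results/base --seed 1
ICER: ¥515,384.64/QALY  NMB: ¥-71,178.97  -> not cost-effective at WTP ¥268,200.00/QALY
```

`results/base/summary.json` then contains (abridged):

```json
{
  "cost":  {"combo": 294449.13, "mono": 146039.64},
  "qalys": {"combo": 0.8796,  "mono": 0.5916},
  "incremental_cost": 148409.49,
  "incremental_qalys": 0.288,
  "icer": 515384.64,
  "verdict": "not cost-effective at WTP ¥268,200.00/QALY",
  "psa": {"n_sims": 10000, "p_ce_at_wtp": 0.0003, "wtp_at_50pct": 515000.0}
}
```

Reading: the combination adds 0.288 discounted QALYs at an extra
¥148,409.49, i.e. ¥515,384.64 per QALY gained — nearly twice the
willingness-to-pay threshold, so the combination is not cost-effective at
¥268,200/QALY. The probabilistic analysis agrees: essentially no draws
(0.03%) are cost-effective at the threshold, and acceptability reaches 50%
only above ¥500,000/QALY. The directory also holds per-arm cohort traces,
the two-row base-case table (`cea_results.csv`), `tornado.csv` (the
combination drug cost and the PFS utility dominate), `psa_samples.csv`,
`ceac.csv`, and a hash manifest; add `--plots` for PNG figures.

The same pipeline runs on synthetic data with known truth:

```sh
oncocea synth --preset sunlight_like --seed 7 --out ws   # curves + config
oncocea reconstruct --curve ws/curves/combo_os.csv --n 246 --out ws/ipd.csv
oncocea fit --ipd ws/ipd.csv --out ws/fits.csv           # six families + AIC/BIC
oncocea run --config ws/config.yaml --out ws/results --seed 7
```

Everything is equally usable as a library:

```python
from oncocea.cli_io import load_config
from oncocea.economics import evaluate_case

cfg = load_config()              # shipped parameter set
print(evaluate_case(cfg.case).verdict)
```

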