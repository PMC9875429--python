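# aircrossover

Time-stratified case-crossover analysis of short-term air-pollution
exposure and mortality, as a reusable, tested Python pipeline.

Environmental epidemiologists studying acute health effects of air
pollution routinely link a national mortality registry to gridded daily
pollutant surfaces and ask whether the odds of death rise on days with
higher exposure. This package implements the full analytical chain for
that question:

* **Referent design** — each death date (the case day) is matched to all
  other days of the same year, month and day of week (3–4 control days),
  so season, trend and weekday are matched by construction and each person
  is their own control.
* **Exposure assessment** — daily pollutant (PM1, PM2.5, PM10, CO, NO2,
  O3, SO2) and meteorology (temperature, relative humidity) fields on a
  regular lat/lon grid (NetCDF or long CSV) are bilinearly interpolated to
  residential coordinates; when fewer than four grid cells carry a value,
  the bilinear weights are re-distributed to sum to one. Exposure enters
  the model as the lag 0–1 moving average; meteorology as lag 0–4.
* **Conditional logistic regression** — the matched-set likelihood
  ℓ(β) = Σ_s [x'_case β − log Σ_{j∈s} exp(x'_j β)] is maximised by
  Newton–Raphson with analytic derivatives. Adjusted models add natural
  cubic splines (df = 4) of MA 0–4 temperature and humidity. Effects are
  reported as percent change in odds, (OR − 1) × 100 per 10 µg/m³
  (1 mg/m³ for CO), with Wald 95% CIs.
* **Downstream analyses** — spline concentration–response curves relative
  to a reference concentration, lag-structure sensitivity tables, BIC-based
  meteorology-lag selection, two-pollutant models behind a Pearson-r > 0.8
  collinearity screen, and subgroup analyses with a joint
  likelihood-ratio interaction test.
* **Synthetic data with known truth** — a generator produces seasonal,
  autocorrelated, spatially smooth gridded fields (with the strong
  PM1/PM2.5/PM10 cross-correlation), a synthetic population, and deaths
  whose case-day placement follows the *exact* conditional-logit law, so
  parameter recovery is a sharp test rather than an approximation.

See `docs/methods.md` for the model details, generator design and
limitations.

## Worked example

Simulate a study in which SO2 truly raises the odds of death by 2.90% per
10 µg/m³ (with temperature and humidity confounders active), then fit the
unadjusted and adjusted models:

```python
from aircrossover.experiments import simulate_linked_study
from aircrossover.simulate import national_truth
from aircrossover.pipeline import run_single_pollutant

truth = national_truth("so2", 2.90)
linked, cases, fields, config = simulate_linked_study(["so2"], truth, 10_000, seed=1)
for adjusted in (False, True):
    est = run_single_pollutant(linked, config, "so2", adjusted=adjusted)
    print(est.as_dict())
```

Output (seed 1):

```
     model pollutant    lag  percent_change   ci_low  ci_high      p_value  n_strata
unadjusted       SO2 MA 0-1        3.551354 2.775477 4.333088 9.512983e-20     10000
  adjusted       SO2 MA 0-1        3.558857 2.770437 4.353325 3.009024e-19     10000
```

Both models estimate the percent increase in the odds of death per
10 µg/m³ of MA 0–1 SO2; the 95% CI [2.77, 4.35] covers the injected truth
of 2.90 (a single 10,000-stratum replicate has a Monte Carlo SE of about
0.4 points; at the 30,000 strata used in the validation runs it shrinks to
about 0.2). The unadjusted and adjusted fits agree here because the
simulated pollutant and meteorology processes are independent within
strata; under the `confounded_fields` preset they diverge and only the
adjusted model recovers the truth.

The same workflow is available from the shell:

```sh
aircrossover --seed 1 --outdir run simulate --pollutant so2 --percent 2.9 --n-strata 10000
aircrossover --outdir run make-strata --cases run/cases.csv
aircrossover --outdir run link-exposure --cases run/cases.csv --strata run/strata.csv \
    --grid so2=run/grid_so2.csv --grid temperature=run/grid_temperature.csv \
    --grid humidity=run/grid_humidity.csv
aircrossover --outdir run fit --strata run/strata_linked.csv --pollutant so2
```

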