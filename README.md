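# saimaa-bycatch

Age-structured bycatch estimation for the endangered Saimaa ringed seal
(*Pusa hispida saimensis*), for population ecologists and fisheries
managers who need to quantify how much gillnet bycatch goes unobserved and
what spatial–temporal fishing closures buy in juvenile survival.

Most bycatch deaths are never recovered as carcasses. The package
reconstructs them for the 1991–2021 birth cohorts by combining three data
streams — the recovered-carcass archive, annual pup production from
birth-lair censuses, and gillnet closure schedules — in a cohort model
over 30 half-month age bins (ages 0–15 months):

```
N_{i+1} = N_i − N_i·e^{−b/2}·Pr_i·[ P(C_i)·O_i + (1 − P(C_i)) ]
```

where `b` is the catch-curve slope of the ln(count+1)-transformed carcass
age frequencies, `Pr_i` the k-NN-smoothed proportion of deaths in bin `i`
(k picked by 10-fold CV), `P(C_i)` the fishing-cause confidence of a
random forest over (age bin, year, zone), and `O_i` the open gillnet-area
fraction implied by that year's closure coverage and season. Potential
fishing deaths in the closed fraction are *averted* and survive — the
mechanism by which closures help. Survivors at 15 months recruit into a
30-class adult projection (pooled catch-curve survival, 189 animals in
1990), and annual removals are assessed against a potential biological
removal limit, `PBR = Nmin·(Rmax/2)·Fr`.

Because the original carcass database is not public, a seeded synthetic
generator reproduces its statistical structure (exponentially declining
carcass age frequencies, a two-peaked seasonal bycatch hazard, the
age-specific cause mix, the 0.08 → 0.95 closure-coverage ramp, and ~1/3
carcass detection) together with the exact ground truth, so every stage of
the pipeline is testable. See `docs/methods.md` for the model details and
design choices.

## Worked example

```python
import saimaa_bycatch as sb

config = sb.SimulationConfig(seed=42)          # 1991-2021 study conditions
carcasses, pups, closures, truth = sb.generate_dataset(config)

result = sb.reconstruct(carcasses, pups, closures, seed=42)
print(result.table[["year", "est_bycatch", "obs_bycatch", "est_survivors_15m",
                    "est_population"]].tail(3).round(1).to_string(index=False))
print(f"b = {result.catch_curve.b:.3f}/month, k = {result.death_proportions.k}, "
      f"adult survival = {result.adult_survival.annual_survival:.3f}")

scen = sb.evaluate_scenarios(pups, result.catch_curve, result.death_proportions,
                             result.cause_model, closures)
for tag, r in scen.items():
    print(f"{tag:>15}: +{r.delta_survivors.loc[2021]:.2f} survivors in 2021")

limit = sb.compute_pbr(n_min_value=414)        # published 2021 lower bound
exceed = sb.compare_removals(result.table.set_index("year")["est_bycatch"], limit.pbr)
print(f"PBR = {limit.pbr:.2f}; estimated bycatch exceeds it in "
      f"{exceed.attrs['n_exceed']}/{exceed.attrs['n_years']} years")
```

prints

```
 year  est_bycatch  obs_bycatch  est_survivors_15m  est_population
 2019          7.5            1               37.1           330.4
 2020          9.5            2               39.6           339.6
 2021          8.7            2               40.5           350.9
b = 0.198/month, k = 3, adult survival = 0.919
     start_aug1: +1.88 survivors in 2021
     start_oct1: +3.34 survivors in 2021
 year_round_ban: +7.20 survivors in 2021
PBR = 2.48; estimated bycatch exceeds it in 31/31 years
```

Reading it: on this synthetic archive the estimated 2021 bycatch (8.7) is
over four times the observed count (2) — carcass detection in the
generator is 1/3, and closure censoring hides more. Delaying the gillnet
season start to August, to October, or banning gillnets year-round would
have added about 1.9, 3.3, and 7.2 fifteen-month survivors in 2021, in the
required order: longer closures always help at least as much. Every year's
estimated bycatch exceeds the removal limit of 2.48 animals/year.

The same stages are available on files via the CLI:

```bash
saimaa-bycatch simulate --out data/ --seed 42
saimaa-bycatch reconstruct --carcasses data/carcasses.csv --pups data/pups.csv \
    --closures data/closures.csv --out table.csv
saimaa-bycatch scenario --carcasses data/carcasses.csv --pups data/pups.csv \
    --closures data/closures.csv --scenario start_aug1 --out deltas.csv
saimaa-bycatch pbr --nmin 414
saimaa-bycatch report --table table.csv --pbr-nmin 414 --out report.json
```

## Published summary statistics

Transcriptions of the published cause-frequency and annual-results tables
ship with the package (`saimaa_bycatch.reporting.load_cause_table()` /
`load_annual_results_table()`); the reporting module recomputes every
derived statistic from them — decadal bycatch means and rates, the
unobserved-to-observed ratio, the geometric-mean population growth rate,
and the PBR exceedance counts.

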