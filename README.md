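# acscea

A four-state Markov cohort cost-utility model comparing **ezetimibe added
to moderate-intensity statin therapy** against **moderate-intensity statin
therapy alone** for secondary prevention after acute coronary syndrome
(ACS), in patients who cannot tolerate high-intensity statins. The package
is written for health-economics analysts: it is config-driven, fully
seeded, and produces the standard cost-utility artefacts — discounted cost
ledgers, ICERs from societal and healthcare-provider perspectives, a
tornado diagram, and a probabilistic sensitivity analysis with
cost-effectiveness plane and acceptability curve.

## The model

States: *no further event* → *non-fatal MI* / *non-fatal stroke* → *death*
(absorbing), annual cycles from age 62 to 100 with half-cycle correction.
Rates convert to probabilities via `p = 1 − exp(−rt)`; hazard ratios act
on rates (the post-ACS excess HR `exp(0.693) ≈ 2` scales background
mortality in the no-event state), relative risks act on probabilities (the
ezetimibe arm's 0.84 / 0.90 / 0.99 on MI-death, stroke-death and all-cause
death). Costs (2024 THB) and QALYs are discounted at 3%/year; the ICER
`ΔC/ΔE` is judged against the 160,000 THB/QALY willingness-to-pay ceiling.
Parameter uncertainty propagates through method-of-moments beta / gamma /
log-normal distributions fitted from each input's 95% interval
(`SE = range/3.92`). See `docs/methods.md` for the full account.

Background mortality comes from any life-table CSV
(`age,mortality_rate`); absent one, a built-in Gompertz–Makeham synthetic
table (remaining life expectancy ≈ 20 y at age 62) is used.

## Worked example

```python
import acscea

params, settings = acscea.load_config()      # packaged base-case inputs
lt = acscea.gen_synthetic_life_table()       # synthetic background mortality
comp = acscea.compare_strategies(params, settings, lt)

print(round(comp.comparator.life_years, 4))          # 10.9792
print(round(comp.intervention.qalys
            - comp.comparator.qalys, 4))             # 0.1723
print(round(comp.icers["societal"].icer_per_qaly))   # 155002
print(round(comp.icers["provider"].icer_per_qaly))   # 149087
print(comp.icers["societal"].cost_effective_at_wtp)  # True
```

The comparator cohort accrues 10.98 discounted life-years; adding
ezetimibe buys 0.1723 QALYs at an extra 26,702 THB (societal), an ICER of
155,002 THB/QALY — under the 160,000 THB/QALY ceiling, so the add-on
strategy is (marginally) cost-effective at base case. The provider
perspective, which excludes direct non-medical costs, gives 149,087
THB/QALY. Sensitivity analyses:

```python
entries = acscea.run_owsa(params, settings, lt)          # tornado, sorted
draws = acscea.run_psa(params, settings, lt, seed=1)     # 1,000 iterations
acscea.quadrant_shares(draws)                            # {'NE': 0.882, ...}
acscea.ceac(draws).at(160_000)                           # 0.505
```

Or from the shell:

```sh
acscea run --out results                 # ledgers, ICERs, traces, manifest
acscea owsa --out results                # tornado.csv
acscea psa --seed 1 --out results        # draws, quadrants, CEAC
acscea validate --out results            # row-sum validity report
acscea synth-lifetable --out lt.csv      # emit the synthetic life table
acscea run --life-table thai_asmr.csv --out results   # national table
```

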