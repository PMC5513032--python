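# Life-table CSV format

`read_life_table` expects a UTF-8 CSV with a header row and two columns:

```
age,q_annual
38,0.012
39,0.013
...
100,1.0
```

- `age`: integer years, strictly increasing, covering at least the model
  start age through 100.
- `q_annual`: probability of dying within the year at that age (nqx with
  n = 1), in [0, 1]; the final age must close the table with `q_annual = 1`.

## Exporting the WHO Kenya 2011 female table

The WHO Global Health Observatory publishes abridged life tables
(indicator `LIFE_0000000029`, "nqx - probability of dying between ages x
and x+n") by country/year/sex.  To reproduce the published setting, export
the Kenya 2011 female table, convert each 5-year nqx to single-year
probabilities under a constant hazard within the age band
(`q1 = 1 - (1 - q5)**(1/5)`), write the columns above, and close the table
at age 100 with `q_annual = 1`.

When no such export is available, `kenya_female_2011_synthetic()` provides
a deterministic Gompertz–Makeham stand-in calibrated to the same era's
summary indicators.
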