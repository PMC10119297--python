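# facesim

Closed-loop simulation and data processing for **Free-Air Concentration
Enrichment (FACE)** fumigation experiments — open-air field plots held at
elevated CO₂ or O₃ concentrations to measure how crops will respond to the
atmosphere of the late century.

`facesim` is for crop ecophysiologists, agricultural modellers and control
engineers who work with FACE fumigation records: it reproduces the full
measurement-to-metric chain of a multi-decade CO₂/O₃ enrichment facility —
a wind-coupled PID gas controller driving octagonal plots, 4-second records
averaged to 1-minute files, quality control, hourly aggregation, ozone
exposure indices and fumigation-efficiency statistics — with seeded
synthetic wind and ambient generators standing in for field conditions, so
every stage can be exercised, tested and extended without the archived
field data.

## The model

**Control law.** Each plot's valve command is a PID law with a wind
feedforward term unique to chamberless fumigation:

```
G_cv = K_p (G_stpt − G_pv) + K_i Int(G_stpt − G_pv) + K_d Der(G_stpt − G_pv) + K_w · ws
```

where `G_stpt` is the setpoint, `G_pv` the measured concentration at the
plot centre, and `ws` the wind speed (m/s). Wind is the dominant loss
process in open air, so the valve opens with the wind before any tracking
error develops. Packaged gains (per species, error in native units):

| gain | CO₂ (ppm) | O₃ (ppb) |
|------|-----------|----------|
| K_p  | 0.0008    | 0.0016   |
| K_i  | 0.000015  | 0.00008  |
| K_d  | 0.016     | 0.016    |
| K_w  | 0.15      | 0.5      |

The command maps linearly onto the physical valve range [0, 10]. The
integral is a rectangle-rule running sum with an anti-windup clamp; the
derivative a first difference, zero on a fresh controller.

**Plot dynamics.** Each octagonal plot (~280 m², 20 m across) is one
well-mixed compartment: `dC/dt = g·valve − d(ws)·(C − ambient)` with
dilution `d(ws) = d₀ + d₁·ws`, stepped by explicit Euler at the 4-second
control cadence. Below 0.2 m/s the system recirculates gas and dilution is
reduced. Release is sectored — the upwind octagon side at full weight, its
two neighbours reduced — so wind carries enriched air across the plot.

**Downstream chain.** 1-minute records (`Avg_MMDDYY` files) are screened by
a repeated-value flagger and species filter windows (250–1500 ppm CO₂,
0–500 ppb O₃), aggregated to hourly means/medians
(`YYYY_HrlyFumData_ByRing` files), and summarised as:

* efficiency — % of fumigation-on minutes within 10%/20% of setpoint;
* ozone exposure indices over daylight hours (8:00–19:00), in ppm·h:
  AOT40 = Σ(C−40) for C > 40 ppb; SUM06 = ΣC for C > 60 ppb;
  W126 = Σ C·[1 + 4403·e^(−126·C_ppm)]⁻¹;
* wind roses — 12 × 30° sectors × speed classes {0–2, 2–4, 4–6, >6 m/s},
  with direction 0° = calm and 360° = north.

A packaged registry mirrors the facility's 2001–2021 experiment record
(year, gases, crop, plots, dates, setpoints — constants like 550 ppm CO₂ or
ambient multiples like 1.5 × ambient O₃).

## Worked example

```python
import dataclasses, datetime as dt
from facesim import (load_registry, generate_environment,
                     simulate_experiment, concat_minutes, target_percentages)

(exp,) = [e for e in load_registry() if e.year == 2001]   # CO2, plots 3,5,14,15
exp = dataclasses.replace(exp, harvest_date=exp.treating_date + dt.timedelta(days=3))
env = generate_environment(exp, seed=1)                   # seeded wind + ambient
minutes = concat_minutes(simulate_experiment(exp, env))   # 4-s loop -> 1-min records
report = target_percentages(minutes, year=exp.year)
print(report.minutes_on, report.pct_within_10, report.pct_within_20)
```

prints

```
7920 98.77525252525253 100.0
```

— 7,920 fumigation-on minutes (4 plots × 3 days × 11 h of daylight
operation), 98.8% of them within 10% of the 550 ppm setpoint and 100%
within 20%. A noise-free simulator is an upper bound on field fidelity;
moving ambient-multiple O₃ targets score lower (see `examples/`). Each
script in `examples/` demonstrates one capability — controller arithmetic,
season simulation, QC, exposure indices, wind roses, the full pipeline —
and prints what its numbers mean.

A thin CLI wraps the same library calls:

```sh
facectl registry --year 2009
facectl simulate --year 2001 --days 1 --seed 1 --out out/
facectl qc --in out/minute --report qc.csv
facectl hourly --in out/minute --out 2001_HrlyFumData_ByRing.csv
facectl metrics --in out/minute
```

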