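# Methods

This note records the models behind `facesim`, the parameters that matter,
and the choices made where the design was genuinely open.

## Control law and its discretization

The valve command is
`G_cv = K_p·e + K_i·Int(e) + K_d·Der(e) + K_w·ws` with error
`e = G_stpt − G_pv` in the species' native unit (ppm CO₂, ppb O₃) and wind
speed `ws` in m/s. The packaged gains (see README table) are the facility's
operational constants and are not tuned by this package.

The continuous `Int()`/`Der()` operators need a discretization, which is a
package choice:

* **Integral** — rectangle rule, `I ← I + e·dt`, with `dt = 4 s`, the
  sampling cadence of the plot records (whether the field controller steps
  at exactly 4 s is not recorded; the sampling interval is the natural
  choice).
* **Derivative** — first difference `(e − e_prev)/dt`, defined as 0 on a
  fresh controller.
* **Anti-windup** — `I` is clamped to ±(10/scale)/K_i, the value at which
  the integral term alone would hold the valve fully open. Without a clamp
  a season-long saturation (e.g. a leak or an undersized supply) would take
  minutes to unwind after recovery. The bound is command-equivalent, so its
  concentration·seconds value differs by species.
* **Valve map** — the raw command is dimensionless; the physical scale of
  the "voltage" it represents is not recorded, so a linear map
  `valve = clamp(scale·raw, 0, 10)` is used with a per-species default
  scale (below). Gas can only be added: the floor at 0 handles overshoot,
  and concentration then decays by dilution alone.

## Plot dispersion model

The octagonal plot is a single well-mixed compartment:

```
dC/dt = g·valve − d(ws)·(C − ambient),   d(ws) = d₀ + d₁·ws
```

stepped by explicit Euler at 4 s. This is deliberately the simplest model
that reproduces the control problem: wind-proportional loss is exactly why
the control law carries a K_w·ws feedforward. There is no spatial field, no
cross-plot contamination, and the sector choice (upwind side at weight 1.0,
neighbours at 0.5) does not affect the centre concentration — sectors are
tracked because the data records them. Below 0.2 m/s the facility
recirculates gas around the plot; this is represented by multiplying the
dilution rate by 0.5 while injection continues.

### Parameter defaults and why

| parameter | CO₂ | O₃ | rationale |
|---|---|---|---|
| d₀ (1/s) | 0.02 | 0.02 | residual mixing with no wind |
| d₁ (1/s per m/s) | 0.04 | 0.04 | 20 m plot ⇒ ~10 s air residence at 2 m/s |
| g (unit/s per valve) | 4.0 ppm | 2.0 ppb | see below |
| valve scale | 6.0 | 2.0 | see below |

The gain–scale pair per species is set jointly by two constraints, worked
out before any season-level scoring:

1. **Discrete-loop stability.** Linearizing the loop (ignoring the slow
   integral) gives the recursion
   `x_{n+1} = (1 − a₁ − a₂ − a₃)x_n + a₂x_{n−1}` with
   `a₁ = dt·g·s·K_p`, `a₂ = g·s·K_d`, `a₃ = dt·d`. Both roots lie inside
   the unit circle iff `a₁ + a₃ + 2a₂ < 2`. With the fixed packaged gains
   this bounds the product `g·s`; the CO₂ defaults (g·s = 24) keep a clear
   margin up to several m/s of wind, where d grows. (An earlier candidate
   g·s = 50 violated the bound and produced a small sustained oscillation
   under constant wind.)
2. **Valve headroom.** The steady valve needed at a typical elevation ΔC is
   `v* = d(ws)·ΔC/g`. Defaults keep `v*` in the lower half of the 0–10
   range at ΔC ≈ 150 ppm CO₂ / 50 ppb O₃ and 2 m/s, so gusts do not
   saturate the valve, and the wind feedforward slope `s·K_w` roughly
   matches the wind-driven loss slope `d₁·ΔC/g`.

These are calibration constants of the simulator, not measurements.

## Synthetic environment

* **Wind speed** is |X| where X follows the discrete mean-reverting
  (Ornstein–Uhlenbeck) recursion
  `X_{k+1} = X_k + θ(μ − X_k)dt + σ√dt·ε_k`, evaluated with a linear
  filter. Defaults μ = 2.0 m/s (the long-run plot-mean speed at the site
  class emulated), θ = 0.02 1/s, σ = 0.16 (stationary s.d. ≈ 0.8 m/s). The
  absolute value rather than stepwise reflection keeps the recursion
  vectorizable; at these parameters the negative-mass correction is
  negligible, so the sample mean tracks μ.
* **Wind direction** is a latent OU attracted to the prevailing direction
  (default 202.5°, south-southwest) wrapped mod 360 — a wrapped-Gaussian
  approximation valid while the distribution is concentrated. Samples
  slower than 0.5 m/s are emitted with direction 0 ("calm"); 360 encodes
  true north. The calm threshold is distinct from, and should not be
  confused with, the controller's 0.2 m/s recirculation rule.
* **Ambient gases** follow smooth diurnal cycles — CO₂ a cosine with its
  pre-dawn (05:00) maximum, mean 400 ppm, amplitude 30 ppm; O₃ a Gaussian
  bump from a 20 ppb night floor to a 60 ppb peak at 14:00 — plus white
  noise (s.d. 2), clipped to the plausibility windows. The site's true
  diurnal amplitudes are not recorded in the material this package draws
  on; these defaults are documented placeholders with the right shape and
  order of magnitude.

What the generators do **not** emulate: gusts/turbulence spectra, frontal
passages, sensor noise and drift, data outages, and within-plot
heterogeneity. Consequently a simulated season is an *upper bound* on field
fumigation fidelity: simulated CO₂ seasons score ~99%/100% (within
10%/20%), above the 66–88%/86–97% of field records, while ambient-multiple
O₃ seasons — whose target moves with ambient — land near the empirical
range (~74%/94%). Passing tests therefore demonstrate the correctness of
the control/processing chain, not the messiness of real data.

## Simulation schedule and record semantics

Fumigation runs daylight hours, 8:00–19:00 by default (the operating hours
are not recorded; the exposure-index daylight window is adopted), giving
660 on-minutes per plot-day. The controller starts each day fresh and the
plot starts at ambient. Stepping covers the operating window plus a
15-minute tail; other minutes are recorded as tracking ambient, since the
~10 s mixing time constant makes the plot indistinguishable from ambient
within a minute of shut-off. Each 1-minute record averages fifteen 4-s
samples; minute wind direction is the circular mean of non-calm samples
(0 when all fifteen are calm). Ambient-multiple setpoints are resolved
against a 15-minute rolling mean of the central ambient series — raw
1-minute ambient would inject noise into the target.

## QC choices

* Repeat equality is judged at written file precision (1 decimal) after
  canonical formatting, so float noise cannot split a genuinely stuck run.
* `min_run` defaults to 5 minutes: short repeats are common under sensor
  quantization, long ones indicate sticking. Configurable.
* Flags are advisory. The archive's repeats were resolved by human review;
  the optional `auto_exclude` heuristic (runs ≥ 15 min differing from
  concurrent ambient by > 10%) is an explicit, configurable stand-in for
  that review, off by default.
* A reportable hour needs ≥ 30 of 60 valid minutes (no completeness rule is
  recorded; half-full is the conventional compromise). Missing stays
  missing — no imputation.
* Filter-window boundaries are inclusive (0 ppb O₃ is valid).
* Aggregation rejects input coarser than 1-minute cadence rather than
  silently re-averaging averages.

## Metric conventions

* Daylight hours are the records labelled 08:00 through 19:00 inclusive
  (12 per day); the phrase "between 8:00 AM and 7:00 PM" is read
  inclusively, and the window is configurable because the endpoint
  convention is ambiguous.
* AOT40/SUM06 use strict ">" at their thresholds as the formulas print;
  `sum06_inclusive` exposes the ≥ variant used in part of the literature.
* W126 is a plain seasonal daylight sum, not the regulatory 3-month rolling
  maximum.
* Efficiency counts 1-minute records (the statistic is defined on minutes),
  pools a treatment's plots by default (per-plot available), and treats
  tolerance bounds inclusively. Zero on-minutes yields an undefined report,
  not a zero.
* Wind-rose mean speed is computed over non-calm samples, matching the
  exclusion of calm samples from the sector cells.

## Registry encoding notes

Harvest-date ranges are encoded as the range's last day; two 2013 maize
experiments with no recorded harvest carry a null date and fall back to
Oct 15 (the conventional growing-period end) as season end. The 2012 O₃
entry "100/110" is encoded as 100 ppb with a flagged alternate 110 profile
— whether it was a mid-season change or two plot groups is not recorded.
Per-plot O₃ gradients (2009–2010) pair plots with setpoints in printed list
order. Obvious year typos in the 2018 rows are corrected and annotated in
the registry file.

## Problem sizes used in validation

The bundled checks run at sizes chosen to exercise every code path while
staying desk-scale: the full-season fidelity figure uses one 100-day,
4-plot CO₂ season (264,000 on-minutes; ~15 s); property suites use 1,000
random hourly series for the indices and 10,000 random minute series for
the QC/RLE equivalence; pipeline determinism uses 1-day runs. Ingesting a
real archive season works through the same `read_minute_file` mapping layer
exercised on synthetic dialect files.

## Known limitations

* One compartment per plot: no gradients, no neighbour contamination, no
  canopy effects on mixing.
* No sensor model (noise, drift, calibration events, outages), hence
  optimistic fidelity statistics (see above).
* The registry's free-text crop/management metadata is carried but not
  interpreted.
* Weather-station ingestion and plotting are out of scope; the wind-rose
  *table* is the contract, not the polar figure.
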