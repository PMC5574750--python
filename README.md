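# tramplerisk

Cattle grazing keeps saltmarsh swards in the patchy condition that breeding
common redshank (*Tringa totanus*) need — and tramples their nests. Whether a
"light" stocking rate (< 1 cattle/ha) is actually light for a nest depends on
where the herd spends its time: cattle on grazed saltmarshes concentrate on
the higher-elevation zones near the seawall, which are exactly the zones
redshank nest in, and they do so during the mid-April-to-mid-July nesting
season. `tramplerisk` quantifies that spatio-temporal overlap for
conservation scientists and reserve managers working with GPS-collared herds
and dummy-nest (clay disc) trials.

The package covers the full chain:

* **Telemetry** — read collar fixes (CSV or GPX), validate and de-duplicate
  them, label each fix with its season week (week 1 begins 14 April), count
  cattle days.
* **Activity surfaces** — a 50 × 50 m grid over the marsh; cells with more
  than 6.25 m² of marsh are included. Per cell *c* and window *w*, cattle
  activity in cattle · ha⁻¹ is

  $$A_{cw} = H \cdot \frac{n_{cw} / N_w}{a_c},$$

  with $H$ the herd size, $n_{cw}$ the fixes in the cell, $N_w$ the total
  within-marsh fixes, and $a_c$ the cell's marsh area in ha — the mean
  cattle abundance in the cell over the window. Summing $A_{cw} a_c$ over
  cells returns $H$ exactly (herd conservation).
* **Range metrics** — CA₁₀₀ (the % of included cells holding 100 % of a
  week's activity, i.e. the visited-cell fraction), the never-visited
  fraction of the marsh, per-habitat-zone activity shares, and the weekly
  95th-percentile distance of fixes from the seawall.
* **Trend models** — generalized least squares with within-marsh AR(1)
  errors for `marsh + week + week² + marsh:week + marsh:week²` global
  models, sequential F tables, backward single-term elimination at
  α = 0.05 (respecting marginality), per-zone Gaussian linear models, and
  residual-ACF diagnostics.
* **Trampling risk** — dummy-nest plots of nine discs checked after two
  14-day periods convert to a daily trampling probability
  $d = 1-(1-p_{\mathrm{period}})^{1/14}$ and to the probability of loss over
  the 24-day redshank incubation $p_{24} = 1-(1-\bar d)^{24}$. A binomial
  penalized-spline smooth (logit link, AIC-selected smoothing) maps local
  cattle activity to $p_{24}$; projecting it through per-cell activity over
  the first 24 days of grazing yields a nest-trampling risk map.
* **Synthetic data** — a seeded generator for marsh geometry (seawall,
  distance-banded habitat zones, creeks), herd tracks (a biased correlated
  random walk with herd cohesion and a hump-shaped seasonal range), and
  Bernoulli disc trials from a known logistic dose–response, so the whole
  analysis runs and is testable with no field data.

## Worked example

Simulate the default study system — a 126-ha marsh grazed by 39 young cattle
(4 collared) from mid-May (week 6) to late October (week 28), with 30
nine-disc dummy-nest plots — and analyse it:

```bash
trample-risk simulate --config cfg.yaml --seed 7 --outdir out
trample-risk analyze  --config cfg.yaml --seed 7 --outdir out
```

prints

```
SCD 0.31 /ha, LSU 0.25 /ha, 46368 fixes, 644 cattle days
never visited: 66.9% of included cells
              zone  mean_p24  max_p24  n_cells
     non_saltmarsh  0.089966 0.998512       72
mid_marsh_redshank  0.112431 1.000000      180
elytrigia_redshank  0.031808 0.035108      108
      non_redshank  0.031777 0.031777      180
```

Reading this: the seasonal cattle density (herd over area) is 0.31
cattle/ha — 0.25 livestock units/ha for young stock — yet two-thirds of the
included marsh is never visited at all, so the herd's pressure lands on a
small fraction of the marsh. The mean 24-day nest-trampling probability in
the mid-marsh redshank nesting zone (0.112) is ~3.5 times that in the
seaward non-redshank zone (0.032), and individual nesting-zone cells reach
certainty ($p_{24} = 1$): risk is concentrated precisely where redshank
nest, far above what the marsh-wide density suggests. `out/` additionally
holds the weekly metrics table, trend-model summaries with removal logs, the
sampled dose–response curve with confidence bands, activity surfaces
(GeoJSON + CSV) and the per-cell risk map.

The same stages are importable functions (`tramplerisk.build_grid`,
`cattle_activity`, `fit_gls_ar1`, `fit_dose_response`, `predict_risk_map`,
…) for use in notebooks and scripts.

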