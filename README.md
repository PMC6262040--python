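# hyphatrack

Growth quantification for filamentous microorganisms at the single-spore
level. `hyphatrack` takes time-lapse image stacks of *Streptomyces*-like
mycelia growing in monolayer microfluidic chambers (90 × 40 µm, one
spore per chamber) and turns them into the four readouts that
characterize early filamentous growth:

* **germination delay** — when the first trackable hypha emerges,
* **specific growth rate µ** (h⁻¹) — slope of a gated log-linear fit of
  total mycelium length (the "exponential growth phase" is the longest
  window with R² > 0.9),
* **hyphal growth unit (HGU)** — µm of mycelium per growing tip, the
  classical branching-density measure, computed as the maximum of
  smoothed total length over smoothed tip count within that window,
* **tip elongation rates** — per-hypha extension speeds from tracked
  skeleton endpoints.

The image chain is chamber-ROI detection → adaptive binarization →
skeletonization → skeleton graphs (endpoints/junctions, chain-metric
lengths) → greedy nearest-neighbour tip tracking with four artefact
filters (≥ 5 consecutive points, final length > 10 µm, growth ≥ 5 µm,
rate ≤ 100 µm/h), truncated once the mycelium covers 20 % of the
chamber. A companion module analyzes scattered-light growth curves from
shaken microtiter plates (per-well blanking, lag-phase detection, and µ
as the maximum of S′/S of a 10-knot least-squares spline), so
single-cell and bulk cultivations can be compared directly. Condition
summaries come with both Student and Welch t-tests.

Because public single-mycelium time-lapse data are scarce, the package
includes a fully ground-truthed synthetic generator (germination delays,
a ramping primary hypha, linearly elongating branches, HGU-controlled
branching, monolayer volume exclusion, raster rendering with noise, and
lag/exponential/saturating plate signals). Every estimator is validated
by parameter recovery against it; `docs/methods.md` describes the model,
the estimators and their quantified biases.

## Worked example

Simulate one chamber at the complex-medium reference condition, render
it, and run the full pipeline on the clean rasters:

```python
import hyphatrack as ht

params = ht.SimulationParams(seed=11, n_frames=24,
                             germ_delay_mean_h=3.0, germ_delay_sd_h=0.8)
geometry, truth = ht.simulate_mycelium(params)
stack = ht.render_frames(geometry, params)
analysis = ht.analyze_chamber(stack, use_clean_masks=True)
r = analysis.result
print(f"germination: true {truth.germination_time_h:.2f} h, "
      f"measured {r.germination_time_h:.2f} h")
print(f"mu = {r.growth_fit.mu_h:.3f} 1/h  (R^2 = {r.growth_fit.r_squared:.3f})")
print(f"HGU = {r.hgu_um:.1f} um   (target {truth.target_hgu_um})")
print(f"tip rate = {r.tip_rate_mean_um_h:.1f} +/- {r.tip_rate_sd_um_h:.1f} um/h "
      f"over {r.n_filtered_tracks} tracks")
```

prints

```
germination: true 4.09 h, measured 4.50 h
mu = 0.672 1/h  (R^2 = 0.931)
HGU = 21.3 um   (target 28.7)
tip rate = 9.5 +/- 3.6 um/h over 3 tracks
```

The measured germination lags truth by one 0.5 h frame (the germ tube
must become resolvable). On a single 12 h-young chamber the HGU has not
plateaued yet and the fitted µ still contains the primary-tip ramp-up;
the statistically sized recovery studies (30 developed chambers)
recover the generating HGU to ≈ +5 % at fast-growth (CM-like)
conditions; at slow-growth conditions the image-based tip count has a
documented ≈ +13 % resolution-floor overshoot (`docs/methods.md`). Image-route tip rates in branched
mycelia underestimate the generating distribution (geodesics shortcut
through skeleton crossings), so the tip-rate recovery study measures
rates on ground-truth trajectories (see `docs/methods.md`).

Plate signals work the same way:

```python
sig = ht.simulate_scatter_signal(ht.ScatterSignalParams(lag_h=9.3,
                                                        mu_h=0.33, seed=1))
well = ht.analyze_well(sig)
print(f"lag = {well.lag_phase_h:.2f} h, mu = {well.mu_h:.3f} 1/h")
# lag = 9.50 h, mu = 0.340 1/h
```

The numbered drivers under `analysis/` run small demonstration cohorts
(simulate → per-chamber metrics → plate wells → condition statistics)
and write their tables under `results/`. The `hyphatrack` CLI exposes
`simulate`, `analyze`, `mtpc` and `report` for file-based workflows.

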