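# Methods

`hyphatrack` quantifies the early growth of filamentous microorganisms
(developed around *Streptomyces lividans*-like phenomenology) from two
kinds of data: time-lapse microscopy of single spores germinating in
monolayer microfluidic chambers, and scattered-light growth curves from
shaken microtiter-plate cultures. Because suitable public single-mycelium
image datasets are essentially nonexistent, the package ships a synthetic
data generator with complete ground truth; every estimator in the
pipeline is validated by parameter recovery against it.

## The growth model behind the generator

One spore sits in a 90 × 40 µm chamber of ~1 µm height, so growth is a
2-D monolayer. The generator implements the phenomenology reported for
this system:

* **Germination.** With probability `germination_prob` the spore
  germinates at a delay drawn from a normal distribution truncated at
  zero (`germ_delay_mean_h` ± `germ_delay_sd_h`). Normality is the
  minimal assumption given that only means and SDs are published;
  truncation keeps delays physical. Non-germinating spores produce empty
  frames — they are data, not errors.
* **Primary hypha.** The first tip accelerates along a saturating ramp
  `v(t) = v∞ (1 − e^{−(t−t_g)/τ})` with `τ` = 2 h by default. The
  published observation is an "approximately exponentially increasing"
  early tip rate without quantification; the bounded ramp reproduces the
  qualitative shape while guaranteeing a finite asymptotic rate `v∞`
  drawn from the tip-rate distribution.
* **Branches.** Every later tip elongates at a constant rate drawn from
  a truncated normal (`tip_rate_mean_um_h` ± `tip_rate_sd_um_h`, > 0);
  linear elongation of post-primary branches is the published pattern.
* **Branching rule.** A new lateral branch is spawned whenever total
  mycelium length per growing tip exceeds `target_hgu_um`, anchored
  uniformly along the existing mycelium, at ±(60–90°) to the local
  parent direction. The deterministic threshold makes the hyphal growth
  unit (HGU) recovery exact in expectation and pins the asymptotic
  specific growth rate of total length to `µ ≈ v̄ / HGU` (total length
  grows by branching, not by individual tips speeding up).
* **Monolayer volume exclusion.** Tips carry a persistent direction with
  Gaussian angular noise (`angle_noise_rad` per frame interval) and
  steer away from occupied space: an
  occupancy grid (`avoidance_grid_um`, default 1.0 µm) records which
  hypha first claimed each cell, and a tip only steps into positions
  whose 3 × 3 cell neighbourhood is free of other hyphae and of its own
  older trail (the most recent ~5 µm of own path is exempt, as is the
  parent corridor for a branch's first 4 µm). Steering is
  curvature-capped (up to 2 rad per µm of laid-down arc, scanned in
  thirds, with a one tube-width look-ahead), so fast and slow tips trace
  equally smooth paths; a tip with no clear deflection stalls until
  space opens. Branches only spawn
  at anchors with a clear escape corridor. The chamber walls are
  modelled as occupied space, so the same steering turns tips smoothly
  away from walls (specular bouncing creates corner kinks whose raster
  blobs sprout skeleton spurs; wall-sliding creates fused wall lanes —
  both were measurable artefacts). This models the physical volume
  exclusion of a 1 µm-high chamber — hyphae push past each other rather
  than overlap — and is also what keeps simulated tips optically
  resolvable at the rendering resolution; without it, rasterized
  crossings and sub-resolution parallel bundles hide a large fraction of
  tips and no image-based tip count can recover the generating HGU.
* **Capacity cap.** Growth stalls once total length reaches
  `max_total_length_um` (default: half the chamber area over the hyphal
  width). Analysis truncates at 20 % chamber coverage long before the
  cap matters.

All randomness flows from one `numpy` generator seeded by `seed`;
identical parameters give bit-identical geometry and ground truth.
Simulation advances in `sim_dt_h` = 0.02 h substeps; tip-step arc
lengths use the exact integral of the rate law, so recorded ground-truth
rates close with measured polyline arc length to machine precision for
unobstructed, wall-free tips (wall reflections fold a substep segment
and shorten its stored chord by design; volume exclusion makes realized
rates fall below drawn rates in crowded scenes — both are properties of
the model, not bugs, and the rate-recovery studies therefore run in
unobstructed mode).

Rendering stamps each centreline with a disk of `hypha_width_um`
(default 0.7 µm) at `pixel_size_um` (default 0.1 µm/px → 900 × 400 px
chambers), dark hyphae on a bright background (configurable polarity),
then Gaussian blur (σ = 1 px) and additive Gaussian noise (`noise_sd`).
The pre-noise binary raster is retained as `clean_masks` so the
geometric stages can be validated independently of segmentation.

The scattered-light generator produces `S(t) = blank + M·E/(M+E) +
noise` with `E = A·e^{µ(t−lag)}` and `M = saturation − blank`:
a flat blank phase, exponential growth at rate `µ` while `E ≪ M`, and a
smooth logistic approach to the saturation level, sampled every 10 min.
Defaults (blank 100, amplitude 15, saturation 600, noise SD 0.5 a.u.)
mirror the signal-to-noise regime of plate readers, where instrument
noise is far below the growth signal.

## The analysis pipeline

1. **Chamber ROI.** The chamber rectangle (expected dimensions in µm ×
   the pixel calibration) is located on the first frame by maximizing
   the summed intensity-gradient response along the candidate border,
   using separable row/column profiles; the ROI is frozen for the whole
   stack since chambers do not move. A normalized border response below
   0.2 raises "chamber not found".
2. **Binarization.** Per-frame local-mean adaptive threshold (block
   51 px) inside the ROI; a pixel is foreground when it is more than
   `offset` = 10 intensity units darker (or brighter, auto-detected via
   the mean/median asymmetry of the minority phase) than its local mean.
   The offset must sit between the blur-halo amplitude and the object
   contrast; zero floods the halos. Components smaller than 1 µm² are
   dropped and a 3 × 3 closing bridges 1-px gaps. Constant frames yield
   an empty mask plus a QC flag. Thresholding against the local mean
   makes the mask invariant to additive illumination shifts.
3. **Skeletonization.** Zhang thinning, followed by removal of isolated
   pixels, deletion of simple points until no 2 × 2 block remains, and
   optional pruning of terminal spurs (default 0.2 µm on segmented
   images, where threshold-boundary roughness sprouts false endpoints;
   off for noise-free rasters, where pruning would only delay the
   detection of emerging branches; whole hyphae are never pruned).
4. **Skeleton graph.** Endpoint (degree-1) and junction (degree ≥ 3)
   pixels become nodes; maximal degree-2 chains become edges with the
   8-connected chain metric (1 px orthogonal, √2 px diagonal). Pure
   cycles get an anchor node with a self-loop. Total length and tip
   count (= endpoint count) feed every downstream metric from this one
   graph. The chain metric overestimates smooth curves by up to ~7 %
   depending on orientation (~5 % averaged over orientations), partly
   offset by thinning's end erosion; length accuracy is validated at 8 %
   on developed mycelia.
5. **Coverage truncation.** Analysis stops at the last frame before
   chamber coverage reaches 20 % (dense mycelium defeats segmentation);
   a chamber already at 20 % in frame one is rejected as overgrown.
6. **Tip tracking.** Endpoints are matched frame-to-frame by greedy
   nearest neighbour inside a gate of `max_rate·Δt + 2 px`, ties broken
   by tip index. New tips open tracks anchored at the nearest junction
   (skeleton centroid before any junction exists); missed detections
   terminate tracks — no gap filling, since the track filters require
   consecutive points. Each track's geodesic length is the shortest path
   along the current skeleton (Dijkstra on the pixel graph) from its
   birth anchor to the tip; where skeleton and anchor are disconnected,
   the Euclidean distance stands in.
7. **Track filters.** (a) ≥ 5 consecutive samples, (b) final geodesic
   length strictly > 10 µm, (c) total growth ≥ 5 µm, (d) no
   frame-to-frame rate above 100 µm/h (single-frame jumps are the
   signature of tracking errors). Rejected tracks carry the first
   violated rule; the filter is idempotent and order-independent.
8. **Chamber metrics.**
   * *Germination delay* — birth time of the first filtered track; none
     means the chamber is counted non-germinated. Detection lags true
     germination by the time the germ tube needs to become resolvable
     plus frame quantization (≈ +0.3 h at default settings).
   * *Specific growth rate* — OLS of ln(total length) on time over the
     longest contiguous window (≥ 5 points, earliest on ties) with
     R² > 0.9; the window defines the "exponential growth phase".
   * *HGU* — maximum over that window of centred-moving-average-smoothed
     total length over smoothed tip count (window 5 frames, shrinking at
     the edges).
   * *Tip elongation rates* — per-track endpoint difference over elapsed
     time (robust to per-frame skeleton jitter), pooled into mean ± SD;
     frame-to-frame instantaneous rates are retained for distribution
     views.
9. **Plate signals.** Per-well blanking by the mean of the first 10
   readings; lag phase as the first time the 3-sample-smoothed blanked
   signal exceeds `max(10·σ̂, 0.02·max)` and stays above for 3 samples,
   with σ̂ estimated from second differences of the blank window
   (robust to growth leaking into it); growth rate as the maximum of
   S′/S of a least-squares cubic spline (10 equally spaced interior
   knots) fitted to the region above the detection threshold — fitting
   across the pre-lag kink would make the spline oscillate. On capped
   logistic signals the S′/S maximum sits just after threshold crossing
   and underestimates µ by ≈ T/saturation (≤ 2 % at defaults; ≤ 5 %
   over the signal family).
10. **Condition statistics.** n/mean/sample-SD summaries per medium;
    two-sided pooled-variance (Student) and Welch t-tests are both
    reported for every pair, with the significance call (p < 0.05) on
    the Welch p-value; no multiple-testing correction by default (an
    optional Bonferroni column exists). Germination fraction =
    germinated chambers / all chambers.

## Quality control instead of manual curation

The reference workflow curated chamber positions by eye. Here every gate
failure is a QC flag on the chamber result: ROI not found, degenerate
frames, overgrown at start, no trackable hypha (non-germinated), no
window past the R² gate, no tips in the fit window, coverage stop not
reached within the horizon, and "underdeveloped" (< 10 tips at analysis
end). Condition-level HGU statistics exclude underdeveloped chambers —
the automated analogue of "properly grown mycelium" curation; a chamber
whose spore drew a near-zero tip rate is real data for germination
statistics but carries no information about branching density.

## What recovery studies show — and what they cannot

The recovery drivers (`hyphatrack.recovery`) re-estimate each quantity
at its published reference value: germination delays of 10.0 h (CM) and
33.5 h (AA04) over 50 chambers each; specific growth rates of 0.38 h⁻¹
(single-cell, from 50 noisy length curves) and 0.23 h⁻¹ (plate spline,
20 wells); HGU targets of 28.7 µm and 14.3 µm over 30 geometric
simulations; the pooled tip elongation rate of 14.1 µm/h against the
closed-form truncated-normal mean; a 9.3 h lag over 10 wells; and a
36.12 % germination fraction over 400 chambers. Problem sizes are the
study sizes; germination-only runs cap mycelium growth at 300 µm and
stop rendering at 6 % coverage because the first trackable hypha decides
the outcome far below that.

Structural estimator properties quantified by these studies:

* Germination delay detection is late by ≈ one frame interval ( + 0.3 h).
* HGU estimates carry competing small biases: the chain metric (+3–5 %
  on length), the basal (non-growing) endpoint in the tip count (−1/n),
  sub-resolution emerging branches (≈ µ·ℓ_e·E[1/v] of the tip
  population, where ℓ_e ≈ 1–1.5 µm is the emergence length below which
  a young branch is hidden inside its parent's tube), and the upward
  bias of a maximum taken over a noisy ratio. At CM-like conditions
  these partially cancel at fast-growth conditions (CM recovery ≈ +5 %
  over 30 chambers). At slow-growth/low-HGU conditions (AA04) the
  hidden-branch term dominates because slow branches linger below
  resolution for hours, and the estimator overshoots by ≈ +13 % —
  insensitive to smoothing window, hyphal width, steering model and
  rate spread, i.e. an optical-resolution floor of image-based tip
  counting at this pixel size, not a tunable parameter. The AA04
  recovery study reports this overshoot as a finding; the 10 % recovery
  band is not met there. Longer spur pruning hides more emerging
  branches and inflates the estimate further; on clean rasters pruning
  is therefore off.
* The plate-signal lag detector has a threshold-crossing bias below one
  sample interval at default signal-to-noise; the spline µ estimator's
  logistic-cap bias is ≤ 2 % at defaults.

What the generator does **not** emulate: real phase-contrast texture
(halos, shading), focus drift, stage jitter, hyphal fusion
(anastomosis), septation, sporulation, spore clusters, germling
agglomeration, or density-dependent nutrient depletion. Passing
recovery therefore demonstrates correctness of the measurement chain on
geometry-faithful, optics-simplified data — not robustness to every
imaging pathology of real microscopes.

## Numerical choices and degenerate inputs

* Pixel coordinates are 0-based (row, column); ROI rectangles are
  half-open; frames are sampled at `frame_interval_h` = 0.5 h.
* Truncated-normal sampling is by rejection (the means sit well above
  zero, so acceptance is high); a draw can legitimately be near zero —
  such spores never produce a trackable hypha and are counted
  non-germinated.
* `fit_growth_rate` uses prefix sums for O(1) OLS per window and scans
  all qualifying windows; constant series have zero log-variance and
  fail the gate (R² treated as 0). All-zero series return none.
* Empty masks skeletonize to empty; empty graph sequences track to no
  tracks; empty track lists give a none germination delay. Zero-area
  ROIs, empty condition samples, non-finite metric values and t-tests
  on n < 2 raise errors.
* Degenerate t-tests (both variances zero) follow the documented
  contract: equal means → t = 0, p = 1; distinct means → p = 0 with
  Welch df clamped to ≥ 1.
* Exports are deterministic given identical inputs; HDF5 round-trips
  reproduce condition summaries bit-identically.

## Known limitations

* The image route's per-tip geodesics shortcut through skeleton
  crossings, so image-based tip *rates* in dense mycelia are
  underestimates; rate statistics should be read from sparse phases or
  validated against ground-truth tracks (as the recovery study does).
* The AA04-condition HGU overshoot (~+15 %) described above.
* Greedy nearest-neighbour matching with a 100 µm/h gate can in
  principle swap tips that approach within one frame's travel; the
  artefact filters remove the resulting jump tracks but the swapped
  identities are not repaired.
* The ROI detector assumes an axis-aligned rectangular chamber of known
  physical size; rotated or distorted fields need upstream
  rectification.
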