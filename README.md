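# spherofuse

Automated monitoring of spheroid-doublet fusion in agarose-microwell
bright-field time-lapses.

When two multicellular spheroids are placed in contact they spontaneously
fuse toward a single rounded body. The rate and extent of this fusion are
sensitive readouts of tissue maturity and building-block quality in
bottom-up biofabrication, but quantifying them by hand over hundreds of
microwells and hundreds of frames is impractical. `spherofuse` implements
the full analysis chain for such assays:

- **Microwell detection and tracking** — circular Hough transform on the
  first frame; per-doublet re-localization in a local crop every frame, with
  samples dropped when the well is lost or drifts out of the field of view.
- **Doublet segmentation** — frame 0 is segmented inside the well interior;
  for each later frame the stored grayscale reference mask is rigidly
  registered (translation + rotation, normalized cross-correlation) to the
  new crop, a fresh segmentation is refined against the transformed
  reference, and both rolling references are replaced.
- **Morphometrics** — per frame: area, perimeter, roundness
  `4πA/P²`, doublet length and width, the contact length across the neck
  between the spheroids, both spheroid widths, upper/lower intersphere
  angles, and frame-to-frame rotation. Neck detection combines boundary
  distance-profile minima with two maximally inscribed circles; contact
  features are monitored only until the doublet roundness reaches 0.8.
- **Candidate triage** — a cost-sensitive random forest (60 trees, 30
  predictors per split, leaf size 3, false negatives charged 5× false
  positives) separates usable doublet wells from empty/debris/overlapping
  ones, evaluated with group-stratified 5-fold cross-validation.
- **Kinetics** — the roundness response is summarized by the bounded
  exponential

  ```
  roundness(t) = plateau + b · exp(−t/τ),   plateau ∈ [0.5, 1],  b ∈ [−0.6, −0.1]
  ```

  where the plateau is the steady-state roundness (fusion quality) and the
  time constant τ (hours) is the time to close ≈63.2 % of the gap to the
  plateau (inverse fusion rate). Early normalized contact length is fitted
  by a bounded line on the first 5 h. Population curves are truncated at
  30 % sample dropout, and groups are compared with ANOVA + Tukey–Kramer or
  Kruskal–Wallis + Dunn–Šidák depending on normality and variance tests.
- **Synthetic phantoms** — a geometric generator renders fusing doublets as
  two-disk unions inside dark-rimmed wells, with debris, single cells,
  intensity gradients, noise and stage drift, and returns exact analytic
  ground truth (masks, centres, contact chord, intersphere angle, union
  area, roundness) for every frame, so the whole pipeline is testable
  without microscope data.

## Worked example

Render a noisy 60-frame phantom of a fusing doublet (plateau 0.9, b −0.3,
τ = 2 h), run the pipeline on it, and fit the kinetic model:

```python
from spherofuse import phantom, microwell, segment, features, kinetics

cfg = phantom.PhantomConfig.test_preset(n_frames=60, noise_sd=4.0, rng_seed=0)
stack, truth = phantom.render_doublet_sequence(cfg, kinetics=(0.9, -0.3, 2.0),
                                               r1=50, r2=50)
wells = microwell.detect_microwells(stack[0], radius_range=(50, 75))
result = segment.segment_sequence(stack, wells[0])
records = features.extract_timeseries(result.masks, result.rotations,
                                      pixel_size=cfg.pixel_size,
                                      frame_interval=cfg.frame_interval)
df = features.records_to_frame(records)
fit = kinetics.fit_exponential(df["time"].to_numpy(), df["roundness"].to_numpy())
print(fit.summary())
```

Output:

```
detected 1 microwell(s); radius 62.5 px
segmented 60 frames; dropped: None
 time     area  roundness  contact_length
0.000 15700.48      0.631            36.8
0.083 15646.72      0.645            40.0
0.167 15626.24      0.654            41.6
roundness(t) = 0.8986 + (-0.2642) * exp(-t / 2.320 h)   [rss=5.355e-04, n=60, converged=True]
```

The fitted plateau 0.899 and τ = 2.32 h recover the generating parameters
(0.9, 2 h) from 5 h of noisy frames; `area` is in µm², `contact_length` in
µm, `time` in hours. A thin CLI wraps the same workflow
(`spherofuse generate-phantom`, `detect`, `analyze`, `fit`,
`classify-train`, `classify-apply`, `validate`, `report`).

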