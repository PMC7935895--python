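# camoseek

Camouflage quantification and search-image analysis for detection-game studies
of variable prey — built for behavioural ecologists asking how natural
variation in colour patterns (e.g. the morphs of juvenile green shore crabs,
*Carcinus maenas*) defeats predator search-image formation.

The package covers the full analysis chain of a "find the hidden crab"
detection game played against natural-texture backgrounds:

1. **Image pipeline** — two-point grey-standard reflectance calibration,
   sRGB → CIELAB conversion (D65, 2° observer), automatic target cutout by
   threshold + border flood fill with a feathered alpha edge, and alpha-blended
   compositing of rotated targets at natural pixel/mm scale.
2. **Camouflage metrics** — for each composited scene, against both the local
   surround (within one body length, where body length is the diameter of the
   least-squares circle fitted to the outline) and the whole background:
   * *edge disruption* (GabRat): at each outline point, Gabor edge energy is
     measured parallel (`E∥`, the "true" boundary edge) and orthogonal
     (`E⊥`, "false" disruptive edges) to the local outline tangent;
     GabRat = mean over the outline of `E⊥ / (E⊥ + E∥)` — achromatic on
     CIE L (σ = 3 px), chromatic on CIE A (σ = 4 px);
   * *luminance match*: L1 distance between 100-bin CIE L histograms;
   * *colour-map match*: L1 distance between 200×200-bin joint (A, B)
     frequency maps over [−100, 100]²;
   * *mean-colour match*: Euclidean distance between mean (A, B) points;
   * *pattern match*: L1 distance between bandpass "granularity" energy
     spectra (per-scale SD of difference-of-Gaussians images).
3. **Game simulation** — 24-slide sessions in which the same individual
   phenotype repeats with probability 0.8 (runs punctuated by switches that
   may or may not change the broad morph), and a synthetic observer whose
   detection hazard is `exp(β₀ + Σ βₘ·metric + β_e·encounters +
   Σ γₘ·metric·encounters + …)` with 15 s timeouts right-censored.
4. **Models** — the four analysis families: per-metric Cox ranking by |z|;
   metric × encounters interactions (search-image formation rate); linear
   mixed models on log capture-time differences between consecutive slides
   with camouflage-difference × novelty terms; and the morph-switch × novelty
   model with its 6×6 switch matrix.
5. **Reporting** — presentation/timeout bookkeeping, stratified medians,
   integer percentage effects, Kaplan–Meier curves with 95% CIs, and the
   morph-switch heat map.

A first-class synthetic-data module (`camoseek.synth`) generates backgrounds
with controlled grain and colour statistics, parametric crabs in the six morph
classes (Black, Disruptive, Green, Mottled, Pale, Spotted; catalog mix
22/15/50/28/20/20), and gameplay logs with known ground-truth hazard
parameters, so every stage is testable without any photographs.

## Worked example

`examples/simulate_game.py` builds a measured 30-crab catalog, plays 200
sessions and summarises the outcomes:

```
sessions:            200
presentations:       4800
timeouts:            216 (4.50%)
mean run length:     4.23 slides (median 3)
median capture time by stratum (ms):
  novel  phenotype, poor colour match:    2454
  novel  phenotype, good colour match:    3397
  repeat phenotype, poor colour match:    2105
  repeat phenotype, good colour match:    2868
```

Reading the numbers: a few percent of presentations hit the 15 s timeout;
the 80% repeat rule yields runs of ~4 slides; and the stratified medians show
the search-image signature — crabs survive longest when the phenotype is novel
*and* well colour-matched (3397 ms), while a repeat encounter with a poorly
matched crab is found fastest (2105 ms).

The other examples demonstrate single-scene metric measurement
(`measure_camouflage.py`), Cox metric ranking and the encounters interaction
(`fit_models.py`), and the switch/morph-switch difference models
(`switch_analysis.py`).

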