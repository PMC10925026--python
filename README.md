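# myodti

Quantitative analysis of pressure-induced cell death in ex vivo skeletal
muscle — the image-and-statistics side of deep-tissue-injury (DTI)
experiments in which a flat circular indenter compresses an isolated muscle
and dead fibers are revealed by a membrane-impermeable fluorescent dye
(Procion Yellow class): viable fibers show only green autofluorescence,
fibers with a ruptured sarcolemma take up the dye.

The package is aimed at labs running stress–time loading studies on muscle
tissue who need to go from two-channel cross-section images and a loading
protocol to a fitted stress–time cell-death threshold, reproducibly and with
every tunable in one validated configuration.

## What it computes

1. **Dye-positive fiber counts.** Each cross-section is background-subtracted
   (morphological opening) and normalised; fibers are instance-segmented
   (distance-transform watershed, pluggable); a fiber is dye-positive when
   its mean dye intensity exceeds the *control threshold* — the pooled mean
   dye intensity over the whole tissue region of the sample's unloaded
   control sections. Counts are averaged over the (normally six) sections of
   a sample.

2. **Damage classification.** Mechanically killed fibers cluster around the
   indentation site; background death is scattered. Each section is tested
   with a permutation statistic (mean pairwise distance among dye-positive
   centroids vs equal-size random fiber subsets). A sample with at least one
   localized section is "damaged"; the lowest mean count among damaged
   samples becomes the **baseline**, and every sample is labelled
   `cell_death` (mean count ≥ baseline) or `no_damage`.

3. **Stress mapping.** Indenter loads convert to external direct stress
   σ = F/(πr²); the average *internal* compressive stress in the muscle layer
   is obtained from a linear model of the finite-element-predicted difference
   σ_ext − σ_int = c₀ + c₁·σ_ext, calibrated by default from the two bundled
   FE operating points (5 → 3.4 kPa, 103 → 69.1 kPa; a 32 % reduction at the
   low end).

4. **Stress–time thresholds.** Classified (t, σ_int) points are fitted with
   the four-parameter decreasing Boltzmann sigmoid

   σ(t) = K / (1 + e^{α(t − t₀)}) + C

   (K range, α slope coefficient, t₀ time at midrange, C minimum-stress
   asymptote) by multi-start bounded least squares, with the conservative
   asymptote constraints **C < 6 kPa** for the cell-death curve and
   **C > 3.7 kPa** for the no-damage curve. Fitted curves are compared
   against the bundled in vivo reference parameters.

A first-class synthetic-data generator renders ground-truthed two-channel
sections (jittered hexagonal fiber tessellation, localized or scattered
planted dead fibers) and whole labelled loading studies, so every stage is
testable without any real data.

## Worked example

Simulate a small rendered study (12 load–duration conditions, 3 sections per
sample, 300 fibers per 256 px section) and run the full pipeline:

```
myodti simulate --output demo/data --seed 0 --n-fibers 300 --image-size 256 --sections 3
cat > demo/config.yaml <<EOF
paths:
  manifest: demo/data/manifest.csv
  loading_table: demo/data/loading.csv
  output_dir: demo/run
preprocessing: {background_radius: 25}
expected_sections: 3
seed: 0
EOF
myodti run-all --config demo/config.yaml
```

prints

```
baseline: 125.3
cell_death: K=50.0 alpha=0.08 t0=75.2 C=6.0 SSE=1733.92
no_damage: K=7.0 alpha=3.70 t0=48.6 C=3.7 SSE=106.85
report: demo/run/report.md
```

Reading this: the least-affected pattern-positive sample averaged 125.3
dye-positive fibers per section, so samples at or above that count are
`cell_death` — in this run all 12 samples match the generator's ground-truth
labels (see the sample table in `report.md`). The fitted curves are loose
because the demo's 12 design points sit far above/below the true threshold
band rather than bracketing it — with one sample per condition the sigmoid
is weakly identified, which the large SSE values make visible. The report
also tabulates parameter deltas against the in vivo reference curves, and
`thresholds.png` shows the stress–time scatter with both fits.

## Layout

- `src/myodti/stress_mapping.py` — indenter loads, external→internal stress
- `src/myodti/threshold_model.py` — Boltzmann thresholds: evaluate/fit/compare
- `src/myodti/image_quantification.py` — preprocessing, segmentation, counting
- `src/myodti/damage_classification.py` — localization test, baseline, labels
- `src/myodti/synthetic_data.py` — ground-truthed scenes and studies
- `src/myodti/{config,pipeline,report,cli}.py` — orchestration and reporting
- `docs/methods.md` — models, assumptions, parameter choices, limitations
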