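# placodyn

Quantitative live-imaging analysis of **pulsatile medial myosin II and apical
constriction** in epithelial placodes, built for two-channel confocal
time-lapse movies (membrane marker + myosin reporter) of tissues such as the
*Drosophila* salivary-gland placode, where coordinated apical constriction
drives tube invagination.

During placode invagination, each cell's apical medial actomyosin network
pulses with a cycle length of roughly 120–180 s, and each myosin pulse is
followed — about one-eighth of a cycle later — by a transient constriction of
the apical surface, part of which is retained (a constriction ratchet).
`placodyn` extracts these statistics from raw z-stacks:

1. **Surface extraction** — the curved apical surface is fitted in each stack
   as a smooth "blanket" over the cortical membrane signal, and a quasi-2D
   image is extracted as the maximum-intensity projection of the 1–1.5 µm
   layer of tissue below it.
2. **Segmentation and tracking** — apical cell outlines are found by an
   adaptive (block-normalized) watershed, linked through time by maximal
   mutual overlap, and filtered by QC rules (cell size, relative speed to
   neighbors, area-change rate, field-of-view clipping, lineage length).
3. **Intensity partitioning** — per cell, myosin fluorescence is split into a
   *medial* pool (cell polygon offset inward by a junctional band width) and
   a *junctional* pool, and reported above the epidermal base level.
4. **Fluctuation analysis** — traces are detrended with a 6-min boxcar;
   myosin cycles run trough→trough and cell-radius cycles peak→peak; each
   cycle has a length, an amplitude (max − min of the detrended signal) and
   an **activity** = amplitude × frequency.  Instances with activity below a
   threshold (0.5 for myosin, 0.005 for radius, in detrended signal units ×
   min⁻¹) are classified non-fluctuating.
5. **Phase and spatial statistics** — pooled cycle instances give the phase
   relationship between detrended medial myosin and the detrended inverse
   cell radius, r⁻¹ (the lead, in cycles, positive = myosin ahead), radial
   profiles of activity and area-change rate around the invagination pit
   (mean ± 1.96·SEM per 5-µm bin), and the neighbor-dispersion statistic
   Dᵢ = |N(i)|⁻¹ Σⱼ |Aᵢ − Aⱼ| that distinguishes clustered from scattered
   constriction.
6. **Statistics** — two-sample Kolmogorov–Smirnov, G test of independence
   (G = 2 Σ O ln(O/E)), and two-tailed Student's/Welch's t tests.

Because no public movies accompany this kind of dataset, the package includes
a first-class **synthetic placode generator** (`placodyn.synthetic`): a
Voronoi epithelium on a curved surface with per-cell raised-cosine myosin
oscillations, a configurable myosin→constriction lag, ratcheting, a radial
activity gradient, myosin flow blobs, PSF blur and photon noise — with full
ground truth retained, so every stage of the pipeline is verifiable.

## Worked example

```python
import placodyn as pl

movie = pl.default_scene(seed=7)          # ~150 placodal cells, 15 min
results = pl.PlacodeAnalysis(movie).fit() # full pipeline
print(results.summary_text())
```

prints

```
placodyn pipeline summary
-----------------------------------------
tracked placodal cell instances : 7445
  with myosin fluctuations      : 5923 (79.6%)
  of those, radius fluctuating  : 5726 (96.7%)
myosin cycles pooled            : 792
mean myosin cycle length        : 145.9 s
myosin lead over 1/radius       : 0.135 cycles
```

The generator was asked for 150 s mean cycles with the inverse radius
trailing myosin by 0.125 cycles; the measured movie — after surface fitting,
segmentation, tracking, QC and detrending — returns 145.9 s and a lead of
0.135 cycles, i.e. the pipeline recovers the generating dynamics to within a
frame interval and a few hundredths of a cycle.  `results.tracks_`,
`results.cycles_`, `results.phase_average_.bins` and
`results.radial_activity_` hold the underlying per-instance, per-cycle,
per-phase-bin and per-radial-bin tables (the radial activity profile falls
from ~2.0 near the pit to ~1.3 at 40 µm, reflecting the generator's radial
activity gradient).

A command-line interface mirrors the library:

```
placodyn simulate --seed 7 --out scene/
placodyn analyze --input scene/movie.ome.tif --pit 52 52 \
    --placode-ellipse 40 40 35 35 --out analysis/
placodyn report --counts counts.csv --out report/
```

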