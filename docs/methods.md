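# Methods

## Scientific setting

Stress-induced hyperthermia (SIH) is the rapid rise in core and body-surface
temperature that follows an acute stressor in mammals, accompanied by
peripheral vasoconstriction that *cools* the tail — the mouse's main
thermoregulatory "thermal window".  Quantifying SIH non-invasively therefore
requires three temperatures per animal and timepoint:

* `T_sc` — subcutaneous temperature from an implanted thermosensitive
  PIT-tag, readable only within the reader's 33–43 °C window;
* `T_body` — mean surface temperature of the segmented body region in a
  radiometric infrared image;
* `T_tail` — mean surface temperature of the segmented tail region.

The package implements the measurement chain (frame I/O → animal detection →
body/tail split → per-region statistics → trial aggregation) and the
statistics used to summarize SIH (grand means with t-based confidence
intervals, per-animal deltas, repeated-measures ANOVA on time with
sphericity handling, factorial between-animal ANOVA, Šidák-corrected
contrasts).  Three behavioural protocols define the schedules:

| protocol | duration | IRT images | PIT readings |
|----------|---------:|------------|--------------|
| DH (daily handling)          | 2 min | 0/60/120 s       | 0/120 s |
| VIT (voluntary interaction)  | 1 min | 0/30/60 s        | 0/60 s  |
| EPM (elevated plus maze)     | 5 min | every 30 s to 300 s | 0/300 s |

Three images are captured per timepoint; frames failing quality control are
excluded before the capture-level means are averaged.

## Animal detection and body/tail split

Detection thresholds the temperature histogram with the Otsu criterion.
The histogram uses fixed-width bins (default 0.1 °C) anchored on the sample
minimum (bin centres at `min + k·width`), which makes the threshold exactly
equivariant under adding a constant to every pixel.  The selected level
maximizes the between-class variance `σ_b² = ω₀ω₁(μ₀ − μ₁)²`; because the
scene is nearly discrete (background / tail / body clusters with empty gaps
between them), the argmax is typically a plateau of tied bin edges, and the
plateau midpoint is returned — a deterministic, symmetric tie-break.

A mouse scene is tri-modal, and the Otsu argmax settles in whichever of the
two histogram gaps (background–tail or tail–body) yields the larger
between-class variance; for realistic area fractions this is usually the
tail–body gap, so a raw Otsu cut amputates the tail.  The detected blob
(largest 8-connected component above threshold, minimum 50 px) is therefore
grown by geodesic dilation to all pixels above `threshold − margin_delta`
that are 8-connected to it.  The margin must bridge the threshold-to-tail
gap while staying above the arena background; the default is **4.0 °C**,
which for typical scenes (body ≈ 29, tail ≈ 24, floor ≈ 20 °C) places the
rescue level near 22–23 °C.  Sweeping this margin on noise-free phantoms
shows 2 °C amputates a 24 °C tail (threshold ≈ 26.5 °C) while 4 °C recovers
the rendered ground-truth mask exactly.  When the argmax instead lands in
the background–tail gap the whole animal is already in the seed and the
margin would dip into the background; a rescue that floods more than
`max_animal_frac` (default 25 %) of the frame is for that reason abandoned
in favour of the seed component.

The body/tail split replaces the original tool's learned segmentation with
a morphological procedure exposing two parameters: opening with a disc of
radius 3 px removes structures thinner than the disc, the largest surviving
component is the body core, and among the residue components the largest
one whose skeleton elongation (`len(skeleton)²/area`, i.e. length over mean
width) reaches 4.0 becomes the tail.  Other residue pixels — boundary
shavings of the opening — are merged back into the body.  Absence of a tail
is a flagged, non-fatal outcome.  A coarse-ROI mode is also provided, where
the user supplies a rectangle containing the tail and excluding the body;
animal pixels inside the box become the tail.

Quality control is rule-based, standing in for the study criterion "full
body visible": a frame is excluded when the animal touches the frame
border, when its area falls outside 0.5–1.5× the session median (a rearing
animal projects a much smaller blob), or when a required tail was not
found.  All three bounds are configurable.

## Synthetic phantoms and cohorts

A phantom is an elliptical body (semi-axes ~16–20 × 9–12 px) with a
tapering curved tail (half-width 2.2 → 1.0 px) on a uniform background,
rendered into a 120×160 raster.  Zero-mean uniform texture (±0.2 °C) is
renormalized so the mean over the true body (tail) pixels equals the latent
body (tail) temperature *exactly* before i.i.d. Gaussian sensor noise
(default SD 0.05 °C, matching a ≤50 mK camera) — so measurement recovery
can be asserted against latent values with no geometric bookkeeping.
Optional extras: a warm distractor disc (e.g. a handling tunnel), partial
body erasure as a rearing surrogate, and deliberate border clipping for QC
test cases.

Latent temperatures follow an additive model per animal `i`, measure `m`,
scheduled second `t`:

    T[i,m,t] = baseline_m(t) + Σ_f centred effect of factor f
               + a[i,m] + e[i,m,t]

with `a ~ N(0, σ_animal)` shared across timepoints and
`e ~ N(0, σ_resid)` independent per timepoint.  Baselines are the published
grand-mean trajectories of each protocol; factor effects (light/dark
period, strain, sex, handling technique, drug, within-cage testing order)
are stored as full level differences and applied as centred deviations
(±d/2), so grand means stay on the baseline trajectory while every
two-level contrast recovers the configured difference.  Where no magnitude
was reported for a cell, the effect is zero.  EPM baselines between the
printed endpoints are filled by monotone linear interpolation — a modelling
choice, not data.  EPM phantoms carry no tail, because the maze is imaged
from far above and tail temperature is not assessed in that protocol.

Variance components are assumptions, not published values:
`σ_animal = 0.30 °C`, `σ_resid = 0.15 °C`, sensor noise 0.05 °C, chosen so
that a 64-animal cohort yields confidence-interval half-widths near
±0.04 °C, the order of magnitude reported for the real cohort of 68.

The default design houses animals in pairs sharing strain, sex and handling
(as in the study); testing order within each cage, and for EPM the
drug/vehicle assignment within each cage, are randomized per cage.  For DH
the light/dark period alternates across cage rounds so each factor cell
sees both periods.  Trios occur rarely in real cohorts and are not part of
the default design; a user-specified design with a third cage-mate gives
that animal the later-tested deviation.

What the generator does **not** emulate: pose articulation and fur
heterogeneity, motion blur, emissivity and reflected-temperature physics,
drift of an uncalibrated camera, occlusion by the tunnel during VIT, and
behaviour-coupled temperature dynamics.  Passing recovery tests therefore
demonstrates that the pipeline is unbiased and well calibrated *given*
calibrated radiometric input and single-animal scenes — not that the
morphological split matches a learned segmenter on real fur.

## Statistics

* `mean_ci` — t-based interval `mean ± t(1−α/2, n−1)·sd/√n`.
* `delta_t` — last minus first scheduled second; positive = hyperthermia.
* Sphericity: orthonormal polynomial contrasts `C` (deterministic sign
  convention) give the contrast covariance `S_c = C'SC`;
  Greenhouse–Geisser `ε = (Σλ)²/((k−1)Σλ²)` from its eigenvalues, bounded
  to `[1/(k−1), 1]`; Mauchly's `W = det(S_c)/(tr(S_c)/(k−1))^(k−1)` with
  the standard chi-square approximation on `k(k−1)/2 − 1` df.  Both match
  an independent Helmert-basis oracle to 1e−10 and the `pingouin`
  implementations to the same precision (`pingouin` adds Box's
  second-order term to the Mauchly p-value; the W and chi-square agree).
* `rm_time_anova` — one-way within-subject F = MS_time / MS_(time×subject),
  with GG-adjusted degrees of freedom.  Under spherical and AR(1) (ρ=0.7)
  nulls the GG-corrected test holds the 5 % level within [0.03, 0.07]
  (2000 replicates each).
* `between_anova` — factorial fixed-effects OLS with sum-to-zero coding,
  main effects plus two-way interactions, type-II sums of squares.
  Interactions with empty cells, and designs without residual degrees of
  freedom, are reported as aliased rather than silently dropped.  For every
  two-level factor the level difference is also estimated directly with a
  Welch interval, in the simulator's canonical direction (dark−light,
  tunnel−tail, BALB−B6, M−F, diazepam−vehicle).
* `sidak` — `1 − (1−p)^m`, computed via `expm1`/`log1p` so the identity
  `p_adj ≥ p_raw` survives for p near machine precision.
* The original mixed design (time × several between factors) is decomposed
  into the within-subject time test plus factorial ANOVAs on per-animal
  baselines and deltas: the same scientific contrasts, estimable on any
  complete-case table.  Missing values propagate as missing; analyses are
  complete-case per contrast.  Animals tested third are only analyzed
  where the design has them.

## Numerical and design notes

* Frame containers: 16-bit radiometric TIFF (DN → °C linear, default
  0.01 °C/DN, calibration echoed in a `.cal` sidecar) and a comma-separated
  DN matrix.  DNs are quantized to integers; round trips are exact to half
  a DN step.  Decoded temperatures outside 0–50 °C are treated as a
  mis-declared dialect and rejected.
* Out-of-window PIT values become missing, never clamped.
* Timepoint schedules are closed sets per protocol; off-schedule rows are
  rejected at parse time because the whole analysis is keyed on scheduled
  seconds.
* Otsu ties are broken at the plateau midpoint; plateau membership uses a
  1e−9 relative tolerance on `σ_b²`.
* Per-animal intercepts are drawn independently per measure; the model does
  not impose cross-measure correlation (a known simplification — in real
  animals `T_sc` and `T_body` co-vary and `T_tail` anti-varies).
* Problem sizes: recovery checks use 64-animal cohorts averaged over five
  seeds (the full pipeline renders and segments ~580 frames per DH/VIT
  cohort and ~2100 per EPM cohort); calibration studies use 2000 synthetic
  replicates, segmentation properties 200 random poses.

## Known limitations

* The morphological body/tail split assumes a single animal whose tail is
  thinner than the opening disc and longer than four times its width;
  curled tails lying against the flank will be merged into the body and
  flagged as absent.
* The Otsu detector assumes the animal is the largest warm object; a
  distractor warmer and larger than the mouse would be mislabelled.
* EPM tail temperature is neither simulated nor measured, mirroring the
  protocol's imaging geometry.
* The factorial ANOVA uses sum-to-zero coding with type-II sums of squares;
  software using different coding or type-III sums will give different F
  statistics for interactions in unbalanced designs.
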