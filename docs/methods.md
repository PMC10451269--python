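# Methods

## Problem and measurement model

During robot-assisted therapy sessions for autistic children, a
therapist scores the child's behaviour on a per-task assessment sheet
while a camera records the child's face. `engagekit` implements the
automated counterpart of that assessment: per-frame facial engagement
classification, session-level engagement percentages, and a
chance-corrected comparison between the two raters.

Engagement is defined on Russell's circumplex model of affect.
Every affective state is a point (v, a) with valence v (pleasantness)
and arousal a (activation), both in [-1, 1]. A frame is *engaged* iff
it falls in the open positive-positive quadrant:

    engaged(v, a)  <=>  v > 0  and  a > 0

Axis points (v = 0 or a = 0) are conservatively labelled not engaged;
the model defines engagement strictly inside the quadrant and an exact
zero carries no evidence of positive affect. The map is invariant to
positive rescaling of the coordinates.

Two session-level percentages are computed per task:

* **EPM** (engagement percentage, model)
  `EPM = 100 * n_engaged_frames / n_total_frames`
* **EPT** (engagement percentage, therapist)
  `EPT = 100 * sum_points / max_points`, where the sheet has 8 items
  scored 0 ("strongly disagree") to 3 ("strongly agree"), so
  `max_points = 24` per task.

Per-child overall values are the **unweighted arithmetic mean of the
per-task percentages, rounded half-up to an integer percent**. This
aggregation rule was chosen because it reproduces four of the five
published per-child overalls exactly from their printed per-task values
(83.67 -> 84, 41.33 -> 41, 15 -> 15, 9.33 -> 9), whereas frame-weighted
pooling does not (82.7 for the first child). The remaining child (C2)
prints 14 where the mean of its printed task values gives 13.33 -> 13;
the most plausible explanation is that pre-rounding task values entered
the published mean. The package reports this child as matching within
±1 and flags it, rather than guessing a different rule.

Agreement between model and therapist binarizes both overall
percentages at an **inclusive 50% threshold** (>= 50 is "engaged") and
computes Cohen's kappa from the 2x2 contingency table,
`kappa = (p_o - p_e) / (1 - p_e)`. Interpretation bands follow the
conventional scale: <= 0 no agreement, 0.01-0.20 slight, 0.21-0.40
fair, 0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00 almost
perfect. Two conventions close gaps in that scale: values in (0, 0.01)
map to "slight" by continuity, and degenerate constant-label tables —
easy to hit with five subjects — are defined explicitly (both raters
constant and identical: kappa = 1; constant but different: kappa = 0)
and flagged instead of raising. Bands are always read from the
unrounded kappa.

## Frame pipeline

Each recording (video file, or directory of frames in lexicographic
order — the codec-free path used throughout testing) is converted to a
grayscale frame stream (BT.601 luma), then per frame:

1. **Face detection.** The default "synthetic" backend thresholds the
   frame and takes the largest connected component; an external
   pretrained detector can be registered under the same two-callable
   contract (detect -> box, landmark -> 68 points). No model files are
   bundled.
2. **Landmark extraction.** 68 points in the iBUG-300W ordering
   (jaw 0-16, brows 17-26, nose 27-35, eyes 36-47, mouth 48-67).
3. **Normalization.** Landmarks are mapped to a canonical similarity
   frame: inter-ocular midpoint at the origin, inter-ocular axis
   horizontal, inter-ocular distance (eye-centroid to eye-centroid)
   equal to 1. This cancels face position, scale and in-plane rotation.
4. **Rasterization.** Normalized landmarks are stamped as Gaussian
   blobs (sigma 1 px) into a fixed canonical window
   (x in [-1.6, 1.6], y in [-1.0, 2.6]) on a 64x64 single-channel
   raster scaled to [0, 1]. Points outside the window are clipped and
   counted in a warning. This bridges the saved (x, y) coordinates to
   a convolutional input while keeping the classification
   position/scale invariant.
5. **Classification.** A small CNN: conv 32 filters 3x3 + ReLU + 2x2
   max-pool, conv 32 3x3 + ReLU + pool, conv 64 3x3 + ReLU + pool,
   flatten, dense 2-way head (engagement / non-engagement). Decision is
   arg-max; ties resolve to not-engaged. The filter counts and kernel
   size are validated, not tunable.

A frame where detection or extraction fails is flagged no-face and
never aborts the session. Two auditable policies govern such frames in
EPM: `count_not_engaged` (default — they stay in the denominator) and
`exclude` (dropped from numerator and denominator). Both are recorded
in the per-task metrics.

The network and its training loop are implemented directly on numpy
(im2col convolution, Adam, softmax cross-entropy, float32). Training
uses a seed-fixed shuffled 80/20 split, batch size 32, learning rate
1e-3, 5 epochs on 2,000 synthetic frames by default; with a single
BLAS thread this takes on the order of three minutes. All randomness
flows through `numpy.random.Generator` seeds, so identical seeds give
identical weights, history and predictions.

## Synthetic sessions

No recordings are distributable, so the generator produces fully
labelled sessions with the statistical structure the analysis assumes:

* **Dynamics.** A two-state Markov chain over {engaged, disengaged}
  with configurable stay-probabilities (default 0.9/0.9, giving a
  stationary engaged fraction of 1/2 and realistic multi-second bouts
  at 10 fps). The engaged state emits (v, a) uniform in the positive
  quadrant; the disengaged state picks one of the other three quadrants
  uniformly — the published definition never distributes the
  non-engaged class over quadrants, and the uniform choice keeps the
  null symmetric. Emitted magnitudes keep a 0.1 margin from the axes:
  exactly-neutral affect is not a meaningful emitted state, and the
  margin keeps the rendered expression resolvable at pixel scale.
* **Rendering.** A schematic grayscale face (filled ellipse, jaw,
  brows, nose, eye polygons, mouth band) whose geometry is strictly
  monotone in the affect coordinates: valence lifts the mouth corners
  (parabolic midline, amplitude 0.13 face-heights per unit valence),
  arousal opens the eyes and thickens the lip band. Feature intensity
  levels are distinct so the synthetic landmark backend can recover the
  expression: the mouth-band corner drop is exactly linear in valence
  (vertical shear of a band symmetric about its midline) and the band's
  pixel area exactly linear in arousal (shear preserves per-column
  counts), each calibrated per box size by re-rendering the template at
  the quadrant extremes. Gaussian landmark jitter (`landmark_noise_px`)
  is applied to the drawn polygons and recorded in the truth manifest.
* **Session layout.** Default three tasks of 19/8/19 s at 10 fps
  (configurable per task; frame counts are `round(duration * fps)`),
  128x128 PNG frames, a CSV manifest with per-frame VA, engagement,
  box and landmarks, and therapist sheets whose 8 items per task score
  `clip(round(3 * (true_fraction + noise)), 0, 3)` with Gaussian rater
  noise (default sd 0.1).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: photographic appearance, head pose,
occlusion, identity variation, illumination, motion blur, or any real
detector's failure modes. The end-to-end results certify that the
pipeline's stages compose correctly and recover known ground truth, not
that the classifier's accuracy transfers to clinical video. Plugging a
pretrained backend into the same contract is the intended path to real
recordings.

## Numerical choices and degenerate inputs

* Rounding of aggregated percentages is half-up (`floor(x + 0.5)`),
  matching the published integer overalls.
* Frame subsampling picks nearest-native-timestamp frames.
* A rasterized ellipse extends its analytic extent by one pixel per
  axis; the detector's box inversion corrects for this.
* Degenerate cases are explicit errors: empty frame sets, zero-area
  boxes, coincident eye centroids, single-class training data, metric
  denominators emptied by the exclude policy.
* Problem sizes in the validation suite — 2,000 training frames, 5
  epochs, 457-frame sessions, 100-frame detection batches — were chosen
  as the smallest sizes at which the measured quantities are stable.

## Known limitations

* The synthetic landmark backend is exact for the schematic face family
  only; it is a test harness, not a face analyzer.
* Kappa is reported without confidence intervals (with five subjects an
  interval would span nearly the whole band scale).
* The classifier is trained on the generator's landmark distribution;
  no claim is made about transfer to other landmark sources without
  retraining.
* Whether the published analysis excluded undetectable-face frames is
  unknown; both policies are implemented and the choice is always
  recorded in the output.
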