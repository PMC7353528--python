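# Methods

This note documents the models and procedures implemented in
`sensefuse`, the defaults that matter, the design decisions that were
genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## The prediction problem

One trial = one participant exposed to one sample (a flavor tasted or
an odor smelled) for roughly ten seconds, yielding three time series —
per-frame facial-expression probabilities, galvanic skin response (GSR)
and cardiac pulse — plus a reported hedonic score on a seven-point
scale coded −3…+3. The package predicts the score from the implicit
signals alone and ranks which signals carry the information.

## Face preprocessing

Eight deterministic steps map a frame to four aligned sections:
grayscale (ITU-R BT.601 weights 0.299/0.587/0.114), HoG face detection,
68 landmarks, rotation that levels the inner eye corners (landmarks 40
and 43 in the standard 68-point numbering), a four-way section split,
mirroring of the right sections, CLAHE, and division by 255.

Design choices the pipeline fixes (all configurable):

* **Section geometry.** The eyes region spans the vertical extent of
  landmarks 18–48 (brows through eyes), the nose-mouth region landmarks
  28–68; both are split at the vertical midline through the nose-bridge
  landmarks 28–31 and expanded by a 10 % margin. Sections are sampled
  at 64×64 with sub-pixel bilinear interpolation (this keeps
  mirror-symmetric faces exactly mirror-consistent, which an integer
  crop would not); out-of-frame coordinates are edge-padded.
* **"First face detected"** = highest detector score, ties broken by
  leftmost box.
* **CLAHE** uses `skimage.exposure.equalize_adapthist` with a
  normalized clip limit (default 0.02) on an 8×8 tile grid. Constant
  sections pass through unchanged.
* **Rotation** resamples bilinearly with edge padding.

Two components are deliberately minimal, built for synthetic imagery
because this package's test bed is synthetic:

* The **detector** is a multi-scale sliding-window HoG scorer (9
  orientations, 8×8 cells, 2×2 blocks, L2-Hys) with a ridge-regressed
  linear weight vector, trained lazily and deterministically on the
  package's own schematic-face renders against structured negatives
  (gradients, stripes, blobs, badly framed or badly scaled faces,
  adjacent half-faces). Greedy non-maximum suppression removes
  cross-scale duplicates.
* **Landmark localization** anchors a canonical 68-point shape to the
  detected face by finding the two dark eye blobs inside the box; the
  interocular segment fixes translation, scale and in-plane roll. It is
  a similarity-transform shape model, not a trained cascade regressor,
  and it assumes schematic-face contrast structure. On the schematic
  fixtures it is accurate to fractions of a pixel and exactly
  translation-equivariant.

## Two-stage emotion classifier

Stage 1: two networks share one architecture — 64×64×1 input, three
blocks of (three 3×3 same-padded convolutions + 2×2 max-pool), then
four dense layers, the last a 10-way softmax; all hidden activations
ReLU. Network A scores the two eye sections (the right one mirrored, so
both sides share weights), network B the two nose-mouth sections.
Stage 2 concatenates the four 10-vectors — order: eye_left,
eye_right_flipped, mouth_left, mouth_right_flipped — into a 40-vector
and maps it through two dense ReLU layers to a final 10-way softmax.

Widths are defaults of this implementation, not structural facts:
filters 32→64→128, dense 256-128-64, stage-2 widths 32-16. A narrow
`TOY_NETWORK` (4→8→8, 32-16-16) is used for desk-scale work. Training:
softmax cross-entropy with Adam (default learning rate 1e-3), 50 epochs,
batch 128, inverted dropout 0.4 after each dense hidden layer,
validation fractions 0.20 (stage 1) and 0.15 (stage 2). The stack is
pure numpy (im2col convolutions, analytic gradients, float32) and is
bit-reproducible under a fixed seed; gradients are verified against
finite differences in the test suite. The capacity check trains the toy
configuration for 100 epochs at learning rate 2e-3 with dropout off on a
40-image grating dataset; the problem sizes keep a full run on one CPU
in the low minutes.

Per-frame results are written to CSV: image index, number of faces
(−1 when detection failed), file name, and ten probability columns left
empty on no-face rows.

## Fusion: 44 features

Nine expressions are carried forward — by default the ten-label set
minus `uncertain`, which marks annotator indecision rather than an
expression; any 9-subset is accepted. Frames without a detected face
are dropped rather than imputed. Each stream (nine expression columns,
GSR, pulse) is reduced to average, **population** (divide-by-n)
standard deviation, minimum and maximum over the trial window — 44
features named `<stream>_<metric>`. No temporal alignment between the
30 fps frames and 8 Hz sensor samples is attempted: the four statistics
are rate-invariant, which removes an interpolation choice entirely. A
single sample summarizes to (x, 0, x, x); a trial with any empty stream
is unusable and is skipped or raised per caller policy.

## Regression forest

The predictor is written from scratch because its importance
bookkeeping is the point.

* **Impurity** of a node is the MSE about the node mean, i.e. the
  variance of its responses.
* **Split search** is exhaustive: candidate thresholds are midpoints
  between consecutive distinct sorted values of each candidate feature;
  the chosen split maximizes the impurity reduction
  `IR_j = w_j I_j − (w_left I_left + w_right I_right)` with weights
  `w = n_node / n_total` relative to the tree's training set. Ties
  break deterministically to the lowest feature index, then the lowest
  threshold. Splits with gain ≤ 1e−12 are treated as no improvement.
* **Stopping**: pure nodes, nodes with fewer than 2 samples, an
  optional depth cap; leaves predict their mean.
* **Forest**: 30 trees by default, each grown on a bootstrap sample
  (n draws with replacement) and a per-tree random feature subset of
  size ⌈p/3⌉ (the regression convention). Prediction averages trees.
* **Importance**: per tree, each feature's share of the summed IR over
  the tree's internal nodes (sums to 1); the forest importance is the
  mean of per-tree shares. Trees that never split carry no importance
  information and are excluded from the average, keeping the report
  normalized.
* **Evaluation**: ten-fold cross-validation — a seeded random partition
  into ten near-equal blocks, one held out per fit — reporting the mean
  of per-fold MAEs. The five-subset benchmark (all 44 / 36 emotion
  features / 8 sensor features / GSR alone / pulse alone) reuses one
  fold partition per seed so subsets are compared split-for-split.

Hot loops (split scan, tree growth, prediction) are numba-compiled;
trees are stored as flat arrays and can be materialized as a node graph
for inspection. The split search is verified against an independent
brute-force search, single trees against scikit-learn's
`DecisionTreeRegressor` (predictions exactly; importances to ~1e−4 —
the two implementations accumulate cancellation-prone node variances in
different orders, and in tiny nodes exactly tied gains may resolve to
different but equivalent splits).

## Synthetic cohorts

The generator emulates the study design: 120 participants × 10 samples
(five flavors, five odors), 10 s trials, 30 fps emotion frames, 8 Hz
sensors, a 2 % no-face frame rate, and a seven-point score. Every
distributional choice is simulation design with a stated goal: **GSR
carries the strongest acceptance signal, pulse a weaker one, and facial
expressions a weak, noisy one** — so that recovering "GSR is the most
relevant variable" is a meaningful test of the pipeline rather than an
artifact of the generator.

Mechanics per trial, given a sample's latent valence v ∈ [−1, 1]:

* **Expressions**: per-frame Dirichlet draws whose concentration
  weights are dominated by sadness and disgust regardless of liking
  (participants concentrate during tasting); happiness (v > 0) or
  disgust (v < 0) receives a small shift scaled by a per-participant
  expressiveness factor (U(0.3, 1.7)) and a per-trial Beta(1.2, 1.8)
  attenuation — many trials show almost no facial gesture, and the
  participant-level factor confounds expression strength with identity.
* **GSR**: baseline (participant-specific) + drift·t + white noise.
  Disliked samples impose a drift (slow rise for clam, abrupt fall for
  Gouda cheese and smoke) and the noise scale grows with arousal |v|,
  so `gsr_std` tracks the elicited reaction closely. Vinegar is
  deliberately a weak reactor: disliked on paper, physiologically
  quiet.
* **Pulse**: baseline + white noise whose scale grows mildly with
  emotional intensity, plus a small intensity-dependent mean dip.
* **Score**: round(3v + N(0, 0.5)) clipped to [−3, 3].

The manifest records every latent parameter (profiles, participant
physiology, config) for recovery tests.

What the simulator does **not** capture: real facial appearance (no
photorealistic rendering — the image pipeline is exercised on schematic
faces), chewing occlusion and head pose, tonic/phasic GSR decomposition
or physiologically mechanistic pulse dynamics, inter-trial carryover,
and panel-order effects. Passing recovery tests therefore shows the
*pipeline* is sound — fusion, prediction and importance ranking recover
a planted effect — not that the specific physiological effect sizes are
realistic.

## Recovery study conditions

The acceptance checks run 20 replicate cohorts at the default scale
(120 × 10) and evaluate the five-subset benchmark and importance
ranking on the taste panel (600 trials; the smell panel contains the
deliberately weak vinegar profile, mirroring the source design). The
criteria are majority-vote across replicates: "GSR only" attains the
lowest mean MAE, and `gsr_std` appears in the importance top-3. Both
hold in 20/20 replicates under the default generator.

## Known limitations

* The detector and landmark localizer are built for schematic imagery;
  they are not general-purpose face-analysis components.
* The numpy network trains toy-scale problems in minutes; full-scale
  expression corpora would need a GPU framework behind the same
  interfaces.
* MAE values on synthetic cohorts are on the same seven-point scale as
  a real panel but are not comparable in magnitude to human data — the
  simulator's noise structure is simpler than human reporting noise.
* Classification-mode forests, permutation importance and
  frequency-domain sensor features are out of scope.
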